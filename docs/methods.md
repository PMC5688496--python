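# Methods

## The data-generating model

The generator emulates a randomised, double-blind, placebo-controlled
crossover trial of microdose rHuEpo: `n_subjects = 14`, arms
(rHuEpo, placebo), and 13 timepoints — three baselines (B1–B3 at days
−14, −7, 0), seven weekly administration samples (D1–D7, days 3–45)
and three post-administration samples (P1–P3, days 52–66). Each
(subject, arm, timepoint) block yields duplicate assay measurements.

Expression of marker *g* in subject *j* at timepoint *t* follows a
two-level Gaussian model on the log2 scale:

    x_gjt = μ_g + b_gj + δ_g(t)·1[arm doped] + ε_gjt
    b_gj ~ N(0, σ²_between,g),   ε_gjt ~ N(0, σ²_within,g)

with `b_gj` drawn once per (marker, subject) and shared across the two
arms of the crossover (the same person participates in both; no
carryover term is modelled, matching the per-arm analysis downstream).
The doping effect δ_g(t) is a step function keyed by timepoint label —
per-timepoint log2 fold-changes are the natural resolution of a weekly
sampling grid. Default μ_g, σ²_within, σ²_between for the 41
analysable transcripts come from the packaged per-marker summary
fixture, and the default δ trajectories plant the published
up-at-D2–D5 / down-at-P1–P3 response in the eleven consistently
responding markers; all other markers are null under both arms.

The latent value maps to a bead-assay readout `MFI = ref_level·2^x +
background` with mean-one multiplicative log-normal duplicate jitter at
a target CV (default 10.6%, the observed assay precision). Reference
probes sit at a constant latent level, so reference-geometric-mean
normalisation recovers `x` exactly in the noise-free limit. The
background magnitude (10 MFI), the detection floor (0.5 MFI), the
reference scale (1000 MFI) and the LOD rule (adjusted MFI > 10 in ≥
80% of samples) are package choices — the corresponding laboratory
values are not published — and are configurable. Four low-abundance
placeholder targets (LOWXPR1–4; the real below-detection transcripts
are unnamed) sit far below the LOD so a default run analyses 41 of 45
targets, mirroring the study's attrition. Whole sample blocks are
dropped independently with probability 21/364, matching the observed
343-of-364 sample yield in expectation; dropping acts on blocks, not
replicates, because samples (not wells) go missing in practice.

Haematology (HGB in g/L, HCT %, RET %) uses the same
between/within-subject decomposition around `baseline_mean ×
trajectory(t)` in the doped arm. Baselines are HGB 150 g/L (variance
components 29/36, all from the packaged summary), HCT 44%, RET 0.94% —
the RET baseline solves OFF = HGB − 60·√RET = 92, the cohort's mean
OFF-score. Trajectory multipliers are chosen once to match the
reported qualitative shape: HGB/HCT rising gradually to a peak one week
after the last injection (+7%), RET elevated during administration
weeks 1–4 (up to +60%) then suppressed to 55–70% of baseline
throughout the post phase. The OFF column is always derived, never
simulated.

What the generator does *not* emulate: pharmacokinetics of
erythropoiesis, iron status, exercise or altitude biology (the
MDS-exercise and ATS-runners presets only re-label the same machinery),
assay drift, batch effects, or heavy-tailed/heteroscedastic noise.
Passing tests therefore demonstrate correctness of the statistical
machinery under its own assumptions, not field performance on real
athletes.

## Normalisation

Fixed order: average technical replicates on the MFI scale →
`max(MFI − background, floor)` → divide each sample's targets by the
geometric mean of its five reference probes → log2. Averaging before
the log matches the convention of computing duplicate CVs on the MFI
scale; the alternative (normalise per replicate, then average logs)
differs by Jensen's inequality and is deliberately not used. The floor
keeps the log defined at a configurable positive value. Normalisation
is scale-invariant per sample, which is the point of ratio
normalisation: a global intensity factor cancels.

## Differential expression

Within-subject pairing is handled in closed form: each subject's
baseline mean (all baselines by default, `baseline_mode="single"` for
the last one) is subtracted from their later observations, cancelling
the subject offset; the per-timepoint coefficient is the mean of those
paired differences over subjects and the crossover contrast
(`diff:<t>`) is the subject-paired difference of the two arms'
baseline-subtracted values. This randomised-block estimator replaces a
full mixed model; it is unbiased for δ and its pooled residual
variance (expectation σ²(1 + 1/n_baseline)) scales the coefficient
variances consistently, so the t statistics are calibrated — verified
by a type-I-error simulation. The residual degrees of freedom ignore
the weak correlation among timepoint deviations induced by the shared
baseline; the calibration test bounds the practical effect.

Variance moderation is re-implemented rather than delegated: the
per-marker sample variances are modelled as s₀²·F(df, d₀); matching
mean and variance of log s² through digamma/trigamma identities gives
the method-of-moments estimates, with the trigamma equation inverted by
Newton iteration. Shrunken variances s̃² = (d₀s₀² + df·s²)/(d₀ + df)
feed moderated t (d₀ + df degrees of freedom) and an overall F
aggregating the doped arm's timepoint contrasts. Exactly constant
sample variances short-circuit to the common value (the log-scale bias
correction assumes sampling scatter such data do not show). The
implementation is cross-checked in the test suite against limma's
`squeezeVar` on simulated variances; limma is never called by the
package itself.

Significance is FDR < 0.05 (Benjamini–Hochberg, per contrast across
markers; ties resolved by the stable order of the input) combined with
a signed fold-change magnitude ≥ 1.5 (|log2FC| ≥ log2 1.5; the signed
transform is sign(L)·2^|L| with sign(0) = +1). The selection cascade
nests four stages: S1 overall-F significant; S2 ⊂ S1 significant at
P1; S3 ⊂ S2 with ≥1.5-fold at D2; S4 ⊂ S3 up ≥1.5-fold at D2–D5 and
down ≤−1.5-fold at P1–P3. Two of the default planted trajectories
(DCAF12, TMOD1) have administration-phase effects of 0.60–0.61 log2 —
on the log2 1.5 = 0.585 boundary — so their S4 membership is
intrinsically a coin flip at finite n; the tests assert recovery of
the clear-margin markers only.

## Haematology testing

Per-timepoint inference on blood markers uses the same paired
within-subject contrast (two-sided one-sample t on baseline-subtracted
values) with Holm step-down adjustment across timepoints. This
replaces the original mixed-model/post-hoc-interaction analysis, whose
exact specification is not reproducible; the substitution preserves the
within-subject design and the stated multiplicity correction. The
OFF-score constant (60) and units (HGB g/L, RET %) follow the standard
ABP OFF-hr definition; the package works in g/L internally.

## Adaptive passport model

"Universal components of variance" is read as one (σ²_w, σ²_b) pair
per marker shared by all subjects. Components are estimated from
placebo profiles by one-way random-effects ANOVA: σ̂²_w = MS_within,
σ̂²_b = (MS_between − MS_within)/n₀ with the unbalanced-design
effective group size n₀ = (N − Σnᵢ²/N)/(k − 1); negative
between-components are clipped to zero and flagged, never propagated.

Evaluation is sequential by default: observation *t* is tested against
the central predictive interval built from observations 1..t−1 (the
first against the prior predictive μ ± z√(σ²_b + σ²_w)); every
observation then joins the history whether or not it was atypical.
This mirrors passport practice, where each new sample is judged
against the record to date. A batch mode (all observations against the
prior predictive) is available via `sequential=False`. z uses the
two-sided convention, so "99% specificity" means a central 99%
interval; a per-observation false-positive rate of 1% compounds to
≈12% per 13-observation profile under the at-least-one-atypical rule —
the null flag rate the sensitivity of an ineffective treatment would
revert to.

Screening uses leave-one-out cross-validation: each placebo subject is
evaluated with components estimated from the other placebo subjects;
doped subjects use components from the full placebo set (they never
contribute to the clean-population estimate). Sensitivity = 100 ×
flagged doped / doped; specificity = 100 × unflagged placebo /
placebo; an empty doped set yields an explicit `None` sensitivity, not
0. The reporting layer rounds percentages to the nearest integer
(13/14 → 93).

The ROC area compares profile scores between groups by Mann–Whitney
pair counting (ties half). The profile score is the maximum over
observations of the two-sided extremeness |2F(x) − 1| under the
sequential posterior predictive — a documented design choice, as the
original percentile construction is ambiguous between per-observation
and per-profile readings; the maximum matches the
at-least-one-atypical flagging logic.

## Numerical and design notes

- All randomness flows through explicit `numpy.random.default_rng`
  seeds; there is no global state, and the pipeline derives per-stage
  seeds from the single config seed.
- Zero within-subject variance with a varying history, or zero total
  variance with history away from μ, raise degenerate-model errors;
  all-identical observations across subjects return zero components
  (a valid, if dull, estimate).
- Problem sizes in the tests are chosen for tight Monte-Carlo error at
  desk scale: variance-recovery checks average several replicates of
  200 subjects × 13 observations; coverage checks use 2000 × 13
  (≈0.06 pp standard error); the Monte-Carlo posterior-predictive
  oracle uses 10⁶ importance draws.
- `bh_fdr` and `holm_adjust` delegate to
  `statsmodels.stats.multitest.multipletests`; ANOVA, the conjugate
  update, moderation and ROC pair counting are authored here (the
  external equivalents serve as independent cross-checks in tests).

## Known limitations

- Gaussian, homoscedastic within-subject noise per marker; no
  per-subject variances, no multivariate combination of markers, no
  Bayesian network across haematological and transcriptomic modules.
- The published real-data tables cannot be re-derived (no raw data is
  deposited); the packaged summary fixture supports aggregate checks
  only, and cohort-scale simulated results (e.g. cascade sizes,
  per-marker sensitivities) fluctuate with seed at n = 14.
- Sequential limits assume exchangeable-in-time observations; true
  seasonal or training-load trends in clean athletes would inflate the
  atypical rate.
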