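"""Within-subject longitudinal differential expression with
empirical-Bayes variance moderation.

Each marker is analysed as a randomised-block contrast: every subject's
baseline mean is subtracted from their later observations, so the
between-subject offset cancels and the per-timepoint coefficient is the
mean paired difference across subjects.  Marker-level residual
variances are shrunk towards a common prior by the standard
empirical-Bayes scheme (the prior degrees of freedom d0 and prior
variance s0^2 estimated by method of moments on the log sample
variances), giving moderated t statistics with d0 + df degrees of
freedom and an overall moderated F per marker.

Significance combines a Benjamini-Hochberg FDR threshold with a signed
fold-change magnitude threshold (defaults 0.05 and 1.5).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .design import StudyDesign
from .normalisation import ExpressionMatrix

__all__ = [
    "ContrastFit",
    "ModerationState",
    "ModeratedDifferentialExpression",
    "fit_contrasts",
    "moderate_variances",
    "moderated_tests",
    "bh_fdr",
    "signed_fold_change",
    "selection_cascade",
]


@dataclass
class ContrastFit:
    """Per-marker contrast coefficients with pooled residual variance.

    ``coefficients`` is markers x contrast labels; arm contrasts are
    labelled ``"<arm>:<timepoint>"`` and crossover arm-difference
    contrasts ``"diff:<timepoint>"``.  ``var_factors`` holds the
    unscaled variance of each coefficient (multiply by the residual
    variance to get its sampling variance).
    """

    coefficients: pd.DataFrame
    var_factors: pd.Series
    s2: pd.Series
    df_resid: float
    arm_labels: dict = field(default_factory=dict)


@dataclass
class ModerationState:
    """Empirical-Bayes variance-shrinkage hyperparameters.

    d0 is the prior degrees of freedom (``inf`` when the sample
    variances are consistent with a single common variance), s0_sq the
    prior variance, and ``posterior`` the per-marker shrunken variances
    s~^2 = (d0*s0^2 + df*s^2) / (d0 + df).
    """

    d0: float
    s0_sq: float
    posterior: pd.Series
    df_resid: float


def fit_contrasts(
    matrix: ExpressionMatrix,
    design: StudyDesign,
    baseline_mode: str = "averaged",
) -> ContrastFit:
    """Closed-form within-subject contrasts for every marker.

    For each arm and non-baseline timepoint the coefficient is the mean
    over subjects of (value at timepoint - subject's baseline mean);
    ``diff:<t>`` contrasts are the subject-paired doped-minus-placebo
    differences of those baseline-subtracted values.  Residual variance
    is pooled across timepoints and arms per marker.
    """
    if baseline_mode not in ("averaged", "single"):
        raise ValueError("baseline_mode must be 'averaged' or 'single'")
    meta = matrix.sample_meta
    values = matrix.values
    base_labels = design.baseline_labels
    if not base_labels:
        raise ValueError("design has no baseline timepoints")
    if baseline_mode == "single":
        base_labels = [base_labels[-1]]
    test_labels = [lab for lab in design.labels if lab not in design.baseline_labels]

    coefs: dict[str, np.ndarray] = {}
    var_factors: dict[str, float] = {}
    arm_labels: dict[str, tuple[str, str]] = {}
    ss_resid = np.zeros(len(values.index))
    df_resid = 0
    block_diffs: dict[tuple[str, str], pd.DataFrame] = {}

    for arm in design.arms:
        cols = meta.index[meta["arm"] == arm]
        arm_meta = meta.loc[cols]
        arm_subjects = sorted(arm_meta["subject"].unique())
        bcols = cols[arm_meta["timepoint"].isin(base_labels)]
        if len(bcols) == 0:
            raise ValueError(f"arm {arm!r}: no baseline samples")
        base = values[bcols].T.groupby(meta.loc[bcols, "subject"]).mean().T
        missing_base = sorted(set(arm_subjects) - set(base.columns))
        if missing_base:
            raise ValueError(f"arm {arm!r}: subjects without baseline samples: {missing_base}")
        for t in test_labels:
            tcols = cols[arm_meta["timepoint"] == t]
            if len(tcols) == 0:
                continue
            subj = meta.loc[tcols, "subject"].to_numpy()
            d = values[tcols].to_numpy() - base[subj].to_numpy()
            label = f"{arm}:{t}"
            beta = d.mean(axis=1)
            coefs[label] = beta
            var_factors[label] = 1.0 / d.shape[1]
            arm_labels[label] = (arm, t)
            ss_resid += ((d - beta[:, None]) ** 2).sum(axis=1)
            df_resid += d.shape[1] - 1
            block_diffs[(arm, t)] = pd.DataFrame(d, index=values.index, columns=subj)

    if len(design.arms) == 2:
        doped, placebo = design.arms
        for t in test_labels:
            kd, kp = (doped, t), (placebo, t)
            if kd not in block_diffs or kp not in block_diffs:
                continue
            common = [s for s in block_diffs[kd].columns if s in block_diffs[kp].columns]
            if len(common) < 2:
                continue
            g = block_diffs[kd][common].to_numpy() - block_diffs[kp][common].to_numpy()
            label = f"diff:{t}"
            coefs[label] = g.mean(axis=1)
            var_factors[label] = 2.0 / len(common)
            arm_labels[label] = ("diff", t)

    if df_resid < 1:
        raise ValueError("not enough replication to estimate residual variance")
    coef_df = pd.DataFrame(coefs, index=values.index)
    return ContrastFit(
        coefficients=coef_df,
        var_factors=pd.Series(var_factors),
        s2=pd.Series(ss_resid / df_resid, index=values.index),
        df_resid=float(df_resid),
        arm_labels=arm_labels,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse needs y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if -dif / x < 1e-8:
            break
    return x


def moderate_variances(sample_variances, df: float, prior_df: float | None = None) -> ModerationState:
    """Estimate (d0, s0^2) by method of moments on log sample variances
    and return the shrunken per-marker variances.

    The sample variances are modelled as s0^2 times a scaled
    F(df, d0) variable; matching the mean and variance of log s^2 via
    digamma/trigamma identities yields closed-form moment equations,
    with the trigamma equation inverted numerically.  ``prior_df``
    overrides the estimated d0 (0 disables moderation).
    """
    s2 = pd.Series(sample_variances, dtype=float)
    if len(s2) < 2:
        raise ValueError("need >= 2 markers to moderate variances")
    if df < 1:
        raise ValueError("df must be >= 1")
    if (s2 == 0).all():
        raise ValueError("all sample variances are zero (degenerate)")

    if prior_df is not None and prior_df == 0:
        return ModerationState(0.0, float(np.exp(np.log(s2[s2 > 0]).mean())), s2.copy(), df)

    pos = s2[s2 > 0]
    z = np.log(pos.to_numpy())
    if np.allclose(z, z[0]):
        # exactly constant variances: the common value is the prior and
        # the shrinkage fixed point (no log-scale bias correction, which
        # assumes chi-squared sampling scatter these data do not show)
        v = float(np.exp(z[0]))
        return ModerationState(math.inf, v, pd.Series(v, index=s2.index), df)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - float(special.polygamma(1, df / 2.0))
    if prior_df is not None:
        d0 = float(prior_df)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))) if np.isfinite(d0) else float(np.exp(emean))
    elif evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)))
    else:
        d0 = math.inf
        s0_sq = float(np.exp(emean))

    if math.isinf(d0):
        posterior = pd.Series(s0_sq, index=s2.index)
    else:
        posterior = (d0 * s0_sq + df * s2) / (d0 + df)
    return ModerationState(d0, s0_sq, posterior, df)


def moderated_tests(
    fit: ContrastFit,
    state: ModerationState,
    f_contrasts: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Moderated t per contrast and overall moderated F per marker.

    Returns ``(t_table, f_table)``: the first tidy over (marker,
    contrast) with t statistics and two-sided p-values at d0 + df
    degrees of freedom, the second per marker with the F statistic
    aggregating ``f_contrasts`` (default: all contrasts).
    """
    if not fit.coefficients.index.equals(state.posterior.index):
        raise ValueError("moderation state fitted on different markers than the contrast fit")
    df_total = state.d0 + state.df_resid
    t_df = min(df_total, 1e6)
    s2_post = state.posterior.to_numpy()

    rows = []
    for label in fit.coefficients.columns:
        beta = fit.coefficients[label].to_numpy()
        se = np.sqrt(s2_post * fit.var_factors[label])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, 0.0)
        p = 2.0 * stats.t.sf(np.abs(t), t_df)
        rows.append(pd.DataFrame({
            "marker": fit.coefficients.index,
            "contrast": label,
            "log2fc": beta,
            "t": t,
            "p_raw": p,
        }))
    t_table = pd.concat(rows, ignore_index=True)

    if f_contrasts is None:
        f_contrasts = list(fit.coefficients.columns)
    missing = [c for c in f_contrasts if c not in fit.coefficients.columns]
    if missing:
        raise KeyError(f"contrasts not present in fit: {missing}")
    q = len(f_contrasts)
    num = np.zeros(len(fit.coefficients.index))
    for label in f_contrasts:
        num += fit.coefficients[label].to_numpy() ** 2 / fit.var_factors[label]
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = np.where(s2_post > 0, num / (q * s2_post), np.inf)
    f_p = stats.f.sf(f_stat, q, t_df)
    f_table = pd.DataFrame({"marker": fit.coefficients.index, "f_stat": f_stat, "p_raw": f_p})
    return t_table, f_table


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def signed_fold_change(log2fc: float) -> float:
    """Signed fold-change ``sign(L) * 2**|L|`` with sign(0) = +1.

    Renders down-regulation as a negative fold: L = -1.32 becomes
    -2.50 (expression halved-and-then-some), L = 0 becomes 1.0.
    """
    if not np.isfinite(log2fc):
        raise ValueError("log2 fold-change must be finite")
    fc = 2.0 ** abs(log2fc)
    return fc if log2fc >= 0 else -fc


def selection_cascade(
    results: pd.DataFrame,
    overall: pd.DataFrame,
    alpha: float = 0.05,
    fc_threshold: float = 1.5,
    doped_arm: str = "rHuEpo",
) -> dict[str, list[str]]:
    """The four-stage nested marker selection.

    S1: overall moderated F significant (FDR < alpha).
    S2: subset of S1 significant at the first post-administration
        timepoint (P1).
    S3: subset of S2 with |FC| >= threshold (and FDR < alpha) at D2.
    S4: subset of S3 consistently up (FC >= +threshold) at D2-D5 and
        down (FC <= -threshold) throughout P1-P3, all at FDR < alpha.

    ``results`` must be the tidy contrast table with columns marker,
    contrast, log2fc, fdr; ``overall`` the per-marker F table with fdr.
    """
    up_labels = [f"{doped_arm}:{t}" for t in ("D2", "D3", "D4", "D5")]
    down_labels = [f"{doped_arm}:{t}" for t in ("P1", "P2", "P3")]
    required = set(up_labels + down_labels)
    present = set(results["contrast"].unique())
    missing = sorted(required - present)
    if missing:
        raise KeyError(f"selection cascade requires contrasts {missing}")

    log2_thr = math.log2(fc_threshold)
    piv_fdr = results.pivot(index="marker", columns="contrast", values="fdr")
    piv_l2 = results.pivot(index="marker", columns="contrast", values="log2fc")

    s1 = list(overall.loc[overall["fdr"] < alpha, "marker"])
    p1 = f"{doped_arm}:P1"
    s2 = [m for m in s1 if piv_fdr.loc[m, p1] < alpha]
    d2 = f"{doped_arm}:D2"
    s3 = [m for m in s2 if piv_fdr.loc[m, d2] < alpha and abs(piv_l2.loc[m, d2]) >= log2_thr]
    s4 = [
        m for m in s3
        if all(piv_fdr.loc[m, c] < alpha and piv_l2.loc[m, c] >= log2_thr for c in up_labels)
        and all(piv_fdr.loc[m, c] < alpha and piv_l2.loc[m, c] <= -log2_thr for c in down_labels)
    ]
    return {"S1": s1, "S2": s2, "S3": s3, "S4": s4}


class ModeratedDifferentialExpression(BaseEstimator):
    """Longitudinal differential-expression estimator.

    Fitting computes within-subject contrasts, empirical-Bayes variance
    moderation, moderated t/F statistics and per-contrast BH-FDR; the
    tidy results land in ``results_`` (marker, contrast, log2fc, fc,
    p_raw, fdr, significant) and the per-marker overall F in
    ``overall_``.

    Parameters
    ----------
    alpha : float
        FDR threshold for calling a contrast significant.
    fc_threshold : float
        Signed fold-change magnitude threshold (1.5 means |log2fc| >=
        log2 1.5).
    baseline_mode : {"averaged", "single"}
        Compare against the mean of all baseline timepoints or only the
        last one.
    doped_arm : str or None
        Arm carrying the treatment effect; defaults to the design's
        first arm.
    prior_df : float or None
        Override for the moderation prior degrees of freedom.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        fc_threshold: float = 1.5,
        baseline_mode: str = "averaged",
        doped_arm: str | None = None,
        prior_df: float | None = None,
    ):
        self.alpha = alpha
        self.fc_threshold = fc_threshold
        self.baseline_mode = baseline_mode
        self.doped_arm = doped_arm
        self.prior_df = prior_df

    def fit(self, X: ExpressionMatrix, design: StudyDesign):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        doped = self.doped_arm or design.arms[0]
        fit = fit_contrasts(X, design, self.baseline_mode)
        state = moderate_variances(fit.s2, fit.df_resid, prior_df=self.prior_df)
        doped_contrasts = [
            c for c, (arm, _) in fit.arm_labels.items() if arm == doped
        ]
        t_table, f_table = moderated_tests(fit, state, f_contrasts=doped_contrasts or None)

        t_table = t_table.copy()
        t_table["fc"] = t_table["log2fc"].map(signed_fold_change)
        t_table["fdr"] = (
            t_table.groupby("contrast")["p_raw"].transform(lambda p: bh_fdr(p.to_numpy()))
        )
        log2_thr = math.log2(self.fc_threshold)
        t_table["significant"] = (t_table["fdr"] < self.alpha) & (
            t_table["log2fc"].abs() >= log2_thr
        )
        f_table = f_table.copy()
        f_table["fdr"] = bh_fdr(f_table["p_raw"].to_numpy())

        self.contrast_fit_ = fit
        self.moderation_ = state
        self.results_ = t_table
        self.overall_ = f_table
        self.doped_arm_ = doped
        return self

    def selection_cascade(self) -> dict[str, list[str]]:
        return selection_cascade(
            self.results_, self.overall_, self.alpha, self.fc_threshold, self.doped_arm_
        )
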