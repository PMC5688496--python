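"""Adaptive Bayesian individual reference ranges for longitudinal
biomarker profiles (the Athlete-Biological-Passport model).

Each marker is described by universal variance components: a population
mean mu, a between-subject variance sigma2_b (spread of individual
set-points) and a within-subject variance sigma2_w (fluctuation around
a set-point).  A subject's unknown set-point theta has prior
N(mu, sigma2_b); observations are N(theta, sigma2_w).  After n
observations with mean xbar the conjugate Normal-Normal update gives

    m_n   = (mu/sigma2_b + n*xbar/sigma2_w) / (1/sigma2_b + n/sigma2_w)
    tau2_n = 1 / (1/sigma2_b + n/sigma2_w)

and the next observation is predicted N(m_n, tau2_n + sigma2_w).
Reference limits are the central interval of that predictive at the
configured specificity; a value outside its limits is *atypical*, and a
profile with at least one atypical value is flagged.

Variance components are estimated from clean (placebo) profiles by
one-way random-effects ANOVA with the unbalanced-design effective group
size, and a leave-one-out scheme guards the specificity estimate
against overfitting.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "MarkerComponents",
    "DetectionResult",
    "AdaptivePassport",
    "estimate_components",
    "predictive_limits",
    "evaluate_profile",
    "loo_screen",
    "profile_percentile_score",
    "roc_auc",
]


@dataclass(frozen=True)
class MarkerComponents:
    """Population mean and variance components of one marker."""

    marker_id: str
    mu: float
    sigma2_within: float
    sigma2_between: float
    clipped: bool = False  # True when a negative ANOVA between-component was clipped to 0

    def __post_init__(self) -> None:
        if self.sigma2_within < 0 or self.sigma2_between < 0:
            raise ValueError("variance components must be >= 0")


@dataclass
class SubjectResult:
    subject_id: str
    atypical_indices: list[int]
    flagged: bool
    score: float


@dataclass
class DetectionResult:
    """Cohort-level screening outcome.

    ``sensitivity`` is 100 x flagged doped / doped total (None when no
    doped profiles were supplied), ``specificity`` 100 x unflagged
    placebo / placebo total, ``roc_area`` the Mann-Whitney AUC of the
    profile percentile scores.
    """

    placebo: dict[str, SubjectResult]
    doped: dict[str, SubjectResult]
    sensitivity: float | None
    specificity: float
    roc_area: float | None


def estimate_components(
    values_by_subject: dict[str, "list[float]"],
    marker_id: str = "",
) -> MarkerComponents:
    """One-way random-effects ANOVA variance components.

    sigma2_within = MS_within; sigma2_between = (MS_between -
    MS_within) / n0 with the unbalanced-design effective group size
    n0 = (N - sum(n_i^2)/N) / (k - 1); negative between-components are
    clipped to zero and flagged.
    """
    groups = {s: np.asarray(v, dtype=float) for s, v in values_by_subject.items() if len(v) > 0}
    k = len(groups)
    if k < 2:
        raise ValueError("variance-component estimation needs >= 2 subjects")
    sizes = np.array([len(v) for v in groups.values()], dtype=float)
    n_total = sizes.sum()
    if n_total <= k:
        raise ValueError("need more observations than subjects for a within-subject variance")
    grand = float(np.concatenate(list(groups.values())).mean())
    group_means = np.array([v.mean() for v in groups.values()])
    ss_within = float(sum(((v - v.mean()) ** 2).sum() for v in groups.values()))
    ss_between = float((sizes * (group_means - grand) ** 2).sum())
    ms_within = ss_within / (n_total - k)
    ms_between = ss_between / (k - 1)
    n0 = (n_total - (sizes**2).sum() / n_total) / (k - 1)
    between = (ms_between - ms_within) / n0
    clipped = between < 0
    return MarkerComponents(
        marker_id=marker_id,
        mu=grand,
        sigma2_within=ms_within,
        sigma2_between=max(between, 0.0),
        clipped=bool(clipped),
    )


def _posterior(components: MarkerComponents, history) -> tuple[float, float]:
    """Posterior (mean, variance) of the subject set-point given history."""
    mu, s2w, s2b = components.mu, components.sigma2_within, components.sigma2_between
    hist = np.asarray(history, dtype=float)
    n = hist.size
    if s2b == 0:
        return mu, 0.0
    if n == 0:
        return mu, s2b
    if s2w == 0:
        # observations pin the set-point exactly
        if not np.allclose(hist, hist[0]):
            raise ValueError("degenerate model: zero within-subject variance with varying history")
        return float(hist[0]), 0.0
    prec = 1.0 / s2b + n / s2w
    m = (mu / s2b + n * hist.mean() / s2w) / prec
    return m, 1.0 / prec


def predictive_limits(
    components: MarkerComponents,
    history=(),
    specificity_level: float = 0.99,
) -> tuple[float, float]:
    """Central predictive interval for the next observation.

    With an empty history this is the prior predictive
    mu +/- z*sqrt(sigma2_b + sigma2_w); as history grows the centre
    shrinks towards the subject's own mean and the width towards
    z*sqrt(sigma2_w).  z = Phi^-1(1 - (1 - specificity)/2).
    """
    if not 0.5 < specificity_level < 1:
        raise ValueError("specificity_level must be in (0.5, 1)")
    hist = np.asarray(history, dtype=float)
    if hist.size and not np.isfinite(hist).all():
        raise ValueError("history contains non-finite observations")
    m, tau2 = _posterior(components, hist)
    z = stats.norm.ppf(1.0 - (1.0 - specificity_level) / 2.0)
    half = z * math.sqrt(tau2 + components.sigma2_within)
    if half == 0 and hist.size and not np.allclose(hist, components.mu):
        raise ValueError("degenerate model: zero variance components with history away from mu")
    return m - half, m + half


def evaluate_profile(
    profile,
    components: MarkerComponents,
    specificity_level: float = 0.99,
    sequential: bool = True,
) -> tuple[list[int], list[tuple[float, float]]]:
    """Sequentially test each observation against limits built from its
    predecessors.

    Observation t is compared with the predictive interval from
    observations 1..t-1 (the first against the prior predictive); every
    observation then joins the history regardless of atypicality.  With
    ``sequential=False`` all observations are tested against the prior
    predictive instead.  Returns (atypical indices, per-step limits).
    """
    prof = np.asarray(profile, dtype=float)
    if prof.size == 0:
        raise ValueError("profile must be nonempty")
    if not np.isfinite(prof).all():
        raise ValueError("profile contains non-finite observations")
    atypical: list[int] = []
    limits: list[tuple[float, float]] = []
    for i, x in enumerate(prof):
        history = prof[:i] if sequential else ()
        lo, hi = predictive_limits(components, history, specificity_level)
        limits.append((lo, hi))
        if x < lo or x > hi:
            atypical.append(i)
    return atypical, limits


def profile_percentile_score(
    profile,
    components: MarkerComponents,
    sequential: bool = True,
) -> float:
    """Maximum two-sided extremeness |2F(x) - 1| of the observations
    under their sequential posterior-predictive distributions.

    0 means every observation sat at its predictive median; values near
    1 mean at least one observation was far in a tail.
    """
    prof = np.asarray(profile, dtype=float)
    if prof.size == 0:
        raise ValueError("profile must be nonempty")
    if not np.isfinite(prof).all():
        raise ValueError("profile contains non-finite observations")
    score = 0.0
    for i, x in enumerate(prof):
        history = prof[:i] if sequential else ()
        m, tau2 = _posterior(components, history)
        sd = math.sqrt(tau2 + components.sigma2_within)
        if sd == 0:
            extremeness = 0.0 if np.isclose(x, m) else 1.0
        else:
            extremeness = abs(2.0 * stats.norm.cdf(x, loc=m, scale=sd) - 1.0)
        score = max(score, extremeness)
    return score


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: fraction of (doped, placebo) pairs where the
    doped score is higher, ties counted half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("roc_auc needs scores from both classes")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (pos.size * neg.size))


def loo_screen(
    placebo_profiles: dict,
    doped_profiles: dict,
    specificity_level: float = 0.99,
    sequential: bool = True,
    marker_id: str = "",
) -> DetectionResult:
    """Leave-one-out screening of a cohort for one marker.

    Each placebo subject is evaluated with components estimated from
    the *other* placebo subjects; doped subjects are evaluated with
    components from the full placebo set (they never contribute to the
    clean-population estimate).  Sensitivity and specificity follow the
    at-least-one-atypical-value rule; the ROC area compares the profile
    percentile scores of the two groups.
    """
    if len(placebo_profiles) < 3:
        raise ValueError("leave-one-out screening needs >= 3 placebo subjects")

    def _subject_result(sid, profile, comp) -> SubjectResult:
        atyp, _ = evaluate_profile(profile, comp, specificity_level, sequential)
        score = profile_percentile_score(profile, comp, sequential)
        return SubjectResult(sid, atyp, len(atyp) > 0, score)

    placebo_results: dict[str, SubjectResult] = {}
    for sid, profile in placebo_profiles.items():
        rest = {s: p for s, p in placebo_profiles.items() if s != sid}
        comp = estimate_components(rest, marker_id)
        placebo_results[sid] = _subject_result(sid, profile, comp)

    full_comp = estimate_components(placebo_profiles, marker_id)
    doped_results = {
        sid: _subject_result(sid, profile, full_comp)
        for sid, profile in doped_profiles.items()
    }

    n_placebo = len(placebo_results)
    specificity = 100.0 * sum(not r.flagged for r in placebo_results.values()) / n_placebo
    if doped_results:
        sensitivity = 100.0 * sum(r.flagged for r in doped_results.values()) / len(doped_results)
        scores = [r.score for r in doped_results.values()] + [r.score for r in placebo_results.values()]
        lab = [True] * len(doped_results) + [False] * len(placebo_results)
        area = roc_auc(scores, lab)
    else:
        sensitivity = None
        area = None
    return DetectionResult(placebo_results, doped_results, sensitivity, specificity, area)


class AdaptivePassport(BaseEstimator):
    """Novelty-detector-style estimator for one marker's passport.

    ``fit(X)`` estimates the universal variance components from clean
    profiles (rows = subjects, columns = ordered observations; NaN for
    missing).  ``predict(X)`` flags profiles containing at least one
    atypical value, ``score_samples(X)`` returns the percentile-based
    profile scores in [0, 1].

    Parameters
    ----------
    specificity_level : float
        Coverage of the individual reference ranges (default 0.99).
    sequential : bool
        Test each observation against limits from its predecessors
        (default) rather than the prior predictive for all.
    """

    def __init__(self, specificity_level: float = 0.99, sequential: bool = True):
        self.specificity_level = specificity_level
        self.sequential = sequential

    @staticmethod
    def _profiles(X) -> list[np.ndarray]:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (subjects x observations)")
        return [row[~np.isnan(row)] for row in X]

    def fit(self, X, y=None):
        profiles = self._profiles(X)
        comp = estimate_components({f"S{i}": p for i, p in enumerate(profiles)})
        self.components_ = comp
        self.mu_ = comp.mu
        self.sigma2_within_ = comp.sigma2_within
        self.sigma2_between_ = comp.sigma2_between
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        """True where a profile contains at least one atypical value."""
        return np.array([
            len(evaluate_profile(p, self.components_, self.specificity_level, self.sequential)[0]) > 0
            for p in self._profiles(X)
        ])

    def score_samples(self, X) -> np.ndarray:
        return np.array([
            profile_percentile_score(p, self.components_, self.sequential)
            for p in self._profiles(X)
        ])

    def limits(self, profile) -> list[tuple[float, float]]:
        """Per-observation reference limits for one profile."""
        return evaluate_profile(profile, self.components_, self.specificity_level, self.sequential)[1]
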