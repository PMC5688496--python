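"""Haematological derived markers and within-subject timepoint tests.

The OFF-score is the haematological stimulation index of the Athlete
Biological Passport, ``OFF = HGB - 60 * sqrt(RET%)`` with HGB in g/L and
RET in percent: a high score flags suppressed erythropoiesis (high
haemoglobin with few reticulocytes) after withdrawal of a stimulating
agent.

Timepoint comparisons are paired within-subject contrasts against each
subject's baseline mean, with Holm step-down adjustment across
timepoints.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def off_score(hgb: float, ret: float) -> float:
    """OFF-hr stimulation index: ``hgb - 60 * sqrt(ret)``.

    Parameters
    ----------
    hgb : float
        Haemoglobin concentration in g/L (must be > 0).
    ret : float
        Reticulocyte percentage (must be >= 0).
    """
    if hgb <= 0:
        raise ValueError("hgb must be > 0 (g/L)")
    if ret < 0:
        raise ValueError("ret must be >= 0 (percent)")
    return hgb - 60.0 * math.sqrt(ret)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, order-preserving with input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def paired_timepoint_tests(
    records: pd.DataFrame,
    marker: str,
    baseline_mode: str = "averaged",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-timepoint paired tests of ``marker`` against baseline.

    For each non-baseline timepoint, each subject contributes the
    difference (value at timepoint - subject's baseline mean); a
    two-sided one-sample t-test against zero is Holm-adjusted across
    timepoints.  ``baseline_mode`` is ``"averaged"`` (mean of all
    baseline timepoints) or ``"single"`` (last baseline only).

    ``records`` must hold one arm's data (filter first for arm-specific
    inference).  Returns a DataFrame with columns timepoint, n, mean_diff,
    p_raw, p_holm, significant.
    """
    if marker not in records.columns:
        raise KeyError(f"marker field {marker!r} not present in records")
    if baseline_mode not in ("averaged", "single"):
        raise ValueError("baseline_mode must be 'averaged' or 'single'")

    labels = list(dict.fromkeys(records["timepoint"]))
    base_labels = [lab for lab in labels if lab.startswith("B")]
    if not base_labels:
        raise ValueError("no baseline timepoints (labels starting with 'B') in records")
    if baseline_mode == "single":
        base_labels = [base_labels[-1]]
    test_labels = [lab for lab in labels if not lab.startswith("B")]

    base = (
        records[records["timepoint"].isin(base_labels)]
        .groupby("subject")[marker]
        .mean()
    )
    rows = []
    for lab in test_labels:
        sub = records[records["timepoint"] == lab].groupby("subject")[marker].mean()
        paired = pd.concat({"value": sub, "base": base}, axis=1).dropna()
        diffs = paired["value"] - paired["base"]
        if len(diffs) < 2:
            raise ValueError(f"timepoint {lab}: need >= 2 subjects with baseline and value")
        if np.allclose(diffs.std(ddof=1), 0):
            p = 1.0 if np.allclose(diffs.mean(), 0) else 0.0
        else:
            p = stats.ttest_1samp(diffs, 0.0).pvalue
        rows.append({"timepoint": lab, "n": len(diffs), "mean_diff": diffs.mean(), "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    out["significant"] = out["p_holm"] < alpha
    return out
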