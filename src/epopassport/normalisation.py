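"""Reference-gene normalisation of raw MFI panel measurements.

Pipeline order (fixed by design): average technical replicates on the
MFI scale, subtract background with a positive floor, divide each
sample's target signals by the geometric mean of its five reference
probes, log2-transform.  A limit-of-detection filter then drops markers
that are rarely above threshold.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gmean
from sklearn.base import BaseEstimator, TransformerMixin

from .synthetic import REFERENCE_PROBES


@dataclass
class ExpressionMatrix:
    """Log2 reference-normalised expression, markers x samples.

    ``values`` is a DataFrame with marker rows and sample-id columns;
    ``sample_meta`` is indexed by the same sample ids and carries
    subject, arm, timepoint and day.  Reference probes never appear as
    analysis rows.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.sample_meta.index):
            raise ValueError("sample_meta index must match value columns")
        missing = {"subject", "arm", "timepoint", "day"} - set(self.sample_meta.columns)
        if missing:
            raise ValueError(f"sample_meta missing columns: {sorted(missing)}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")

    @property
    def markers(self) -> list[str]:
        return list(self.values.index)


def subtract_background(mfi: float, background: float, floor: float = 0.5) -> float:
    """``max(mfi - background, floor)``; the floor keeps log2 defined."""
    if floor <= 0:
        raise ValueError("floor must be > 0")
    if mfi < 0 or background < 0:
        raise ValueError("mfi and background must be >= 0")
    return max(mfi - background, floor)


def geometric_mean(values) -> float:
    """exp(mean(log values)) of a nonempty, strictly positive list."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of an empty list")
    if np.any(arr <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return float(gmean(arr))


def normalise_sample(probe_mfis: dict, reference_probes=REFERENCE_PROBES) -> dict:
    """Log2 target/reference ratios for one sample.

    ``probe_mfis`` maps probe id to background-adjusted MFI; every
    reference probe must be present and positive.  Returns a map over
    target (non-reference) probes.
    """
    for ref in reference_probes:
        if ref not in probe_mfis:
            raise KeyError(f"reference probe {ref!r} missing from sample")
        if probe_mfis[ref] <= 0:
            raise ValueError(f"reference probe {ref!r} has nonpositive adjusted MFI")
    ref_gm = geometric_mean([probe_mfis[r] for r in reference_probes])
    return {
        probe: float(np.log2(mfi / ref_gm))
        for probe, mfi in probe_mfis.items()
        if probe not in reference_probes
    }


def replicate_cv(replicate_values) -> float:
    """Percent coefficient of variation of technical replicates on the
    MFI scale: 100 * sd / mean."""
    arr = np.asarray(replicate_values, dtype=float)
    if arr.size < 2:
        raise ValueError("replicate CV needs >= 2 replicates")
    return float(100.0 * arr.std(ddof=1) / arr.mean())


def lod_filter(
    matrix: ExpressionMatrix,
    raw_adjusted_mfi: pd.DataFrame,
    lod: float = 10.0,
    min_fraction: float = 0.8,
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop markers whose adjusted MFI exceeds ``lod`` in fewer than
    ``min_fraction`` of samples.

    ``raw_adjusted_mfi`` is markers x samples of background-adjusted,
    replicate-averaged MFI (aligned with ``matrix``).  Returns the kept
    matrix and the dropped marker ids.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    if matrix.values.empty:
        raise ValueError("empty expression matrix")
    frac_above = (raw_adjusted_mfi.loc[matrix.markers] > lod).mean(axis=1)
    keep = frac_above >= min_fraction
    dropped = [m for m, k in keep.items() if not k]
    kept = ExpressionMatrix(matrix.values.loc[keep[keep].index], matrix.sample_meta)
    return kept, dropped


class PanelNormalizer(BaseEstimator, TransformerMixin):
    """Transform long-format MFI panel records into a log2
    reference-normalised expression matrix.

    Parameters
    ----------
    background : float
        Constant assay background subtracted from every MFI.
    floor : float
        Positive floor applied after background subtraction.
    reference_probes : tuple of str
        Probes whose geometric mean normalises each sample.
    lod : float
        Adjusted-MFI limit of detection.
    min_fraction : float
        Minimum fraction of samples above ``lod`` for a marker to be
        kept; set to 0 together with ``apply_lod=False`` to skip.
    apply_lod : bool
        Whether to run the LOD filter during :meth:`transform`.
    """

    def __init__(
        self,
        background: float = 10.0,
        floor: float = 0.5,
        reference_probes: tuple = REFERENCE_PROBES,
        lod: float = 10.0,
        min_fraction: float = 0.8,
        apply_lod: bool = True,
    ):
        self.background = background
        self.floor = floor
        self.reference_probes = reference_probes
        self.lod = lod
        self.min_fraction = min_fraction
        self.apply_lod = apply_lod

    def fit(self, X: pd.DataFrame, y=None):
        self._validate(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> ExpressionMatrix:
        self._validate(X)
        df = X.copy()
        df["sample_id"] = (
            df["subject"].astype(str) + ":" + df["arm"].astype(str) + ":" + df["timepoint"].astype(str)
        )
        # replicates averaged on the MFI scale, then background-adjusted
        mean_mfi = df.groupby(["sample_id", "probe"], sort=True)["MFI"].mean().unstack("sample_id")
        adjusted = mean_mfi.map(lambda v: subtract_background(v, self.background, self.floor))
        refs = [r for r in self.reference_probes if r in adjusted.index]
        missing = set(self.reference_probes) - set(refs)
        if missing:
            raise KeyError(f"reference probes missing from panel: {sorted(missing)}")
        ref_gm = adjusted.loc[list(self.reference_probes)].apply(geometric_mean, axis=0)
        targets = adjusted.drop(index=list(self.reference_probes))
        values = np.log2(targets.div(ref_gm, axis=1))

        meta = (
            df.drop_duplicates("sample_id")
            .set_index("sample_id")[["subject", "arm", "timepoint", "day"]]
            .loc[values.columns]
        )
        matrix = ExpressionMatrix(values, meta)
        self.adjusted_mfi_ = targets
        if self.apply_lod:
            matrix, dropped = lod_filter(matrix, targets, self.lod, self.min_fraction)
            self.dropped_markers_ = dropped
        else:
            self.dropped_markers_ = []
        return matrix

    def _validate(self, X: pd.DataFrame) -> None:
        required = {"subject", "arm", "timepoint", "day", "probe", "replicate", "MFI"}
        missing = required - set(X.columns)
        if missing:
            raise KeyError(f"panel table missing columns: {sorted(missing)}")
        if len(X) == 0:
            raise ValueError("panel table is empty")
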