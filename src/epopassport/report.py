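"""Published adaptive-model summary fixture and report assembly.

The packaged fixture transcribes the published per-marker summary of
the microdose trial's adaptive-model analysis: mean, within- and
between-subject variance, sensitivity, specificity and ROC area for
HGB, the OFF-score and the 41 analysable transcripts.  It ships as a
checksummed TSV; the aggregation operations here recompute the printed
cohort summaries from it.  ``build_results_tables`` assembles the
pipeline's own outputs into the same layouts.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

_FIXTURE_NAME = "table3_adaptive_model.tsv"
_FIXTURE_SHA256 = "936929ac205357a0f82ff2c6a47b9621ee0851b1a833b858c54b41dab3f10a94"


@dataclass(frozen=True)
class Table3Row:
    marker: str
    kind: str  # "blood" or "transcript"
    mean: float
    sigma2_within: float
    sigma2_between: float
    sensitivity_pct: int
    specificity_pct: int
    roc_area: float


@dataclass(frozen=True)
class Table3Fixture:
    rows: tuple[Table3Row, ...]

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])

    @property
    def transcripts(self) -> pd.DataFrame:
        df = self.frame
        return df[df["kind"] == "transcript"].reset_index(drop=True)


def load_table3_fixture() -> Table3Fixture:
    """Load the packaged per-marker adaptive-model summary.

    Raises if the packaged file's SHA-256 does not match the recorded
    transcription checksum.
    """
    data = resources.files("epopassport.data").joinpath(_FIXTURE_NAME).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise ValueError(
            f"adaptive-model fixture checksum mismatch: {digest} != {_FIXTURE_SHA256}"
        )
    df = pd.read_csv(pd.io.common.BytesIO(data), sep="\t")
    rows = tuple(
        Table3Row(
            marker=r.marker,
            kind=r.kind,
            mean=float(r.mean),
            sigma2_within=float(r.sigma2_within),
            sigma2_between=float(r.sigma2_between),
            sensitivity_pct=int(r.sensitivity_pct),
            specificity_pct=int(r.specificity_pct),
            roc_area=float(r.roc_area),
        )
        for r in df.itertuples()
    )
    return Table3Fixture(rows)


def mean_variances(fixture: Table3Fixture) -> tuple[float, float]:
    """(mean within-subject, mean between-subject) variance over the
    transcript rows, rounded to 2 dp for reporting."""
    t = fixture.transcripts
    if (fixture.frame["kind"] == "blood").sum() and len(t) == 0:
        raise ValueError("fixture holds no transcript rows")
    return (
        round(float(t["sigma2_within"].mean()), 2),
        round(float(t["sigma2_between"].mean()), 2),
    )


def filter_high_performers(
    fixture: Table3Fixture, sens_min: float = 93, spec_min: float = 71
) -> list[str]:
    """Transcripts with sensitivity >= sens_min and specificity >=
    spec_min, in fixture order."""
    if not (0 <= sens_min <= 101 and 0 <= spec_min <= 101):
        raise ValueError("thresholds must be percentages")
    t = fixture.transcripts
    keep = (t["sensitivity_pct"] >= sens_min) & (t["specificity_pct"] >= spec_min)
    return list(t.loc[keep, "marker"])


def de_results_table(results: pd.DataFrame, contrasts: list[str] | None = None) -> pd.DataFrame:
    """Wide per-marker table of Log2 FC / FC / p / FDR per contrast,
    fold-changes rendered at 2 dp."""
    required = {"marker", "contrast", "log2fc", "fc", "p_raw", "fdr"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"DE results missing columns: {sorted(missing)}")
    if len(results) == 0:
        return pd.DataFrame(columns=["marker"])
    df = results.copy()
    if contrasts is not None:
        df = df[df["contrast"].isin(contrasts)]
    wide = df.pivot(index="marker", columns="contrast")
    out = pd.DataFrame(index=wide.index)
    for c in dict.fromkeys(df["contrast"]):
        out[f"log2fc:{c}"] = wide[("log2fc", c)].round(2)
        out[f"fc:{c}"] = wide[("fc", c)].round(2)
        out[f"p:{c}"] = wide[("p_raw", c)]
        out[f"fdr:{c}"] = wide[("fdr", c)]
    return out.reset_index()


def passport_summary_table(rows: list[dict]) -> pd.DataFrame:
    """Per-marker adaptive-model summary in the published layout:
    marker, mean, variances (3 dp), integer sensitivity/specificity,
    ROC area (2 dp)."""
    cols = ["marker", "mean", "sigma2_within", "sigma2_between",
            "sensitivity_pct", "specificity_pct", "roc_area"]
    if not rows:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows)
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"passport summary missing columns: {sorted(missing)}")
    out = df[cols].copy()
    out["mean"] = out["mean"].round(2)
    out["sigma2_within"] = out["sigma2_within"].round(3)
    out["sigma2_between"] = out["sigma2_between"].round(3)
    # the published convention: integer nearest-rounded percentages
    for c in ("sensitivity_pct", "specificity_pct"):
        out[c] = out[c].map(lambda v: int(round(v)) if pd.notna(v) else pd.NA)
    out["roc_area"] = out["roc_area"].round(2)
    return out


def build_results_tables(
    de_results: pd.DataFrame,
    passport_rows: list[dict],
    out_dir: str | Path,
    doped_arm: str = "rHuEpo",
) -> dict[str, Path]:
    """Write the three output documents (doped-arm DE, arm-difference
    DE, adaptive-model summary) as TSVs and return their paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    if len(de_results):
        arm_contrasts = sorted(
            c for c in de_results["contrast"].unique() if c.startswith(f"{doped_arm}:")
        )
        diff_contrasts = sorted(
            c for c in de_results["contrast"].unique() if c.startswith("diff:")
        )
    else:
        arm_contrasts = diff_contrasts = []
    tables = {
        "de_doped_vs_baseline.tsv": de_results_table(de_results, arm_contrasts or None),
        "de_arm_difference.tsv": de_results_table(de_results, diff_contrasts or None),
        "adaptive_model_summary.tsv": passport_summary_table(passport_rows),
    }
    for name, table in tables.items():
        path = out_dir / name
        table.to_csv(path, sep="\t", index=False)
        paths[name] = path
    return paths
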