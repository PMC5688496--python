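"""File formats, configuration and the staged pipeline runner.

Raw panel data travels in long (tidy) format — one row per (subject,
arm, timepoint, probe, replicate) — because replicates and missingness
are block-structured; the expression matrix is the only wide file.
All randomness flows from the single config seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import make_mds_design
from .de import ModeratedDifferentialExpression
from .normalisation import PanelNormalizer
from .passport import estimate_components, loo_screen
from .report import build_results_tables
from . import synthetic

log = logging.getLogger("epopassport")

PANEL_COLUMNS = synthetic.PANEL_COLUMNS


@dataclass
class PipelineConfig:
    """Declarative configuration for one end-to-end run.

    Defaults reproduce the study constants: FDR 0.05 with fold-change
    1.5 for differential expression, 99% specificity for the adaptive
    reference ranges, duplicate CV 10.6%, and block attrition 21/364.
    """

    seed: int = 0
    preset: str = "MDS"
    out_dir: str = "results"
    # generator
    ref_level: float = 1000.0
    background: float = 10.0
    cv_dup: float = 0.106
    drop_rate: float = 21 / 364
    # normalisation
    floor: float = 0.5
    lod: float = 10.0
    min_fraction: float = 0.8
    # differential expression
    alpha: float = 0.05
    fc_threshold: float = 1.5
    baseline_mode: str = "averaged"
    # passport
    specificity: float = 0.99
    sequential: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if not 0.5 < self.specificity < 1:
            raise ValueError("specificity must be in (0.5, 1)")
        if not 0 <= self.drop_rate <= 1:
            raise ValueError("drop_rate must be in [0, 1]")
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")
        if self.cv_dup < 0 or self.background < 0 or self.floor <= 0 or self.ref_level <= 0:
            raise ValueError("generator/normalisation scales out of range")
        if self.baseline_mode not in ("averaged", "single"):
            raise ValueError("baseline_mode must be 'averaged' or 'single'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def read_panel_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format panel CSV/TSV, validating schema.

    Unknown columns are preserved as annotations.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(f"panel table {path} missing column(s): {missing}")
    mfi = pd.to_numeric(df["MFI"], errors="coerce")
    bad = df.index[mfi.isna() & df["MFI"].notna()]
    if len(bad):
        raise ValueError(f"non-numeric MFI at row {bad[0] + 2} of {path}")  # +2: header + 1-based
    df["MFI"] = mfi
    return df


def write_panel_table(samples: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    samples.to_csv(path, sep=sep, index=False)


def write_expression_matrix(matrix, out_dir: str | Path) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    values_path = out_dir / "expression_matrix.tsv"
    meta_path = out_dir / "sample_meta.tsv"
    matrix.values.to_csv(values_path, sep="\t", index_label="marker")
    matrix.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")
    return values_path, meta_path


def _profiles_by_arm(matrix, marker: str, arm: str) -> dict[str, list[float]]:
    meta = matrix.sample_meta
    cols = meta.index[meta["arm"] == arm]
    sub = meta.loc[cols].assign(value=matrix.values.loc[marker, cols])
    sub = sub.sort_values("day", kind="stable")
    return {s: list(g["value"]) for s, g in sub.groupby("subject", sort=True)}


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute simulate -> normalise -> DE -> passport -> report.

    Deterministic given ``config.seed``; returns the output paths.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage_seeds = {name: int(rng.integers(2**31)) for name in ("expression", "haematology", "missingness")}
    paths: dict[str, Path] = {}

    design = make_mds_design(config.preset)
    doped_arm = design.arms[0]

    try:
        params = synthetic.default_gene_params()
        panel = synthetic.simulate_expression(
            design, params, ref_level=config.ref_level, background=config.background,
            cv_dup=config.cv_dup, seed=stage_seeds["expression"],
        )
        panel = synthetic.apply_missingness(panel, config.drop_rate, seed=stage_seeds["missingness"])
        haem = synthetic.simulate_haematology(design, seed=stage_seeds["haematology"])
        n_blocks = len(panel[["subject", "arm", "timepoint"]].drop_duplicates())
        log.info("simulate: %d of %d scheduled sample blocks retained, %d panel rows",
                 n_blocks, design.n_scheduled_samples, len(panel))
        paths["panel_long.csv"] = out_dir / "panel_long.csv"
        write_panel_table(panel, paths["panel_long.csv"])
        paths["haematology.csv"] = out_dir / "haematology.csv"
        haem.to_csv(paths["haematology.csv"], index=False)
    except Exception as exc:
        raise RuntimeError(f"[simulate] {exc}") from exc

    try:
        norm = PanelNormalizer(
            background=config.background, floor=config.floor,
            lod=config.lod, min_fraction=config.min_fraction,
        )
        matrix = norm.fit(panel).transform(panel)
        log.info("normalise: %d markers kept, %d dropped below LOD (%s), %d samples",
                 len(matrix.markers), len(norm.dropped_markers_),
                 ",".join(norm.dropped_markers_) or "-", matrix.values.shape[1])
        vp, mp = write_expression_matrix(matrix, out_dir)
        paths["expression_matrix.tsv"] = vp
        paths["sample_meta.tsv"] = mp
    except Exception as exc:
        raise RuntimeError(f"[normalise] {exc}") from exc

    try:
        de = ModeratedDifferentialExpression(
            alpha=config.alpha, fc_threshold=config.fc_threshold,
            baseline_mode=config.baseline_mode, doped_arm=doped_arm,
        ).fit(matrix, design)
        cascade = de.selection_cascade()
        log.info("de: %d markers, cascade sizes S1=%d S2=%d S3=%d S4=%d",
                 len(matrix.markers), *(len(cascade[k]) for k in ("S1", "S2", "S3", "S4")))
    except Exception as exc:
        raise RuntimeError(f"[de] {exc}") from exc

    try:
        passport_rows, profile_rows = [], []
        sources: list[tuple[str, dict, dict]] = []
        for marker in matrix.markers:
            sources.append((
                marker,
                _profiles_by_arm(matrix, marker, design.arms[1]),
                _profiles_by_arm(matrix, marker, doped_arm),
            ))
        for col in ("HGB_gL", "OFF"):
            by_arm = {}
            for arm in design.arms:
                sub = haem[haem["arm"] == arm].sort_values("day", kind="stable")
                by_arm[arm] = {s: list(g[col]) for s, g in sub.groupby("subject", sort=True)}
            sources.append((col, by_arm[design.arms[1]], by_arm[doped_arm]))
        for marker, placebo, doped in sources:
            result = loo_screen(placebo, doped, config.specificity, config.sequential, marker)
            comp = estimate_components(placebo, marker)
            passport_rows.append({
                "marker": marker, "mean": comp.mu,
                "sigma2_within": comp.sigma2_within, "sigma2_between": comp.sigma2_between,
                "sensitivity_pct": result.sensitivity, "specificity_pct": result.specificity,
                "roc_area": result.roc_area,
            })
            for group, results in (("placebo", result.placebo), (doped_arm, result.doped)):
                for sid, r in results.items():
                    profile_rows.append({
                        "marker": marker, "group": group, "subject": sid,
                        "flagged": r.flagged, "score": r.score,
                        "n_atypical": len(r.atypical_indices),
                    })
        log.info("passport: %d markers screened (%d transcripts + HGB/OFF)",
                 len(sources), len(matrix.markers))
        profiles = pd.DataFrame(profile_rows)
        paths["passport_profiles.csv"] = out_dir / "passport_profiles.csv"
        profiles.to_csv(paths["passport_profiles.csv"], index=False)
    except Exception as exc:
        raise RuntimeError(f"[passport] {exc}") from exc

    try:
        table_paths = build_results_tables(de.results_, passport_rows, out_dir, doped_arm)
        paths.update(table_paths)
        log.info("report: wrote %s", ", ".join(sorted(table_paths)))
    except Exception as exc:
        raise RuntimeError(f"[report] {exc}") from exc

    return paths
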