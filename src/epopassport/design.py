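"""Crossover study designs: arms, timepoints and sampling days.

The microdose study (MDS) design is the sampling grid everything else
indexes: 14 subjects, rHuEpo and placebo arms, and 13 weekly timepoints
split into baseline (B1-B3), administration (D1-D7) and post (P1-P3)
phases.
"""
from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class StudyDesign:
    """Arms, timepoints and day offsets of a crossover trial.

    Parameters
    ----------
    n_subjects : int
        Number of subjects, each observed in every arm (crossover).
    arms : tuple of str
        Ordered arm labels; the first is treated as the doped arm by the
        generator when an effect trajectory is supplied.
    timepoints : tuple of (str, int)
        Ordered (label, day) pairs. Labels starting with ``B`` are
        baseline.
    replicates_per_sample : int
        Technical replicates measured per sample (duplicates by default).
    """

    n_subjects: int
    arms: tuple[str, ...]
    timepoints: tuple[tuple[str, int], ...]
    replicates_per_sample: int = 2

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if len(self.arms) == 0:
            raise ValueError("design needs at least one arm")
        if len(set(self.arms)) != len(self.arms):
            raise ValueError("arm labels must be unique")
        labels = [lab for lab, _ in self.timepoints]
        if len(set(labels)) != len(labels):
            raise ValueError("timepoint labels must be unique")
        days = [day for _, day in self.timepoints]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("timepoint days must be strictly increasing")
        if self.replicates_per_sample < 1:
            raise ValueError("replicates_per_sample must be >= 1")

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.timepoints]

    @property
    def days(self) -> dict[str, int]:
        return dict(self.timepoints)

    @property
    def baseline_labels(self) -> list[str]:
        return [lab for lab in self.labels if lab.startswith("B")]

    @property
    def subjects(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]

    @property
    def n_scheduled_samples(self) -> int:
        """Subjects x arms x timepoints (replicates not counted)."""
        return self.n_subjects * len(self.arms) * len(self.timepoints)


_MDS_TIMEPOINTS = (
    ("B1", -14), ("B2", -7), ("B3", 0),
    ("D1", 3), ("D2", 10), ("D3", 17), ("D4", 24),
    ("D5", 31), ("D6", 38), ("D7", 45),
    ("P1", 52), ("P2", 59), ("P3", 66),
)

_PRESETS: dict[str, StudyDesign] = {
    # 14 subjects x 2 arms x 13 weekly timepoints, duplicate assays
    "MDS": StudyDesign(
        n_subjects=14,
        arms=("rHuEpo", "placebo"),
        timepoints=_MDS_TIMEPOINTS,
    ),
    # exercise sub-study template: pre / immediately-post / 30-min-post
    # around the repeated-sprint test, before and after treatment
    "MDS-exercise": StudyDesign(
        n_subjects=14,
        arms=("rHuEpo", "placebo"),
        timepoints=(
            ("PRE1", 0), ("POST1", 1), ("REC1", 2),
            ("PRE2", 49), ("POST2", 50), ("REC2", 51),
        ),
    ),
    # altitude template for elite runners: baseline, during, and four
    # post-altitude follow-ups
    "ATS-runners": StudyDesign(
        n_subjects=12,
        arms=("altitude", "control"),
        timepoints=(
            ("B1", -14), ("D1", 10), ("P1", 16),
            ("P2", 21), ("P3", 30), ("P4", 42),
        ),
    ),
}


def make_mds_design(preset: str = "MDS") -> StudyDesign:
    """Return a preset crossover design.

    ``"MDS"`` is the microdose trial grid (14 subjects x 2 arms x 13
    timepoints = 364 scheduled samples); ``"MDS-exercise"`` and
    ``"ATS-runners"`` are scenario templates reusing the same machinery.
    """
    try:
        return _PRESETS[preset]
    except KeyError:
        valid = ", ".join(sorted(_PRESETS))
        raise ValueError(f"unknown preset {preset!r}; valid presets: {valid}") from None
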