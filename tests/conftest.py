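import numpy as np
import pandas as pd
import pytest

from epopassport.design import StudyDesign, make_mds_design
from epopassport.normalisation import ExpressionMatrix
from epopassport.synthetic import GeneParams


@pytest.fixture(scope="session")
def mds_design() -> StudyDesign:
    return make_mds_design("MDS")


def make_latent_matrix(design, gene_params, seed=0, doped_arm=None) -> ExpressionMatrix:
    """Build an ExpressionMatrix directly from the hierarchical log2
    model, bypassing the MFI layer (independent of the generator's
    MFI/normalisation path; used to test downstream stages in
    isolation)."""
    rng = np.random.default_rng(seed)
    if doped_arm is None:
        doped_arm = design.arms[0]
    subjects = design.subjects
    labels = design.labels
    cols, meta_rows = [], []
    for s in subjects:
        for arm in design.arms:
            for lab, day in design.timepoints:
                cols.append(f"{s}:{arm}:{lab}")
                meta_rows.append({"subject": s, "arm": arm, "timepoint": lab, "day": day})
    meta = pd.DataFrame(meta_rows, index=cols)
    values = {}
    for p in gene_params:
        b = {s: rng.normal(0, np.sqrt(p.sigma2_between)) for s in subjects}
        row = []
        for s in subjects:
            for arm in design.arms:
                for lab in labels:
                    delta = p.effect.get(lab, 0.0) if arm == doped_arm else 0.0
                    row.append(p.mu + b[s] + delta + rng.normal(0, np.sqrt(p.sigma2_within)))
        values[p.marker_id] = row
    mat = pd.DataFrame(values, index=cols).T
    return ExpressionMatrix(mat, meta)


@pytest.fixture
def null_params():
    """Ten markers with no treatment effect."""
    return [GeneParams(f"G{i:02d}", mu=1.0, sigma2_within=0.14, sigma2_between=0.20) for i in range(10)]
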