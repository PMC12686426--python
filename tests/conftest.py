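import numpy as np
import pytest

from mtclone.io_formats import AlleleCountMatrix, CellAnnotation
import pandas as pd

#: suite-wide seed convention
SEED = 0


def make_annotation(n_epi: int, n_ref: int, tissue="BE", sample="S1", patient="P1"):
    """Minimal annotation: n_epi epithelial cells then n_ref reference cells."""
    n = n_epi + n_ref
    return CellAnnotation(
        pd.DataFrame(
            {
                "cell_id": [f"c{i:04d}" for i in range(n)],
                "sample_id": sample,
                "patient_id": patient,
                "tissue": [tissue] * n_epi + ["stroma"] * n_ref,
                "cell_type": ["epithelial"] * n_epi + ["fibroblast"] * n_ref,
                "is_epithelial": [True] * n_epi + [False] * n_ref,
                "is_reference": [False] * n_epi + [True] * n_ref,
            }
        )
    )


def make_matrix(alt, cov, qual=None, variant_ids=None, cell_ids=None):
    """Dense AlleleCountMatrix from (cells x variants) arrays."""
    alt = np.atleast_2d(np.asarray(alt))
    cov = np.atleast_2d(np.asarray(cov))
    if qual is None:
        qual = np.where(cov > 0, 30.0, np.nan)
    else:
        qual = np.where(cov > 0, np.atleast_2d(np.asarray(qual, dtype=float)), np.nan)
    n_cells, n_vars = alt.shape
    if variant_ids is None:
        variant_ids = [f"{100 + 7 * j}G>A" for j in range(n_vars)]
    if cell_ids is None:
        cell_ids = [f"c{i:04d}" for i in range(n_cells)]
    return AlleleCountMatrix(variant_ids, cell_ids, alt, cov, qual)


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
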