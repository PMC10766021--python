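import numpy as np
import pytest

from ki67cl.cells_io import CellClass, CellRecord, CellTable


def make_blob_table(
    blob_specs: list[tuple[float, float, int, int]],
    sigma: float = 20.0,
    seed: int = 0,
    slide_id: str = "fixture",
) -> CellTable:
    """Cell table from (cx, cy, n_pos, n_neg) blob specs.

    Cells scatter Gaussian around each center; used wherever a test needs
    exact control over per-blob class composition.
    """
    rng = np.random.default_rng(seed)
    cells = []
    for cx, cy, n_pos, n_neg in blob_specs:
        for cls, n in ((CellClass.TUMOR_POS, n_pos), (CellClass.TUMOR_NEG, n_neg)):
            pts = np.abs(rng.normal([cx, cy], sigma, size=(n, 2)))
            for x, y in pts:
                cells.append(CellRecord(x=float(x), y=float(y), cell_class=cls))
    return CellTable(slide_id=slide_id, cells=cells)


@pytest.fixture
def two_far_blobs_mixed():
    """Two blobs far beyond the 300-px threshold, each perfectly balanced."""
    return make_blob_table([(500, 500, 25, 25), (5000, 5000, 25, 25)], seed=3)


@pytest.fixture
def two_far_blobs_pure():
    """One pure-positive and one pure-negative blob, far apart."""
    return make_blob_table([(500, 500, 40, 0), (5000, 5000, 0, 40)], seed=4)
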