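import numpy as np
import pandas as pd
import pytest

from scqc.dataset import ExpressionMatrix, SCEDataset, designate_controls


@pytest.fixture
def worked_dataset() -> SCEDataset:
    """The small hand-checkable matrix used throughout the QC tests.

    counts (features x cells c1,c2,c3):
        A: 6 0 3
        B: 2 1 0
        C: 0 0 0
        D: 2 9 1   <- designated control set "spike"
    """
    counts = np.array(
        [
            [6.0, 0.0, 3.0],
            [2.0, 1.0, 0.0],
            [0.0, 0.0, 0.0],
            [2.0, 9.0, 1.0],
        ]
    )
    ds = SCEDataset(
        assays={
            "counts": ExpressionMatrix(
                counts,
                np.array(["A", "B", "C", "D"], dtype=object),
                np.array(["c1", "c2", "c3"], dtype=object),
                "counts",
            )
        }
    )
    return designate_controls(ds, "spike", ["D"])


@pytest.fixture
def small_dataset() -> SCEDataset:
    """4 features x 3 cells with metadata, controls, size factors, embedding."""
    rng = np.random.default_rng(7)
    counts = rng.poisson(5.0, size=(4, 3)).astype(float) + 1.0
    fids = np.array(["g1", "g2", "g3", "ercc1"], dtype=object)
    cids = np.array(["c1", "c2", "c3"], dtype=object)
    ds = SCEDataset(
        assays={"counts": ExpressionMatrix(counts, fids, cids, "counts")},
        cell_metadata=pd.DataFrame(
            {"batch": ["b1", "b1", "b2"], "depth": [1.0, 2.0, 3.0]},
            index=pd.Index(cids, name="cell_id"),
        ),
        size_factors={"default": np.array([1.0, 2.0, 0.5])},
        reduced_dims={"PCA": pd.DataFrame(rng.normal(size=(3, 2)), index=cids)},
    )
    return designate_controls(ds, "ERCC", ["ercc1"])
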