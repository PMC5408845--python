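import logging

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from scqc.dataset import (
    DatasetError,
    ExpressionMatrix,
    SCEDataset,
    combine_cells,
    designate_controls,
    subset,
)
from scqc.io import read_dataset, write_dataset


def test_expression_matrix_rejects_negative_counts():
    with pytest.raises(DatasetError, match="negative"):
        ExpressionMatrix(
            np.array([[-1.0]]), np.array(["g"], object), np.array(["c"], object), "counts"
        )


def test_expression_matrix_rejects_duplicate_ids():
    with pytest.raises(DatasetError, match="duplicate"):
        ExpressionMatrix(
            np.zeros((2, 1)), np.array(["g", "g"], object), np.array(["c"], object)
        )


def test_subset_restricts_every_slot(small_dataset):
    out = subset(small_dataset, keep_cells=["c1", "c3"])
    assert out.assay("counts").shape == (4, 2)
    assert list(out.cell_ids) == ["c1", "c3"]
    assert len(out.cell_metadata) == 2
    assert out.size_factors["default"].shape == (2,)
    assert out.reduced_dims["PCA"].shape[0] == 2
    np.testing.assert_array_equal(
        out.assay("counts").values, small_dataset.assay("counts").values[:, [0, 2]]
    )


def test_subset_identity(small_dataset):
    out = subset(small_dataset, list(small_dataset.feature_ids), list(small_dataset.cell_ids))
    np.testing.assert_array_equal(out.assay("counts").values, small_dataset.assay("counts").values)
    pd.testing.assert_frame_equal(out.cell_metadata, small_dataset.cell_metadata)


def test_subset_empties_control_set_with_warning(small_dataset, caplog):
    with caplog.at_level(logging.WARNING):
        out = subset(small_dataset, keep_features=["g1", "g2"])
    assert out.control_sets["ERCC"] == []
    assert any("ERCC" in r.message for r in caplog.records)


def test_subset_unknown_id_names_the_id(small_dataset):
    with pytest.raises(DatasetError, match="nope"):
        subset(small_dataset, keep_cells=["c1", "nope"])
    with pytest.raises(DatasetError, match="every cell"):
        subset(small_dataset, keep_cells=[])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    f1=st.sets(st.sampled_from(["g1", "g2", "g3", "ercc1"]), min_size=1),
    f2=st.sets(st.sampled_from(["g1", "g2", "g3", "ercc1"]), min_size=1),
    c1=st.sets(st.sampled_from(["c1", "c2", "c3"]), min_size=1),
    c2=st.sets(st.sampled_from(["c1", "c2", "c3"]), min_size=1),
)
def test_subset_composes_like_intersection(f1, f2, c1, c2):
    """subset(subset(ds, F1, C1), F2, C2) == subset(ds, F1&F2, C1&C2)."""
    if not (f1 & f2) or not (c1 & c2):
        return
    rng = np.random.default_rng(3)
    ds = SCEDataset(
        assays={
            "counts": ExpressionMatrix(
                rng.poisson(5.0, size=(4, 3)).astype(float),
                np.array(["g1", "g2", "g3", "ercc1"], object),
                np.array(["c1", "c2", "c3"], object),
                "counts",
            )
        }
    )
    nested = subset(subset(ds, f1, c1), f1 & f2, c1 & c2)
    direct = subset(ds, f1 & f2, c1 & c2)
    np.testing.assert_array_equal(
        nested.assay("counts").values, direct.assay("counts").values
    )
    assert list(nested.feature_ids) == list(direct.feature_ids)


def _make(cells, seed=0, features=("g1", "g2", "g3", "g4")):
    rng = np.random.default_rng(seed)
    m = rng.poisson(4.0, size=(len(features), len(cells))).astype(float)
    return SCEDataset(
        assays={
            "counts": ExpressionMatrix(
                m, np.array(features, object), np.array(cells, object), "counts"
            )
        }
    )


def test_combine_cells_concatenates():
    a, b = _make(["a1", "a2", "a3"]), _make(["b1", "b2"], seed=1)
    out = combine_cells(a, b)
    assert out.assay("counts").shape == (4, 5)
    assert list(out.cell_ids) == ["a1", "a2", "a3", "b1", "b2"]


def test_combine_then_subset_recovers_left_operand():
    a, b = _make(["a1", "a2", "a3"]), _make(["b1", "b2"], seed=1)
    back = subset(combine_cells(a, b), keep_cells=list(a.cell_ids))
    np.testing.assert_array_equal(back.assay("counts").values, a.assay("counts").values)


def test_combine_unions_metadata_with_missing_markers():
    a, b = _make(["a1", "a2"]), _make(["b1"], seed=1)
    a.cell_metadata["plate"] = ["p1", "p2"]
    out = combine_cells(a, b)
    assert out.cell_metadata.loc["b1", "plate"] is np.nan or pd.isna(
        out.cell_metadata.loc["b1", "plate"]
    )


def test_combine_rejects_feature_mismatch_and_duplicates():
    a = _make(["a1", "a2"])
    b = _make(["b1"], features=("g2", "g1", "g3", "g4"))
    with pytest.raises(DatasetError, match="feature ids"):
        combine_cells(a, b)
    with pytest.raises(DatasetError, match="duplicate cell"):
        combine_cells(a, _make(["a1"]))


def test_combine_rejects_conflicting_control_sets():
    a = designate_controls(_make(["a1", "a2"]), "spike", ["g1"])
    b = designate_controls(_make(["b1"]), "spike", ["g2"])
    with pytest.raises(DatasetError, match="control sets"):
        combine_cells(a, b)


def test_designate_controls_sets_flags(small_dataset):
    ds = designate_controls(small_dataset, "mito", ["g2"])
    np.testing.assert_array_equal(
        ds.feature_metadata["is_control_mito"].to_numpy(), [False, True, False, False]
    )
    # derived any-control column covers both sets
    np.testing.assert_array_equal(
        ds.feature_metadata["is_feature_control"].to_numpy(), [False, True, False, True]
    )


def test_designate_empty_and_unknown(small_dataset):
    ds = designate_controls(small_dataset, "none", [])
    assert not ds.feature_metadata["is_control_none"].any()
    with pytest.raises(DatasetError, match="X"):
        designate_controls(small_dataset, "bad", ["X"])


@pytest.mark.parametrize("sparse", [False, True])
def test_disk_round_trip_preserves_values(tmp_path, small_dataset, sparse):
    ds = small_dataset
    if sparse:
        a = ds.assay("counts")
        ds.assays["counts"] = ExpressionMatrix(
            sp.csr_matrix(a.values), a.feature_ids, a.cell_ids, a.scale_tag
        )
    write_dataset(ds, tmp_path / "d")
    back = read_dataset(tmp_path / "d")
    orig = ds.assay("counts")
    got = back.assay("counts")
    np.testing.assert_array_equal(
        np.asarray(got.values.todense()) if sp.issparse(got.values) else got.values,
        np.asarray(orig.values.todense()) if sp.issparse(orig.values) else orig.values,
    )
    assert list(back.cell_ids) == list(ds.cell_ids)
    assert back.control_sets == {k: list(v) for k, v in ds.control_sets.items()}
    np.testing.assert_allclose(back.size_factors["default"], ds.size_factors["default"])
    pd.testing.assert_frame_equal(
        back.cell_metadata.sort_index(axis=1),
        ds.cell_metadata.sort_index(axis=1),
        check_dtype=False,  # 1.0 round-trips as the equal value 1
    )
    assert got.scale_tag == "counts"
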