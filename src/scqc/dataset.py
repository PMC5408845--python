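"""Single-cell expression dataset container.

The central data structure couples one or more expression assays
(features x cells) with cell- and feature-level metadata tables, named
control-feature sets (e.g. ERCC spike-ins, mitochondrial genes), per-cell
size factors and stored reduced-dimension embeddings.  All operations that
restrict or combine cells/features act on every slot consistently, so a
dataset can never drift into a state where an assay and its metadata
disagree about which cells exist.

Matrices may be dense :class:`numpy.ndarray` or any
:class:`scipy.sparse.spmatrix`; operations avoid densifying sparse data
above a configurable element-count threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: Known interpretation tags for expression values.
SCALE_TAGS = {
    "counts",
    "tpm",
    "cpm",
    "fpkm",
    "normalized",
    "log_expression",
    "residuals",
}

#: Tags whose values must be non-negative.
_NONNEG_TAGS = {"counts", "tpm", "cpm", "fpkm", "normalized"}

#: Sparse matrices with more stored elements than this are never silently
#: densified; callers that need dense data must raise the limit explicitly.
DENSIFY_LIMIT = 50_000_000


class DatasetError(ValueError):
    """Raised on any structural violation of the dataset contract."""


def densify(values, limit: int = DENSIFY_LIMIT) -> np.ndarray:
    """Return a dense ndarray view of ``values``, guarding against blow-up."""
    if sp.issparse(values):
        n = int(values.shape[0]) * int(values.shape[1])
        if n > limit:
            raise DatasetError(
                f"refusing to densify a {values.shape} sparse matrix "
                f"({n} elements > limit {limit})"
            )
        return np.asarray(values.todense())
    return np.asarray(values)


def _check_unique(ids: Iterable[str], axis: str) -> np.ndarray:
    arr = np.asarray(list(ids), dtype=object)
    if arr.size != pd.unique(arr).size:
        dup = pd.Series(arr).loc[pd.Series(arr).duplicated()].iloc[0]
        raise DatasetError(f"duplicate {axis} id: {dup!r}")
    return arr


@dataclass
class ExpressionMatrix:
    """A features x cells expression matrix with typed scale semantics.

    Parameters
    ----------
    values
        Dense or sparse matrix, rows are features, columns are cells.
    feature_ids, cell_ids
        Unique string identifiers matching the matrix dimensions.
    scale_tag
        One of :data:`SCALE_TAGS`; tags representing abundances
        (counts/tpm/cpm/fpkm/normalized) must be non-negative.
    """

    values: object
    feature_ids: np.ndarray
    cell_ids: np.ndarray
    scale_tag: str = "counts"

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise DatasetError(
                f"unknown scale_tag {self.scale_tag!r}; expected one of {sorted(SCALE_TAGS)}"
            )
        self.feature_ids = _check_unique(self.feature_ids, "feature")
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        shape = self.values.shape
        if shape != (len(self.feature_ids), len(self.cell_ids)):
            raise DatasetError(
                f"matrix shape {shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.cell_ids)} cells"
            )
        if self.scale_tag in _NONNEG_TAGS:
            mn = self.values.min() if sp.issparse(self.values) else np.min(self.values) if self.values.size else 0.0
            if self.values.size and mn < 0:
                raise DatasetError(
                    f"negative values not allowed for scale_tag={self.scale_tag!r}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        return densify(self.values)

    def take(self, feat_idx: np.ndarray | None, cell_idx: np.ndarray | None) -> "ExpressionMatrix":
        """Positional subsetting preserving sparsity."""
        v = self.values
        if feat_idx is not None:
            v = v[feat_idx, :]
        if cell_idx is not None:
            v = v[:, cell_idx]
        fids = self.feature_ids if feat_idx is None else self.feature_ids[feat_idx]
        cids = self.cell_ids if cell_idx is None else self.cell_ids[cell_idx]
        return ExpressionMatrix(v, fids, cids, self.scale_tag)


@dataclass
class SCEDataset:
    """Container coupling assays, metadata, controls, size factors, embeddings.

    Invariants (enforced by :meth:`validate`, called on construction):

    * every assay has identical ``feature_ids`` and ``cell_ids``;
    * every control set is a subset of the feature ids;
    * each reduced-dim entry has one row per cell, in cell order;
    * each size-factor entry is strictly positive, one value per cell.

    ``extra_slots`` holds opaque objects (bootstrap arrays, cell-cell or
    gene-gene distance matrices, consensus clusterings); they are stored
    and carried along but never computed on.
    """

    assays: dict[str, ExpressionMatrix]
    cell_metadata: pd.DataFrame | None = None
    feature_metadata: pd.DataFrame | None = None
    control_sets: dict[str, list[str]] = field(default_factory=dict)
    reduced_dims: dict[str, pd.DataFrame] = field(default_factory=dict)
    size_factors: dict[str, np.ndarray] = field(default_factory=dict)
    extra_slots: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.assays:
            raise DatasetError("a dataset needs at least one assay")
        ref = next(iter(self.assays.values()))
        if self.cell_metadata is None:
            self.cell_metadata = pd.DataFrame(index=pd.Index(ref.cell_ids, name="cell_id"))
        if self.feature_metadata is None:
            self.feature_metadata = pd.DataFrame(index=pd.Index(ref.feature_ids, name="feature_id"))
        self.cell_metadata.index.name = "cell_id"
        self.feature_metadata.index.name = "feature_id"
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def feature_ids(self) -> np.ndarray:
        return next(iter(self.assays.values())).feature_ids

    @property
    def cell_ids(self) -> np.ndarray:
        return next(iter(self.assays.values())).cell_ids

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def assay(self, name: str) -> ExpressionMatrix:
        try:
            return self.assays[name]
        except KeyError:
            raise DatasetError(
                f"no assay {name!r}; available: {sorted(self.assays)}"
            ) from None

    def validate(self) -> None:
        ref = next(iter(self.assays.values()))
        fids, cids = ref.feature_ids, ref.cell_ids
        for name, a in self.assays.items():
            if not np.array_equal(a.feature_ids, fids) or not np.array_equal(a.cell_ids, cids):
                raise DatasetError(f"assay {name!r} has mismatching feature/cell ids")
        if not np.array_equal(np.asarray(self.cell_metadata.index, dtype=object), cids):
            raise DatasetError("cell_metadata index does not match cell ids")
        if not np.array_equal(np.asarray(self.feature_metadata.index, dtype=object), fids):
            raise DatasetError("feature_metadata index does not match feature ids")
        fset = set(fids)
        for name, ids in self.control_sets.items():
            unknown = [i for i in ids if i not in fset]
            if unknown:
                raise DatasetError(
                    f"control set {name!r} contains unknown feature ids: {unknown[:5]}"
                )
        for name, rd in self.reduced_dims.items():
            if rd.shape[0] != len(cids):
                raise DatasetError(
                    f"reduced_dims[{name!r}] has {rd.shape[0]} rows for {len(cids)} cells"
                )
        for name, sf in self.size_factors.items():
            sf = np.asarray(sf, dtype=float)
            if sf.shape != (len(cids),):
                raise DatasetError(
                    f"size_factors[{name!r}] has length {sf.shape} for {len(cids)} cells"
                )
            if not np.all(np.isfinite(sf)) or np.any(sf <= 0):
                raise DatasetError(f"size_factors[{name!r}] must be finite and > 0")
            self.size_factors[name] = sf

    # -- convenience -------------------------------------------------------
    def copy(self) -> "SCEDataset":
        return SCEDataset(
            assays={k: ExpressionMatrix(v.values.copy(), v.feature_ids.copy(), v.cell_ids.copy(), v.scale_tag) for k, v in self.assays.items()},
            cell_metadata=self.cell_metadata.copy(),
            feature_metadata=self.feature_metadata.copy(),
            control_sets={k: list(v) for k, v in self.control_sets.items()},
            reduced_dims={k: v.copy() for k, v in self.reduced_dims.items()},
            size_factors={k: np.array(v, dtype=float) for k, v in self.size_factors.items()},
            extra_slots=dict(self.extra_slots),
        )

    def set_assay(self, name: str, matrix: ExpressionMatrix) -> None:
        if not np.array_equal(matrix.feature_ids, self.feature_ids) or not np.array_equal(
            matrix.cell_ids, self.cell_ids
        ):
            raise DatasetError("new assay ids must match the dataset")
        self.assays[name] = matrix


def _resolve(ids_wanted, universe: np.ndarray, axis: str) -> np.ndarray:
    """Map an id collection onto positional indices, preserving dataset order."""
    wanted = set(ids_wanted)
    unknown = wanted - set(universe)
    if unknown:
        raise DatasetError(f"unknown {axis} id(s): {sorted(unknown)[:5]}")
    idx = np.flatnonzero(np.fromiter((u in wanted for u in universe), bool, len(universe)))
    if idx.size == 0:
        raise DatasetError(f"subsetting would remove every {axis}")
    return idx


def subset(
    ds: SCEDataset,
    keep_features: Iterable[str] | None = None,
    keep_cells: Iterable[str] | None = None,
) -> SCEDataset:
    """Restrict a dataset to the given feature/cell ids, consistently.

    Every assay, metadata table, control set, size-factor vector and
    reduced-dim matrix is restricted together.  The relative order of
    retained ids is the dataset's order, regardless of the order of the
    requested sets.  Control sets drop removed members (with a warning if a
    set becomes empty).  Unknown ids and empty results raise.
    """
    fi = None if keep_features is None else _resolve(keep_features, ds.feature_ids, "feature")
    ci = None if keep_cells is None else _resolve(keep_cells, ds.cell_ids, "cell")

    assays = {k: a.take(fi, ci) for k, a in ds.assays.items()}
    fids = next(iter(assays.values())).feature_ids
    fset = set(fids)

    new_controls: dict[str, list[str]] = {}
    for name, ids in ds.control_sets.items():
        kept = [i for i in ids if i in fset]
        if ids and not kept:
            logger.warning("control set %r is empty after subsetting", name)
        new_controls[name] = kept

    cm = ds.cell_metadata if ci is None else ds.cell_metadata.iloc[ci]
    fm = ds.feature_metadata if fi is None else ds.feature_metadata.iloc[fi]
    rdims = {
        k: (v if ci is None else v.iloc[ci] if isinstance(v, pd.DataFrame) else v[ci])
        for k, v in ds.reduced_dims.items()
    }
    sfs = {k: (v if ci is None else np.asarray(v)[ci]) for k, v in ds.size_factors.items()}

    return SCEDataset(
        assays=assays,
        cell_metadata=cm.copy(),
        feature_metadata=fm.copy(),
        control_sets=new_controls,
        reduced_dims={k: v.copy() for k, v in rdims.items()},
        size_factors=sfs,
        extra_slots=dict(ds.extra_slots),
    )


def combine_cells(a: SCEDataset, b: SCEDataset) -> SCEDataset:
    """Concatenate the cells of two datasets over identical features.

    Requires identical feature ids in identical order, identical assay
    names, disjoint cell ids and identical control sets.  Cell-metadata
    columns are unioned, with missing values marked as NA.  Reduced
    dimensions are dropped (embeddings of different runs cannot be
    concatenated meaningfully); this is logged.  Size-factor entries
    present in both datasets are concatenated; others are dropped with a
    warning.
    """
    if not np.array_equal(a.feature_ids, b.feature_ids):
        raise DatasetError("feature ids differ (or are ordered differently)")
    if set(a.assays) != set(b.assays):
        raise DatasetError(
            f"assay names differ: {sorted(a.assays)} vs {sorted(b.assays)}"
        )
    overlap = set(a.cell_ids) & set(b.cell_ids)
    if overlap:
        raise DatasetError(f"duplicate cell ids in combine: {sorted(overlap)[:5]}")
    if {k: list(v) for k, v in a.control_sets.items()} != {
        k: list(v) for k, v in b.control_sets.items()
    }:
        raise DatasetError("control sets conflict between the two datasets")

    def _hcat(x, y):
        if sp.issparse(x) or sp.issparse(y):
            return sp.hstack([sp.csr_matrix(x), sp.csr_matrix(y)]).tocsr()
        return np.hstack([np.asarray(x), np.asarray(y)])

    assays = {}
    for name, am in a.assays.items():
        bm = b.assays[name]
        if am.scale_tag != bm.scale_tag:
            raise DatasetError(f"assay {name!r} scale_tag mismatch")
        assays[name] = ExpressionMatrix(
            _hcat(am.values, bm.values),
            am.feature_ids,
            np.concatenate([am.cell_ids, bm.cell_ids]),
            am.scale_tag,
        )

    cm = pd.concat([a.cell_metadata, b.cell_metadata], axis=0, join="outer")
    # conflicting dtypes for a shared column are an error, not a coercion
    for col in set(a.cell_metadata.columns) & set(b.cell_metadata.columns):
        ta, tb = a.cell_metadata[col].dtype, b.cell_metadata[col].dtype
        if ta != tb and not (
            pd.api.types.is_numeric_dtype(ta) and pd.api.types.is_numeric_dtype(tb)
        ):
            raise DatasetError(
                f"cell_metadata column {col!r} has conflicting dtypes {ta} vs {tb}"
            )
    fm = a.feature_metadata.copy()

    if a.reduced_dims or b.reduced_dims:
        logger.info("dropping reduced_dims on combine; embeddings are not concatenable")
    sfs = {}
    for name in set(a.size_factors) | set(b.size_factors):
        if name in a.size_factors and name in b.size_factors:
            sfs[name] = np.concatenate([a.size_factors[name], b.size_factors[name]])
        else:
            logger.warning("size factor %r present in only one dataset; dropped", name)

    return SCEDataset(
        assays=assays,
        cell_metadata=cm,
        feature_metadata=fm,
        control_sets={k: list(v) for k, v in a.control_sets.items()},
        size_factors=sfs,
        extra_slots={**a.extra_slots, **b.extra_slots},
    )


def designate_controls(ds: SCEDataset, name: str, ids: Iterable[str]) -> SCEDataset:
    """Register a named control-feature set (e.g. ``"ERCC"`` spike-ins).

    Adds a boolean ``is_control_<name>`` column to the feature metadata and
    refreshes the derived ``is_feature_control`` column (true iff the
    feature belongs to any control set).  Returns a modified copy.
    """
    if not name:
        raise DatasetError("control set name must be non-empty")
    ids = list(ids)
    fset = set(ds.feature_ids)
    unknown = [i for i in ids if i not in fset]
    if unknown:
        raise DatasetError(f"unknown feature id(s) in control set: {unknown[:5]}")
    out = ds.copy()
    out.control_sets[name] = [f for f in out.feature_ids if f in set(ids)]
    member = np.isin(out.feature_ids, list(ids))
    out.feature_metadata[f"is_control_{name}"] = member
    any_control = np.zeros(out.n_features, dtype=bool)
    for ids_ in out.control_sets.values():
        any_control |= np.isin(out.feature_ids, ids_)
    out.feature_metadata["is_feature_control"] = any_control
    return out


def endogenous_features(ds: SCEDataset) -> np.ndarray:
    """Boolean mask over features that belong to no control set."""
    mask = np.ones(ds.n_features, dtype=bool)
    for ids in ds.control_sets.values():
        mask &= ~np.isin(ds.feature_ids, ids)
    return mask
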