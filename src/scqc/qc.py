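"""Automated per-cell and per-feature quality-control metrics.

Given a dataset with designated control-feature sets (spike-ins,
mitochondrial genes, ...), a single call computes:

per cell
    total counts, log10 total counts, number of detected features,
    percentage of counts in the top-k most highly expressed features
    (k in 50/100/200/500 by default), and, per control set ``S``,
    ``pct_counts_S`` / ``n_detected_S`` / ``log10_counts_S``; plus totals
    over endogenous (non-control) features.

per feature
    mean expression, total counts, number and percentage of cells with
    detectable expression ("frequency of expression"), share of the grand
    total, and dropout percentage.

A high control percentage in a cell typically indicates that little
endogenous RNA was captured — the classic signature of a broken or dying
cell — while feature-level frequency/mean metrics flag low-abundance genes
worth filtering before downstream analysis.
"""

from __future__ import annotations

import logging
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .dataset import DatasetError, SCEDataset, endogenous_features, subset

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = (50, 100, 200, 500)

#: Cell-level QC column names that do not depend on control sets.
_BASE_CELL_COLS = ("total_counts", "log10_total_counts", "total_features")


def _log10p1(x: np.ndarray) -> np.ndarray:
    return np.log10(np.asarray(x, dtype=float) + 1.0)


def _dense_cols(values) -> np.ndarray:
    if sp.issparse(values):
        return np.asarray(values.todense())
    return np.asarray(values, dtype=float)


def _top_k_fractions(col: np.ndarray, ks: Sequence[int]) -> np.ndarray:
    """Fraction of a cell's total in its k most-expressed features.

    Ties are broken by sorting on (count descending, feature position
    ascending), which is deterministic because feature positions follow
    feature_id order within the dataset.
    """
    total = col.sum()
    if total <= 0:
        return np.zeros(len(ks))
    srt = np.sort(col)[::-1]
    csum = np.cumsum(srt)
    out = np.empty(len(ks))
    for j, k in enumerate(ks):
        kk = min(k, col.size)
        out[j] = csum[kk - 1] / total
    return out


def calculate_qc_metrics(
    ds: SCEDataset,
    assay: str = "counts",
    detection_threshold: float = 0.0,
    top_k: Sequence[int] = DEFAULT_TOP_K,
) -> SCEDataset:
    """Compute QC metric columns and append them to the metadata tables.

    Recomputation overwrites any previous QC columns, so the operation is
    idempotent.  ``detection_threshold`` uses a strict inequality: a value
    counts as "expressed" when it is strictly greater than the threshold.
    Returns a modified copy of the dataset.
    """
    out = ds.copy()
    a = out.assay(assay)
    X = _dense_cols(a.values)  # features x cells
    n_features, n_cells = X.shape

    col_sums = X.sum(axis=0)
    if np.all(col_sums == 0):
        logger.warning("assay %r is all zero; percentage metrics defined as 0", assay)

    cm = pd.DataFrame(index=out.cell_metadata.index)
    cm["total_counts"] = col_sums
    cm["log10_total_counts"] = _log10p1(col_sums)
    cm["total_features"] = (X > detection_threshold).sum(axis=0)

    ks = [int(k) for k in top_k]
    topk = np.stack([_top_k_fractions(X[:, c], ks) for c in range(n_cells)])
    for j, k in enumerate(ks):
        cm[f"pct_counts_top_{k}"] = 100.0 * topk[:, j]

    with np.errstate(divide="ignore", invalid="ignore"):
        for name, ids in out.control_sets.items():
            mask = np.isin(out.feature_ids, ids)
            sub = X[mask, :]
            csum = sub.sum(axis=0) if sub.size else np.zeros(n_cells)
            pct = np.where(col_sums > 0, 100.0 * csum / np.where(col_sums > 0, col_sums, 1.0), 0.0)
            cm[f"pct_counts_{name}"] = pct
            cm[f"n_detected_{name}"] = (sub > detection_threshold).sum(axis=0) if sub.size else 0
            cm[f"log10_counts_{name}"] = _log10p1(csum)

    endo = endogenous_features(out)
    endo_sum = X[endo, :].sum(axis=0) if endo.any() else np.zeros(n_cells)
    cm["total_counts_endogenous"] = endo_sum
    cm["log10_counts_endogenous"] = _log10p1(endo_sum)

    fm = pd.DataFrame(index=out.feature_metadata.index)
    fm["mean_expression"] = X.mean(axis=1)
    fm["total_feature_counts"] = X.sum(axis=1)
    fm["n_cells_expressed"] = (X > detection_threshold).sum(axis=1)
    fm["pct_cells_expressed"] = 100.0 * fm["n_cells_expressed"] / n_cells
    grand = X.sum()
    fm["pct_total_counts"] = (
        100.0 * fm["total_feature_counts"] / grand if grand > 0 else 0.0
    )
    fm["pct_dropout"] = 100.0 - fm["pct_cells_expressed"]

    # overwrite-and-append: drop any stale QC columns first
    out.cell_metadata = out.cell_metadata.drop(columns=cm.columns, errors="ignore").join(cm)
    out.feature_metadata = out.feature_metadata.drop(columns=fm.columns, errors="ignore").join(fm)
    return out


def _filter(ds: SCEDataset, table: pd.DataFrame, predicate, axis: str) -> SCEDataset:
    try:
        keep = np.asarray(predicate(table), dtype=bool)
    except KeyError as exc:
        raise DatasetError(f"predicate references missing QC column: {exc}") from None
    if keep.shape != (len(table),):
        raise DatasetError("predicate must return one boolean per row of the QC table")
    kept_ids = list(table.index[keep])
    logger.info("filter_%ss: kept %d, removed %d", axis, keep.sum(), (~keep).sum())
    if axis == "cell":
        return subset(ds, keep_cells=kept_ids)
    return subset(ds, keep_features=kept_ids)


def filter_cells(ds: SCEDataset, predicate: Callable[[pd.DataFrame], "pd.Series"]) -> SCEDataset:
    """Keep cells for which ``predicate(cell_metadata)`` is true."""
    return _filter(ds, ds.cell_metadata, predicate, "cell")


def filter_features(ds: SCEDataset, predicate: Callable[[pd.DataFrame], "pd.Series"]) -> SCEDataset:
    """Keep features for which ``predicate(feature_metadata)`` is true."""
    return _filter(ds, ds.feature_metadata, predicate, "feature")
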