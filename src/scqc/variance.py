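"""Explanatory-variable analysis: marginal R-squared screening.

For every feature and every candidate metadata variable we fit the
one-covariate linear model

    expression_f = intercept + variable + error

(categorical variables are one-hot encoded against a reference level) and
record R-squared = 1 - RSS/TSS.  Ranking variables by their median
R-squared across features identifies experimental factors — batch,
capture machine, library depth — that drive expression variation and
should be handled during normalization or modelling.  The analysis is
purely descriptive; no significance testing is attached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import DatasetError, SCEDataset

logger = logging.getLogger(__name__)


@dataclass
class R2Matrix:
    """Features x variables marginal R-squared values."""

    values: pd.DataFrame  # index: feature ids, columns: variable names

    @property
    def median_r2(self) -> pd.Series:
        return self.values.median(axis=0)

    @property
    def variable_ranking(self) -> list[str]:
        return rank_variables(self)


def _encode(values: pd.Series) -> np.ndarray | None:
    """Design columns (without intercept) for one metadata variable.

    Continuous -> the numeric column itself; categorical -> one-hot
    indicators dropping the first (reference) level.  Returns ``None``
    when the variable has a single distinct value.
    """
    if pd.api.types.is_numeric_dtype(values) and not pd.api.types.is_bool_dtype(values):
        x = values.to_numpy(dtype=float)[:, None]
        if np.ptp(x) == 0:
            return None
        return x
    levels = pd.unique(values.astype(str))
    if len(levels) < 2:
        return None
    levels = np.sort(levels)
    return np.column_stack([(values.astype(str) == lv).to_numpy(float) for lv in levels[1:]])


def _r2_one_variable(Y: np.ndarray, x_cols: np.ndarray) -> np.ndarray:
    """Vectorised R-squared of every row of Y on [1, x_cols].

    Features with zero variance get R-squared 0 by convention.
    """
    n = Y.shape[1]
    X = np.column_stack([np.ones(n), x_cols])
    # residual-maker applied to centred responses
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ beta
    rss = (resid**2).sum(axis=0)
    tss = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    r2 = np.zeros(Y.shape[0])
    ok = tss > 0
    r2[ok] = 1.0 - rss[ok] / tss[ok]
    return np.clip(r2, 0.0, 1.0)


def explanatory_r2(
    ds: SCEDataset,
    assay: str = "log_expression",
    variables: list[str] | None = None,
) -> R2Matrix:
    """Marginal R-squared of every feature on each metadata variable.

    Cells with a missing value in a variable are dropped for that
    variable's fits only.  Variables with a single observed level are
    dropped with a warning; if nothing remains an error is raised.
    """
    a = ds.assay(assay)
    Y_all = a.dense().astype(float)
    if variables is None:
        variables = list(ds.cell_metadata.columns)
    out: dict[str, np.ndarray] = {}
    for v in variables:
        if v not in ds.cell_metadata.columns:
            raise DatasetError(f"unknown cell metadata variable {v!r}")
        col = ds.cell_metadata[v]
        ok = col.notna().to_numpy()
        enc = _encode(col[ok]) if ok.any() else None
        if enc is None:
            logger.warning("variable %r has a single level; dropped", v)
            continue
        n_params = 1 + enc.shape[1]
        if ok.sum() <= n_params:
            logger.warning("variable %r has too few cells for its levels; dropped", v)
            continue
        out[v] = _r2_one_variable(Y_all[:, ok], enc)
    if not out:
        raise DatasetError("no usable explanatory variables")
    return R2Matrix(pd.DataFrame(out, index=pd.Index(ds.feature_ids, name="feature_id")))


def rank_variables(r2: R2Matrix) -> list[str]:
    """Variables sorted by median R-squared descending, ties alphabetical."""
    med = r2.median_r2
    return sorted(med.index, key=lambda v: (-med[v], v))


def pcs_vs_variable(
    ds: SCEDataset,
    assay: str,
    variable: str,
    n_pcs: int = 10,
    **pca_kwargs,
) -> pd.DataFrame:
    """R-squared of each principal component score on one variable.

    PCs are the expression-matrix components of :func:`scqc.dimred.pca`;
    each PC's scores act as the response in the same one-covariate model
    used by :func:`explanatory_r2`.  Returns a table with columns
    ``pc`` (1-based index) and ``r2``, sorted by ``r2`` descending.
    """
    from .dimred import pca  # deferred import to avoid a cycle

    if variable not in ds.cell_metadata.columns:
        raise DatasetError(f"unknown cell metadata variable {variable!r}")
    emb = pca(ds, assay=assay, n_components=n_pcs, **pca_kwargs)
    scores = emb.coordinates.to_numpy()
    col = ds.cell_metadata[variable]
    ok = col.notna().to_numpy()
    enc = _encode(col[ok])
    if enc is None:
        raise DatasetError(f"variable {variable!r} has a single level")
    r2 = _r2_one_variable(scores[ok].T, enc)
    tab = pd.DataFrame({"pc": np.arange(1, scores.shape[1] + 1), "r2": r2})
    return tab.sort_values("r2", ascending=False, kind="mergesort").reset_index(drop=True)
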