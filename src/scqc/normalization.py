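"""Scaling normalization and design-matrix batch correction.

Size factors are per-cell positive constants dividing the counts to
remove differences in sequencing depth and capture efficiency.  Four
scaling methods are provided:

library
    column sum divided by the mean column sum.
RLE (relative log expression, median-of-ratios)
    per cell, the median over features of count / geometric-mean
    reference; features with any zero across cells are excluded from the
    reference.
TMM (trimmed mean of M-values)
    against a reference cell (the one whose upper quartile is closest to
    the mean upper quartile), the per-gene log2 ratios M are trimmed
    (30% two-sided on M, 5% on average log2 abundance A) and combined by
    a precision-weighted mean with binomial variance weights; the factor
    is 2 to that mean.
UQ (upper quartile)
    75th percentile of each cell's counts over features expressed in at
    least one cell, divided by the mean of those percentiles.

Dividing counts by the factors yields the ``normalized`` assay and
``log2(normalized + pseudocount)`` the ``log_expression`` assay.  Known
unwanted factors (batch, capture machine, QC covariates) can then be
removed by regressing each feature on a design matrix and keeping the
residuals plus the fitted intercept, so corrected values stay on the
original scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import DatasetError, ExpressionMatrix, SCEDataset, densify

logger = logging.getLogger(__name__)

METHODS = ("library", "RLE", "TMM", "UQ")


@dataclass
class SizeFactorVector:
    values: np.ndarray
    method_tag: str            # library | TMM | RLE | UQ | external
    rescaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise DatasetError("size factors must be finite and strictly positive")


@dataclass
class TMMParams:
    """Trim fractions and quantile conventions of the TMM scheme."""

    trim_m: float = 0.30        # two-sided trim fraction on M-values
    trim_a: float = 0.05        # two-sided trim fraction on A-values
    uq_quantile: float = 0.75   # reference-cell selection quantile


def _geometric_mean_rescale(sf: np.ndarray) -> np.ndarray:
    return sf / np.exp(np.mean(np.log(sf)))


def _check_counts(X: np.ndarray, cell_ids) -> None:
    zero = X.sum(axis=0) == 0
    if zero.any():
        bad = np.asarray(cell_ids)[zero]
        raise DatasetError(f"cell(s) with all-zero counts: {list(bad[:5])}")


def _sf_library(X: np.ndarray) -> np.ndarray:
    s = X.sum(axis=0)
    return s / s.mean()


def _sf_rle(X: np.ndarray) -> np.ndarray:
    expressed_everywhere = np.all(X > 0, axis=1)
    if not expressed_everywhere.any():
        raise DatasetError(
            "RLE reference is empty (no feature nonzero in all cells); "
            "filter low-abundance features first"
        )
    sub = X[expressed_everywhere]
    ref = np.exp(np.mean(np.log(sub), axis=1))  # per-feature geometric mean
    return np.median(sub / ref[:, None], axis=0)


def _sf_uq(X: np.ndarray, q: float = 0.75) -> np.ndarray:
    nonzero_somewhere = X.sum(axis=1) > 0
    sub = X[nonzero_somewhere]
    uq = np.quantile(sub, q, axis=0)  # type-7 linear interpolation
    if np.any(uq == 0):
        raise DatasetError("upper quartile is zero for some cell; filter features first")
    return uq / uq.mean()


def _trim_keep(x: np.ndarray, trim: float) -> np.ndarray:
    """Two-sided trim by order statistics; boundary ties are kept.

    Values equal to the trim-boundary order statistics stay in, which
    makes the mask independent of how exact ties happen to be ordered.
    """
    n = x.size
    lo = int(np.floor(n * trim))
    srt = np.sort(x)
    return (x >= srt[lo]) & (x <= srt[n - 1 - lo])


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    """Trimmed, precision-weighted mean of per-gene log2 ratios obs/ref."""
    both = (obs > 0) & (ref > 0)
    o, r = obs[both], ref[both]
    m = np.log2(o) - np.log2(r)
    a = 0.5 * (np.log2(o) + np.log2(r))
    # asymptotic binomial variance of M for the cell pair
    var = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)

    n = m.size
    if n == 0:
        return 0.0
    keep = _trim_keep(m, trim_m) & _trim_keep(a, trim_a)
    if not keep.any() or np.ptp(m) == 0:
        # degenerate (e.g. all M equal): the untrimmed weighted mean
        keep = np.ones(n, dtype=bool)
    w = 1.0 / var[keep]
    return float(np.sum(w * m[keep]) / np.sum(w))


def size_factors(
    counts: ExpressionMatrix,
    method: str = "TMM",
    rescale: bool = True,
    tmm_params: TMMParams | None = None,
) -> SizeFactorVector:
    """Compute per-cell size factors from a counts matrix.

    Every method is scale-equivariant: multiplying one cell's counts by a
    constant multiplies its factor by that constant (exactly for
    library/RLE/UQ; for TMM exactly when M-values are constant).  With
    ``rescale`` the factors are divided by their geometric mean so they
    average out to 1 on the log scale.
    """
    if method not in METHODS:
        raise DatasetError(f"unknown method {method!r}; choose from {METHODS}")
    X = densify(counts.values).astype(float)
    _check_counts(X, counts.cell_ids)

    if method == "library":
        sf = _sf_library(X)
    elif method == "RLE":
        sf = _sf_rle(X)
    elif method == "UQ":
        sf = _sf_uq(X)
    else:  # TMM
        p = tmm_params or TMMParams()
        lib = X.sum(axis=0)
        scaled_uq = np.array(
            [np.quantile(X[:, c][X[:, c] > 0], p.uq_quantile) for c in range(X.shape[1])]
        )
        ref_idx = int(np.argmin(np.abs(scaled_uq - scaled_uq.mean())))
        ref = X[:, ref_idx]
        logf = np.array(
            [
                _tmm_pair(X[:, c], ref, lib[c], lib[ref_idx], p.trim_m, p.trim_a)
                if c != ref_idx
                else 0.0
                for c in range(X.shape[1])
            ]
        )
        sf = 2.0**logf

    if rescale:
        sf = _geometric_mean_rescale(sf)
    return SizeFactorVector(sf, method_tag=method, rescaled=rescale)


def normalize_expression(
    ds: SCEDataset,
    sf: SizeFactorVector | np.ndarray,
    assay: str = "counts",
    pseudocount: float = 1.0,
) -> SCEDataset:
    """Add ``normalized`` (= counts / size factor) and ``log_expression``
    (= log2(normalized + pseudocount)) assays; stores the factors under
    the name ``"default"``."""
    values = sf.values if isinstance(sf, SizeFactorVector) else np.asarray(sf, dtype=float)
    if values.shape != (ds.n_cells,):
        raise DatasetError("size factor length does not match number of cells")
    out = ds.copy()
    X = densify(out.assay(assay).values).astype(float)
    norm = X / values[None, :]
    out.set_assay("normalized", ExpressionMatrix(norm, out.feature_ids, out.cell_ids, "normalized"))
    out.set_assay(
        "log_expression",
        ExpressionMatrix(np.log2(norm + pseudocount), out.feature_ids, out.cell_ids, "log_expression"),
    )
    out.size_factors["default"] = values
    out.validate()
    return out


def build_design_matrix(
    metadata: pd.DataFrame, variables: list[str]
) -> pd.DataFrame:
    """Cells x q design matrix with an intercept, from metadata variables.

    Categorical variables are one-hot encoded dropping the reference
    (alphabetically first) level; continuous variables enter as-is.
    Aliased (linearly dependent) columns are dropped with a log message;
    the result is full column rank.
    """
    cols: dict[str, np.ndarray] = {"(intercept)": np.ones(len(metadata))}
    for v in variables:
        if v not in metadata.columns:
            raise DatasetError(f"unknown metadata variable {v!r}")
        s = metadata[v]
        if pd.api.types.is_numeric_dtype(s) and not pd.api.types.is_bool_dtype(s):
            cols[v] = s.to_numpy(dtype=float)
        else:
            levels = np.sort(pd.unique(s.astype(str)))
            for lv in levels[1:]:
                cols[f"{v}[{lv}]"] = (s.astype(str) == lv).to_numpy(float)
    X = pd.DataFrame(cols, index=metadata.index)
    # drop aliased columns greedily, keeping earlier columns
    keep: list[str] = []
    for c in X.columns:
        trial = X[keep + [c]].to_numpy()
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(c)
        else:
            logger.warning("design column %r is aliased; dropped", c)
    return X[keep]


def regress_out(
    ds: SCEDataset,
    assay: str,
    design: pd.DataFrame,
) -> ExpressionMatrix:
    """Residual expression after removing design-matrix effects.

    Each feature is fit by least squares on the design; the output is the
    residuals plus the fitted intercept term, so feature-level location
    is preserved while nuisance terms are removed.  Deterministic and
    idempotent (regressing the residuals on the same design returns them
    unchanged).
    """
    X = design.to_numpy(dtype=float)
    n, q = X.shape
    if n != ds.n_cells:
        raise DatasetError("design matrix rows must match number of cells")
    if n <= q:
        raise DatasetError(f"{n} cells cannot support a {q}-column design")
    rank = np.linalg.matrix_rank(X)
    if rank < q:
        raise DatasetError(
            f"design matrix is rank deficient ({rank} < {q}); "
            f"columns: {list(design.columns)}"
        )
    if "(intercept)" not in design.columns:
        raise DatasetError("design matrix must contain an '(intercept)' column")

    Y = densify(ds.assay(assay).values).astype(float)  # features x cells
    zero_heavy = (Y == 0).mean(axis=1) > 0.5
    if zero_heavy.any():
        logger.warning(
            "%d feature(s) have >50%% zeros; linear-model residuals may be "
            "poorly behaved for them",
            int(zero_heavy.sum()),
        )
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # q x features
    resid = Y.T - X @ beta                           # cells x features
    icol = list(design.columns).index("(intercept)")
    corrected = (resid + np.outer(X[:, icol], beta[icol])).T
    return ExpressionMatrix(corrected, ds.feature_ids, ds.cell_ids, "residuals")
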