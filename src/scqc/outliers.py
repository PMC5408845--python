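"""Automatic multivariate outlier detection on cell QC metrics.

Low-quality cells rarely fail on a single metric; they show a joint
signature (few detected genes, low endogenous counts, inflated spike-in
percentage).  This module flags such cells with the two-phase
principal-component outlier scheme of Filzmoser, Maronna & Werner (2008),
operating on robustly sphered QC metrics:

Phase 1 (location outliers)
    Each variable is sphered by (x - median) / MAD.  Principal components
    covering >= 99% of variance are retained and re-sphered by their own
    median/MAD.  Components are weighted by absolute excess kurtosis — a
    component containing grouped outliers has kurtosis far from the
    Gaussian value 3 — and a weighted norm per cell is converted to a
    weight ``w1`` in [0, 1] through a translated biweight whose constants
    come from the empirical distance distribution.

Phase 2 (scatter outliers)
    The unweighted norm on the same components is converted to ``w2`` via
    chi-square quantile cutoffs.

The final weight ``w = (w1 + s)(w2 + s) / (1 + s)^2`` is compared with a
cutoff (default 0.25): cells below it are declared outliers.  The whole
procedure is deterministic — no randomness anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: normal-consistency constant used by the robust MAD scale estimate
MAD_SCALE = 1.4826


class OutlierError(ValueError):
    pass


@dataclass(frozen=True)
class PcoutConfig:
    """Constants of the two-phase outlier scheme (published defaults)."""

    explained_variance: float = 0.99   # PCs retained to cover this fraction
    location_m_quantile: float = 1 / 3  # distance quantile where downweighting starts
    location_c: float = 2.5             # median + c * MAD -> zero-weight bound
    scatter_m_quantile: float = 0.25    # chi-square quantile where downweighting starts
    scatter_c_quantile: float = 0.99    # chi-square quantile -> zero-weight bound
    scaling_constant: float = 0.25      # s in the weight combination
    outlier_cutoff: float = 0.25        # flag cells with final weight below this


DEFAULT_CONFIG = PcoutConfig()


@dataclass
class OutlierResult:
    """Per-cell weights/flags plus the internals used to compute them."""

    cell_ids: np.ndarray
    location_weight: np.ndarray    # w1
    scatter_weight: np.ndarray     # w2
    final_weight: np.ndarray       # w
    is_outlier: np.ndarray
    sphered: pd.DataFrame          # cells x p robustly sphered metrics
    components: np.ndarray         # cells x p* re-sphered semi-robust PCs
    variables: list[str] = field(default_factory=list)
    config: PcoutConfig = DEFAULT_CONFIG

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "w1": self.location_weight,
                "w2": self.scatter_weight,
                "w": self.final_weight,
                "is_outlier": self.is_outlier,
            },
            index=pd.Index(self.cell_ids, name="cell_id"),
        )


def _median_mad(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    med = np.median(x, axis=0)
    mad = MAD_SCALE * np.median(np.abs(x - med), axis=0)
    return med, mad


def _biweight(dist: np.ndarray, lower: float, upper: float) -> np.ndarray:
    """Translated biweight: 1 below ``lower``, 0 above ``upper``, smooth between."""
    if upper <= lower:
        # degenerate distance distribution: nothing is downweighted
        return np.ones_like(dist)
    w = (1.0 - ((dist - lower) / (upper - lower)) ** 2) ** 2
    w[dist < lower] = 1.0
    w[dist > upper] = 0.0
    return w


def detect_outliers(
    qc: pd.DataFrame,
    selected_variables: list[str] | None = None,
    outlier_cutoff: float | None = None,
    config: PcoutConfig = DEFAULT_CONFIG,
) -> OutlierResult:
    """Run the two-phase robust-PC outlier detector on a cell QC table.

    Parameters
    ----------
    qc
        Cell metadata / QC table indexed by cell id.
    selected_variables
        Numeric columns to use; defaults to
        :func:`default_outlier_variables`.  Variables with zero spread
        (MAD = 0) are dropped with a warning.
    outlier_cutoff
        Cells with final weight strictly below this are flagged
        (default from ``config``).
    """
    if selected_variables is None:
        selected_variables = default_outlier_variables(qc)
    if outlier_cutoff is None:
        outlier_cutoff = config.outlier_cutoff

    missing = [v for v in selected_variables if v not in qc.columns]
    if missing:
        raise OutlierError(f"QC table lacks column(s): {missing}")
    if len(selected_variables) < 2:
        raise OutlierError("need at least 2 variables for multivariate detection")

    X = qc[selected_variables].to_numpy(dtype=float)
    n = X.shape[0]
    if n < 10:
        raise OutlierError(f"need at least 10 cells, got {n}")

    med, mad = _median_mad(X)
    keep = mad > 0
    if not keep.all():
        dropped = [v for v, k in zip(selected_variables, keep) if not k]
        logger.warning("dropping constant variable(s) with zero MAD: %s", dropped)
    variables = [v for v, k in zip(selected_variables, keep) if k]
    X, med, mad = X[:, keep], med[keep], mad[keep]
    p = X.shape[1]
    if p < 2:
        raise OutlierError("fewer than 2 variables with nonzero spread")
    if n <= p:
        raise OutlierError(
            f"{n} cells for {p} variables; select fewer variables than cells"
        )

    # robust sphering of the raw metrics
    Z = (X - med) / mad

    # semi-robust principal components: classical PCA on the sphered data
    Zc = Z - Z.mean(axis=0)
    _, svals, Vt = np.linalg.svd(Zc, full_matrices=False)
    var = svals**2
    frac = np.cumsum(var) / var.sum()
    p_star = int(np.searchsorted(frac, config.explained_variance) + 1)
    p_star = min(p_star, p)
    scores = Z @ Vt[:p_star].T  # scores of the *uncentered* sphered data

    s_med, s_mad = _median_mad(scores)
    if np.any(s_mad == 0):
        s_mad = np.where(s_mad == 0, 1.0, s_mad)
    comps = (scores - s_med) / s_mad

    # phase 1: kurtosis-weighted robust distance -> location weight w1
    kurt_w = np.abs((comps**4).mean(axis=0) - 3.0)
    if kurt_w.sum() == 0:
        kurt_w = np.ones(p_star)
    kurt_w = kurt_w / kurt_w.sum()
    d1 = np.sqrt(((comps**2) * kurt_w).sum(axis=1))
    med_d1 = np.median(d1)
    if med_d1 > 0:
        d1 = d1 * np.sqrt(stats.chi2.ppf(0.5, p_star)) / med_d1
    m1 = np.quantile(d1, config.location_m_quantile)
    c1 = np.median(d1) + config.location_c * MAD_SCALE * np.median(np.abs(d1 - np.median(d1)))
    w1 = _biweight(d1, m1, c1)

    # phase 2: unweighted distance with chi-square cutoffs -> scatter weight w2
    d2 = np.sqrt((comps**2).sum(axis=1))
    med_d2 = np.median(d2)
    if med_d2 > 0:
        d2 = d2 * np.sqrt(stats.chi2.ppf(0.5, p_star)) / med_d2
    m2 = np.sqrt(stats.chi2.ppf(config.scatter_m_quantile, p_star))
    c2 = np.sqrt(stats.chi2.ppf(config.scatter_c_quantile, p_star))
    w2 = _biweight(d2, m2, c2)

    s = config.scaling_constant
    w = (w1 + s) * (w2 + s) / (1 + s) ** 2
    flagged = w < outlier_cutoff

    return OutlierResult(
        cell_ids=np.asarray(qc.index, dtype=object),
        location_weight=w1,
        scatter_weight=w2,
        final_weight=w,
        is_outlier=flagged,
        sphered=pd.DataFrame(Z, index=qc.index, columns=variables),
        components=comps,
        variables=variables,
        config=config,
    )


def default_outlier_variables(qc: pd.DataFrame) -> list[str]:
    """The default QC variables for outlier detection.

    Per control set: percentage of counts, number detected and log-counts
    of the control features; plus the top-100 percentage, the number of
    detected features and the log-counts from endogenous features.  When
    no control set was designated the control-based entries are skipped
    with a warning.
    """
    if qc.shape[0] == 0 or qc.shape[1] == 0:
        raise OutlierError("empty QC table; run calculate_qc_metrics first")
    control_sets = sorted(
        c[len("pct_counts_"):]
        for c in qc.columns
        if c.startswith("pct_counts_") and not c.startswith("pct_counts_top_")
    )
    cols: list[str] = []

    def _add(c: str) -> None:
        if c in qc.columns and c not in cols:
            cols.append(c)

    _add("pct_counts_top_100")
    _add("total_features")
    for s in control_sets:
        _add(f"pct_counts_{s}")
    for s in control_sets:
        _add(f"n_detected_{s}")
    if control_sets:
        # endogenous/control split is only informative when controls exist
        _add("log10_counts_endogenous")
    for s in control_sets:
        _add(f"log10_counts_{s}")
    if not control_sets:
        logger.warning(
            "no control sets designated; outlier detection uses only %s", cols
        )
    return cols
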