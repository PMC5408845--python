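"""Statistics behind the QC plots, plus rendering.

Each diagnostic plot is backed by a pure computation that returns plain
tables and is tested numerically; :func:`render` is the only operation
that writes image files.

* cumulative expression profiles — per cell, the proportion of the
  library contained in its top-k most-expressed features (k = 1..K).
  Low-complexity libraries (few genes holding most counts) rise steeply;
  failed wells look like blanks.  Preferred over boxplots, which handle
  the long tail of zero/low observations poorly.
* highest-expressed features — the n features with the largest total
  counts, their share of the grand total and the per-cell distribution
  of that share.  Spike-ins, mitochondrial and ribosomal genes commonly
  dominate; anything unexpected flags a quantification problem.
* frequency vs mean — per feature, mean expression against the
  percentage of cells expressing it, with control features highlighted
  and reference lines at the median feature mean and 50% frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import DatasetError, SCEDataset, densify

logger = logging.getLogger(__name__)

JITTER_SEED = 0  # default seed for categorical-axis jitter


@dataclass
class CumulativeProfile:
    """Per-cell cumulative top-k expression proportions, k = 1..K."""

    proportions: pd.DataFrame  # cells x K, columns "top_1".."top_K"

    @property
    def k_max(self) -> int:
        return self.proportions.shape[1]


def cumulative_expression(ds: SCEDataset, assay: str = "counts", K: int = 500) -> CumulativeProfile:
    """Proportion of each cell's total in its k most-expressed features.

    Counts are sorted descending (ties by feature id, which is the row
    order); cells with zero total get an all-zero profile and a warning.
    """
    X = densify(ds.assay(assay).values).astype(float)
    if X.size and X.min() < 0:
        raise DatasetError("cumulative expression requires a non-negative assay")
    n_features, n_cells = X.shape
    K = int(K)
    out = np.zeros((n_cells, K))
    for c in range(n_cells):
        col = X[:, c]
        total = col.sum()
        if total == 0:
            logger.warning("cell %r has zero total; profile set to 0", str(ds.cell_ids[c]))
            continue
        csum = np.cumsum(np.sort(col)[::-1]) / total
        if K <= n_features:
            out[c] = csum[:K]
        else:
            out[c, :n_features] = csum
            out[c, n_features:] = csum[-1]
    df = pd.DataFrame(out, index=pd.Index(ds.cell_ids, name="cell_id"),
                      columns=[f"top_{k}" for k in range(1, K + 1)])
    return CumulativeProfile(df)


def highest_expressed(ds: SCEDataset, assay: str = "counts", n: int = 20) -> pd.DataFrame:
    """The ``n`` features with highest total counts.

    Returns a table indexed by feature id with ``pct_total`` (share of the
    grand total) and one ``pct_in_<cell>`` column per cell (the feature's
    share within that cell), sorted by total descending with ties broken
    by feature id ascending.
    """
    if n < 1:
        raise DatasetError("n must be >= 1")
    X = densify(ds.assay(assay).values).astype(float)
    totals = X.sum(axis=1)
    grand = totals.sum()
    order = sorted(range(len(totals)), key=lambda i: (-totals[i], str(ds.feature_ids[i])))
    top = order[: min(n, len(totals))]
    cell_totals = X.sum(axis=0)
    safe = np.where(cell_totals > 0, cell_totals, 1.0)
    rows = {}
    for i in top:
        rows[str(ds.feature_ids[i])] = {
            "total_counts": totals[i],
            "pct_total": 100.0 * totals[i] / grand if grand > 0 else 0.0,
            **{
                f"pct_in_{ds.cell_ids[c]}": 100.0 * X[i, c] / safe[c] if cell_totals[c] > 0 else 0.0
                for c in range(X.shape[1])
            },
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "feature_id"
    return df


def freq_vs_mean(ds: SCEDataset) -> dict:
    """Frequency-of-expression vs mean-expression table with reference lines.

    A pure projection of the feature QC table; requires
    :func:`scqc.qc.calculate_qc_metrics` to have run.  Returns a dict
    with the per-feature ``table`` and the two reference lines: the
    median of feature mean expression (vertical) and 50% frequency
    (horizontal).
    """
    fm = ds.feature_metadata
    needed = {"mean_expression", "pct_cells_expressed"}
    if not needed <= set(fm.columns):
        raise DatasetError("feature QC metrics missing; run calculate_qc_metrics first")
    is_control = (
        fm["is_feature_control"].to_numpy(bool)
        if "is_feature_control" in fm.columns
        else np.zeros(len(fm), dtype=bool)
    )
    table = pd.DataFrame(
        {
            "mean_expression": fm["mean_expression"],
            "pct_cells_expressed": fm["pct_cells_expressed"],
            "is_control": is_control,
        },
        index=fm.index,
    )
    return {
        "table": table,
        "median_mean_expression": float(np.median(table["mean_expression"])),
        "frequency_line": 50.0,
    }


# --------------------------------------------------------------------------
# rendering


def _deterministic_rc():
    import matplotlib

    matplotlib.use("Agg", force=False)
    matplotlib.rcParams["svg.hashsalt"] = "scqc"
    return matplotlib


def _aesthetic(ds: SCEDataset | None, column: str | None):
    if column is None:
        return None
    if ds is None or column not in ds.cell_metadata.columns:
        raise DatasetError(f"unknown aesthetic column {column!r}")
    return ds.cell_metadata[column]


def render(
    plot_kind: str,
    data,
    out_path: str,
    ds: SCEDataset | None = None,
    colour_by: str | None = None,
    shape_by: str | None = None,
    size_by: str | None = None,
    facet_by: str | None = None,
    jitter_seed: int = JITTER_SEED,
) -> str:
    """Render a computed plot table to PNG/SVG/PDF.

    ``plot_kind`` is one of ``cumexpr`` (a :class:`CumulativeProfile`),
    ``highexpr`` (a :func:`highest_expressed` table), ``freqmean`` (a
    :func:`freq_vs_mean` dict), ``reduceddim`` (an embedding data frame)
    or ``expression`` (a cells-long data frame with columns ``x`` and
    ``y``; a categorical x-axis is jittered with a seeded jitter).
    Aesthetic columns are looked up in the dataset's cell metadata.
    Output is deterministic for a fixed jitter seed (SVG included).
    """
    _deterministic_rc()
    import matplotlib.pyplot as plt

    colour = _aesthetic(ds, colour_by)
    shape = _aesthetic(ds, shape_by)
    size = _aesthetic(ds, size_by)
    facet = _aesthetic(ds, facet_by)

    markers = "osD^vP*X"

    def _facet_axes():
        if facet is None:
            fig, ax = plt.subplots(figsize=(6, 4.5))
            return fig, {None: ax}, lambda _v: None
        levels = list(pd.unique(facet.astype(str)))
        fig, axes = plt.subplots(1, len(levels), figsize=(4.5 * len(levels), 4.5), squeeze=False)
        return fig, dict(zip(levels, axes[0])), None

    def _colour_values(idx):
        if colour is None:
            return None
        vals = colour.loc[idx]
        if pd.api.types.is_numeric_dtype(vals):
            return vals.to_numpy(float)
        levels = {v: i for i, v in enumerate(sorted(pd.unique(vals.astype(str))))}
        return np.array([levels[str(v)] for v in vals], dtype=float)

    if plot_kind == "cumexpr":
        profile = data.proportions if isinstance(data, CumulativeProfile) else data
        fig, axes, _ = _facet_axes()
        ks = np.arange(1, profile.shape[1] + 1)
        for cell in profile.index:
            level = str(facet.loc[cell]) if facet is not None else None
            ax = axes[level]
            cvals = _colour_values([cell]) if colour is not None else None
            ax.plot(ks, profile.loc[cell].to_numpy(), lw=0.8,
                    color=plt.cm.viridis(cvals[0] / max(1.0, np.nanmax(_colour_values(profile.index))))
                    if cvals is not None else "0.4")
        for ax in axes.values():
            ax.set_xlabel("top k features")
            ax.set_ylabel("cumulative proportion of library")
    elif plot_kind == "highexpr":
        fig, ax = plt.subplots(figsize=(6, 0.3 * len(data) + 1.5))
        y = np.arange(len(data))[::-1]
        pct_cols = [c for c in data.columns if c.startswith("pct_in_")]
        rng = np.random.default_rng(jitter_seed)
        for yi, (_fid, row) in zip(y, data.iterrows()):
            ax.scatter(row[pct_cols].to_numpy(float),
                       np.full(len(pct_cols), yi) + rng.uniform(-0.2, 0.2, len(pct_cols)),
                       s=4, color="0.6", alpha=0.5)
        ax.scatter(data["pct_total"], y, s=40, color="crimson", zorder=3)
        ax.set_yticks(y)
        ax.set_yticklabels(data.index)
        ax.set_xlabel("% of counts")
    elif plot_kind == "freqmean":
        fig, ax = plt.subplots(figsize=(6, 4.5))
        t = data["table"]
        ctrl = t["is_control"].to_numpy(bool)
        ax.scatter(t["mean_expression"][~ctrl], t["pct_cells_expressed"][~ctrl], s=8, color="0.4")
        if ctrl.any():
            ax.scatter(t["mean_expression"][ctrl], t["pct_cells_expressed"][ctrl],
                       s=14, color="crimson", label="control")
            ax.legend()
        ax.axvline(data["median_mean_expression"], ls=":", color="k")
        ax.axhline(data["frequency_line"], ls=":", color="k")
        ax.set_xscale("symlog")
        ax.set_xlabel("mean expression")
        ax.set_ylabel("% cells expressing")
    elif plot_kind == "reduceddim":
        coords = data.coordinates if hasattr(data, "coordinates") else data
        fig, ax = plt.subplots(figsize=(5.5, 4.5))
        c = _colour_values(coords.index)
        s = 20.0 if size is None else 5 + 40 * _rescale(size.loc[coords.index])
        if shape is None:
            ax.scatter(coords.iloc[:, 0], coords.iloc[:, 1], c=c, s=s, cmap="viridis")
        else:
            sh = shape.loc[coords.index].astype(str)
            for i, lv in enumerate(sorted(pd.unique(sh))):
                m = (sh == lv).to_numpy()
                ax.scatter(coords.iloc[:, 0][m], coords.iloc[:, 1][m],
                           c=None if c is None else c[m],
                           s=s if np.isscalar(s) else s[m],
                           marker=markers[i % len(markers)], cmap="viridis", label=lv)
            ax.legend()
        ax.set_xlabel(coords.columns[0])
        ax.set_ylabel(coords.columns[1])
    elif plot_kind == "expression":
        fig, ax = plt.subplots(figsize=(5.5, 4.5))
        x, yv = data["x"], data["y"]
        if pd.api.types.is_numeric_dtype(x):
            ax.scatter(x, yv, s=12, color="0.3")
        else:
            levels = sorted(pd.unique(x.astype(str)))
            pos = {lv: i for i, lv in enumerate(levels)}
            rng = np.random.default_rng(jitter_seed)
            xj = np.array([pos[str(v)] for v in x], float) + rng.uniform(-0.2, 0.2, len(x))
            ax.scatter(xj, yv, s=12, color="0.3")
            ax.set_xticks(range(len(levels)))
            ax.set_xticklabels(levels)
        ax.set_ylabel("expression")
    else:
        raise DatasetError(f"unknown plot kind {plot_kind!r}")

    fig.tight_layout()
    fig.savefig(out_path, metadata=_clean_metadata(out_path))
    plt.close(fig)
    return out_path


def _rescale(s: pd.Series) -> np.ndarray:
    v = s.to_numpy(float)
    rng_ = np.ptp(v)
    return (v - v.min()) / rng_ if rng_ > 0 else np.full(v.shape, 0.5)


def _clean_metadata(path: str) -> dict | None:
    # strip timestamps so identical inputs give byte-identical vector output
    if path.endswith(".svg"):
        return {"Date": None}
    if path.endswith(".pdf"):
        return {"CreationDate": None}
    return None
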