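"""Low-dimensional embeddings of cells.

PCA, classical multi-dimensional scaling (Torgerson), t-SNE and diffusion
maps over a chosen assay, computed by default on the features with the
most variable expression (variation across cells is what distinguishes
cell subpopulations; the most-variable genes capture it at a fraction of
the cost).  A user-supplied feature set — e.g. cell-cycle genes chosen
from prior knowledge — bypasses the variance ranking.

Every embedding is returned as an :class:`Embedding` and stored back into
the dataset's ``reduced_dims`` slot under its method name, so any stored
representation (including externally computed ones) is retrievable
through the same accessor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .dataset import DatasetError, SCEDataset, densify

logger = logging.getLogger(__name__)

DEFAULT_N_TOP = 500


@dataclass
class Embedding:
    """Cells x k coordinates plus provenance of how they were computed."""

    coordinates: pd.DataFrame        # index: cell ids
    method: str                      # PCA | tSNE | MDS | diffusion
    feature_ids: list[str]
    variance_fractions: np.ndarray | None = None  # PCA only, non-increasing
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variance_fractions is not None:
            vf = np.asarray(self.variance_fractions, dtype=float)
            if np.any(np.diff(vf) > 1e-12) or vf.sum() > 1 + 1e-9:
                raise DatasetError("PCA variance fractions must be non-increasing and sum <= 1")


def select_variable_features(ds: SCEDataset, assay: str, n_top: int = DEFAULT_N_TOP) -> list[str]:
    """Ids of the ``n_top`` features with highest variance across cells.

    Ties are broken by feature id (ascending); a constant matrix raises.
    """
    if n_top < 2:
        raise DatasetError("n_top must be at least 2")
    X = densify(ds.assay(assay).values)
    var = X.var(axis=1)
    if np.all(var == 0):
        raise DatasetError("no variable features (assay is constant)")
    order = sorted(range(len(var)), key=lambda i: (-var[i], str(ds.feature_ids[i])))
    return [str(ds.feature_ids[i]) for i in order[: min(n_top, len(var))]]


def _cells_matrix(ds: SCEDataset, assay: str, n_top: int | None, feature_ids=None):
    """cells x features matrix restricted to the working feature set."""
    if feature_ids is None:
        feature_ids = (
            select_variable_features(ds, assay, n_top) if n_top else list(map(str, ds.feature_ids))
        )
    fidx = {str(f): i for i, f in enumerate(ds.feature_ids)}
    unknown = [f for f in feature_ids if str(f) not in fidx]
    if unknown:
        raise DatasetError(f"unknown feature id(s): {unknown[:5]}")
    rows = [fidx[str(f)] for f in feature_ids]
    X = densify(ds.assay(assay).values)[rows, :].T
    return X, [str(f) for f in feature_ids]


def _store(ds: SCEDataset, emb: Embedding, name: str | None = None) -> Embedding:
    ds.reduced_dims[name or emb.method] = emb.coordinates
    return emb


def pca(
    ds: SCEDataset,
    assay: str = "log_expression",
    n_components: int = 2,
    n_top: int | None = DEFAULT_N_TOP,
    scale_features: bool = True,
    feature_ids: list[str] | None = None,
    store: bool = True,
) -> Embedding:
    """Exact principal components analysis of cells.

    Features are centred and (by default) scaled to unit variance;
    zero-variance features are dropped with a warning before scaling.
    The decomposition is an exact SVD with a deterministic sign
    convention: the largest-magnitude loading of each component is made
    positive.  ``variance_fractions`` are each component's share of the
    total variance of the (centred, scaled) matrix.
    """
    if ds.n_cells < 2:
        raise DatasetError("PCA needs at least 2 cells")
    X, feats = _cells_matrix(ds, assay, n_top, feature_ids)
    Xc = X - X.mean(axis=0)
    if scale_features:
        sd = Xc.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            logger.warning("dropping %d zero-variance feature(s) before scaling", (~keep).sum())
            Xc, feats = Xc[:, keep], [f for f, k in zip(feats, keep) if k]
            sd = sd[keep]
        Xc = Xc / sd

    max_rank = min(ds.n_cells - 1, Xc.shape[1])
    if n_components > max_rank:
        logger.warning("n_components clipped from %d to %d", n_components, max_rank)
        n_components = max_rank

    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for j in range(len(S)):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    total = (S**2).sum()
    frac = (S[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    coords = U[:, :n_components] * S[:n_components]
    df = pd.DataFrame(
        coords,
        index=pd.Index(ds.cell_ids, name="cell_id"),
        columns=[f"PC{i+1}" for i in range(n_components)],
    )
    emb = Embedding(df, "PCA", feats, variance_fractions=frac,
                    params={"scale_features": scale_features, "assay": assay})
    return _store(ds, emb) if store else emb


def mds(
    ds: SCEDataset,
    assay: str = "log_expression",
    k: int = 2,
    n_top: int | None = DEFAULT_N_TOP,
    feature_ids: list[str] | None = None,
    store: bool = True,
) -> Embedding:
    """Classical (Torgerson) scaling of Euclidean cell-cell distances."""
    n = ds.n_cells
    if n < k + 1:
        raise DatasetError(f"MDS with k={k} needs at least {k + 1} cells")
    X, feats = _cells_matrix(ds, assay, n_top, feature_ids)
    d2 = _sq_dists(X)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = np.clip(evals[:k], 0, None)
    coords = evecs[:, :k] * np.sqrt(pos)
    for j in range(k):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] *= -1
    df = pd.DataFrame(coords, index=pd.Index(ds.cell_ids, name="cell_id"),
                      columns=[f"MDS{i+1}" for i in range(k)])
    emb = Embedding(df, "MDS", feats, params={"assay": assay})
    return _store(ds, emb) if store else emb


def tsne(
    ds: SCEDataset,
    assay: str = "log_expression",
    k: int = 2,
    perplexity: float = 30.0,
    seed: int = 0,
    n_top: int | None = DEFAULT_N_TOP,
    feature_ids: list[str] | None = None,
    store: bool = True,
) -> Embedding:
    """t-distributed stochastic neighbour embedding with a mandatory seed."""
    n = ds.n_cells
    if perplexity >= (n - 1) / 3:
        raise DatasetError(
            f"perplexity {perplexity} too large for {n} cells; "
            f"use a value below {(n - 1) / 3:.1f}"
        )
    X, feats = _cells_matrix(ds, assay, n_top, feature_ids)
    logger.info("t-SNE: perplexity=%s seed=%s on %d features", perplexity, seed, len(feats))
    model = TSNE(n_components=k, perplexity=perplexity, random_state=seed, init="pca")
    coords = model.fit_transform(X)
    df = pd.DataFrame(np.asarray(coords, dtype=np.float64),
                      index=pd.Index(ds.cell_ids, name="cell_id"),
                      columns=[f"TSNE{i+1}" for i in range(k)])
    emb = Embedding(df, "tSNE", feats, seed=seed,
                    params={"perplexity": perplexity, "assay": assay})
    return _store(ds, emb) if store else emb


def diffusion_map(
    ds: SCEDataset,
    assay: str = "log_expression",
    k: int = 2,
    kernel_sigma: float | None = None,
    n_top: int | None = DEFAULT_N_TOP,
    feature_ids: list[str] | None = None,
    store: bool = True,
) -> Embedding:
    """Diffusion-map embedding from a Gaussian-kernel transition operator.

    A Gaussian kernel on Euclidean distances (width: the median pairwise
    distance unless given) is row-normalised into a transition matrix;
    the first ``k`` non-trivial right eigenvectors, scaled by their
    eigenvalues, are the diffusion coordinates.  Useful for visualising
    continuous processes such as differentiation trajectories.
    """
    n = ds.n_cells
    if n < k + 2:
        raise DatasetError(f"diffusion map with k={k} needs at least {k + 2} cells")
    X, feats = _cells_matrix(ds, assay, n_top, feature_ids)
    d2 = _sq_dists(X)
    if kernel_sigma is None:
        off = np.sqrt(d2[np.triu_indices(n, 1)])
        kernel_sigma = float(np.median(off))
        if kernel_sigma == 0:
            raise DatasetError("all cells identical; diffusion map undefined")
    K = np.exp(-d2 / (2.0 * kernel_sigma**2))
    deg = K.sum(axis=1)
    # symmetric conjugate of the row-normalised transition operator
    Di = 1.0 / np.sqrt(deg)
    A = Di[:, None] * K * Di[None, :]
    evals, evecs = np.linalg.eigh(A)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    psi = Di[:, None] * evecs  # right eigenvectors of the transition matrix
    coords = psi[:, 1 : k + 1] * evals[1 : k + 1][None, :]
    for j in range(k):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] *= -1
    df = pd.DataFrame(coords, index=pd.Index(ds.cell_ids, name="cell_id"),
                      columns=[f"DC{i+1}" for i in range(k)])
    emb = Embedding(df, "diffusion", feats,
                    params={"kernel_sigma": kernel_sigma, "assay": assay})
    return _store(ds, emb) if store else emb


def _sq_dists(X: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(X, metric="sqeuclidean"))
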