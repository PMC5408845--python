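"""Deterministic synthetic scRNA-seq count generator with known truth.

Counts follow the standard overdispersed gamma-Poisson (negative
binomial) model: gene means are drawn log-normal, each cell has a
log-normal depth factor, and observed counts are Poisson draws around a
gamma-perturbed mean.  Dropout arises naturally from low means; no
separate zero-inflation knob is used.

Planted structure gives every downstream module a ground truth to
recover:

* spike-in controls — expected counts constant across cells, so a cell
  that captured little endogenous RNA shows an inflated spike-in
  percentage (the classic failed-cell signature);
* low-quality cells — a capture-efficiency multiplier < 1 applied to the
  endogenous means only;
* a batch effect — a multiplicative log2 fold change applied to a fixed
  fraction of genes in the second batch;
* a "machine"-like metadata factor assigned independently of expression,
  usable as a null explanatory variable.

The same seed always reproduces the identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import DatasetError, ExpressionMatrix, SCEDataset, designate_controls


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are a realistic small C1-style run."""

    n_genes: int = 1000
    n_cells: int = 100
    n_spikeins: int = 20
    seed: int = 0

    # log-normal gene mean distribution (endogenous genes)
    gene_meanlog: float = 1.0
    gene_sdlog: float = 1.5
    # spike-in pool: fewer, individually higher-abundance species
    spike_meanlog: float = 3.0
    spike_sdlog: float = 0.5

    # per-cell depth: log-normal(0, sd_sf)
    sd_sf: float = 0.3
    # gamma-Poisson dispersion (0 -> pure Poisson)
    dispersion: float = 0.1

    # batch effect: multiplicative 2**batch_lfc on a gene fraction in batch 2
    batch_lfc: float = 0.0
    batch_gene_fraction: float = 0.3

    # planted low-quality cells: endogenous capture multiplier in (0, 1]
    n_low_quality: int = 0
    capture_efficiency: float = 0.05

    def validate(self) -> None:
        if self.n_cells < 2 or self.n_genes < 1:
            raise DatasetError("need at least 2 cells and 1 gene")
        if not (0 < self.capture_efficiency <= 1):
            raise DatasetError("capture_efficiency must be in (0, 1]")
        if self.n_low_quality > self.n_cells:
            raise DatasetError("more low-quality cells than cells")
        if not (0 <= self.batch_gene_fraction <= 1):
            raise DatasetError("batch_gene_fraction must be in [0, 1]")
        if self.dispersion < 0 or self.sd_sf < 0:
            raise DatasetError("dispersion and sd_sf must be non-negative")


def simulate_dataset(cfg: SimulationConfig) -> tuple[SCEDataset, pd.DataFrame]:
    """Generate a dataset plus a per-cell ground-truth table.

    Returns ``(dataset, truth)`` where ``truth`` has columns
    ``true_batch``, ``true_low_quality`` and ``true_size_factor``.
    The dataset carries ``counts``, metadata columns ``batch`` and
    ``machine``, and the spike-ins designated as control set ``"ERCC"``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    gene_ids = np.array([f"gene_{i + 1:05d}" for i in range(cfg.n_genes)], dtype=object)
    spike_ids = np.array([f"ERCC-{i + 1:05d}" for i in range(cfg.n_spikeins)], dtype=object)
    cell_ids = np.array([f"cell_{i + 1:04d}" for i in range(cfg.n_cells)], dtype=object)

    gene_means = rng.lognormal(cfg.gene_meanlog, cfg.gene_sdlog, cfg.n_genes)
    spike_means = rng.lognormal(cfg.spike_meanlog, cfg.spike_sdlog, cfg.n_spikeins)
    sf = rng.lognormal(0.0, cfg.sd_sf, cfg.n_cells) if cfg.sd_sf > 0 else np.ones(cfg.n_cells)

    batch = np.where(np.arange(cfg.n_cells) < cfg.n_cells // 2, "batch1", "batch2")
    n_affected = int(round(cfg.batch_gene_fraction * cfg.n_genes))
    affected = rng.choice(cfg.n_genes, size=n_affected, replace=False)
    batch_mult = np.ones((cfg.n_genes, cfg.n_cells))
    if cfg.batch_lfc != 0 and n_affected:
        batch_mult[np.ix_(affected, batch == "batch2")] = 2.0**cfg.batch_lfc

    low_quality = np.zeros(cfg.n_cells, dtype=bool)
    if cfg.n_low_quality:
        low_quality[rng.choice(cfg.n_cells, size=cfg.n_low_quality, replace=False)] = True
    capture = np.where(low_quality, cfg.capture_efficiency, 1.0)

    # endogenous means scale with depth, capture and batch; spike-in
    # expected counts are constant per cell (only capture-independent)
    mu_endo = gene_means[:, None] * sf[None, :] * capture[None, :] * batch_mult
    mu_spike = np.tile(spike_means[:, None], (1, cfg.n_cells))
    mu = np.vstack([mu_endo, mu_spike])

    if cfg.dispersion > 0:
        lam = rng.gamma(shape=1.0 / cfg.dispersion, scale=mu * cfg.dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(float)

    feature_ids = np.concatenate([gene_ids, spike_ids])
    ds = SCEDataset(
        assays={"counts": ExpressionMatrix(counts, feature_ids, cell_ids, "counts")}
    )
    ds.cell_metadata["batch"] = batch
    ds.cell_metadata["machine"] = rng.permutation(
        np.where(np.arange(cfg.n_cells) % 2 == 0, "machine1", "machine2")
    )
    if cfg.n_spikeins:
        ds = designate_controls(ds, "ERCC", list(spike_ids))
    ds.feature_metadata["true_mean"] = np.concatenate([gene_means, spike_means])
    ds.feature_metadata["true_batch_affected"] = np.concatenate(
        [np.isin(np.arange(cfg.n_genes), affected), np.zeros(cfg.n_spikeins, bool)]
    )

    truth = pd.DataFrame(
        {
            "true_batch": batch,
            "true_low_quality": low_quality,
            "true_size_factor": sf,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    return ds, truth
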