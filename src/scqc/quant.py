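"""Import of kallisto/Salmon per-cell quantification output.

Pseudoalignment quantifiers write one directory per cell: kallisto an
``abundance.tsv`` (columns ``target_id``, ``length``, ``eff_length``,
``est_counts``, ``tpm``), Salmon a ``quant.sf`` (``Name``, ``Length``,
``EffectiveLength``, ``TPM``, ``NumReads``).  This module reads a root
directory of such per-cell outputs into transcript x cell matrices and
collapses transcript-level values to gene level through a many-to-one
transcript-to-gene map (2-column TSV), summing counts and TPM per gene.
Running the quantifiers themselves is out of scope; only their output
tables are consumed.  Bootstrap/inferential-replicate files, when
present, are recorded as opaque paths in ``extra_slots`` — stored, never
parsed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import DatasetError, ExpressionMatrix, SCEDataset

logger = logging.getLogger(__name__)

_TOOL_FILES = {"kallisto": "abundance.tsv", "salmon": "quant.sf"}
_TOOL_COLS = {
    "kallisto": {"id": "target_id", "length": "length", "eff_length": "eff_length",
                 "counts": "est_counts", "tpm": "tpm"},
    "salmon": {"id": "Name", "length": "Length", "eff_length": "EffectiveLength",
               "counts": "NumReads", "tpm": "TPM"},
}
_BOOTSTRAP_FILES = ("abundance.h5", "aux_info")


def read_quant_dir(root: str | Path, tool: str) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Read every per-cell quantification table under ``root``.

    Cell ids are the subdirectory names (sorted).  Columns are matched by
    name, so reordered headers parse correctly.  All cells must share one
    transcript universe; differences are reported explicitly.
    """
    if tool not in _TOOL_FILES:
        raise DatasetError(f"unknown tool {tool!r}; expected one of {sorted(_TOOL_FILES)}")
    root = Path(root)
    fname, cols = _TOOL_FILES[tool], _TOOL_COLS[tool]
    cell_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not cell_dirs:
        raise DatasetError(f"no per-cell directories under {root}")

    tables: dict[str, pd.DataFrame] = {}
    for d in cell_dirs:
        f = d / fname
        if not f.exists():
            raise DatasetError(f"cell directory {d.name!r} is missing {fname}")
        df = pd.read_csv(f, sep="\t")
        missing = [c for c in cols.values() if c not in df.columns]
        if missing:
            raise DatasetError(
                f"malformed {fname} in cell {d.name!r}: missing column(s) {missing}"
            )
        t = df[[cols["id"], cols["length"], cols["eff_length"], cols["counts"], cols["tpm"]]]
        t = t.set_axis(["transcript_id", "length", "eff_length", "est_counts", "tpm"], axis=1)
        if (t["est_counts"] < 0).any():
            raise DatasetError(f"negative counts in cell {d.name!r}")
        tpm_sum = t["tpm"].sum()
        if abs(tpm_sum - 1e6) > 0.1 and tpm_sum > 0:
            logger.warning("cell %r TPM sums to %.3f, not 1e6", d.name, tpm_sum)
        tables[d.name] = t.set_index("transcript_id")

    ref = next(iter(tables.values())).index
    for cid, t in tables.items():
        if not t.index.equals(ref):
            extra = sorted(set(t.index) - set(ref))
            miss = sorted(set(ref) - set(t.index))
            raise DatasetError(
                f"cell {cid!r} transcript set differs from the first cell: "
                f"extra {extra[:5]}, missing {miss[:5]}"
            )
    return tables, [d.name for d in cell_dirs]


def read_tx2gene(path: str | Path) -> pd.Series:
    """Two-column TSV transcript_id -> gene_id map (no header required)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise DatasetError("tx2gene file must have two tab-separated columns")
    if df.iloc[0, 0].lower() in {"transcript_id", "tx", "transcript"}:
        df = df.iloc[1:]
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].to_numpy())
    dup = s.index[s.index.duplicated()]
    if len(dup):
        raise DatasetError(f"transcript(s) mapped more than once: {list(dup[:5])}")
    return s


def collapse_to_genes(
    tables: dict[str, pd.DataFrame],
    tx2gene: pd.Series,
    unmapped_policy: str = "error",
) -> SCEDataset:
    """Sum transcript-level counts and TPM into gene-level assays.

    Mass is conserved exactly per cell over mapped transcripts.  With
    ``unmapped_policy="drop"`` transcripts absent from the map are
    discarded (and logged); with ``"error"`` they raise.  The number of
    transcripts per gene is recorded in the feature metadata.
    """
    if unmapped_policy not in {"error", "drop"}:
        raise DatasetError("unmapped_policy must be 'error' or 'drop'")
    if len(tx2gene) == 0:
        raise DatasetError("empty transcript-to-gene map")
    cell_ids = list(tables)
    ref = next(iter(tables.values())).index
    unmapped = [t for t in ref if t not in tx2gene.index]
    if unmapped:
        if unmapped_policy == "error":
            raise DatasetError(f"unmapped transcript id(s): {unmapped[:10]}")
        logger.info("dropping %d unmapped transcript(s): %s", len(unmapped), unmapped[:5])
    mapped = [t for t in ref if t in tx2gene.index]
    genes = pd.Index(sorted(pd.unique(tx2gene.loc[mapped])), name="feature_id")
    gene_of = tx2gene.loc[mapped]

    counts = np.zeros((len(genes), len(cell_ids)))
    tpm = np.zeros_like(counts)
    gpos = {g: i for i, g in enumerate(genes)}
    rows = np.array([gpos[g] for g in gene_of], dtype=int)
    for j, cid in enumerate(cell_ids):
        t = tables[cid].loc[mapped]
        np.add.at(counts[:, j], rows, t["est_counts"].to_numpy(float))
        np.add.at(tpm[:, j], rows, t["tpm"].to_numpy(float))

    fids = np.asarray(genes, dtype=object)
    cids = np.asarray(cell_ids, dtype=object)
    ds = SCEDataset(
        assays={
            "counts": ExpressionMatrix(counts, fids, cids, "counts"),
            "tpm": ExpressionMatrix(tpm, fids, cids, "tpm"),
        }
    )
    ds.feature_metadata["n_transcripts"] = gene_of.groupby(gene_of).size().reindex(genes).to_numpy()
    return ds


def import_quant(root: str | Path, tool: str, tx2gene_path: str | Path,
                 unmapped_policy: str = "error") -> SCEDataset:
    """Read a quantification directory and collapse it to gene level."""
    tables, cells = read_quant_dir(root, tool)
    ds = collapse_to_genes(tables, read_tx2gene(tx2gene_path), unmapped_policy)
    # record, but never parse, any bootstrap/auxiliary outputs
    root = Path(root)
    aux = {
        f"{c}/{b}": str(root / c / b)
        for c in cells
        for b in _BOOTSTRAP_FILES
        if (root / c / b).exists()
    }
    if aux:
        ds.extra_slots["quant_bootstrap_paths"] = aux
    return ds
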