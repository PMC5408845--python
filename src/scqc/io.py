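"""On-disk dataset format.

A dataset is a directory::

    <root>/
      assays/<name>.mtx        # MatrixMarket coordinate, 1-based (sparse)
      assays/<name>.tsv        # or dense: header row of cell ids,
                               # first column feature ids
      cell_metadata.tsv
      feature_metadata.tsv
      control_sets.json
      size_factors.tsv         # cell_id + one column per size-factor name
      reduced_dims/<name>.tsv

All TSVs are UTF-8, tab-delimited with ``.`` as decimal separator.  Floats
are written with 17 significant digits so that write -> read round-trips
float64 values exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .dataset import DatasetError, ExpressionMatrix, SCEDataset

_FLOAT_FMT = "%.17g"


def _ids_path(assay_dir: Path, which: str) -> Path:
    return assay_dir / f"{which}.txt"


def write_dataset(ds: SCEDataset, root: str | Path) -> Path:
    root = Path(root)
    assay_dir = root / "assays"
    assay_dir.mkdir(parents=True, exist_ok=True)

    # shared id files for sparse assays
    _ids_path(assay_dir, "feature_ids").write_text("\n".join(map(str, ds.feature_ids)) + "\n")
    _ids_path(assay_dir, "cell_ids").write_text("\n".join(map(str, ds.cell_ids)) + "\n")

    for name, a in ds.assays.items():
        if sp.issparse(a.values):
            mmwrite(str(assay_dir / f"{name}.mtx"), sp.coo_matrix(a.values), precision=17)
        else:
            df = pd.DataFrame(a.values, index=pd.Index(a.feature_ids, name="feature_id"), columns=a.cell_ids)
            df.to_csv(assay_dir / f"{name}.tsv", sep="\t", float_format=_FLOAT_FMT)

    tags = {name: a.scale_tag for name, a in ds.assays.items()}
    (root / "assay_tags.json").write_text(json.dumps(tags, indent=1, sort_keys=True))

    ds.cell_metadata.to_csv(root / "cell_metadata.tsv", sep="\t", float_format=_FLOAT_FMT)
    ds.feature_metadata.to_csv(root / "feature_metadata.tsv", sep="\t", float_format=_FLOAT_FMT)
    (root / "control_sets.json").write_text(
        json.dumps({k: list(v) for k, v in ds.control_sets.items()}, indent=1, sort_keys=True)
    )

    if ds.size_factors:
        sf = pd.DataFrame(ds.size_factors, index=pd.Index(ds.cell_ids, name="cell_id"))
        sf.to_csv(root / "size_factors.tsv", sep="\t", float_format=_FLOAT_FMT)

    if ds.reduced_dims:
        rd_dir = root / "reduced_dims"
        rd_dir.mkdir(exist_ok=True)
        for name, rd in ds.reduced_dims.items():
            df = rd if isinstance(rd, pd.DataFrame) else pd.DataFrame(np.asarray(rd))
            df = df.copy()
            df.index = pd.Index(ds.cell_ids, name="cell_id")
            df.to_csv(rd_dir / f"{name}.tsv", sep="\t", float_format=_FLOAT_FMT)
    return root


def read_dataset(root: str | Path) -> SCEDataset:
    root = Path(root)
    assay_dir = root / "assays"
    if not assay_dir.is_dir():
        raise DatasetError(f"{root} has no assays/ directory")

    tags = {}
    tag_file = root / "assay_tags.json"
    if tag_file.exists():
        tags = json.loads(tag_file.read_text())

    fid_file, cid_file = _ids_path(assay_dir, "feature_ids"), _ids_path(assay_dir, "cell_ids")
    shared_fids = np.array(fid_file.read_text().splitlines(), dtype=object) if fid_file.exists() else None
    shared_cids = np.array(cid_file.read_text().splitlines(), dtype=object) if cid_file.exists() else None

    assays = {}
    for path in sorted(assay_dir.iterdir()):
        name = path.stem
        if path.suffix == ".mtx":
            if shared_fids is None or shared_cids is None:
                raise DatasetError("sparse assay requires feature_ids.txt and cell_ids.txt")
            values = sp.csr_matrix(mmread(str(path)))
            assays[name] = ExpressionMatrix(values, shared_fids, shared_cids, tags.get(name, "counts"))
        elif path.suffix == ".tsv":
            df = pd.read_csv(path, sep="\t", index_col=0)
            assays[name] = ExpressionMatrix(
                df.to_numpy(dtype=float),
                np.asarray(df.index.astype(str), dtype=object),
                np.asarray(df.columns.astype(str), dtype=object),
                tags.get(name, "counts"),
            )
    if not assays:
        raise DatasetError(f"no assays found under {assay_dir}")

    def _read_meta(path: Path, idx_name: str) -> pd.DataFrame | None:
        if not path.exists():
            return None
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.index.name = idx_name
        return df

    cm = _read_meta(root / "cell_metadata.tsv", "cell_id")
    fm = _read_meta(root / "feature_metadata.tsv", "feature_id")

    controls = {}
    cs_file = root / "control_sets.json"
    if cs_file.exists():
        controls = {k: list(v) for k, v in json.loads(cs_file.read_text()).items()}

    size_factors = {}
    sf_file = root / "size_factors.tsv"
    if sf_file.exists():
        sf = pd.read_csv(sf_file, sep="\t", index_col=0)
        size_factors = {c: sf[c].to_numpy(dtype=float) for c in sf.columns}

    reduced = {}
    rd_dir = root / "reduced_dims"
    if rd_dir.is_dir():
        for path in sorted(rd_dir.glob("*.tsv")):
            reduced[path.stem] = pd.read_csv(path, sep="\t", index_col=0)

    return SCEDataset(
        assays=assays,
        cell_metadata=cm,
        feature_metadata=fm,
        control_sets=controls,
        reduced_dims=reduced,
        size_factors=size_factors,
    )
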