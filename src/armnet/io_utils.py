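"""Reading and writing count matrices and tables.

Supports the MatrixMarket triplet layout (``matrix.mtx`` genes x cells or
cells x genes plus ``genes.tsv``/``barcodes.tsv``), a single-file HDF5
container mirroring the same content, and plain TSV tables (UTF-8, header
row, no index column).
"""

from __future__ import annotations

import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from armnet.simulate import MITO_PREFIX, CaseMetadata, CountMatrix

logger = logging.getLogger(__name__)


def write_mtx(cm: CountMatrix, outdir: str | Path) -> Path:
    """Write matrix.mtx + genes.tsv + barcodes.tsv (+ cell sample labels)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(cm.counts), field="integer")
    pd.DataFrame({"gene_id": cm.gene_ids, "mito": cm.mito_gene_flags.astype(int)}).to_csv(
        outdir / "genes.tsv", sep="\t", index=False
    )
    pd.DataFrame({"barcode": cm.cell_ids, "sample": cm.sample_of_cell}).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False
    )
    return outdir


def _validate_mtx_indices(path: Path) -> None:
    """Reject coordinate files with 0-based indices (MatrixMarket is 1-based)."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("%%MatrixMarket"):
            raise ValueError(f"{path}: missing MatrixMarket header")
        for line in fh:
            if line.startswith("%"):
                continue
            break  # dims line
        for line in fh:
            if not line.strip():
                continue
            i, j = line.split()[:2]
            if int(i) < 1 or int(j) < 1:
                raise ValueError(
                    f"{path}: found a 0-based index; MatrixMarket coordinates are 1-based"
                )
            break


def read_mtx(indir: str | Path) -> CountMatrix:
    """Read the triplet layout written by :func:`write_mtx`."""
    indir = Path(indir)
    mtx_path = indir / "matrix.mtx"
    _validate_mtx_indices(mtx_path)
    try:
        counts = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise ValueError(f"malformed MatrixMarket file {mtx_path}: {exc}") from exc
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t")
    if genes["gene_id"].duplicated().any():
        raise ValueError("duplicate gene IDs in genes.tsv")
    if barcodes["barcode"].duplicated().any():
        raise ValueError("duplicate barcodes in barcodes.tsv")
    mito = (
        genes["mito"].astype(bool).to_numpy()
        if "mito" in genes
        else genes["gene_id"].str.startswith(MITO_PREFIX).to_numpy()
    )
    return CountMatrix(
        counts=counts,
        gene_ids=genes["gene_id"].to_numpy(dtype=object),
        cell_ids=barcodes["barcode"].to_numpy(dtype=object),
        sample_of_cell=barcodes["sample"].to_numpy(dtype=object),
        mito_gene_flags=mito,
    )


def write_h5(cm: CountMatrix, path: str | Path, meta: CaseMetadata | None = None) -> Path:
    """Single-file HDF5 container (CSR arrays + identifier datasets)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    csr = cm.counts.tocsr()
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        g = f.create_group("matrix")
        g.create_dataset("data", data=csr.data)
        g.create_dataset("indices", data=csr.indices)
        g.create_dataset("indptr", data=csr.indptr)
        g.attrs["shape"] = csr.shape
        def _str_ds(group, name, values):
            group.create_dataset(
                name, data=[str(v) for v in values], dtype=str_dt
            )

        _str_ds(f, "gene_ids", cm.gene_ids)
        _str_ds(f, "cell_ids", cm.cell_ids)
        _str_ds(f, "sample_of_cell", cm.sample_of_cell)
        f.create_dataset("mito_gene_flags", data=cm.mito_gene_flags)
        if meta is not None:
            mg = f.create_group("metadata")
            for col in meta.table.columns:
                vals = meta.table[col].to_numpy()
                if vals.dtype.kind in ("O", "U", "S"):
                    _str_ds(mg, col, vals)
                else:
                    mg.create_dataset(col, data=vals)
    return path


def read_h5(path: str | Path) -> tuple[CountMatrix, CaseMetadata | None]:
    path = Path(path)
    with h5py.File(path, "r") as f:
        g = f["matrix"]
        counts = sp.csr_matrix(
            (g["data"][:], g["indices"][:], g["indptr"][:]),
            shape=tuple(g.attrs["shape"]),
        )
        cm = CountMatrix(
            counts=counts,
            gene_ids=f["gene_ids"].asstr()[:].astype(object),
            cell_ids=f["cell_ids"].asstr()[:].astype(object),
            sample_of_cell=f["sample_of_cell"].asstr()[:].astype(object),
            mito_gene_flags=f["mito_gene_flags"][:].astype(bool),
        )
        meta = None
        if "metadata" in f:
            cols = {}
            for col in f["metadata"]:
                ds = f["metadata"][col]
                cols[col] = ds.asstr()[:] if ds.dtype.kind == "O" else ds[:]
            meta = CaseMetadata(pd.DataFrame(cols))
    return cm, meta


def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")
    return path


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", encoding="utf-8")


def write_metadata(meta: CaseMetadata, path: str | Path) -> Path:
    return write_tsv(meta.table, path)


def read_metadata(path: str | Path) -> CaseMetadata:
    return CaseMetadata(read_tsv(path))
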