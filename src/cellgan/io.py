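"""Reading and writing single-cell count matrices.

The on-disk 10x conventions store genes x cells; everything in memory here is
cells x genes (rows are cells). Supported dialects: MatrixMarket triplet
directories with gene/barcode TSVs (legacy ``genes.tsv`` and v3
``features.tsv`` names, gzipped or not), 10x-style HDF5, and a dense TSV
table. Counts stay sparse in memory.
"""

from __future__ import annotations

import gzip
import io as _stdio
import os
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, IntegrityError, ParameterError

_NORM_TAG = "normalized_to="


@dataclass
class CountMatrix:
    """Sparse cells x genes expression matrix with identifiers.

    ``normalized_to`` carries the library-size target phi once rows have been
    rescaled to a common total; it is ``None`` for raw counts.
    """

    values: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    normalized_to: float | None = None

    def __post_init__(self):
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self):
        n_cells, n_genes = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise IntegrityError(
                f"{len(self.gene_ids)} gene ids for {n_genes} columns")
        if len(self.cell_ids) != n_cells:
            raise IntegrityError(
                f"{len(self.cell_ids)} cell ids for {n_cells} rows")
        if len(set(self.gene_ids)) != n_genes:
            raise IntegrityError("gene ids are not unique")
        if len(set(self.cell_ids)) != n_cells:
            raise IntegrityError("cell ids are not unique")
        if self.values.nnz and self.values.data.min() < 0:
            raise IntegrityError("negative entries in count matrix")
        if self.normalized_to is not None:
            sums = np.asarray(self.values.sum(axis=1)).ravel()
            if not np.allclose(sums, self.normalized_to, rtol=1e-6):
                raise IntegrityError(
                    "normalized_to set but row sums deviate from it")

    # -- conveniences -----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense(), dtype=np.float64)

    def gene_index(self, gene_ids) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in gene_ids], dtype=np.intp)
        except KeyError as e:
            raise ParameterError(f"gene id not present: {e.args[0]}") from None

    def subset_cells(self, idx) -> "CountMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return CountMatrix(self.values[idx], self.gene_ids,
                           [self.cell_ids[i] for i in idx], self.normalized_to)


# ---------------------------------------------------------------------------
# MTX triplet directories
# ---------------------------------------------------------------------------

def _find(dir_path: Path, names):
    for name in names:
        p = dir_path / name
        if p.exists():
            return p
    raise FormatError(
        f"none of {names} found in {dir_path}")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return _stdio.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def _read_id_column(path: Path) -> list[str]:
    with _open_text(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_10x_mtx(dir_path) -> CountMatrix:
    """Read a 10x-style MTX directory into a cells x genes matrix."""
    dir_path = Path(dir_path)
    if not dir_path.is_dir():
        raise FormatError(f"not a directory: {dir_path}")
    mtx_path = _find(dir_path, ["matrix.mtx", "matrix.mtx.gz"])
    genes_path = _find(dir_path, ["genes.tsv", "genes.tsv.gz",
                                  "features.tsv", "features.tsv.gz"])
    barcodes_path = _find(dir_path, ["barcodes.tsv", "barcodes.tsv.gz"])
    genes = _read_id_column(genes_path)
    barcodes = _read_id_column(barcodes_path)
    normalized_to = None
    opener = gzip.open if mtx_path.suffix == ".gz" else open
    with opener(mtx_path, "rb") as fh:
        head = [fh.readline() for _ in range(8)]
        for line in head:
            text = line.decode("latin1", "ignore")
            if text.startswith("%") and _NORM_TAG in text:
                normalized_to = float(text.split(_NORM_TAG)[1].strip())
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as e:
        raise FormatError(f"cannot parse {mtx_path}: {e}") from e
    if mat.shape != (len(genes), len(barcodes)):
        raise IntegrityError(
            f"MTX header {mat.shape} does not match TSVs "
            f"({len(genes)} genes, {len(barcodes)} barcodes)")
    return CountMatrix(sp.csr_matrix(mat.T), genes, barcodes, normalized_to)


# ---------------------------------------------------------------------------
# HDF5
# ---------------------------------------------------------------------------

def read_h5_matrix(path) -> CountMatrix:
    """Read a 10x-style HDF5 count file (CellRanger v3 ``matrix`` group or a
    legacy single genome group)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with h5py.File(path, "r") as f:
        groups = list(f.keys())
        if "matrix" in groups:
            g = f["matrix"]
            feature_key = "features/id" if "features" in g else "genes"
        elif len(groups) == 1 and isinstance(f[groups[0]], h5py.Group) \
                and "data" in f[groups[0]]:
            g = f[groups[0]]
            feature_key = "genes"
        else:
            raise FormatError(
                f"unrecognized HDF5 layout in {path}; groups found: {groups}")
        for key in ("data", "indices", "indptr", "shape", "barcodes"):
            if key not in g:
                raise FormatError(
                    f"HDF5 group '{g.name}' lacks dataset '{key}'")
        shape = tuple(int(s) for s in g["shape"][...])  # genes x cells
        mat = sp.csc_matrix(
            (g["data"][...], g["indices"][...], g["indptr"][...]), shape=shape)
        genes = [x.decode() if isinstance(x, bytes) else str(x)
                 for x in g[feature_key][...]]
        barcodes = [x.decode() if isinstance(x, bytes) else str(x)
                    for x in g["barcodes"][...]]
        normalized_to = g.attrs.get("normalized_to", None)
        if normalized_to is not None:
            normalized_to = float(normalized_to)
    if len(genes) != shape[0] or len(barcodes) != shape[1]:
        raise IntegrityError("HDF5 shape does not match identifier lengths")
    return CountMatrix(sp.csr_matrix(mat.T), genes, barcodes, normalized_to)


# ---------------------------------------------------------------------------
# dense TSV
# ---------------------------------------------------------------------------

def read_tsv_matrix(path) -> CountMatrix:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    normalized_to = None
    with _open_text(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            if _NORM_TAG in first:
                normalized_to = float(first.split(_NORM_TAG)[1].strip())
            header = fh.readline()
        else:
            header = first
        genes = header.rstrip("\n").split("\t")[1:]
        cells, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            cells.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    vals = np.array(rows) if rows else np.zeros((0, len(genes)))
    return CountMatrix(sp.csr_matrix(vals), genes, cells, normalized_to)


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------

def write_matrix(m: CountMatrix, path, dialect: str = "mtx"):
    """Write ``m`` in the requested dialect; returns the path written.

    ``mtx`` writes a 10x-style directory (genes x cells on disk), ``h5`` a
    v3-style HDF5 file, ``tsv`` a dense table with gene ids as header.
    """
    path = Path(path)
    if dialect == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        comment = f"{_NORM_TAG}{m.normalized_to}" if m.normalized_to else ""
        scipy.io.mmwrite(str(path / "matrix.mtx"), sp.coo_matrix(m.values.T),
                         comment=comment)
        with open(path / "genes.tsv", "w") as fh:
            fh.writelines(f"{g}\t{g}\n" for g in m.gene_ids)
        with open(path / "barcodes.tsv", "w") as fh:
            fh.writelines(f"{c}\n" for c in m.cell_ids)
        return path
    if dialect == "h5":
        csc = sp.csc_matrix(m.values.T)  # genes x cells on disk
        with h5py.File(path, "w") as f:
            g = f.create_group("matrix")
            g.create_dataset("data", data=csc.data)
            g.create_dataset("indices", data=csc.indices)
            g.create_dataset("indptr", data=csc.indptr)
            g.create_dataset("shape", data=np.array(csc.shape, dtype=np.int64))
            feats = g.create_group("features")
            feats.create_dataset(
                "id", data=np.array(m.gene_ids, dtype="S"))
            g.create_dataset(
                "barcodes", data=np.array(m.cell_ids, dtype="S"))
            if m.normalized_to is not None:
                g.attrs["normalized_to"] = float(m.normalized_to)
        return path
    if dialect == "tsv":
        dense = m.to_dense()
        with open(path, "w") as fh:
            if m.normalized_to is not None:
                fh.write(f"# {_NORM_TAG}{m.normalized_to}\n")
            fh.write("cell_id\t" + "\t".join(m.gene_ids) + "\n")
            for cid, row in zip(m.cell_ids, dense):
                fh.write(cid + "\t"
                         + "\t".join(format(float(v), ".17g") for v in row)
                         + "\n")
        return path
    raise ParameterError(f"unknown dialect: {dialect!r}")


def write_labels_tsv(cell_ids, labels, path):
    """Two-column (cell_id, cluster) TSV, the exchange format for labels."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("cell_id\tcluster\n")
        for cid, lab in zip(cell_ids, labels):
            fh.write(f"{cid}\t{int(lab)}\n")
    return path


def read_labels_tsv(path, cell_ids=None):
    """Read a (cell_id, cluster) TSV; if ``cell_ids`` given, align to them."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if cell_ids is not None:
        df = df.set_index("cell_id").loc[list(cell_ids)].reset_index()
    return df["cluster"].to_numpy(dtype=np.int64)


def infer_and_read(path) -> CountMatrix:
    """Dispatch on path type/extension: directory -> mtx, .h5 -> HDF5,
    otherwise dense TSV."""
    p = Path(path)
    if p.is_dir():
        return read_10x_mtx(p)
    if p.suffix in {".h5", ".hdf5"}:
        return read_h5_matrix(p)
    return read_tsv_matrix(p)
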