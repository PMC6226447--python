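"""Readers and writers for the plain-text formats the package exchanges.

Supported inputs: MatrixMarket triplets with 10x CellRanger v2 sidecars
(``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``, gene-major on disk) and
dense CSV/TSV with a header row of gene names and a first column of cell
identifiers. All outputs are TSV/JSON so runs stay diff-able.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .matrix import ProcessedMatrix, RawCountMatrix


class MatrixFormatError(ValueError):
    """Raised when an on-disk matrix is malformed or inconsistent."""


def _read_sidecar(path: Path, what: str) -> list[str]:
    if not path.exists():
        raise MatrixFormatError(f"missing {what} sidecar file: {path}")
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                # genes.tsv may carry ensembl_id<TAB>symbol; first field is the id
                ids.append(line.split("\t")[0])
    return ids


def read_matrix(
    path: str | Path,
    format: str | None = None,
    genes_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
    genes_as_rows: bool | None = None,
) -> RawCountMatrix:
    """Read a count matrix into cells × genes orientation.

    Parameters
    ----------
    path
        The ``.mtx`` file (or a directory containing ``matrix.mtx``), or a
        dense CSV/TSV file.
    format
        ``"mtx"``, ``"csv"`` or ``"tsv"``; inferred from the suffix if omitted.
    genes_path, barcodes_path
        Explicit sidecar paths for MTX; default to ``genes.tsv`` /
        ``barcodes.tsv`` next to the matrix.
    genes_as_rows
        On-disk orientation. Defaults to ``True`` for MTX (the 10x
        convention is gene-major) and ``False`` for CSV/TSV.
    """
    path = Path(path)
    if path.is_dir():
        path = path / "matrix.mtx"
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = suffix if suffix in {"mtx", "csv", "tsv"} else "csv"
    format = format.lower()

    if format == "mtx":
        if genes_as_rows is None:
            genes_as_rows = True
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # pragma: no cover - message passthrough
            raise MatrixFormatError(f"cannot parse MatrixMarket file {path}: {exc}")
        mat = sp.csr_matrix(mat)
        genes_path = Path(genes_path) if genes_path else path.parent / "genes.tsv"
        barcodes_path = (
            Path(barcodes_path) if barcodes_path else path.parent / "barcodes.tsv"
        )
        gene_ids = _read_sidecar(genes_path, "gene")
        cell_ids = _read_sidecar(barcodes_path, "barcode")
        if genes_as_rows:
            mat = sp.csr_matrix(mat.T)
        n_cells, n_genes = mat.shape
        if len(gene_ids) != n_genes or len(cell_ids) != n_cells:
            raise MatrixFormatError(
                f"matrix is {n_cells} cells x {n_genes} genes but sidecars "
                f"list {len(cell_ids)} barcodes and {len(gene_ids)} genes"
            )
        return RawCountMatrix(mat, cell_ids, gene_ids)

    if format in {"csv", "tsv"}:
        sep = "," if format == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:
            raise MatrixFormatError(f"cannot parse {format.upper()} file {path}: {exc}")
        values = df.to_numpy(dtype=np.float64)
        if genes_as_rows:
            values = values.T
            cell_ids = [str(c) for c in df.columns]
            gene_ids = [str(g) for g in df.index]
        else:
            cell_ids = [str(c) for c in df.index]
            gene_ids = [str(g) for g in df.columns]
        if np.isnan(values).any():
            raise MatrixFormatError(f"{path} contains missing values")
        return RawCountMatrix(values, cell_ids, gene_ids)

    raise ValueError(f"unknown format {format!r}; expected mtx, csv or tsv")


def write_mtx_dataset(m: RawCountMatrix, outdir: str | Path) -> Path:
    """Write a RawCountMatrix as 10x-style ``matrix.mtx`` + sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = m.counts if sp.issparse(m.counts) else sp.csr_matrix(m.counts)
    scipy.io.mmwrite(outdir / "matrix.mtx", sp.coo_matrix(counts.T))
    (outdir / "genes.tsv").write_text("".join(f"{g}\t{g}\n" for g in m.gene_ids))
    (outdir / "barcodes.tsv").write_text("".join(f"{c}\n" for c in m.cell_ids))
    return outdir


def write_processed(pm: ProcessedMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write a processed matrix as TSV plus a JSON provenance sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv = prefix.with_suffix(".tsv")
    df = pd.DataFrame(pm.values, index=pm.cell_ids, columns=pm.gene_ids)
    df.to_csv(tsv, sep="\t")
    sidecar = prefix.with_suffix(".provenance.json")
    sidecar.write_text(json.dumps(pm.provenance, indent=2))
    return tsv, sidecar


def read_labels(path: str | Path) -> list[str]:
    """One label per line, aligned with matrix cell order."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
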