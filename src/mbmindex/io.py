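"""Readers and writers for the plain-text formats the pipeline exchanges.

Supported formats: MatrixMarket coordinate triplets (matrix.mtx +
genes.tsv + barcodes.tsv, 10x convention, genes as rows), dense TSV with the
gene id in the first column, GMT gene-set files, and CSV survival tables
with required columns sample_id, time, event. Writers are deterministic:
identical inputs produce byte-identical files.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import (
    CellAnnotation,
    DimensionMismatchError,
    DuplicateIdError,
    ExpressionMatrix,
    GeneSignature,
)

FORMATS = ("mtx_triplet", "dense_tsv")


class FormatError(ValueError):
    """Malformed on-disk representation (bad header, unparsable values)."""


def _read_ids(path: Path, what: str) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"missing {what} file: {path}")
    ids = [line.split("\t")[0].strip() for line in path.read_text().splitlines() if line.strip()]
    if len(set(ids)) != len(ids):
        raise DuplicateIdError(f"duplicate identifiers in {path}")
    return ids


def read_expression(path: str | Path, format: str, genes_as_rows: bool = True) -> ExpressionMatrix:
    """Read an expression matrix as the counts layer.

    For ``mtx_triplet``, *path* is the directory holding ``matrix.mtx``,
    ``genes.tsv`` and ``barcodes.tsv``. For ``dense_tsv`` it is the TSV file
    itself; set ``genes_as_rows=False`` if the file stores observations as
    rows. The in-memory orientation is always genes x observations.
    """
    path = Path(path)
    if format == "mtx_triplet":
        mtx = path / "matrix.mtx"
        if not mtx.exists():
            raise FileNotFoundError(f"missing matrix file: {mtx}")
        try:
            mat = scipy.io.mmread(mtx)
        except Exception as exc:  # pragma: no cover - scipy error text varies
            raise FormatError(f"malformed MatrixMarket file {mtx}: {exc}") from exc
        genes = _read_ids(path / "genes.tsv", "gene")
        barcodes = _read_ids(path / "barcodes.tsv", "barcode")
        mat = scipy.sparse.coo_matrix(mat)
        if not genes_as_rows:
            mat = mat.T
        if mat.shape != (len(genes), len(barcodes)):
            raise DimensionMismatchError(
                f"matrix is {mat.shape} but triplet declares "
                f"{len(genes)} genes x {len(barcodes)} barcodes"
            )
        df = pd.DataFrame(mat.toarray(), index=genes, columns=barcodes)
        return ExpressionMatrix(df, layer="counts")
    if format == "dense_tsv":
        if not path.exists():
            raise FileNotFoundError(f"missing expression file: {path}")
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:
            raise FormatError(f"unparsable dense TSV {path}: {exc}") from exc
        if not genes_as_rows:
            df = df.T
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return ExpressionMatrix(df.rename_axis(None), layer="counts")
    raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")


def write_expression(m: ExpressionMatrix, path: str | Path, format: str) -> None:
    """Write genes-as-rows; MTX values are written exactly for integers."""
    path = Path(path)
    if format == "mtx_triplet":
        path.mkdir(parents=True, exist_ok=True)
        arr = m.values.to_numpy()
        sp = scipy.sparse.coo_matrix(arr)
        is_int = np.allclose(arr, np.round(arr))
        buf = _io.BytesIO()
        scipy.io.mmwrite(buf, sp.astype(np.int64) if is_int else sp, field="integer" if is_int else "real")
        (path / "matrix.mtx").write_bytes(buf.getvalue())
        (path / "genes.tsv").write_text("".join(f"{g}\n" for g in m.gene_ids))
        (path / "barcodes.tsv").write_text("".join(f"{b}\n" for b in m.obs_ids))
    elif format == "dense_tsv":
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="\n") as fh:
            m.values.rename_axis("gene_id").to_csv(fh, sep="\t", lineterminator="\n", float_format="%.10g")
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")


def read_gene_lengths(path: str | Path) -> pd.Series:
    """Two-column TSV (gene_id, length_bp) -> Series of float lengths."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(float)


def write_gene_lengths(lengths: pd.Series, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        lengths.rename("length_bp").rename_axis("gene_id").to_csv(fh, sep="\t", lineterminator="\n")


def read_gmt(path: str | Path) -> list[GeneSignature]:
    sigs = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
        sigs.append(GeneSignature(name=parts[0], genes=[g for g in parts[2:] if g]))
    return sigs


def write_gmt(signatures: Iterable[GeneSignature], path: str | Path) -> None:
    lines = [
        "\t".join([s.name, "na", *s.genes]) + "\n" for s in signatures
    ]
    Path(path).write_text("".join(lines))


def read_survival(path: str | Path) -> pd.DataFrame:
    """Survival CSV with required columns sample_id, time, event."""
    df = pd.read_csv(path)
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise FormatError(f"survival table {path} missing column {col!r}")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        raise DuplicateIdError(f"duplicate sample ids in {path}")
    df["time"] = df["time"].astype(float)
    df["event"] = df["event"].astype(bool)
    return df


def write_survival(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["event"] = out["event"].astype(int)
    with open(path, "w", newline="\n") as fh:
        out.rename_axis("sample_id").to_csv(fh, lineterminator="\n", float_format="%.10g")


def read_annotation(path: str | Path) -> CellAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return CellAnnotation(df)


def write_annotation(ann: CellAnnotation, path: str | Path) -> None:
    out = ann.table.copy()
    out["is_malignant"] = out["is_malignant"].astype(int)
    with open(path, "w", newline="\n") as fh:
        out.rename_axis("cell_id").to_csv(fh, sep="\t", lineterminator="\n")


def read_sensitivity(path: str | Path) -> pd.DataFrame:
    """Samples x drugs sensitivity TSV (lower score = more sensitive)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df.astype(float)


def write_sensitivity(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        df.rename_axis("sample_id").to_csv(fh, sep="\t", lineterminator="\n", float_format="%.10g")
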