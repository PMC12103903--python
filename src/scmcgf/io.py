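"""Reading and writing the file formats the pipeline touches.

Expression matrices travel as dense delimited text (header row = cell ids,
first column = gene ids) or as MatrixMarket coordinate triplets with
``genes.tsv`` / ``barcodes.tsv`` sidecars.  Gene sets use the tab-separated
GMT dialect.  The in-memory orientation is always genes x cells.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "ExpressionMatrix",
    "PathwayGeneSets",
    "read_expression",
    "write_expression",
    "read_gene_sets",
    "write_gene_sets",
    "read_labels",
    "write_labels",
]


@dataclass
class ExpressionMatrix:
    """A genes x cells numeric matrix with identifier bookkeeping.

    Parameters
    ----------
    values
        Nonnegative ``(n_genes, n_cells)`` array (raw counts or normalized
        expression).
    gene_ids, cell_ids
        Unique identifiers for rows and columns respectively.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} gene ids and {len(self.cell_ids)} cell ids"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be nonnegative")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene identifiers are not unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell identifiers are not unique")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, indices: Sequence[int]) -> "ExpressionMatrix":
        idx = np.asarray(list(indices), dtype=int)
        return ExpressionMatrix(
            self.values[idx, :],
            [self.gene_ids[i] for i in idx],
            self.cell_ids,
        )


@dataclass
class PathwayGeneSets:
    """A named collection of gene sets (pathways, regulons, signatures)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


# --- expression matrices ---------------------------------------------------

_BARCODE_RE = re.compile(r"^[ACGTN]{6,}([-_]\d+)?$")
_CELL_RE = re.compile(r"^(cell|barcode|bc|c)[-_]?\d+$", re.IGNORECASE)
_ENSEMBL_RE = re.compile(r"^ENS[A-Z]*G\d+(\.\d+)?$")
_SYMBOL_RE = re.compile(r"^[A-Za-z][A-Za-z0-9.\-]{0,14}$")


def _gene_likeness(ids: Sequence[str]) -> float:
    """Score in [-1, 1]: positive if identifiers look like genes, negative
    if they look like cell barcodes."""
    score = 0.0
    for s in ids:
        if _BARCODE_RE.match(s) or _CELL_RE.match(s):
            score -= 1.0
        elif _ENSEMBL_RE.match(s):
            score += 1.0
        elif _SYMBOL_RE.match(s):
            score += 0.25
    return score / max(len(ids), 1)


def _read_sidecar_ids(path: Path) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def read_expression(path: str | Path, layout_hint: str = "auto") -> ExpressionMatrix:
    """Read an expression matrix from dense delimited text or MatrixMarket.

    ``layout_hint`` is one of ``"genes_by_cells"``, ``"cells_by_genes"`` or
    ``"auto"``.  Under ``"auto"`` the axis whose identifiers look gene-like
    (Ensembl ids / symbols rather than nucleotide barcodes) becomes the rows;
    when the heuristic is inconclusive the file is taken as genes x cells.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout_hint not in ("auto", "genes_by_cells", "cells_by_genes"):
        raise ValueError(f"unknown layout_hint {layout_hint!r}")

    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        genes = _read_sidecar_ids(path.parent / "genes.tsv")
        cells = _read_sidecar_ids(path.parent / "barcodes.tsv")
        if mat.shape == (len(genes), len(cells)):
            row_ids, col_ids = genes, cells
        elif mat.shape == (len(cells), len(genes)):
            mat = mat.T
            row_ids, col_ids = genes, cells
        else:
            raise ValueError(
                f"matrix shape {mat.shape} does not match sidecars "
                f"({len(genes)} genes, {len(cells)} barcodes)"
            )
        # sidecars disambiguate the orientation; layout_hint is moot here
        return ExpressionMatrix(mat, row_ids, col_ids)

    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - message wrapper
        raise ValueError(f"could not parse expression file {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"expression file {path} has no data")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"non-numeric entries in expression file {path}")

    transpose = False
    if layout_hint == "cells_by_genes":
        transpose = True
    elif layout_hint == "auto":
        row_score = _gene_likeness([str(i) for i in df.index])
        col_score = _gene_likeness([str(c) for c in df.columns])
        transpose = col_score > row_score
    if transpose:
        df = df.T
    return ExpressionMatrix(
        df.to_numpy(dtype=float),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
    )


def write_expression(em: ExpressionMatrix, path: str | Path) -> None:
    """Write genes x cells to dense CSV/TSV or MatrixMarket + sidecars."""
    path = Path(path)
    if path.suffix == ".mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(em.values))
        (path.parent / "genes.tsv").write_text("\n".join(em.gene_ids) + "\n")
        (path.parent / "barcodes.tsv").write_text("\n".join(em.cell_ids) + "\n")
        return
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.DataFrame(em.values, index=em.gene_ids, columns=em.cell_ids)
    df.to_csv(path, sep=sep)


# --- gene sets (GMT) -------------------------------------------------------

def read_gene_sets(path: str | Path) -> PathwayGeneSets:
    """Parse a GMT file: tab-separated ``name<TAB>description<TAB>gene...``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = genes
            descriptions[name] = desc
    return PathwayGeneSets(sets, descriptions)


def write_gene_sets(gs: PathwayGeneSets, path: str | Path) -> None:
    lines = []
    for name, genes in gs.sets.items():
        desc = gs.descriptions.get(name, "")
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# --- cluster labels --------------------------------------------------------

def write_labels(cell_ids: Sequence[str], labels: Sequence[int], path: str | Path) -> None:
    """Two-column CSV: cell_id, cluster."""
    pd.DataFrame({"cell_id": list(cell_ids), "cluster": list(labels)}).to_csv(
        path, index=False
    )


def read_labels(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path)
    if not {"cell_id", "cluster"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns cell_id, cluster")
    return [str(c) for c in df["cell_id"]], df["cluster"].to_numpy()
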