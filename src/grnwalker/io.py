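"""Readers and writers for the standard input formats.

Expression matrices are genes x cells everywhere internally; h5ad files
(cells x genes by convention) are transposed on read.  Edge lists are
2-column TSV, regulator first, with an optional third score column.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .gcen import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_edge_list",
    "write_edge_list",
    "read_tf_list",
    "write_tf_list",
]

_EDGE_HEADER_TOKENS = {"regulator", "target", "source", "tf", "gene1", "gene2", "score", "weight"}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".tsv", ".txt"):
        return "tsv"
    if suffix == ".csv":
        return "csv"
    if suffix == ".mtx":
        return "mtx"
    if suffix == ".h5ad":
        return "h5ad"
    raise ValueError(f"cannot infer expression format from {path.name!r}")


def read_expression(
    path: str | Path,
    fmt: str | None = None,
    gene_file: str | Path | None = None,
    cell_file: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a genes x cells expression matrix.

    ``fmt`` is one of ``tsv``, ``csv``, ``mtx`` (MatrixMarket triplet with
    sidecar gene/cell id files) or ``h5ad``; inferred from the suffix when
    omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _infer_format(path)

    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        dup = [g for g, n in Counter(df.index.astype(str)).items() if n > 1]
        if dup:
            raise ValueError(f"duplicate gene identifiers in {path.name}: {sorted(dup)}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            for j, col in enumerate(df.columns):
                coerced = pd.to_numeric(df[col], errors="coerce")
                bad = coerced.isna() & df[col].notna()
                if bad.any():
                    row = df.index[np.where(bad)[0][0]]
                    raise ValueError(
                        f"non-numeric expression value at gene {row!r}, cell {col!r}"
                    )
            values = df.apply(pd.to_numeric).to_numpy()
        return ExpressionMatrix(
            values=values.astype(float),
            gene_ids=[str(g) for g in df.index],
            cell_ids=[str(c) for c in df.columns],
        )

    if fmt == "mtx":
        from scipy.io import mmread

        m = mmread(path)
        matrix = np.asarray(m.todense()) if hasattr(m, "todense") else np.asarray(m)
        gene_file = Path(gene_file) if gene_file else path.with_name(path.stem + "_genes.txt")
        cell_file = Path(cell_file) if cell_file else path.with_name(path.stem + "_cells.txt")
        gene_ids = [line.strip() for line in Path(gene_file).read_text().splitlines() if line.strip()]
        cell_ids = [line.strip() for line in Path(cell_file).read_text().splitlines() if line.strip()]
        dup = [g for g, n in Counter(gene_ids).items() if n > 1]
        if dup:
            raise ValueError(f"duplicate gene identifiers in {gene_file.name}: {sorted(dup)}")
        return ExpressionMatrix(values=matrix.astype(float), gene_ids=gene_ids, cell_ids=cell_ids)

    if fmt == "h5ad":
        import anndata

        adata = anndata.read_h5ad(path)
        x = adata.X
        values = np.asarray(x.todense() if hasattr(x, "todense") else x, dtype=float).T
        gene_ids = [str(g) for g in adata.var_names]
        dup = [g for g, n in Counter(gene_ids).items() if n > 1]
        if dup:
            raise ValueError(f"duplicate gene identifiers in {path.name}: {sorted(dup)}")
        return ExpressionMatrix(
            values=values,
            gene_ids=gene_ids,
            cell_ids=[str(c) for c in adata.obs_names],
        )

    raise ValueError(f"unknown expression format {fmt!r}")


def write_expression(expr: ExpressionMatrix, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.cell_ids).to_csv(
            path, sep=sep
        )
    elif fmt == "mtx":
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix

        mmwrite(path, coo_matrix(expr.values))
        path.with_name(path.stem + "_genes.txt").write_text("\n".join(expr.gene_ids) + "\n")
        path.with_name(path.stem + "_cells.txt").write_text("\n".join(expr.cell_ids) + "\n")
    else:
        raise ValueError(f"unsupported output format {fmt!r}")


def read_edge_list(path: str | Path) -> set[tuple[str, str]]:
    """Read a directed (regulator, target[, score]) edge list.

    Self-loops are dropped with a logged count; an optional header row with
    recognisable column names is skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=r"\s+|\t|,", engine="python", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return set()
    if df.shape[1] < 2:
        raise ValueError(f"{path.name}: expected at least 2 columns (regulator, target)")
    first = [str(v).strip().lower() for v in df.iloc[0, :2]]
    if all(v in _EDGE_HEADER_TOKENS for v in first):
        df = df.iloc[1:]
    edges = {(str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])}
    loops = {e for e in edges if e[0] == e[1]}
    if loops:
        logger.info("dropped %d self-loop(s) from %s", len(loops), path.name)
    return edges - loops


def write_edge_list(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    rows = sorted((str(a), str(b)) for a, b in edges)
    pd.DataFrame(rows, columns=["regulator", "target"]).to_csv(path, sep="\t", index=False)


def read_tf_list(path: str | Path) -> list[str]:
    """One TF identifier per line; order preserved, duplicates removed."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return list(dict.fromkeys(ln for ln in lines if ln and not ln.startswith("#")))


def write_tf_list(tf_ids: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(str(t) for t in tf_ids) + "\n")
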