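"""Plain-text I/O: dense TSV and sparse triplet count matrices.

Dense matrices are gene x cell TSVs with gene ids as the index column.
The sparse form is an MTX-style whitespace triplet file (1-based
gene_index cell_index count) with ``<stem>.genes.txt`` / ``<stem>.cells.txt``
name sidecars, one id per line.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_dense_tsv", "read_dense_tsv",
    "write_sparse_triplet", "read_sparse_triplet",
    "read_id_list",
]


def write_dense_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_dense_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    df.index.name = None
    return df


def _sidecars(path) -> tuple[Path, Path]:
    stem = Path(path)
    stem = stem.with_suffix("") if stem.suffix else stem
    return stem.with_suffix(".genes.txt"), stem.with_suffix(".cells.txt")


def write_sparse_triplet(counts: pd.DataFrame, path) -> None:
    mat = counts.to_numpy()
    gi, ci = np.nonzero(mat)
    with open(path, "w") as fh:
        fh.write(f"{mat.shape[0]} {mat.shape[1]} {len(gi)}\n")
        for g, c in zip(gi, ci):
            fh.write(f"{g + 1} {c + 1} {mat[g, c]}\n")
    genes_path, cells_path = _sidecars(path)
    genes_path.write_text("\n".join(counts.index.astype(str)) + "\n")
    cells_path.write_text("\n".join(counts.columns.astype(str)) + "\n")


def read_sparse_triplet(path) -> pd.DataFrame:
    genes_path, cells_path = _sidecars(path)
    genes = read_id_list(genes_path)
    cells = read_id_list(cells_path)
    with open(path) as fh:
        n_genes, n_cells, nnz = map(int, fh.readline().split())
        mat = np.zeros((n_genes, n_cells), dtype=np.int64)
        for _ in range(nnz):
            g, c, v = fh.readline().split()
            mat[int(g) - 1, int(c) - 1] = int(v)
    if len(genes) != n_genes or len(cells) != n_cells:
        raise ValueError("sidecar lengths do not match triplet header")
    return pd.DataFrame(mat, index=genes, columns=cells)


def read_id_list(path) -> list[str]:
    """One identifier per line (marker sets, gene/cell name sidecars)."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
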