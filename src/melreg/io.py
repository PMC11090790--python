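"""Expression-matrix I/O: genes × samples TSV, or MTX with name sidecars."""

from __future__ import annotations

import os

import pandas as pd

from .errors import ParseError

__all__ = ["read_expression_tsv", "read_expression_mtx", "write_expression_tsv"]


def read_expression_tsv(path) -> pd.DataFrame:
    """Genes × samples TSV; first column = gene ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.duplicated().any():
        raise ParseError(f"{path}: duplicate gene ids")
    return df


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t")


def read_expression_mtx(mtx_path, genes_path=None, samples_path=None) -> pd.DataFrame:
    """MatrixMarket matrix plus row (genes) and column (samples) sidecars.

    Sidecars default to ``<stem>.genes.txt`` / ``<stem>.samples.txt`` next to
    the matrix, one name per line.
    """
    from scipy.io import mmread

    stem = os.path.splitext(str(mtx_path))[0]
    genes_path = genes_path or f"{stem}.genes.txt"
    samples_path = samples_path or f"{stem}.samples.txt"
    mat = mmread(mtx_path).toarray() if hasattr(mmread(mtx_path), "toarray") else mmread(mtx_path)
    with open(genes_path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    with open(samples_path) as fh:
        samples = [line.strip() for line in fh if line.strip()]
    if mat.shape != (len(genes), len(samples)):
        raise ParseError(
            f"{mtx_path}: shape {mat.shape} does not match sidecars "
            f"({len(genes)} genes, {len(samples)} samples)"
        )
    return pd.DataFrame(mat, index=genes, columns=samples)
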