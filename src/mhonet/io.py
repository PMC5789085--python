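"""Reading and writing the tabular formats the pipeline exchanges."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from gseapy import read_gmt
from scipy.io import mmread

__all__ = ["read_counts", "write_counts", "read_clinical", "read_gene_sets"]


def read_counts(path) -> pd.DataFrame:
    """Gene x sample count matrix from TSV (or MatrixMarket .mtx)."""
    path = Path(path)
    if path.suffix == ".mtx":
        mat = np.asarray(mmread(path).todense())
        return pd.DataFrame(
            mat,
            index=[f"G{i + 1:05d}" for i in range(mat.shape[0])],
            columns=[f"S{j + 1:02d}" for j in range(mat.shape[1])],
        )
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.select_dtypes(exclude="number").shape[1]:
        raise ValueError("count matrix contains non-numeric columns")
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def read_clinical(path) -> pd.DataFrame:
    """Per-sample clinical metadata table (TSV, first column = sample id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gene_sets(path) -> dict[str, list[str]]:
    """Gene-set collection in GMT format, as {set name: [genes]}."""
    return read_gmt(str(path))
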