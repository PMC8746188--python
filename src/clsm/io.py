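"""File I/O for labeled connectome matrices and run provenance."""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "write_connectome_csv",
    "read_connectome_csv",
    "file_sha256",
]


def write_connectome_csv(
    path: Union[str, Path], matrix: np.ndarray, labels: Sequence[str]
) -> Path:
    """Write a labeled square matrix as CSV (header row + index column)."""
    matrix = np.asarray(matrix, float)
    n = len(labels)
    if matrix.shape != (n, n):
        raise ValueError(f"matrix shape {matrix.shape} does not match {n} labels")
    df = pd.DataFrame(matrix, index=list(labels), columns=list(labels))
    path = Path(path)
    df.to_csv(path, index_label="roi", float_format="%.17g")
    return path


def read_connectome_csv(
    path: Union[str, Path],
    expected_labels: Optional[Sequence[str]] = None,
    atol: float = 1e-8,
) -> tuple[np.ndarray, list[str]]:
    """Read a labeled square connectome CSV.

    Row and column labels must match as sets; asymmetry beyond ``atol`` is
    symmetrized by averaging with a warning. When ``expected_labels`` is
    given the matrix is reindexed to that order (labels must match as a
    set).
    """
    path = Path(path)
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: matrix is not square ({df.shape[0]}x{df.shape[1]})")
    if set(df.index) != set(df.columns):
        raise ValueError(f"{path}: row and column labels differ")
    if list(df.index) != list(df.columns):
        df = df.loc[df.columns]  # align row order to column order
    if expected_labels is not None:
        expected = [str(x) for x in expected_labels]
        if set(expected) != set(df.index):
            missing = sorted(set(expected) - set(df.index))
            extra = sorted(set(df.index) - set(expected))
            raise ValueError(
                f"{path}: labels do not match parcellation (missing {missing}, extra {extra})"
            )
        df = df.loc[expected, expected]
    m = df.to_numpy(float)
    if not np.allclose(m, m.T, atol=atol):
        warnings.warn(f"{path}: matrix asymmetric beyond tolerance; symmetrized by averaging")
        m = (m + m.T) / 2.0
    else:
        m = (m + m.T) / 2.0  # remove printable round-off asymmetry too
    return m, list(df.index)


def file_sha256(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
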