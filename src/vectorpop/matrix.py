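"""Labeled square matrices (shipping intensity, distance, F_ST, migration).

Thin wrapper around a pandas DataFrame that enforces squareness, keeps an
explicit label order, and auto-detects symmetry. Directional matrices follow
the convention rows = source, columns = recipient.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

_SYM_TOL = 1e-9


class SquareMatrix:
    def __init__(self, labels: Sequence[str], values: np.ndarray):
        self.labels = [str(x) for x in labels]
        values = np.asarray(values, dtype=float)
        k = len(self.labels)
        if values.shape != (k, k):
            raise ValueError(f"values shape {values.shape} != ({k}, {k})")
        if len(set(self.labels)) != k:
            raise ValueError("labels must be unique")
        self.values = values

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def symmetric(self) -> bool:
        return bool(np.allclose(self.values, self.values.T, atol=_SYM_TOL))

    def off_diagonal(self) -> np.ndarray:
        """All n(n-1) off-diagonal cells in row-major order."""
        mask = ~np.eye(self.n, dtype=bool)
        return self.values[mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SquareMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("row and column labels differ")
        return cls(list(df.index), df.to_numpy(dtype=float))

    def reindex(self, labels: Sequence[str]) -> "SquareMatrix":
        """Reorder/subset to the given labels (must all be present)."""
        missing = [l for l in labels if l not in self.labels]
        if missing:
            raise KeyError(f"labels not in matrix: {missing}")
        idx = [self.labels.index(l) for l in labels]
        return SquareMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def drop(self, labels: Sequence[str]) -> "SquareMatrix":
        keep = [l for l in self.labels if l not in set(labels)]
        return self.reindex(keep)

    def write(self, path: str | Path, float_format: str = "%.6g") -> None:
        self.to_frame().to_csv(path, sep="\t", float_format=float_format)

    @classmethod
    def read(cls, path: str | Path) -> "SquareMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls.from_frame(df)

    def __repr__(self) -> str:
        kind = "symmetric" if self.symmetric else "directional"
        return f"SquareMatrix({self.n} labels, {kind})"
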