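"""Rank-based Mantel tests for labeled square matrices.

Follows the CADM recipe for comparing (possibly asymmetric) matrices: all
off-diagonal cells are replaced by mid-ranks, the statistic is the Pearson
correlation of the two rank vectors (i.e. a Spearman correlation over
cells), and the null distribution is generated by jointly permuting the
rows and columns of one matrix under random label permutations. Asymmetric
matrices contribute all n(n-1) directed cells; for symmetric matrices each
unordered pair simply contributes two equal cells, which leaves the
statistic unchanged relative to using each pair once.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import SquareMatrix

log = logging.getLogger(__name__)

TAILS = ("greater", "less", "two-sided")


def rank_transform(matrix: SquareMatrix) -> SquareMatrix:
    """Replace off-diagonal cells by mid-ranks (ties averaged)."""
    if matrix.n < 3:
        raise ValueError("need at least 3 labels to rank a distance matrix")
    vals = matrix.values.copy()
    mask = ~np.eye(matrix.n, dtype=bool)
    cells = vals[mask]
    if np.ptp(cells) == 0:
        log.warning("all off-diagonal cells are equal; ranks are all tied")
    vals[mask] = rankdata(cells)
    return SquareMatrix(matrix.labels, vals)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    tail: str
    n_labels: int
    excluded_labels: tuple[str, ...] = ()
    exhaustive: bool = False

    def __repr__(self) -> str:
        return (
            f"MantelResult(R={self.r:.4f}, P={self.p:.4f}, "
            f"n_perm={self.n_perm}, tail={self.tail!r}, n={self.n_labels})"
        )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx, sy = np.sqrt((xc**2).sum()), np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        raise ValueError("degenerate rank vector: correlation undefined")
    return float((xc * yc).sum() / (sx * sy))


def mantel(
    mat_a: SquareMatrix,
    mat_b: SquareMatrix,
    n_perm: int = 9999,
    tail: str = "greater",
    seed: int | None = None,
    exclude: Sequence[str] = (),
    exhaustive: bool | None = None,
) -> MantelResult:
    """Rank-based Mantel test between two labeled square matrices.

    ``exclude`` drops labels from both matrices first. The null permutes
    the labels of the second matrix; permuting either matrix is equivalent.
    With ``exhaustive=True`` (or automatically when the full permutation
    group is smaller than ``n_perm``) all n! label permutations are
    enumerated and P is the exact tail fraction (the identity permutation
    counts once, making P = (#{stat >= obs} ) / n! with identity included).
    """
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}")
    labels = [l for l in mat_a.labels if l not in set(exclude)]
    other = [l for l in mat_b.labels if l not in set(exclude)]
    if set(labels) != set(other):
        only_a = sorted(set(labels) - set(other))
        only_b = sorted(set(other) - set(labels))
        raise ValueError(
            f"label mismatch: only in first {only_a}, only in second {only_b}"
        )
    if len(labels) < 4:
        raise ValueError("need at least 4 retained labels")
    A = mat_a.reindex(labels)
    B = mat_b.reindex(labels)
    k = len(labels)
    mask = ~np.eye(k, dtype=bool)

    ra = rank_transform(A).values
    rb = rank_transform(B).values
    va = ra[mask]
    r_obs = _pearson(va, rb[mask])

    n_total = math.factorial(k)
    if exhaustive is None:
        exhaustive = n_total <= n_perm
    eps = 1e-12
    if exhaustive:
        stats = np.empty(n_total)
        for i, perm in enumerate(itertools.permutations(range(k))):
            p = np.array(perm)
            stats[i] = _pearson(va, rb[np.ix_(p, p)][mask])
        if tail == "greater":
            count = int((stats >= r_obs - eps).sum())
        elif tail == "less":
            count = int((stats <= r_obs + eps).sum())
        else:
            count = int((np.abs(stats) >= abs(r_obs) - eps).sum())
        return MantelResult(
            r=r_obs, p=count / n_total, n_perm=n_total, tail=tail,
            n_labels=k, excluded_labels=tuple(exclude), exhaustive=True,
        )

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(k) for _ in range(n_perm)])
    permuted = rb[perms[:, :, None], perms[:, None, :]]  # (n_perm, k, k)
    cells = permuted[:, mask]  # (n_perm, k(k-1))
    vc = cells - cells.mean(axis=1, keepdims=True)
    ac = va - va.mean()
    denom = np.sqrt((vc**2).sum(axis=1)) * np.sqrt((ac**2).sum())
    stats = (vc @ ac) / denom
    if tail == "greater":
        count = int((stats >= r_obs - eps).sum())
    elif tail == "less":
        count = int((stats <= r_obs + eps).sum())
    else:
        count = int((np.abs(stats) >= abs(r_obs) - eps).sum())
    return MantelResult(
        r=r_obs, p=(count + 1) / (n_perm + 1), n_perm=n_perm, tail=tail,
        n_labels=k, excluded_labels=tuple(exclude),
    )


@dataclass
class CorrelationTable:
    """All pairwise Mantel results, laid out R above / P below diagonal."""

    names: list[str]
    results: dict[tuple[str, str], MantelResult] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        k = len(self.names)
        out = np.full((k, k), np.nan)
        for (a, b), res in self.results.items():
            i, j = self.names.index(a), self.names.index(b)
            i, j = min(i, j), max(i, j)
            out[i, j] = res.r
            out[j, i] = res.p
        return pd.DataFrame(out, index=self.names, columns=self.names)


def correlation_table(
    matrices: Mapping[str, SquareMatrix],
    n_perm: int = 9999,
    tail: str = "greater",
    seed: int | None = None,
    exclude: Sequence[str] = (),
) -> CorrelationTable:
    """Mantel-test every unordered pair of named matrices."""
    names = list(matrices)
    if len(names) < 2:
        raise ValueError("need at least 2 matrices")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names) * (len(names) - 1) // 2)
    table = CorrelationTable(names)
    pair_i = 0
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            res = mantel(
                matrices[a], matrices[b], n_perm=n_perm, tail=tail,
                seed=children[pair_i], exclude=exclude,
            )
            table.results[(a, b)] = res
            pair_i += 1
    return table
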