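"""Descriptive diversity and differentiation statistics for microsatellites.

Implements the classical single- and multi-population summaries for
codominant data: allele counts and frequencies, mean number of alleles,
rarefied allelic richness (hypergeometric rarefaction on gene copies, the
FSTAT convention), Nei's unbiased expected heterozygosity, and the Weir &
Cockerham (1984) variance-component estimators of F_IS (within-population f)
and pairwise F_ST (theta). Missing genotypes are excluded locus-wise; no
imputation is performed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import SquareMatrix
from .panel import MISSING, GenotypePanel

log = logging.getLogger(__name__)

#: returned where a statistic is undefined (e.g. < 2 gene copies)
UNDEFINED = float("nan")


# ---------------------------------------------------------------------------
# allele counts
# ---------------------------------------------------------------------------
@dataclass
class AlleleFrequencyTable:
    """Per group x locus allele counts (gene copies, missing excluded)."""

    groups: list[str]
    loci: list[str]
    counts: dict[tuple[str, str], dict[int, int]] = field(default_factory=dict)

    def n_copies(self, group: str, locus: str) -> int:
        return sum(self.counts.get((group, locus), {}).values())

    def frequencies(self, group: str, locus: str) -> dict[int, float]:
        c = self.counts.get((group, locus), {})
        n = sum(c.values())
        if n == 0:
            return {}
        return {a: k / n for a, k in c.items()}

    def alleles(self, locus: str) -> set[int]:
        """Distinct alleles at a locus across all groups."""
        out: set[int] = set()
        for g in self.groups:
            out |= set(self.counts.get((g, locus), {}))
        return out

    def pooled(self) -> "AlleleFrequencyTable":
        """Collapse all groups into one global group '_all'."""
        pooled = AlleleFrequencyTable(["_all"], list(self.loci))
        for locus in self.loci:
            acc: dict[int, int] = {}
            for g in self.groups:
                for a, k in self.counts.get((g, locus), {}).items():
                    acc[a] = acc.get(a, 0) + k
            pooled.counts[("_all", locus)] = acc
        return pooled


def allele_counts(panel: GenotypePanel, by: str = "cluster") -> AlleleFrequencyTable:
    """Count gene copies per group x locus (2 per fully typed individual)."""
    groups = panel.group_names(by)
    table = AlleleFrequencyTable(groups, list(panel.loci))
    idx = panel.group_indices(by)
    for g in groups:
        rows = idx[g]
        if rows.size == 0:
            log.warning("group %r is empty; emitting empty counts", g)
        geno = panel.genotypes[rows]  # (m, L, 2)
        for j, locus in enumerate(panel.loci):
            flat = geno[:, j, :].ravel()
            flat = flat[flat != MISSING]
            alleles, cnt = np.unique(flat, return_counts=True)
            table.counts[(g, locus)] = {int(a): int(c) for a, c in zip(alleles, cnt)}
    return table


# ---------------------------------------------------------------------------
# per-locus diversity statistics
# ---------------------------------------------------------------------------
def expected_heterozygosity(counts_at_locus: dict[int, int]) -> float:
    """Nei's unbiased gene diversity (n/(n-1)) (1 - sum p_j^2).

    ``n`` is the number of gene copies. Returns NaN for n < 2.
    """
    n = sum(counts_at_locus.values())
    if n < 2:
        return UNDEFINED
    sum_p2 = sum((k / n) ** 2 for k in counts_at_locus.values())
    return (n / (n - 1)) * (1.0 - sum_p2)


def allelic_richness(counts_at_locus: dict[int, int], g: int) -> float:
    """Hypergeometric rarefaction to ``g`` gene copies.

    A_R(g) = sum_j [1 - C(n - n_j, g) / C(n, g)]: the expected number of
    distinct alleles in a random subsample of g of the n observed copies.
    Returns NaN when g exceeds the available copies.
    """
    n = sum(counts_at_locus.values())
    if g < 1 or g > n:
        return UNDEFINED
    denom = math.comb(n, g)
    total = 0.0
    for nj in counts_at_locus.values():
        total += 1.0 - math.comb(n - nj, g) / denom
    return total


# ---------------------------------------------------------------------------
# Weir & Cockerham variance components
# ---------------------------------------------------------------------------
def _per_allele_stats(panel: GenotypePanel, rows: np.ndarray, locus_j: int):
    """For one group at one locus: (n_ind, {allele: (p, h_obs)})."""
    geno = panel.genotypes[rows, locus_j, :]
    typed = (geno != MISSING).all(axis=1)
    geno = geno[typed]
    n = geno.shape[0]
    if n == 0:
        return 0, {}
    alleles = np.unique(geno)
    out = {}
    for a in alleles:
        carries = geno == a
        p = carries.sum() / (2 * n)
        het = (carries.sum(axis=1) == 1).sum() / n
        out[int(a)] = (p, het)
    return n, out


def f_is(panel: GenotypePanel, group: str, by: str = "cluster") -> float:
    """Weir & Cockerham within-population fixation index f.

    Combined over loci and alleles by ratio of sums of the b (among
    individuals) and c (within individuals) variance components:
    f = 1 - sum(c) / sum(b + c).
    """
    rows = panel.group_indices(by).get(group)
    if rows is None:
        raise KeyError(f"no group {group!r}")
    sum_c = 0.0
    sum_bc = 0.0
    for j in range(panel.n_loci):
        n, stats = _per_allele_stats(panel, rows, j)
        if n < 2 or len(stats) < 2:
            continue  # monomorphic or undersampled locus carries no information
        for p, h in stats.values():
            b = (n / (n - 1)) * (p * (1 - p) - ((2 * n - 1) / (4 * n)) * h)
            c = h / 2.0
            sum_c += c
            sum_bc += b + c
    if sum_bc == 0.0:
        return UNDEFINED
    return 1.0 - sum_c / sum_bc


def _theta_components(panel: GenotypePanel, rows_a: np.ndarray, rows_b: np.ndarray):
    """Sum W&C (1984) a, b, c components over loci/alleles for two groups."""
    r = 2
    sum_a = sum_b = sum_c = 0.0
    for j in range(panel.n_loci):
        n1, s1 = _per_allele_stats(panel, rows_a, j)
        n2, s2 = _per_allele_stats(panel, rows_b, j)
        if n1 < 1 or n2 < 1:
            continue
        alleles = set(s1) | set(s2)
        if len(alleles) < 2:
            continue
        n_bar = (n1 + n2) / r
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
        if n_bar <= 1 or n_c <= 0:
            continue
        for a in alleles:
            p1, h1 = s1.get(a, (0.0, 0.0))
            p2, h2 = s2.get(a, (0.0, 0.0))
            p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
            s2_var = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / (
                (r - 1) * n_bar
            )
            h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
            a_comp = (n_bar / n_c) * (
                s2_var
                - (1 / (n_bar - 1))
                * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2_var - h_bar / 4)
            )
            b_comp = (n_bar / (n_bar - 1)) * (
                p_bar * (1 - p_bar)
                - ((r - 1) / r) * s2_var
                - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
            )
            c_comp = h_bar / 2
            sum_a += a_comp
            sum_b += b_comp
            sum_c += c_comp
    return sum_a, sum_b, sum_c


def theta_pair(panel: GenotypePanel, group_a: str, group_b: str, by: str = "cluster") -> float:
    """Multi-locus Weir & Cockerham theta between two groups."""
    idx = panel.group_indices(by)
    sa, sb, sc = _theta_components(panel, idx[group_a], idx[group_b])
    denom = sa + sb + sc
    if denom == 0.0:
        return UNDEFINED
    return sa / denom


def pairwise_fst(
    panel: GenotypePanel, by: str = "cluster", truncate_at_zero: bool = False
) -> SquareMatrix:
    """Symmetric matrix of pairwise Weir & Cockerham theta.

    Negative estimates are retained unless ``truncate_at_zero``.
    """
    groups = panel.group_names(by)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for pairwise F_ST")
    idx = panel.group_indices(by)
    for g in groups:
        typed = panel.typed_mask()[idx[g]]
        if (typed.sum(axis=0) < 2).all():
            raise ValueError(f"cluster {g!r} has < 2 typed individuals at every locus")
    k = len(groups)
    vals = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            t = theta_pair(panel, groups[i], groups[j], by)
            if truncate_at_zero and t < 0:
                t = 0.0
            vals[i, j] = vals[j, i] = t
    return SquareMatrix(groups, vals)


# ---------------------------------------------------------------------------
# private alleles and summary table
# ---------------------------------------------------------------------------
def private_alleles(table: AlleleFrequencyTable):
    """Per-group private-allele proportion.

    A private allele is observed in exactly one group. The proportion is
    (number of alleles private to the group) / (total distinct alleles in
    the dataset, over all loci). Also returns the frequency of each private
    allele within its group.
    """
    if len(table.groups) < 2:
        raise ValueError("private alleles need >= 2 groups")
    total_alleles = 0
    private_count = {g: 0 for g in table.groups}
    records = []
    for locus in table.loci:
        carriers: dict[int, list[str]] = {}
        for g in table.groups:
            for a in table.counts.get((g, locus), {}):
                carriers.setdefault(a, []).append(g)
        total_alleles += len(carriers)
        for a, gs in carriers.items():
            if len(gs) == 1:
                g = gs[0]
                private_count[g] += 1
                records.append(
                    {
                        "cluster": g,
                        "locus": locus,
                        "allele": a,
                        "frequency": table.frequencies(g, locus)[a],
                    }
                )
    if total_alleles == 0:
        props = pd.Series({g: 0.0 for g in table.groups})
    else:
        props = pd.Series(
            {g: private_count[g] / total_alleles for g in table.groups}
        )
    detail = pd.DataFrame(records, columns=["cluster", "locus", "allele", "frequency"])
    return props, detail


def diversity_summary(
    panel: GenotypePanel, by: str = "site", rarefaction_copies: int = 36
) -> pd.DataFrame:
    """Per-group summary: n, N_A, A_R(g), H_E, F_IS (Table-1 layout).

    ``rarefaction_copies`` is g in gene copies (36 = 18 diploids). Loci with
    fewer nonmissing copies than g are excluded from A_R with a warning.
    """
    table = allele_counts(panel, by)
    idx = panel.group_indices(by)
    rows = []
    for g in table.groups:
        na_vals, ar_vals, he_vals = [], [], []
        for locus in table.loci:
            c = table.counts.get((g, locus), {})
            n = sum(c.values())
            if n == 0:
                continue
            na_vals.append(len(c))
            he = expected_heterozygosity(c)
            if not math.isnan(he):
                he_vals.append(he)
            if n >= rarefaction_copies:
                ar_vals.append(allelic_richness(c, rarefaction_copies))
            else:
                log.warning(
                    "group %s locus %s: %d copies < g=%d, excluded from A_R",
                    g, locus, n, rarefaction_copies,
                )
        rows.append(
            {
                "group": g,
                "n": int(len(idx[g])),
                "N_A": float(np.mean(na_vals)) if na_vals else UNDEFINED,
                "A_R": float(np.mean(ar_vals)) if ar_vals else UNDEFINED,
                "H_E": float(np.mean(he_vals)) if he_vals else UNDEFINED,
                "F_IS": f_is(panel, g, by),
            }
        )
    return pd.DataFrame(rows).set_index("group")
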