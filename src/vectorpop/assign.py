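"""Bayesian genotype assignment and directional migration matrices.

Assignment follows the Rannala & Mountain posterior-predictive criterion
(as popularized by GENECLASS): each candidate source cluster's allele
frequencies get a Dirichlet(1/k) prior, where k is the number of distinct
alleles at the locus across the whole dataset, and the likelihood of a
multilocus genotype is the product over loci of the posterior-predictive
probability of the observed allele pair given the cluster's allele counts.
Directional gene flow between clusters is then summarized as the proportion
of individuals sampled in a *recipient* cluster whose most-likely source is
each candidate *source* cluster (rows = source, columns = recipient).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import SquareMatrix
from .panel import MISSING, GenotypePanel

log = logging.getLogger(__name__)


def genotype_likelihood(
    genotype,
    cluster_counts,
    k_per_locus,
) -> float:
    """Log-likelihood of one multilocus genotype in one candidate cluster.

    Parameters
    ----------
    genotype : sequence of (a1, a2) allele sizes, 0 = missing
    cluster_counts : sequence of {allele: count} per locus (gene copies in
        the candidate cluster; exclude the focal individual's copies for a
        leave-one-out likelihood)
    k_per_locus : sequence of int, dataset-wide distinct allele count per
        locus (sets the Dirichlet prior mass 1/k per allele)

    Missing loci are skipped. The Dirichlet prior keeps every term positive
    (an allele unseen in the cluster never yields -inf).
    """
    total = 0.0
    for (a1, a2), counts, k in zip(genotype, cluster_counts, k_per_locus):
        if a1 == MISSING or a2 == MISSING:
            continue
        n = sum(counts.values())
        tau = 1.0 / k
        denom = (n + 1) * (n + 2)
        if a1 == a2:
            nj = counts.get(a1, 0)
            p = (nj + tau) * (nj + 1 + tau) / denom
        else:
            p = 2.0 * (counts.get(a1, 0) + tau) * (counts.get(a2, 0) + tau) / denom
        total += np.log(p)
    return float(total)


@dataclass
class AssignmentResult:
    individuals: list[str]
    clusters: list[str]  # candidate source clusters, in panel order
    home: np.ndarray  # per-individual home cluster label
    loglik: pd.DataFrame  # individuals x clusters
    modal: np.ndarray  # per-individual most-likely source cluster
    tied: np.ndarray  # True where the modal choice was a tie-break
    leave_one_out: bool

    def to_frame(self) -> pd.DataFrame:
        df = self.loglik.copy()
        df.insert(0, "home", self.home)
        df["modal"] = self.modal
        df["tied"] = self.tied
        return df


def _encode(panel: GenotypePanel):
    """Dataset-wide per-locus allele index arrays; -1 marks missing."""
    n, L = panel.n_individuals, panel.n_loci
    idx = np.full((n, L, 2), -1, dtype=np.int64)
    k_per_locus = np.zeros(L, dtype=np.int64)
    maps = []
    for j in range(L):
        col = panel.genotypes[:, j, :]
        alleles = np.unique(col[col != MISSING])
        amap = {int(a): i for i, a in enumerate(alleles)}
        maps.append(amap)
        k_per_locus[j] = len(alleles)
        for c in (0, 1):
            vals = col[:, c]
            typed = vals != MISSING
            idx[typed, j, c] = [amap[int(v)] for v in vals[typed]]
    return idx, k_per_locus, maps


def assign_all(
    panel: GenotypePanel, by: str = "cluster", leave_one_out: bool = True
) -> AssignmentResult:
    """Assign every individual to its most likely source cluster.

    With ``leave_one_out`` the focal individual's own gene copies are
    removed from its home cluster's counts before computing that cluster's
    likelihood. Ties are broken by cluster order and logged.
    """
    clusters = panel.group_names(by)
    labels = panel.labels(by)
    idx, k_per_locus, _ = _encode(panel)
    n, L = panel.n_individuals, panel.n_loci
    K = len(clusters)
    a_max = max(int(k_per_locus.max()), 1)

    counts = np.zeros((K, L, a_max), dtype=np.int64)
    home_k = np.array([clusters.index(c) for c in labels])
    for c in (0, 1):
        a = idx[:, :, c]
        typed = a >= 0
        np.add.at(
            counts,
            (home_k[:, None].repeat(L, 1)[typed], np.broadcast_to(np.arange(L), (n, L))[typed], a[typed]),
            1,
        )
    for g, rows in panel.group_indices(by).items():
        if panel.typed_mask()[rows].sum() == 0:
            raise ValueError(f"cluster {g!r} has no typed individual")

    a1, a2 = idx[:, :, 0], idx[:, :, 1]
    typed = (a1 >= 0) & (a2 >= 0)
    hom = typed & (a1 == a2)
    tau = 1.0 / np.maximum(k_per_locus, 1)  # (L,)
    lo = np.arange(L)
    loglik = np.zeros((n, K))
    a1s, a2s = np.where(a1 >= 0, a1, 0), np.where(a2 >= 0, a2, 0)
    for k in range(K):
        n_cop = counts[k].sum(axis=1)[None, :].astype(float)  # (1, L)
        nj1 = counts[k][lo, a1s].astype(float)
        nj2 = counts[k][lo, a2s].astype(float)
        if leave_one_out:
            sub = (home_k == k).astype(float)[:, None]
            nj1 = nj1 - sub
            nj2 = nj2 - sub
            n_eff = n_cop - 2 * sub
        else:
            n_eff = np.broadcast_to(n_cop, (n, L)).copy()
        denom = (n_eff + 1) * (n_eff + 2)
        p_het = 2.0 * (nj1 + tau) * (nj2 + tau) / denom
        # homozygote: both copies are the same allele; with leave-one-out
        # the remaining count is nj - 2, and nj1 already had 1 removed
        nj_hom = np.where(
            hom, nj1 - (1.0 if leave_one_out else 0.0) * (home_k == k)[:, None], nj1
        )
        p_hom = (nj_hom + tau) * (nj_hom + 1 + tau) / denom
        p = np.where(hom, p_hom, p_het)
        p = np.where(typed, p, 1.0)
        loglik[:, k] = np.log(p).sum(axis=1)

    best = loglik.max(axis=1, keepdims=True)
    is_max = np.isclose(loglik, best, rtol=0, atol=1e-10)
    modal_k = is_max.argmax(axis=1)  # first max = cluster-order tie-break
    tied = is_max.sum(axis=1) > 1
    if tied.any():
        log.warning(
            "%d individuals had tied assignment likelihoods; broke ties by "
            "cluster order", int(tied.sum()),
        )
    return AssignmentResult(
        individuals=list(panel.individuals),
        clusters=clusters,
        home=labels.copy(),
        loglik=pd.DataFrame(loglik, index=panel.individuals, columns=clusters),
        modal=np.array([clusters[k] for k in modal_k], dtype=object),
        tied=tied,
        leave_one_out=leave_one_out,
    )


def migration_matrix(
    assignments: AssignmentResult, exclude_self: bool = False
) -> SquareMatrix:
    """Directional migration matrix from modal assignments.

    Cell (source, recipient) is the proportion of individuals sampled in
    the recipient cluster whose modal assignment is the source cluster.
    Columns sum to 1. With ``exclude_self`` the self-assigned individuals
    are dropped from the denominator and the diagonal is zero (columns with
    no non-self assignments are left all-zero with a warning).
    """
    clusters = assignments.clusters
    K = len(clusters)
    M = np.zeros((K, K))
    for j, rec in enumerate(clusters):
        in_rec = assignments.home == rec
        if not in_rec.any():
            raise ValueError(f"recipient cluster {rec!r} is empty")
        modal = assignments.modal[in_rec]
        if exclude_self:
            modal = modal[modal != rec]
            if modal.size == 0:
                log.warning("cluster %r: no non-self assignments", rec)
                continue
        for i, src in enumerate(clusters):
            if exclude_self and src == rec:
                continue
            M[i, j] = np.mean(modal == src)
    return SquareMatrix(clusters, M)
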