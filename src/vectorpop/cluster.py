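"""Bayesian clustering of multilocus genotypes and Evanno's delta-K.

A no-admixture, uncorrelated-allele-frequency Gibbs sampler: each
individual carries a single latent cluster label; cluster-by-locus allele
frequencies get independent Dirichlet(1) priors and genotypes are
Hardy-Weinberg draws within their cluster. The sampler alternates blocked
updates — all labels given frequencies, then all frequencies given labels —
which is a valid two-block Gibbs scheme and fully vectorizable.

Model choice across K uses the Evanno second-difference statistic
delta-K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)) over
replicate runs, where L is the usual mean-minus-half-variance estimate of
ln P(X | K) from the post-burn-in log-likelihood trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel

log = logging.getLogger(__name__)


@dataclass
class ClusterModel:
    K: int
    memberships: np.ndarray  # (n, K) posterior label frequencies
    loglik_trace: np.ndarray  # per post-burn-in iteration ln P(X | Z, P)
    L: float  # estimate of ln P(X | K): mean - var/2
    burn_in: int
    iters: int
    seed: int
    individuals: list[str]

    def modal_labels(self) -> np.ndarray:
        return self.memberships.argmax(axis=1)

    def membership_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.memberships,
            index=self.individuals,
            columns=[f"cluster_{k+1}" for k in range(self.K)],
        )


def _encode(panel: GenotypePanel):
    n, L = panel.n_individuals, panel.n_loci
    idx = np.full((n, L, 2), -1, dtype=np.int64)
    n_alleles = np.zeros(L, dtype=np.int64)
    for j in range(L):
        col = panel.genotypes[:, j, :]
        alleles = np.unique(col[col != MISSING])
        amap = {int(a): i for i, a in enumerate(alleles)}
        n_alleles[j] = max(len(alleles), 1)
        for c in (0, 1):
            vals = col[:, c]
            typed = vals != MISSING
            idx[typed, j, c] = [amap[int(v)] for v in vals[typed]]
    return idx, n_alleles


def gibbs_cluster(
    panel: GenotypePanel,
    K: int,
    burn_in: int = 1000,
    iters: int = 10_000,
    seed: int = 0,
) -> ClusterModel:
    """Run the no-admixture Gibbs sampler at a fixed number of clusters."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > panel.n_individuals:
        raise ValueError(
            f"K={K} exceeds the number of individuals ({panel.n_individuals})"
        )
    if iters < 1:
        raise ValueError("iters must be positive")
    rng = np.random.default_rng(seed)
    idx, n_alleles = _encode(panel)
    n, L = panel.n_individuals, panel.n_loci
    a_max = int(n_alleles.max())
    lo = np.arange(L)
    a1 = np.where(idx[:, :, 0] >= 0, idx[:, :, 0], 0)
    a2 = np.where(idx[:, :, 1] >= 0, idx[:, :, 1], 0)
    typed = (idx[:, :, 0] >= 0) & (idx[:, :, 1] >= 0)
    het = typed & (idx[:, :, 0] != idx[:, :, 1])
    het_const = float(het.sum()) * np.log(2.0)  # HWE 2pq factor, fixed given data
    valid = np.arange(a_max)[None, :] < n_alleles[:, None]  # (L, a_max)
    alpha_prior = np.where(valid, 1.0, 0.0)  # Dirichlet(1) on real alleles only

    z = rng.integers(0, K, size=n)
    memb_counts = np.zeros((n, K))
    trace = np.empty(iters)

    def sample_freqs(z_now: np.ndarray) -> np.ndarray:
        counts = np.zeros((K, L, a_max))
        for c, a in ((0, a1), (1, a2)):
            np.add.at(
                counts,
                (
                    np.broadcast_to(z_now[:, None], (n, L))[typed],
                    np.broadcast_to(lo, (n, L))[typed],
                    a[typed],
                ),
                1.0,
            )
        gam = rng.gamma(alpha_prior[None, :, :] + counts)
        with np.errstate(invalid="ignore"):
            p = gam / gam.sum(axis=2, keepdims=True)
        return p

    p = sample_freqs(z)
    for it in range(burn_in + iters):
        with np.errstate(divide="ignore"):
            logp = np.where(p > 0, np.log(p), -np.inf)  # (K, L, a_max)
        ll = logp[:, lo, a1] + logp[:, lo, a2]  # (K, n, L) via broadcasting
        ll = np.where(typed[None, :, :], ll, 0.0).sum(axis=2).T  # (n, K)
        if K > 1:
            gumb = rng.gumbel(size=(n, K))
            z = (ll + gumb).argmax(axis=1)
        else:
            z = np.zeros(n, dtype=np.int64)
        if it >= burn_in:
            memb_counts[np.arange(n), z] += 1.0
            trace[it - burn_in] = float(ll[np.arange(n), z].sum()) + het_const
        p = sample_freqs(z)

    memberships = memb_counts / iters
    L_est = float(trace.mean() - trace.var(ddof=1) / 2.0) if iters > 1 else float(trace.mean())
    return ClusterModel(
        K=K, memberships=memberships, loglik_trace=trace, L=L_est,
        burn_in=burn_in, iters=iters, seed=seed,
        individuals=list(panel.individuals),
    )


# ---------------------------------------------------------------------------
# Evanno model choice
# ---------------------------------------------------------------------------
@dataclass
class EvannoTable:
    table: pd.DataFrame  # index K: mean_L, sd_L, delta_K
    selected_K: int | None


def evanno_select(runs_by_K: dict[int, list[ClusterModel]]) -> EvannoTable:
    """Evanno delta-K over replicate runs; selected K = argmax delta-K.

    Requires at least 3 consecutive K values with >= 2 replicates each.
    delta-K is undefined at the boundary K values and wherever sd(L) = 0.
    """
    ks = sorted(runs_by_K)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need >= 3 consecutive K values")
    for k in ks:
        if len(runs_by_K[k]) < 2:
            raise ValueError(f"K={k}: need >= 2 replicate runs")
    mean_L = {k: float(np.mean([m.L for m in runs_by_K[k]])) for k in ks}
    sd_L = {k: float(np.std([m.L for m in runs_by_K[k]], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        dk = np.nan
        if k != ks[0] and k != ks[-1]:
            if sd_L[k] > 0:
                dk = abs(mean_L[k + 1] - 2 * mean_L[k] + mean_L[k - 1]) / sd_L[k]
            else:
                log.warning("K=%d: sd(L) = 0, delta-K undefined there", k)
        rows.append({"K": k, "mean_L": mean_L[k], "sd_L": sd_L[k], "delta_K": dk})
    df = pd.DataFrame(rows).set_index("K")
    defined = df["delta_K"].dropna()
    if defined.empty:
        log.warning("delta-K undefined at every interior K; no selection")
        selected = None
    else:
        selected = int(defined.idxmax())
    return EvannoTable(table=df, selected_K=selected)


# ---------------------------------------------------------------------------
# label-switching repair
# ---------------------------------------------------------------------------
def align_labels(models: list[ClusterModel]) -> list[ClusterModel]:
    """Greedily align cluster labels across replicate runs.

    The first model is the reference; every other model's columns are
    permuted to maximize summed membership agreement with it (greedy
    assignment on the K x K overlap matrix). Deterministic in input order.
    A single model is returned unchanged.
    """
    if len(models) < 2:
        return list(models)
    K = models[0].K
    if any(m.K != K for m in models):
        raise ValueError("all models must share the same K")
    ref = models[0]
    out = [ref]
    for m in models[1:]:
        overlap = ref.memberships.T @ m.memberships  # (K, K)
        perm = np.full(K, -1)
        work = overlap.copy()
        for _ in range(K):
            i, j = np.unravel_index(np.argmax(work), work.shape)
            perm[j] = i
            work[i, :] = -np.inf
            work[:, j] = -np.inf
        new_memb = np.empty_like(m.memberships)
        for j, i in enumerate(perm):
            new_memb[:, i] = m.memberships[:, j]
        out.append(
            ClusterModel(
                K=m.K, memberships=new_memb, loglik_trace=m.loglik_trace,
                L=m.L, burn_in=m.burn_in, iters=m.iters, seed=m.seed,
                individuals=m.individuals,
            )
        )
    return out


def membership_agreement(a: ClusterModel, b: ClusterModel) -> float:
    """Mean per-individual overlap of membership fractions (1 = identical)."""
    if a.K != b.K:
        raise ValueError("models must share K")
    return float(np.minimum(a.memberships, b.memberships).sum(axis=1).mean())
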