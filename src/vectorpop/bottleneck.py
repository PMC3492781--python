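"""Heterozygosity-excess bottleneck detection (Cornuet & Luikart style).

A recently bottlenecked population loses rare alleles faster than gene
diversity, so its observed heterozygosity exceeds the equilibrium
heterozygosity expected from the observed number of alleles. The null
distribution of equilibrium heterozygosity given (n gene copies, k observed
alleles) is built by simulating Kingman coalescent genealogies, overlaying
two-phase-model (TPM) mutations at a scaled mutation rate theta calibrated
so replicates hit the observed allele count, and keeping only replicates
with exactly k alleles. Per-locus excesses are combined with a Wilcoxon
signed-rank test (exact tail probabilities up to 20 loci); the qualitative
mode-shift check inspects the pooled allele-frequency histogram for loss of
its expected L shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .popgen import AlleleFrequencyTable, expected_heterozygosity
from .synthio import tpm_steps

log = logging.getLogger(__name__)

_EQ_CACHE: dict[tuple, tuple[float, float, np.ndarray]] = {}


# ---------------------------------------------------------------------------
# coalescent simulation with TPM mutations
# ---------------------------------------------------------------------------
def _simulate_locus(n_copies: int, theta: float, p_multistep: float,
                    multistep_variance: float, rng: np.random.Generator,
                    crash_factor: float = 1.0, crash_duration: float = 0.0):
    """One coalescent genealogy of n genes + TPM mutations -> (k, H_E).

    A recent population crash can be emulated on the coalescent time
    scale: for the most recent ``crash_duration`` units of scaled time the
    coalescent rate is multiplied by ``crash_factor`` (a population that
    shrank by that factor coalesces that much faster); earlier history is
    standard.
    """
    n = n_copies
    total_nodes = 2 * n - 1
    parent = np.full(total_nodes, -1, dtype=np.int64)
    node_time = np.zeros(total_nodes)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        i = len(active)
        base_rate = i * (i - 1) / 2.0
        if crash_duration > 0.0 and t < crash_duration:
            dt = rng.exponential(1.0 / (base_rate * crash_factor))
            if t + dt > crash_duration:
                # crossed out of the crash window: re-draw in the slow regime
                t = crash_duration
                dt = rng.exponential(1.0 / base_rate)
        else:
            dt = rng.exponential(1.0 / base_rate)
        t += dt
        a_pos, b_pos = rng.choice(i, size=2, replace=False)
        if a_pos > b_pos:
            a_pos, b_pos = b_pos, a_pos
        b = active.pop(b_pos)
        a = active.pop(a_pos)
        parent[a] = parent[b] = nxt
        node_time[nxt] = t
        active.append(nxt)
        nxt += 1
    root = total_nodes - 1
    branch = node_time[parent[:root]] - node_time[:root]
    n_mut = rng.poisson(theta / 2.0 * branch)
    step_sum = np.zeros(total_nodes, dtype=np.int64)
    tot = int(n_mut.sum())
    if tot:
        steps = tpm_steps(tot, p_multistep, multistep_variance, rng)
        step_sum[:root] = np.add.reduceat(
            np.concatenate([steps, [0]]),
            np.concatenate([[0], np.cumsum(n_mut)[:-1]]),
        ) * (n_mut > 0)
    value = np.zeros(total_nodes, dtype=np.int64)
    value[root] = 1000  # arbitrary origin; identity statistics are shift-invariant
    for v in range(root - 1, -1, -1):  # children precede parents by construction
        value[v] = value[parent[v]] + step_sum[v]
    leaves = value[:n]
    _, counts = np.unique(leaves, return_counts=True)
    k = counts.size
    h = expected_heterozygosity({i: int(c) for i, c in enumerate(counts)})
    return k, h


def _mean_k(n_copies: int, theta: float, tpm: tuple[float, float],
            n_pilot: int, rng: np.random.Generator) -> float:
    ks = [
        _simulate_locus(n_copies, theta, tpm[0], tpm[1], rng)[0]
        for _ in range(n_pilot)
    ]
    return float(np.mean(ks))


def equilibrium_h_distribution(
    n_copies: int,
    k_obs: int,
    tpm_params: tuple[float, float] = (0.10, 12.0),
    n_sims: int = 500,
    seed: int = 0,
    theta_spread: float = 8.0,
    _n_pilot: int = 100,
):
    """Equilibrium heterozygosity distribution given (n, k) under the TPM.

    A coarse theta search (bisection on the mean simulated allele count)
    centres the mutation parameter; the conditional null is then built by
    rejection sampling on the exact allele count with theta drawn
    log-uniformly from [theta0/spread, theta0*spread] at every attempt.
    Integrating theta over the bracket instead of plugging in the point
    estimate removes the k-dependent centring bias of a single-theta null
    (acceptance itself reweights the theta draws by P(k_obs | theta), so
    the accepted replicates follow the theta-integrated conditional law).
    Returns (mean, sd, accepted H samples). Raises if the acceptance rate
    collapses below 0.1%.
    """
    if not 2 <= k_obs <= n_copies:
        raise ValueError("need 2 <= k_obs <= n_copies")
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    key = (n_copies, k_obs, tpm_params, n_sims, seed, theta_spread)
    if key in _EQ_CACHE:
        return _EQ_CACHE[key]
    rng = np.random.default_rng(seed)
    p_ms, var_ms = tpm_params

    lo, hi = 1e-3, 8.0
    while _mean_k(n_copies, hi, tpm_params, _n_pilot, rng) < k_obs:
        hi *= 2.0
        if hi > 1e5:
            raise RuntimeError("theta search failed to bracket k_obs from above")
    while _mean_k(n_copies, lo, tpm_params, _n_pilot, rng) > k_obs:
        lo /= 4.0
        if lo < 1e-8:
            raise RuntimeError("theta search failed to bracket k_obs from below")
    for _ in range(14):
        mid = np.sqrt(lo * hi)
        if _mean_k(n_copies, mid, tpm_params, _n_pilot, rng) < k_obs:
            lo = mid
        else:
            hi = mid
    theta0 = np.sqrt(lo * hi)

    samples = []
    attempts = 0
    max_attempts = max(400 * n_sims, 40_000)
    while len(samples) < n_sims:
        attempts += 1
        if attempts > max_attempts:
            rate = len(samples) / attempts
            if rate < 1e-3:
                raise RuntimeError(
                    f"acceptance rate {rate:.2e} < 0.1% at theta={theta0:.3g}; "
                    "review n_copies/k_obs/TPM parameters"
                )
            break
        theta = theta0 * theta_spread ** rng.uniform(-1.0, 1.0)
        k, h = _simulate_locus(n_copies, theta, p_ms, var_ms, rng)
        if k == k_obs:
            samples.append(h)
    arr = np.array(samples)
    out = (float(arr.mean()), float(arr.std(ddof=1)), arr)
    _EQ_CACHE[key] = out
    return out


def pseudomedian(samples: np.ndarray) -> float:
    """Hodges-Lehmann pseudo-median: median of all pairwise Walsh averages.

    The Wilcoxon signed-rank statistic tests whether the pseudo-median of
    the paired differences is zero, so the equilibrium null must be
    centred on the conditional pseudo-median rather than the mean — the
    conditional law of H given k is left-skewed, and mean-centring makes
    the excess tail anticonservative.
    """
    arr = np.asarray(samples, dtype=float)
    walsh = (arr[:, None] + arr[None, :]) / 2.0
    return float(np.median(walsh[np.triu_indices(arr.size)]))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank with exact small-sample tails
# ---------------------------------------------------------------------------
def _exact_wplus_tail(ranks2: np.ndarray, w2_obs: int, upper: bool) -> float:
    """P(W+ >= or <= observed) over all 2^L equally likely sign patterns.

    ``ranks2`` holds doubled ranks (integers even with midranks); a
    dynamic-programming convolution enumerates the exact distribution,
    equivalent to brute-force sign enumeration.
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    if upper:
        return float(dist[w2_obs:].sum())
    return float(dist[: w2_obs + 1].sum())


def wilcoxon_het_excess(
    observed_H,
    equilibrium_means,
    tail: str = "excess",
) -> float:
    """Wilcoxon signed-rank p-value on per-locus (H_obs - H_eq) pairs.

    ``tail='excess'`` is the one-sided bottleneck alternative (observed
    heterozygosity above equilibrium); ``'deficit'`` the opposite side;
    ``'two-sided'`` doubles the smaller tail. Exact distribution by
    enumeration for <= 20 informative loci, normal approximation with
    continuity and tie corrections above.
    """
    if tail not in ("excess", "deficit", "two-sided"):
        raise ValueError("tail must be excess, deficit or two-sided")
    obs = np.asarray(observed_H, dtype=float)
    eq = np.asarray(equilibrium_means, dtype=float)
    if obs.shape != eq.shape:
        raise ValueError("paired vectors must have equal length")
    d = obs - eq
    d = d[d != 0.0]
    L = d.size
    if L == 0:
        log.warning("all per-locus differences are zero; p = 1")
        return 1.0
    if np.count_nonzero(np.asarray(observed_H) != np.asarray(equilibrium_means)) < 4:
        log.warning("fewer than 4 informative loci; Wilcoxon p is coarse")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if L <= 20:
        ranks2 = np.round(2 * ranks).astype(int)
        w2 = int(round(2 * w_plus))
        p_up = _exact_wplus_tail(ranks2, w2, upper=True)
        p_dn = _exact_wplus_tail(ranks2, w2, upper=False)
    else:
        mean = L * (L + 1) / 4.0
        ties = pd.Series(ranks).value_counts().to_numpy()
        var = L * (L + 1) * (2 * L + 1) / 24.0 - (ties**3 - ties).sum() / 48.0
        sd = np.sqrt(var)
        p_up = float(norm.sf((w_plus - 0.5 - mean) / sd))
        p_dn = float(norm.cdf((w_plus + 0.5 - mean) / sd))
    if tail == "excess":
        return min(p_up, 1.0)
    if tail == "deficit":
        return min(p_dn, 1.0)
    return min(1.0, 2.0 * min(p_up, p_dn))


# ---------------------------------------------------------------------------
# mode shift
# ---------------------------------------------------------------------------
def mode_shift(table: AlleleFrequencyTable, group: str):
    """Allele-frequency mode-shift check for one cluster.

    Pools every allele's frequency across loci into ten classes
    (0, 0.1], (0.1, 0.2], ..., (0.9, 1.0]. The distribution is L-shaped
    when the lowest class is the strict mode; a mode shift is its absence.
    Returns (mode_shift, histogram counts).
    """
    freqs = []
    for locus in table.loci:
        freqs.extend(table.frequencies(group, locus).values())
    freqs = np.asarray(freqs)
    if freqs.size == 0:
        raise ValueError(f"group {group!r} carries no alleles")
    # classes are left-open: (0, 0.1], ... ; a frequency is never 0 here
    classes = np.clip(np.ceil(freqs * 10 - 1e-12).astype(int) - 1, 0, 9)
    hist = np.bincount(classes, minlength=10)
    shifted = not (hist[0] > hist[1:].max())
    return bool(shifted), hist


# ---------------------------------------------------------------------------
# per-cluster driver
# ---------------------------------------------------------------------------
@dataclass
class BottleneckResult:
    group: str
    per_locus: pd.DataFrame  # locus, n_copies, k_obs, H_obs, H_eq_mean, H_eq_sd, DH
    p_excess: float
    p_deficit: float
    p_two_sided: float
    mode_shift: bool
    histogram: np.ndarray


def bottleneck_test(
    table: AlleleFrequencyTable,
    group: str,
    tpm_params: tuple[float, float] = (0.10, 12.0),
    n_sims: int = 500,
    seed: int = 0,
) -> BottleneckResult:
    """Full heterozygosity-excess test for one cluster.

    Monomorphic loci are uninformative and skipped. Equilibrium
    distributions are cached per (n, k, TPM) with a deterministic
    per-locus seed derived from ``seed``.
    """
    rows = []
    for locus in table.loci:
        counts = table.counts.get((group, locus), {})
        n = sum(counts.values())
        k = len(counts)
        if k < 2 or n < 4:
            continue
        locus_seed = int(
            np.random.SeedSequence([seed, n, k]).generate_state(1)[0] % (2**31)
        )
        mean, sd, samples = equilibrium_h_distribution(
            n, k, tpm_params, n_sims=n_sims, seed=locus_seed
        )
        h_obs = expected_heterozygosity(counts)
        dh = (h_obs - mean) / sd if sd > 0 else np.nan
        rows.append(
            {
                "locus": locus, "n_copies": n, "k_obs": k, "H_obs": h_obs,
                "H_eq_mean": mean, "H_eq_sd": sd,
                "H_eq_pmed": pseudomedian(samples), "DH": dh,
            }
        )
    if len(rows) < 4:
        raise ValueError(f"group {group!r}: fewer than 4 polymorphic loci")
    per_locus = pd.DataFrame(rows)
    # the signed-rank test is centred on the conditional pseudo-median (see
    # pseudomedian); DH keeps the conventional mean/sd standardization
    p_exc = wilcoxon_het_excess(per_locus["H_obs"], per_locus["H_eq_pmed"], "excess")
    p_def = wilcoxon_het_excess(per_locus["H_obs"], per_locus["H_eq_pmed"], "deficit")
    p_two = wilcoxon_het_excess(per_locus["H_obs"], per_locus["H_eq_pmed"], "two-sided")
    shifted, hist = mode_shift(table, group)
    return BottleneckResult(
        group=group, per_locus=per_locus, p_excess=p_exc, p_deficit=p_def,
        p_two_sided=p_two, mode_shift=shifted, histogram=hist,
    )
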