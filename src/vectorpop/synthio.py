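"""Synthetic study-system generator.

Produces the three inputs the analysis chain consumes — a directed
vessel-transit network, alongshore geographic distances, and diploid
microsatellite genotypes — for an invasion scenario with a known truth:
demes are founded from a common ancestral allele pool, drift apart under
partial selfing, and exchange migrants in proportion to the directed
network's inbound edge weights. One deme can optionally be seeded from a
partly disjoint allele pool, emulating an independent introduction that
carries private alleles.

The genotype simulator is forward-time Wright–Fisher (discrete
non-overlapping generations) so that directional migration follows the
vector network exactly. Mutation follows a two-phase model (TPM):
single-step with probability 1 - p_multistep, otherwise a multi-step change
drawn from a symmetric geometric distribution scaled to a configured
variance. Allele sizes are repeat counts, reflected at a floor of 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .matrix import SquareMatrix
from .panel import GenotypePanel


# ---------------------------------------------------------------------------
# vector network and distances
# ---------------------------------------------------------------------------
@dataclass
class VectorNetwork:
    """Directed annual vessel-transit counts between clusters."""

    labels: list[str]
    weights: np.ndarray  # (k, k), cell (i, j) = transits from i to j

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.weights = np.asarray(self.weights, dtype=float)
        k = len(self.labels)
        if self.weights.shape != (k, k):
            raise ValueError("weights must be square and match labels")
        if (self.weights < 0).any():
            raise ValueError("transit counts must be nonnegative")

    def to_matrix(self) -> SquareMatrix:
        return SquareMatrix(self.labels, self.weights.copy())

    def inbound(self, label: str) -> np.ndarray:
        j = self.labels.index(label)
        w = self.weights[:, j].copy()
        w[j] = 0.0  # self-transits carry no migrants
        return w

    def write(self, path) -> None:
        self.to_matrix().write(path)

    @classmethod
    def read(cls, path) -> "VectorNetwork":
        m = SquareMatrix.read(path)
        return cls(m.labels, m.values)


def generate_vector_network(
    labels: Sequence[str], total_transits: float, asymmetry: float, seed: int
) -> VectorNetwork:
    """Random directed transit network with a controlled asymmetry level.

    Edge intensities are heavy-tailed (log-normal), matching the strongly
    skewed port-to-port traffic distributions of coastal shipping data.
    ``asymmetry`` interpolates between a symmetric network (0) and fully
    independent directed edges (1). Off-diagonal weights are scaled to sum
    to ``total_transits``; the diagonal is zero.
    """
    labels = [str(x) for x in labels]
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")
    if total_transits <= 0:
        raise ValueError("total_transits must be positive")
    if not 0.0 <= asymmetry <= 1.0:
        raise ValueError("asymmetry must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    k = len(labels)
    raw = rng.lognormal(mean=0.0, sigma=1.0, size=(k, k))
    sym = (raw + raw.T) / 2.0
    w = (1.0 - asymmetry) * sym + asymmetry * raw
    np.fill_diagonal(w, 0.0)
    w *= total_transits / w.sum()
    return VectorNetwork(labels, w)


def distance_matrix_from_layout(coordinates: Mapping[str, float]) -> SquareMatrix:
    """Pairwise alongshore distances from 1-D coastline coordinates."""
    labels = list(coordinates)
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate labels in layout")
    x = np.array([float(coordinates[l]) for l in labels])
    return SquareMatrix(labels, np.abs(x[:, None] - x[None, :]))


# ---------------------------------------------------------------------------
# simulation configuration
# ---------------------------------------------------------------------------
@dataclass
class SimulationConfig:
    """Forward-simulation parameters.

    ``sample_sizes`` maps site label -> individuals sampled; ``site_to_deme``
    maps each site to the deme it is drawn from (several sites may share a
    deme — they are split from one deme at sampling time). When
    ``site_to_deme`` is omitted each site is its own deme.

    ``migration_onset`` is the generation index at which vector-driven
    migration switches on; the default 0 applies migration throughout. A
    late onset emulates an invasion timeline in which demes diverge during
    colonization before contemporary vessel traffic begins moving
    individuals, keeping the system away from migration–drift equilibrium.
    """

    n_demes: int
    n_loci: int = 10
    alleles_per_locus: int = 6
    generations: int = 40
    founder_size: int = 50
    deme_size: int = 150
    migration_scale: float = 0.05  # per-individual immigration prob per generation
    migration_baseline: float = 0.0  # immigration prob before migration_onset
    selfing_rate: float = 0.4
    mutation_rate: float = 1e-3
    p_multistep: float = 0.10
    multistep_variance: float = 12.0
    outlier_deme: str | None = None
    outlier_pool_fraction: float = 0.35  # founder gene copies drawn from private pool
    outlier_extra_alleles: int = 3  # private-pool alleles per locus
    ancestral_decay: float = 0.45  # geometric ratio of ancestral frequency profile
    ancestral_decay_jitter: float = 0.05  # per-locus uniform jitter on the ratio
    sample_sizes: dict[str, int] = field(default_factory=dict)
    site_to_deme: dict[str, str] = field(default_factory=dict)
    migration_onset: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "migration_scale": self.migration_scale,
            "migration_baseline": self.migration_baseline,
            "selfing_rate": self.selfing_rate,
            "mutation_rate": self.mutation_rate,
            "p_multistep": self.p_multistep,
            "outlier_pool_fraction": self.outlier_pool_fraction,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_demes", "n_loci", "alleles_per_locus", "generations",
                     "founder_size", "deme_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.multistep_variance <= 0:
            raise ValueError("multistep_variance must be positive")
        if not self.site_to_deme:
            self.site_to_deme = {s: s for s in self.sample_sizes}


def _multistep_geom_q(target_variance: float) -> float:
    """Success prob q of the geometric magnitude law |step| = 1 + Geom(q).

    Chosen so E[step^2] equals the configured multistep variance (the step
    is symmetric, so its mean is 0 and variance = E[step^2]). Magnitudes
    are >= 2 by construction, hence the smallest attainable variance is 4;
    smaller requests collapse to deterministic +/-2 steps.
    """
    if target_variance <= 4.0:
        return 1.0

    def excess(q: float) -> float:
        return 1.0 + 2.0 / q + (2.0 - q) / q**2 - target_variance

    return brentq(excess, 1e-9, 1.0)


def tpm_steps(n: int, p_multistep: float, multistep_variance: float,
              rng: np.random.Generator) -> np.ndarray:
    """Draw n signed TPM mutation steps."""
    signs = rng.choice((-1, 1), size=n)
    mags = np.ones(n, dtype=np.int64)
    multi = rng.random(n) < p_multistep
    k = int(multi.sum())
    if k:
        q = _multistep_geom_q(multistep_variance)
        mags[multi] = 1 + rng.geometric(q, size=k)
    return signs * mags


def _reflect_floor(alleles: np.ndarray, floor: int = 1) -> np.ndarray:
    """Reflect allele sizes at a positive floor (no nonpositive repeats)."""
    out = alleles.copy()
    while True:
        below = out < floor
        if not below.any():
            return out
        out[below] = 2 * floor - out[below]


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------
def _ancestral_pools(config: SimulationConfig, rng: np.random.Generator):
    """Per-locus shared (and optional private) allele pools.

    Ancestral frequencies follow a geometric profile p_i proportional to
    r^i (r = ``ancestral_decay`` with a small per-locus jitter), randomly
    assigned to allele sizes, so every locus starts with near-identical
    gene diversity — variation between loci and demes then comes from
    drift, migration and mutation rather than from the ancestral draw.
    Allele sizes are spaced contiguously from a per-locus base repeat
    count; the private pool for an outlier deme occupies a disjoint range.
    """
    shared = []
    private = []
    k0 = config.alleles_per_locus
    for _ in range(config.n_loci):
        base = int(rng.integers(8, 25))
        sizes = np.arange(base, base + k0)
        r = config.ancestral_decay + rng.uniform(
            -config.ancestral_decay_jitter, config.ancestral_decay_jitter
        )
        freqs = r ** np.arange(k0)
        freqs = freqs / freqs.sum()
        rng.shuffle(freqs)
        shared.append((sizes, freqs))
        ke = config.outlier_extra_alleles
        priv_sizes = np.arange(base + k0 + 10, base + k0 + 10 + ke)
        priv_freqs = rng.dirichlet(np.full(ke, 1.0)) if ke else np.empty(0)
        private.append((priv_sizes, priv_freqs))
    return shared, private


def _draw_copies(pool, n: int, rng: np.random.Generator) -> np.ndarray:
    sizes, freqs = pool
    return rng.choice(sizes, size=n, p=freqs)


def simulate_panel(
    config: SimulationConfig,
    network: VectorNetwork,
    return_details: bool = False,
):
    """Forward Wright–Fisher simulation under vector-proportional migration.

    Each generation every newborn in deme j is an immigrant with
    probability ``migration_scale``; its source deme i is drawn with
    probability proportional to the inbound edge weight weights(i, j).
    Reproduction is partial selfing (prob ``selfing_rate`` the two gametes
    come from one parent). Returns a :class:`GenotypePanel` sampled without
    replacement at the configured per-site sizes; with ``return_details``
    also returns a dict with the realized migrant-count matrix and the
    per-locus allele pools.
    """
    rng = np.random.default_rng(config.seed)
    demes = list(dict.fromkeys(config.site_to_deme.values())) if config.site_to_deme \
        else list(network.labels[: config.n_demes])
    if len(demes) != config.n_demes:
        raise ValueError(
            f"site_to_deme implies {len(demes)} demes, config says {config.n_demes}"
        )
    missing = [d for d in demes if d not in network.labels]
    if missing:
        raise ValueError(f"demes absent from network: {missing}")
    if config.outlier_deme is not None and config.outlier_deme not in demes:
        raise ValueError(f"outlier deme {config.outlier_deme!r} not among demes")

    # per-deme sampling demand
    demand = {d: 0 for d in demes}
    for site, n in config.sample_sizes.items():
        demand[config.site_to_deme[site]] += int(n)
    for d, tot in demand.items():
        if tot > config.deme_size:
            raise ValueError(
                f"deme {d!r}: requested {tot} samples > deme_size {config.deme_size}"
            )

    shared_pools, private_pools = _ancestral_pools(config, rng)
    L = config.n_loci
    N = config.deme_size
    F = config.founder_size

    # founders: independent gene copies from the ancestral pool(s)
    state: dict[str, np.ndarray] = {}
    for d in demes:
        geno = np.empty((F, L, 2), dtype=np.int64)
        for j in range(L):
            if d == config.outlier_deme:
                n_copies = 2 * F
                from_priv = rng.random(n_copies) < config.outlier_pool_fraction
                copies = np.empty(n_copies, dtype=np.int64)
                n_priv = int(from_priv.sum())
                if n_priv:
                    copies[from_priv] = _draw_copies(private_pools[j], n_priv, rng)
                copies[~from_priv] = _draw_copies(
                    shared_pools[j], n_copies - n_priv, rng
                )
            else:
                copies = _draw_copies(shared_pools[j], 2 * F, rng)
            geno[:, j, :] = copies.reshape(F, 2)
        state[d] = geno

    w_in = {}  # inbound weight vectors over source demes, diagonal removed
    for d in demes:
        j = network.labels.index(d)
        w = np.array([network.weights[network.labels.index(s), j] for s in demes])
        w[demes.index(d)] = 0.0
        w_in[d] = w

    realized = np.zeros((len(demes), len(demes)))

    for t in range(config.generations):
        m = (
            config.migration_scale
            if t >= config.migration_onset
            else config.migration_baseline
        )
        new_state: dict[str, np.ndarray] = {}
        for d in demes:
            dj = demes.index(d)
            w = w_in[d]
            wsum = w.sum()
            # source deme of each newborn
            if m > 0 and wsum > 0:
                probs = m * w / wsum
                p_full = probs.copy()
                p_full[dj] = 1.0 - probs.sum()
                src = rng.choice(len(demes), size=N, p=p_full)
            else:
                src = np.full(N, dj)
            children = np.empty((N, L, 2), dtype=np.int64)
            for s_idx in np.unique(src):
                sel = np.flatnonzero(src == s_idx)
                k = sel.size
                if s_idx != dj:
                    realized[s_idx, dj] += k
                parents_pool = state[demes[s_idx]]
                np_pool = parents_pool.shape[0]
                p1 = rng.integers(0, np_pool, size=k)
                p2 = rng.integers(0, np_pool, size=k)
                selfed = rng.random(k) < config.selfing_rate
                p2[selfed] = p1[selfed]
                g1 = rng.integers(0, 2, size=(k, L))
                g2 = rng.integers(0, 2, size=(k, L))
                lo = np.arange(L)
                children[sel, :, 0] = parents_pool[p1[:, None], lo[None, :], g1]
                children[sel, :, 1] = parents_pool[p2[:, None], lo[None, :], g2]
            # TPM mutation per gamete copy
            if config.mutation_rate > 0:
                mut = rng.random(children.shape) < config.mutation_rate
                n_mut = int(mut.sum())
                if n_mut:
                    steps = tpm_steps(
                        n_mut, config.p_multistep, config.multistep_variance, rng
                    )
                    children[mut] = _reflect_floor(children[mut] + steps)
            new_state[d] = children
        state = new_state

    # sampling without replacement; sites sharing a deme draw disjoint sets
    individuals, sites, clusters = [], [], []
    geno_rows = []
    available = {d: rng.permutation(N) for d in demes}
    cursor = {d: 0 for d in demes}
    for site, n in config.sample_sizes.items():
        d = config.site_to_deme[site]
        take = available[d][cursor[d] : cursor[d] + int(n)]
        cursor[d] += int(n)
        for i, row in enumerate(take, start=1):
            individuals.append(f"{site}_{i:03d}")
            sites.append(site)
            clusters.append(d)
            geno_rows.append(state[d][row])
    panel = GenotypePanel(
        individuals,
        np.array(sites, dtype=object),
        [f"L{j+1:02d}" for j in range(L)],
        np.stack(geno_rows) if geno_rows else np.empty((0, L, 2), dtype=np.int64),
        np.array(clusters, dtype=object),
    )
    if return_details:
        details = {
            "realized_migrants": SquareMatrix(demes, realized),
            "shared_pools": shared_pools,
            "private_pools": private_pools,
            "demes": demes,
        }
        return panel, details
    return panel
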