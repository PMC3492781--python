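"""Heterozygosity-excess bottleneck test components."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata, wilcoxon

from vectorpop.bottleneck import (
    _simulate_locus,
    bottleneck_test,
    equilibrium_h_distribution,
    mode_shift,
    wilcoxon_het_excess,
)
from vectorpop.popgen import AlleleFrequencyTable, allele_counts

from .conftest import make_panel


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank with exact tails
# ---------------------------------------------------------------------------
def test_all_positive_five_loci():
    obs = [0.6, 0.7, 0.55, 0.8, 0.65]
    eq = [0.5, 0.6, 0.5, 0.7, 0.6]
    assert wilcoxon_het_excess(obs, eq, "excess") == pytest.approx(1 / 32)


def test_symmetric_signs_two_sided_p1():
    obs = [0.6, 0.4]
    eq = [0.5, 0.5]
    assert wilcoxon_het_excess(obs, eq, "two-sided") == pytest.approx(1.0)


def _brute_force_p(diffs, w_obs, upper=True):
    """Enumerate all 2^L sign patterns of |d| ranks."""
    ranks = rankdata(np.abs(diffs))
    count = 0
    total = 0
    for signs in itertools.product([0, 1], repeat=len(ranks)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        if (w >= w_obs - 1e-12) if upper else (w <= w_obs + 1e-12):
            count += 1
    return count / total


@pytest.mark.parametrize(
    "diffs",
    [
        [0.1, 0.2, 0.3, 0.4, 0.5, -0.6],  # signed ranks (+1..+5, -6)
        [0.05, -0.02, 0.07, 0.01, -0.09, 0.03, 0.08],
        [0.1, 0.1, -0.2, 0.3, -0.1],  # ties in |d|
    ],
)
def test_exact_p_matches_sign_enumeration(diffs):
    diffs = np.asarray(diffs)
    obs = 0.5 + diffs
    eq = np.full_like(diffs, 0.5)
    ranks = rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    assert wilcoxon_het_excess(obs, eq, "excess") == pytest.approx(
        _brute_force_p(diffs, w_obs, upper=True)
    )
    assert wilcoxon_het_excess(obs, eq, "deficit") == pytest.approx(
        _brute_force_p(diffs, w_obs, upper=False)
    )


def test_exact_p_matches_scipy_without_ties():
    rng = np.random.default_rng(0)
    d = rng.normal(size=12)
    obs = 0.5 + d
    eq = np.full(12, 0.5)
    ours = wilcoxon_het_excess(obs, eq, "excess")
    ref = wilcoxon(d, alternative="greater", mode="exact").pvalue
    assert ours == pytest.approx(ref)


def test_all_zero_differences_warns(caplog):
    assert wilcoxon_het_excess([0.5, 0.5], [0.5, 0.5], "excess") == 1.0


def test_normal_approximation_large_panels():
    rng = np.random.default_rng(1)
    d = rng.normal(0.02, 0.05, size=30)
    obs, eq = 0.5 + d, np.full(30, 0.5)
    ours = wilcoxon_het_excess(obs, eq, "excess")
    ref = wilcoxon(d, alternative="greater", mode="approx", correction=True).pvalue
    assert ours == pytest.approx(ref, abs=0.02)


# ---------------------------------------------------------------------------
# equilibrium distribution
# ---------------------------------------------------------------------------
def test_equilibrium_deterministic_under_seed():
    a = equilibrium_h_distribution(40, 5, (0.10, 12.0), n_sims=150, seed=3)
    b = equilibrium_h_distribution(40, 5, (0.10, 12.0), n_sims=150, seed=3)
    assert a[0] == b[0] and a[1] == b[1]


def test_equilibrium_saturation_limit():
    # k_obs near n: all lineages distinct -> H near its maximum
    mean, sd, samples = equilibrium_h_distribution(
        12, 11, (0.10, 12.0), n_sims=100, seed=4
    )
    assert mean > 0.9
    assert (samples <= 1.0 + 1e-9).all()


def test_smm_closed_form_tracks_simulated_mean():
    """Pure SMM: E[H] = 1 - 1/sqrt(1 + 2 theta)."""
    rng = np.random.default_rng(5)
    for theta in (0.5, 2.0, 5.0):
        hs = [_simulate_locus(80, theta, 0.0, 12.0, rng)[1] for _ in range(1500)]
        assert np.mean(hs) == pytest.approx(
            1 - 1 / np.sqrt(1 + 2 * theta), abs=0.02
        )


def test_smm_cross_check_against_msprime():
    """Independent genealogy engine: msprime coalescent + its stepwise
    microsatellite mutation model should give the same mean H.

    One microsatellite = one site of a length-1 genome whose state steps
    under msprime's SMM. With ploidy 1 and population size 1 the pairwise
    coalescence time is 1, so a per-site rate of theta/2 reproduces the
    standard theta = 4 N mu scaling of the hand-rolled coalescent.
    """
    msprime = pytest.importorskip("msprime")
    theta = 2.0
    n = 60
    hs = []
    for rep in range(150):
        ts = msprime.sim_ancestry(
            samples=n, ploidy=1, population_size=1.0, sequence_length=1,
            random_seed=rep + 1,
        )
        mts = msprime.sim_mutations(
            ts, rate=theta / 2, model=msprime.SMM(lo=1, hi=100),
            random_seed=rep + 1000,
        )
        if mts.num_sites == 0:
            counts = np.array([n])
        else:
            var = next(mts.variants())
            states = np.array([int(var.alleles[g]) for g in var.genotypes])
            _, counts = np.unique(states, return_counts=True)
        p = counts / counts.sum()
        hs.append((n / (n - 1)) * (1 - (p**2).sum()))
    rng = np.random.default_rng(6)
    ours = [_simulate_locus(n, theta, 0.0, 12.0, rng)[1] for _ in range(1000)]
    assert np.mean(hs) == pytest.approx(np.mean(ours), abs=0.04)


def test_dh_standardization_centered():
    """Mean DH over equilibrium replicates is near 0 when scored against
    the conditional null (a small negative residual remains because the
    theta-averaged null sits slightly above the fixed-theta conditional
    mean — the reason the signed-rank test centres on the pseudo-median
    instead; see pseudomedian)."""
    rng = np.random.default_rng(7)
    n = 60
    dhs = []
    for _ in range(300):
        k, h = _simulate_locus(n, 1.5, 0.10, 12.0, rng)
        if k < 2:
            continue
        mean, sd, _ = equilibrium_h_distribution(
            n, k, (0.10, 12.0), n_sims=200, seed=100 + k
        )
        if sd > 0:
            dhs.append((h - mean) / sd)
    assert abs(np.mean(dhs)) < 0.25


def test_invalid_inputs():
    with pytest.raises(ValueError):
        equilibrium_h_distribution(10, 1, n_sims=100, seed=0)
    with pytest.raises(ValueError):
        equilibrium_h_distribution(10, 4, n_sims=10, seed=0)


# ---------------------------------------------------------------------------
# mode shift
# ---------------------------------------------------------------------------
def _table_from_freqs(freq_lists):
    table = AlleleFrequencyTable(["g"], [f"L{i}" for i in range(len(freq_lists))])
    for i, freqs in enumerate(freq_lists):
        # represent frequencies as counts over 1000 copies
        table.counts[("g", f"L{i}")] = {
            j: int(round(f * 1000)) for j, f in enumerate(freqs)
        }
    return table


def test_l_shape_detected():
    freqs = [[0.02, 0.03, 0.05, 0.9], [0.01, 0.04, 0.95]]
    shifted, hist = mode_shift(_table_from_freqs(freqs), "g")
    assert not shifted
    assert hist[0] == 5
    assert hist.sum() == 7


def test_mode_shift_when_rare_classes_empty():
    freqs = [[0.5, 0.5], [0.45, 0.55]]
    shifted, hist = mode_shift(_table_from_freqs(freqs), "g")
    assert shifted
    assert hist[0] == 0


def test_founder_event_causes_mode_shift_majority():
    """Severe founder events empty the rare-allele class in most replicates."""
    from vectorpop.synthio import SimulationConfig, VectorNetwork, simulate_panel

    shifted_count = 0
    reps = 10
    for seed in range(reps):
        cfg = SimulationConfig(
            n_demes=1, n_loci=10, alleles_per_locus=6, generations=3,
            founder_size=3, deme_size=50, migration_scale=0.0,
            selfing_rate=0.0, mutation_rate=0.0, ancestral_decay=0.6,
            sample_sizes={"d": 40}, site_to_deme={"d": "d"}, seed=500 + seed,
        )
        panel = simulate_panel(cfg, VectorNetwork(["d"], np.zeros((1, 1))))
        table = allele_counts(panel, by="site")
        shifted, _ = mode_shift(table, "d")
        shifted_count += int(shifted)
    assert shifted_count > reps / 2


# ---------------------------------------------------------------------------
# per-cluster driver
# ---------------------------------------------------------------------------
def test_bottleneck_test_report_structure():
    rng = np.random.default_rng(8)
    geno = rng.integers(10, 16, size=(30, 6, 2))
    panel = make_panel(geno, sites=["g"] * 30)
    table = allele_counts(panel, by="site")
    res = bottleneck_test(table, "g", n_sims=120, seed=9)
    assert 0 < res.p_excess <= 1
    assert 0 < res.p_deficit <= 1
    assert 0 < res.p_two_sided <= 1
    assert res.histogram.sum() == sum(
        len(table.counts[("g", loc)]) for loc in table.loci
    )
    assert {"locus", "H_obs", "H_eq_mean", "DH"} <= set(res.per_locus.columns)


def test_bottleneck_test_needs_polymorphic_loci():
    panel = make_panel([[(1, 1)], [(1, 1)], [(1, 1)], [(1, 1)]], sites=["g"] * 4)
    table = allele_counts(panel, by="site")
    with pytest.raises(ValueError, match="polymorphic"):
        bottleneck_test(table, "g", n_sims=120, seed=0)
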