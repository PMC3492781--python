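"""Diversity and differentiation statistics against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vectorpop.popgen import (
    allele_counts,
    allelic_richness,
    diversity_summary,
    expected_heterozygosity,
    f_is,
    pairwise_fst,
    private_alleles,
    theta_pair,
)

from .conftest import make_panel


# ---------------------------------------------------------------------------
# allele counts
# ---------------------------------------------------------------------------
def test_allele_counts_direct_and_missing():
    panel = make_panel(
        [[(1, 1), (3, 4)], [(1, 2), (0, 0)]],
        sites=["s", "s"],
    )
    table = allele_counts(panel, by="site")
    assert table.counts[("s", "L1")] == {1: 3, 2: 1}
    # missing genotype contributes nothing at that locus
    assert table.counts[("s", "L2")] == {3: 1, 4: 1}
    assert table.n_copies("s", "L1") == 4
    assert table.n_copies("s", "L2") == 2


def test_allele_counts_additive_over_groups():
    rng = np.random.default_rng(0)
    geno = rng.integers(1, 5, size=(12, 3, 2))
    panel = make_panel(geno, sites=["a"] * 4 + ["b"] * 4 + ["c"] * 4)
    split = allele_counts(panel, by="site")
    pooled = split.pooled()
    single = allele_counts(
        make_panel(geno, sites=["all"] * 12), by="site"
    )
    for locus in panel.loci:
        assert pooled.counts[("_all", locus)] == single.counts[("all", locus)]


# ---------------------------------------------------------------------------
# expected heterozygosity
# ---------------------------------------------------------------------------
def test_he_matches_pairwise_oracle():
    # oracle: fraction of unordered gene-copy pairs that differ
    counts = {1: 3, 2: 1}
    copies = [1, 1, 1, 2]
    pairs = list(itertools.combinations(copies, 2))
    oracle = sum(a != b for a, b in pairs) / len(pairs)
    assert expected_heterozygosity(counts) == pytest.approx(oracle)
    assert oracle == pytest.approx(0.5)


@pytest.mark.parametrize(
    "counts, expected",
    [
        ({5: 12}, 0.0),  # monomorphic
        ({1: 1}, float("nan")),  # n < 2 undefined
    ],
)
def test_he_degenerate(counts, expected):
    got = expected_heterozygosity(counts)
    if math.isnan(expected):
        assert math.isnan(got)
    else:
        assert got == pytest.approx(expected)


def test_he_large_sample_limit():
    assert expected_heterozygosity({1: 50_000, 2: 50_000}) == pytest.approx(
        0.5, abs=1e-4
    )


@given(
    st.lists(st.integers(min_value=1, max_value=30), min_size=1, max_size=6),
    st.integers(min_value=-5, max_value=5),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_he_invariant_under_allele_translation(raw_counts, shift):
    counts = {10 + i: c for i, c in enumerate(raw_counts)}
    shifted = {a + shift for a in counts}
    if len(shifted) == len(counts):
        translated = {a + shift: c for a, c in counts.items()}
        a = expected_heterozygosity(counts)
        b = expected_heterozygosity(translated)
        if math.isnan(a):
            assert math.isnan(b)
        else:
            assert a == pytest.approx(b)


# ---------------------------------------------------------------------------
# allelic richness
# ---------------------------------------------------------------------------
def _richness_by_enumeration(counts, g):
    """Oracle: average distinct-allele count over all C(n, g) subsets."""
    copies = [a for a, c in counts.items() for _ in range(c)]
    subsets = list(itertools.combinations(range(len(copies)), g))
    total = sum(len({copies[i] for i in sub}) for sub in subsets)
    return total / len(subsets)


@pytest.mark.parametrize(
    "counts, g",
    [({1: 6, 2: 2}, 2), ({1: 4, 2: 3, 3: 2}, 4), ({1: 5, 2: 5}, 3)],
)
def test_richness_matches_subset_enumeration(counts, g):
    assert allelic_richness(counts, g) == pytest.approx(
        _richness_by_enumeration(counts, g)
    )


def test_richness_frozen_example():
    # {A: 6, B: 2}, g = 2 -> 27/28 + 13/28 = 10/7
    assert allelic_richness({1: 6, 2: 2}, 2) == pytest.approx(10 / 7)


def test_richness_boundaries():
    counts = {1: 4, 2: 3, 3: 1}
    assert allelic_richness(counts, sum(counts.values())) == len(counts)
    assert allelic_richness(counts, 1) == pytest.approx(1.0)
    assert math.isnan(allelic_richness(counts, 99))


@given(st.lists(st.integers(min_value=1, max_value=8), min_size=2, max_size=5))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_richness_nondecreasing_in_g(raw_counts):
    counts = {i: c for i, c in enumerate(raw_counts)}
    n = sum(counts.values())
    values = [allelic_richness(counts, g) for g in range(1, n + 1)]
    assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
    assert values[-1] == len(counts)


# ---------------------------------------------------------------------------
# F_IS
# ---------------------------------------------------------------------------
def test_fis_sign_checks():
    # all heterozygous -> maximal heterozygote excess
    het = make_panel([[(1, 2)]] * 8, sites=["p"] * 8)
    assert f_is(het, "p", by="site") == pytest.approx(-1.0)
    # no heterozygotes with two alleles present -> complete fixation
    hom = make_panel([[(1, 1)]] * 4 + [[(2, 2)]] * 4, sites=["p"] * 8)
    assert f_is(hom, "p", by="site") == pytest.approx(1.0)


def test_fis_selfing_equilibrium():
    """Simulated selfing at rate s gives F_IS ~ s/(2-s)."""
    from vectorpop.synthio import SimulationConfig, VectorNetwork, simulate_panel

    s = 0.4
    config = SimulationConfig(
        n_demes=1, n_loci=12, alleles_per_locus=6, generations=30,
        founder_size=500, deme_size=500, migration_scale=0.0,
        selfing_rate=s, mutation_rate=0.0, ancestral_decay=0.7,
        sample_sizes={"d": 400}, site_to_deme={"d": "d"}, seed=11,
    )
    net = VectorNetwork(["d"], np.zeros((1, 1)))
    panel = simulate_panel(config, net)
    expected = s / (2 - s)
    assert f_is(panel, "d", by="site") == pytest.approx(expected, abs=0.06)


def test_fis_zero_without_selfing():
    from vectorpop.synthio import SimulationConfig, VectorNetwork, simulate_panel

    config = SimulationConfig(
        n_demes=1, n_loci=12, alleles_per_locus=6, generations=30,
        founder_size=500, deme_size=500, migration_scale=0.0,
        selfing_rate=0.0, mutation_rate=0.0, ancestral_decay=0.7,
        sample_sizes={"d": 400}, site_to_deme={"d": "d"}, seed=12,
    )
    net = VectorNetwork(["d"], np.zeros((1, 1)))
    panel = simulate_panel(config, net)
    assert abs(f_is(panel, "d", by="site")) < 0.05


# ---------------------------------------------------------------------------
# pairwise F_ST
# ---------------------------------------------------------------------------
def _wc_theta_oracle(panel, ga, gb):
    """Independent step-by-step Weir-Cockerham variance components."""
    idx = panel.group_indices("site")
    sum_a = sum_bc = 0.0
    r = 2
    for j in range(panel.n_loci):
        sub = {}
        for g in (ga, gb):
            geno = panel.genotypes[idx[g], j, :]
            typed = (geno != 0).all(axis=1)
            sub[g] = geno[typed]
        n1, n2 = len(sub[ga]), len(sub[gb])
        alleles = sorted(set(sub[ga].ravel()) | set(sub[gb].ravel()))
        if len(alleles) < 2:
            continue
        n_bar = (n1 + n2) / 2
        n_c = (2 * n_bar - (n1**2 + n2**2) / (2 * n_bar)) / (r - 1)
        for al in alleles:
            p1 = (sub[ga] == al).sum() / (2 * n1)
            p2 = (sub[gb] == al).sum() / (2 * n2)
            h1 = ((sub[ga] == al).sum(axis=1) == 1).mean()
            h2 = ((sub[gb] == al).sum(axis=1) == 1).mean()
            p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
            s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / n_bar
            h_bar = (n1 * h1 + n2 * h2) / (n1 + n2)
            a = (n_bar / n_c) * (
                s2 - (p_bar * (1 - p_bar) - s2 / 2 - h_bar / 4) / (n_bar - 1)
            )
            b = (n_bar / (n_bar - 1)) * (
                p_bar * (1 - p_bar) - s2 / 2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
            )
            c = h_bar / 2
            sum_a += a
            sum_bc += a + b + c
    return sum_a / sum_bc


def test_theta_matches_hand_computation(two_cluster_toy):
    expected = _wc_theta_oracle(two_cluster_toy, "A", "B")
    got = theta_pair(two_cluster_toy, "A", "B", by="site")
    assert got == pytest.approx(expected)


def test_theta_complete_differentiation():
    panel = make_panel(
        [[(1, 1), (3, 3)]] * 4 + [[(2, 2), (4, 4)]] * 4,
        sites=["A"] * 4 + ["B"] * 4,
    )
    assert theta_pair(panel, "A", "B", by="site") == pytest.approx(1.0)


def test_theta_null_case_two_samples_one_deme():
    from vectorpop.synthio import SimulationConfig, VectorNetwork, simulate_panel

    thetas = []
    for seed in range(6):
        config = SimulationConfig(
            n_demes=1, n_loci=10, alleles_per_locus=5, generations=10,
            founder_size=300, deme_size=300, migration_scale=0.0,
            selfing_rate=0.0, mutation_rate=0.0,
            sample_sizes={"x": 50, "y": 50},
            site_to_deme={"x": "d", "y": "d"}, seed=100 + seed,
        )
        net = VectorNetwork(["d"], np.zeros((1, 1)))
        panel = simulate_panel(config, net)
        thetas.append(theta_pair(panel, "x", "y", by="site"))
    thetas = np.array(thetas)
    assert abs(thetas.mean()) < 3 * thetas.std(ddof=1) / np.sqrt(len(thetas)) + 0.01


def test_pairwise_fst_matrix_properties(two_cluster_toy):
    m = pairwise_fst(two_cluster_toy, by="site")
    assert m.symmetric
    assert np.all(np.diag(m.values) == 0)
    truncated = pairwise_fst(two_cluster_toy, by="site", truncate_at_zero=True)
    assert (truncated.values >= 0).all()


def test_fst_invariant_under_allele_relabeling():
    rng = np.random.default_rng(3)
    geno = rng.integers(1, 5, size=(20, 4, 2))
    sites = ["A"] * 10 + ["B"] * 10
    panel = make_panel(geno, sites=sites)
    relabeled = make_panel(10 - geno, sites=sites)  # bijective allele map
    a = theta_pair(panel, "A", "B", by="site")
    b = theta_pair(relabeled, "A", "B", by="site")
    assert a == pytest.approx(b)


def test_statistics_invariant_under_individual_reordering():
    rng = np.random.default_rng(4)
    geno = rng.integers(1, 6, size=(16, 3, 2))
    sites = ["A"] * 8 + ["B"] * 8
    panel = make_panel(geno, sites=sites)
    perm = rng.permutation(16)
    shuffled = panel.subset(perm)
    a = diversity_summary(panel, by="site")
    b = diversity_summary(shuffled, by="site")
    for col in ("N_A", "H_E", "F_IS"):
        assert np.allclose(
            a[col].sort_index().to_numpy(), b[col].sort_index().to_numpy(),
            equal_nan=True,
        )


# ---------------------------------------------------------------------------
# private alleles
# ---------------------------------------------------------------------------
def test_private_alleles_counting():
    panel = make_panel(
        [[(1, 2)], [(1, 1)], [(1, 3)], [(3, 3)]],
        sites=["A", "A", "B", "B"],
    )
    table = allele_counts(panel, by="site")
    props, detail = private_alleles(table)
    # alleles: 1 shared, 2 private to A, 3 private to B -> 1/3 each
    assert props["A"] == pytest.approx(1 / 3)
    assert props["B"] == pytest.approx(1 / 3)
    assert set(detail["allele"]) == {2, 3}


def test_private_alleles_monomorphic():
    panel = make_panel([[(1, 1)], [(1, 1)]], sites=["A", "B"])
    props, detail = private_alleles(allele_counts(panel, by="site"))
    assert (props == 0).all()
    assert detail.empty


def test_outlier_deme_has_top_private_proportion():
    from vectorpop.experiments import OUTLIER, simulate_study

    sim = simulate_study(0, scenario="vector_outlier")
    table = allele_counts(sim["panel"], by="cluster")
    props, _ = private_alleles(table)
    assert props.idxmax() == OUTLIER
    # direct set comparison on the simulated pools: at every locus the
    # outlier's private founder alleles are disjoint from the shared pool
    for (sh_sizes, _), (pr_sizes, _) in zip(
        sim["details"]["shared_pools"], sim["details"]["private_pools"]
    ):
        assert set(sh_sizes).isdisjoint(pr_sizes)


def test_diversity_summary_rarefaction_bound():
    from vectorpop.experiments import simulate_study

    summary = diversity_summary(
        simulate_study(0)["panel"], by="cluster", rarefaction_copies=36
    )
    assert (summary["A_R"] <= summary["N_A"] + 1e-9).all()
    assert summary["H_E"].between(0, 1).all()
    assert summary["F_IS"].between(-1, 1).all()
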