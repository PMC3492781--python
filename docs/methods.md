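# Methods

`vectorpop` implements the inference chain used to ask whether directional
commercial-vessel traffic predicts the population-genetic connectivity of a
recently spread marine invertebrate: microsatellite diversity statistics,
Bayesian clustering with delta-K model choice, assignment-based directional
migration, heterozygosity-excess bottleneck tests, and rank-based Mantel
correlations between (possibly asymmetric) connectivity matrices. Because
the field collections this kind of study rests on are rarely deposited, the
package ships a forward simulator that generates study systems with a known
vector-driven truth; every statistical claim the package makes is validated
against that truth or against exact enumeration oracles.

## The synthetic study system

**Demography.** Each of 8 clusters is one Wright–Fisher deme of `deme_size`
(default 140) diploids with non-overlapping generations, founded by
`founder_size` (35) individuals whose gene copies are drawn i.i.d. from a
shared ancestral allele pool, and run for `generations` (65) generations.
Partial selfing at rate *s* (`selfing_rate`, 0.4) produces the heterozygote
deficits ubiquitous in tunicate microsatellite data; at equilibrium
F_IS ≈ s/(2−s) = 0.25, which the simulator reproduces (property-tested at
deme size 500). Sites are not simulated separately: sites sharing a cluster
are disjoint subsamples of one deme, drawn without replacement at the
configured per-site sizes (13 sites, n = 18–58, matching the study design).

**Ancestral variation.** Per locus, `alleles_per_locus` (5) allele sizes on
the repeat-count scale carry a geometric frequency profile p_i ∝ r^i with
r = `ancestral_decay` (0.445) plus a small per-locus jitter (±0.05),
randomly permuted across sizes. A fixed profile (rather than a Dirichlet
draw) keeps every locus's starting gene diversity nearly equal, so
between-locus and between-deme variance reflects drift, migration and
mutation rather than the ancestral lottery.

**Mutation.** Two-phase model: with probability 1 − `p_multistep` (0.90) a
mutation steps ±1 repeat; otherwise the magnitude is 1 + Geometric(q) with
q solved so the step variance equals `multistep_variance` (12, a common
convention for the two-phase model's variance parameter; the smallest
attainable variance under this law is 4). Allele sizes reflect at a floor
of 1. The same TPM parameterization is shared with the bottleneck null so
the data generator and the test assume the same mutation process. Default
rate 5 × 10⁻⁴ per locus per generation, mid-range for microsatellites.

**Migration.** Each newborn in deme *j* immigrates with probability *m*,
and its source *i* is drawn proportionally to the inbound edge weights
w(i, j) of the directed vessel-transit network. Two extra schedule knobs
encode the invasion timeline: `migration_baseline` (0) applies before
`migration_onset` (62) and `migration_scale` (0.20) after. The default is
therefore a *recent pulse*: demes diverge in isolation for 62 generations
and exchange vector-driven migrants only in the last 3. This mirrors the
biology (colonization and divergence long before the modern traffic data
were collected) and is also what makes the inference problem well-posed:
with strong vector-proportional migration active from generation 0, drift
and migration equilibrate to near-zero differentiation and no
assignment-based method can recover the network, while with no recent
migration there is nothing to recover. The pulse leaves median pairwise
theta ≈ 0.05–0.08 with first-generation migrants still present in the
sample.

**The outlier deme.** One cluster ("PS") can be founded from a pool whose
gene copies come, with probability `outlier_pool_fraction` (0.10), from
`outlier_extra_alleles` (3) private alleles per locus occupying a disjoint
allele-size range. In the `vector_outlier` scenario the migration edges
touching PS are zeroed while the shipping matrix keeps them: an
independent introduction whose vessel connectivity is not expressed as
gene flow. Typical realized private-allele proportion is 0.08–0.17
(the study system this emulates reported 8.2%).

**The shipping network.** A fixed 8×8 directed matrix (scaled to 32,000
annual transits) with a southern hub (LA) dominating most inbound columns
and a strong LA→PS edge, plus `generate_vector_network` for random
log-normal networks with a tunable asymmetry. Each recipient column of the
fixed network has one clearly dominant inbound source (≥ ~2× the
runner-up) so that "the strongest edge into j" is a well-defined truth for
recovery experiments. Alongshore geography is a 1-D coastline coordinate
per cluster; distance is the absolute coordinate difference.

**What the generator does not emulate.** Null alleles and genotyping error
(heterozygote deficit is produced only by selfing), overlapping
generations and age structure, larval dispersal or any oceanographic
connectivity, recreational-boating and aquaculture vectors, and
within-cluster site structure (sites within a cluster are exchangeable by
construction — the study found no within-cluster differentiation, but real
sites could differ). Passing tests therefore show the chain recovers a
vector-driven truth under these idealizations, not that any particular
empirical dataset satisfies them.

## Statistics

**Diversity.** Allele counts are gene copies with locus-wise exclusion of
missing genotypes. H_E is Nei's unbiased gene diversity
(n/(n−1))(1 − Σp²) (the source tables do not state which variant they
print; unbiased is the common default of the standard tools). Allelic
richness uses hypergeometric rarefaction A_R(g) = Σ_j [1 − C(n−n_j, g)/C(n, g)]
with g = 36 gene copies ("18 individuals" on the diploid scale); loci with
fewer than g copies are excluded with a warning. F_IS and pairwise F_ST
are Weir & Cockerham (1984) estimators combined over alleles and loci by
ratio of sums; negative estimates are retained by default (a
truncate-at-zero switch exists) so matrix tests see an unbiased scale.
Private alleles are counted against the total distinct alleles in the
dataset.

**Clustering.** A no-admixture, uncorrelated-frequency Gibbs sampler:
latent per-individual labels, Dirichlet(1) priors on cluster-by-locus
allele frequencies, Hardy–Weinberg genotype likelihoods, blocked updates
(all labels given frequencies, then frequencies given labels — a valid
two-block sampler that vectorizes). ln P(X|K) is estimated as
mean − var/2 of the post-burn-in data log-likelihood trace, the quantity
the delta-K procedure expects; delta-K(K) = |L̄(K+1) − 2L̄(K) + L̄(K−1)|/sd(L(K))
over replicate runs, selected K = argmax. Label switching across replicate
runs is repaired by greedy maximum-overlap matching. This is deliberately
simpler than the full admixture/correlated-frequency model; it suffices
for discrete, well-differentiated clusters, and equivalence with richer
samplers is not claimed. Defaults (burn-in 10³, iterations 10⁴) are
desk-scale; the analysis scripts use shorter chains (300/1200–1500), which
on these panels already give stationary traces (trend-tested).

**Assignment.** Rannala–Mountain posterior-predictive likelihoods with a
Dirichlet(1/k) prior, k = the dataset-wide distinct-allele count at the
locus: heterozygote (j1, j2): 2(n_j1 + 1/k)(n_j2 + 1/k)/((n+1)(n+2));
homozygote: (n_j + 1/k)(n_j + 1 + 1/k)/((n+1)(n+2)); missing loci are
skipped and unseen alleles never yield −∞. Leave-one-out removal of the
focal individual's copies from its home cluster is the default (it removes
self-inclusion bias in small samples) and is switchable. The migration
matrix M(source, recipient) is the proportion of the recipient cluster's
individuals whose modal assignment is the source; columns sum to 1, the
diagonal (self-assignment) is kept, and an off-diagonal-only renormalized
variant is available — whether the original analysis counted self-assigned
individuals in the denominator is not documented, so both are computed
(the Mantel stage ignores diagonals either way). Ties are broken by
cluster order and logged.

**Bottleneck tests.** The conditional equilibrium law of heterozygosity
given (n copies, k alleles) is built from Kingman coalescent genealogies
with TPM mutations: a coarse bisection on the mean simulated allele count
centres theta, then rejection sampling keeps genealogies with exactly k
alleles while drawing theta log-uniformly from [theta₀/8, 8·theta₀] at
each attempt. Integrating theta over the bracket (acceptance reweights
draws by P(k|theta)) removes the k-dependent centring bias a plug-in
theta produces. Per-locus standardized differences DH use the conditional
mean and sd, as is conventional; the Wilcoxon signed-rank test, however,
is centred on the Hodges–Lehmann pseudo-median of the accepted samples,
because the signed-rank statistic tests the pseudo-median of the paired
differences and the conditional law of H given k is left-skewed —
mean-centring makes the excess tail anticonservative (measured ~0.08–0.13
at nominal 0.05 versus 0.050–0.055 with pseudo-median centring, 400
equilibrium replicates per seed). Signed-rank tail probabilities are
exact (dynamic-programming enumeration over sign patterns, midranks for
tied |d|) up to 20 informative loci, then a tie-corrected normal
approximation with continuity correction. Excess, deficit and two-sided
p-values are all reported since the original tail choice is not
documented. The mode-shift check pools allele frequencies into ten 0.1
classes; L-shaped means the lowest class is the strict mode. Equilibrium
distributions are memoized per (n, k, TPM) with seeds derived
deterministically from the key.

**Matrix association.** The CADM-style recipe: off-diagonal cells replaced
by midranks, R = Pearson correlation of the rank vectors (a cell-wise
Spearman), null by jointly permuting rows and columns of the second matrix
under random label permutations, P = (#{stat ≥ observed} + 1)/(n_perm + 1).
Asymmetric matrices contribute all n(n−1) directed cells; for symmetric
pairs the duplicated cells leave R unchanged, so the full off-diagonal set
is used uniformly. Permuting either matrix is equivalent
(property-tested). When the full permutation group is small the test
enumerates it exactly. Default 9999 permutations; default tail "greater"
(one-tailed toward positive correlation, the convention implied by
published tables in this literature where strongly negative correlations
print P ≈ 1); similarity matrices are not converted to distances — signs
are interpreted by the user. Exclusion of a label set is applied to both
matrices before ranking and is identical to testing pre-sliced matrices.

## Numerical and interface choices

- Reproducibility: every pipeline stage and experiment derives its RNG
  from a single seed through named `SeedSequence` substreams; identical
  config + seed gives byte-identical outputs (tested).
- GENEPOP I/O: 2- or 3-digit codes, "00"/"000" missing, site label = last
  whitespace token of the individual identifier; parse errors carry line
  numbers. Matrices are labeled TSV; configs are YAML.
- Degenerate inputs: monomorphic loci carry no information (skipped by
  F-statistics, bottleneck tests); < 2 gene copies → NaN sentinel; empty
  clusters raise errors naming the cluster; all-equal off-diagonal cells
  make the Mantel R undefined (error) after a warning at ranking.
- The pipeline runs site clustering from the configured mapping
  (mirroring the original analysis, where clusters came from Bayesian
  structure plus port proximity); the Gibbs-sampler output is advisory.

## Validation problem sizes

The test suite and `scripts/acceptance.py` validate the chain at sizes
chosen to finish in minutes on one CPU: exact-oracle checks at ≤ 10 gene
copies / ≤ 8 loci / 4 labels; Mantel type-I on 500 independent 8×8 pairs
at 199 permutations; bottleneck type-I on 400–500 equilibrium panels
(10 loci, 60 copies, theta 1.5) with memoized nulls and power against a
20-fold recent crash; network recovery and outlier-exclusion experiments
on 40–50 simulated study systems (484 individuals each) at 999
permutations; clustering recovery on a 5-deme system with 3 replicate
chains at K = 1..7 (burn-in 300, 1500 iterations).

## Known limitations

- With 10 loci and the study's per-site sample sizes, the per-cluster
  mean H_E has an irreducible spread (sampling + drift) of ~0.03–0.04
  whenever differentiation is strong enough for assignment tests to work;
  the default panels therefore land only ~4–5 of 8 demes inside the
  narrow published H_E band (0.53–0.59) in a typical run, while the
  allelic-richness band, F_IS range and private-allele structure are
  reproduced. Matching all of them simultaneously appears infeasible at
  this locus count; the corresponding check is left failing rather than
  loosened, and the tension is documented here deliberately.
- The bottleneck null conditions on the observed allele count via a
  theta-integrated rejection sampler; DH values retain a small negative
  mean (~−0.15 sd) under the null, which is why significance rests on the
  pseudo-median-centred signed-rank test rather than on DH.
- The Gibbs sampler has no admixture component: individuals with mixed
  ancestry are forced into one cluster, and delta-K inherits its usual
  inability to evaluate K = 1.
- F_ST-based conclusions assume migration–drift equilibrium that invasion
  systems violate; in the simulations (as in the motivating study) the
  equilibrium measure correlates with geography while only the
  nonequilibrium assignment measure tracks the vector network.
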