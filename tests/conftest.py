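import numpy as np
import pytest

from vectorpop.panel import GenotypePanel


def make_panel(genotypes, sites=None, loci=None, clusters=None):
    """Build a small panel from a nested list [(ind) [(locus) (a1, a2)]]."""
    geno = np.asarray(genotypes, dtype=np.int64)
    n, L = geno.shape[0], geno.shape[1]
    sites = sites if sites is not None else ["s1"] * n
    loci = loci if loci is not None else [f"L{j+1}" for j in range(L)]
    return GenotypePanel(
        [f"ind{i+1}" for i in range(n)],
        np.array(sites, dtype=object),
        loci,
        geno,
        np.array(clusters, dtype=object) if clusters is not None else None,
    )


@pytest.fixture
def two_cluster_toy():
    """Cluster A: A/A, A/A; cluster B: A/B, B/B at a single locus (alleles
    coded 1=A, 2=B)."""
    return make_panel(
        [[(1, 1)], [(1, 1)], [(1, 2)], [(2, 2)]],
        sites=["A", "A", "B", "B"],
    )
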