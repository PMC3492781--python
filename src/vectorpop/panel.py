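"""Core genotype container for diploid microsatellite panels.

Alleles are positive integers on the repeat-number scale; ``0`` is the
missing sentinel (mirroring the "000" code of GENEPOP files). A panel keeps
two levels of grouping: the *site* an individual was sampled at and the
*cluster* the site belongs to (several sites may share one cluster).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

MISSING = 0


@dataclass
class GenotypePanel:
    """Diploid multi-locus genotypes with site and cluster labels.

    Parameters
    ----------
    individuals : sequence of str
        Unique individual identifiers.
    sites : sequence of str
        Per-individual sampling-site label.
    loci : sequence of str
        Ordered locus names.
    genotypes : ndarray of int, shape (n_individuals, n_loci, 2)
        Unordered allele pairs; ``MISSING`` (0) marks an untyped locus
        (both copies are then 0).
    clusters : sequence of str, optional
        Per-individual cluster label; defaults to a copy of ``sites``.
    """

    individuals: list[str]
    sites: np.ndarray
    loci: list[str]
    genotypes: np.ndarray
    clusters: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.individuals = list(self.individuals)
        self.sites = np.asarray(self.sites, dtype=object)
        self.loci = list(self.loci)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        if self.clusters is None:
            self.clusters = self.sites.copy()
        else:
            self.clusters = np.asarray(self.clusters, dtype=object)
        n, L = len(self.individuals), len(self.loci)
        if self.genotypes.shape != (n, L, 2):
            raise ValueError(
                f"genotypes shape {self.genotypes.shape} != ({n}, {L}, 2)"
            )
        if len(self.sites) != n or len(self.clusters) != n:
            raise ValueError("sites/clusters length mismatch with individuals")
        if (self.genotypes < 0).any():
            raise ValueError("allele sizes must be nonnegative (0 = missing)")
        # a genotype is either fully typed or fully missing at a locus
        half_missing = (self.genotypes == MISSING).sum(axis=2) == 1
        if half_missing.any():
            raise ValueError("half-missing genotypes are not representable")

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def labels(self, by: str = "cluster") -> np.ndarray:
        """Per-individual grouping labels (``by`` in {'site', 'cluster'})."""
        if by == "site":
            return self.sites
        if by == "cluster":
            return self.clusters
        raise ValueError(f"unknown grouping {by!r}")

    def group_names(self, by: str = "cluster") -> list[str]:
        """Group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.labels(by):
            seen.setdefault(g, None)
        return list(seen)

    def group_indices(self, by: str = "cluster") -> dict[str, np.ndarray]:
        lab = self.labels(by)
        return {g: np.flatnonzero(lab == g) for g in self.group_names(by)}

    def typed_mask(self) -> np.ndarray:
        """Boolean (n, L): True where the genotype is fully typed."""
        return (self.genotypes != MISSING).all(axis=2)

    # ------------------------------------------------------------------
    def with_cluster_map(self, site_to_cluster: Mapping[str, str]) -> "GenotypePanel":
        """Return a panel whose clusters follow a site->cluster mapping."""
        missing = sorted(set(self.sites) - set(site_to_cluster))
        if missing:
            raise KeyError(f"sites without cluster assignment: {missing}")
        clusters = np.array([site_to_cluster[s] for s in self.sites], dtype=object)
        return GenotypePanel(
            self.individuals, self.sites, self.loci, self.genotypes, clusters
        )

    def subset(self, index: Sequence[int] | np.ndarray) -> "GenotypePanel":
        index = np.asarray(index)
        return GenotypePanel(
            [self.individuals[i] for i in index],
            self.sites[index],
            self.loci,
            self.genotypes[index],
            self.clusters[index],
        )

    def drop_clusters(self, clusters: Sequence[str]) -> "GenotypePanel":
        keep = ~np.isin(self.clusters.astype(str), list(clusters))
        return self.subset(np.flatnonzero(keep))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypePanel):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.loci == other.loci
            and np.array_equal(self.sites, other.sites)
            and np.array_equal(self.clusters, other.clusters)
            and np.array_equal(
                np.sort(self.genotypes, axis=2), np.sort(other.genotypes, axis=2)
            )
        )
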