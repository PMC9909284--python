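"""Diplotype enumeration, combined definitions, Hardy-Weinberg
frequencies, indistinguishable-diplotype detection and cross-population
variability.

A diplotype is an unordered pair of haplotypes of one gene.  Its
*combined definition* maps every locus of the gene's position set to the
unordered pair of alleles the two haplotypes carry there; at a locus a
haplotype does not declare, it contributes the reference base.  Because
short-read genotypes are unphased, two different haplotype pairs whose
combined definitions coincide cannot be told apart from a VCF — these
are the *indistinguishable diplotypes* the frequency ranking exists to
break.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Mapping

import numpy as np

from .model import BIOGEOGRAPHIC_GROUPS, StateError, UsageError
from .kb import FrequencyTable, GeneDefinition

#: locus -> unordered pair of allele strings (sorted tuple of length 2)
CombinedDefinition = Mapping[tuple[str, int], tuple[str, str]]


@dataclass(frozen=True, order=True)
class Diplotype:
    """Unordered pair of haplotype names of one gene."""

    gene: str
    pair: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.pair) != 2:
            raise UsageError("a diplotype is a pair of two haplotypes")
        if list(self.pair) != sorted(self.pair):
            object.__setattr__(self, "pair", tuple(sorted(self.pair)))

    @property
    def label(self) -> str:
        """Canonical ``A/B`` label with A <= B lexicographically."""
        return f"{self.pair[0]}/{self.pair[1]}"

    @property
    def homozygous(self) -> bool:
        return self.pair[0] == self.pair[1]


def enumerate_diplotypes(gene_def: GeneDefinition) -> list[Diplotype]:
    """All H(H+1)/2 unordered haplotype pairs, sorted by canonical label."""
    names = sorted(gene_def.haplotypes)
    dips = [
        Diplotype(gene_def.gene, (a, b))
        for a, b in combinations_with_replacement(names, 2)
    ]
    return sorted(dips, key=lambda d: d.label)


def combined_definition(
    diplotype: Diplotype, gene_def: GeneDefinition
) -> dict[tuple[str, int], tuple[str, str]]:
    """Expected unphased genotype of ``diplotype`` at every gene locus."""
    alleles_of = []
    for name in diplotype.pair:
        if name not in gene_def.haplotypes:
            raise UsageError(
                f"haplotype {name!r} not defined for {gene_def.gene}"
            )
        alleles_of.append(gene_def.haplotypes[name].declared)
    out: dict[tuple[str, int], tuple[str, str]] = {}
    for locus in gene_def.positions:
        ref = gene_def.ref_allele[locus]
        a = alleles_of[0][locus].alt if locus in alleles_of[0] else ref
        b = alleles_of[1][locus].alt if locus in alleles_of[1] else ref
        out[locus] = tuple(sorted((a, b)))
    return out


def declared_loci(
    diplotype: Diplotype, gene_def: GeneDefinition
) -> frozenset[tuple[str, int]]:
    """Loci where at least one constituent haplotype declares a variant."""
    loci: set[tuple[str, int]] = set()
    for name in diplotype.pair:
        loci.update(gene_def.haplotypes[name].declared)
    return frozenset(loci)


def diplotype_frequency(
    diplotype: Diplotype, group: str, freqs: FrequencyTable
) -> float:
    """Hardy-Weinberg expected frequency: p^2 (homozygote) or 2pq."""
    p = freqs.get(diplotype.gene, diplotype.pair[0], group)
    q = freqs.get(diplotype.gene, diplotype.pair[1], group)
    if p is None or q is None:
        raise StateError(
            f"unfilled null frequency for {diplotype.gene} "
            f"{diplotype.label} in {group}; call fill_nulls first"
        )
    return p * p if diplotype.homozygous else 2.0 * p * q


def indistinguishable_groups(
    gene_def: GeneDefinition,
) -> list[list[Diplotype]]:
    """Partition diplotypes by combined definition; keep groups of >= 2.

    Members of a returned group have identical expected unphased
    genotypes at every locus, so no VCF can separate them.
    """
    buckets: dict[tuple, list[Diplotype]] = {}
    for dip in enumerate_diplotypes(gene_def):
        signature = tuple(sorted(combined_definition(dip, gene_def).items()))
        buckets.setdefault(signature, []).append(dip)
    groups = [sorted(g, key=lambda d: d.label)
              for g in buckets.values() if len(g) >= 2]
    return sorted(groups, key=lambda g: g[0].label)


def frequency_cv(diplotype: Diplotype, freqs: FrequencyTable) -> float:
    """Coefficient of variation of the diplotype frequency across the
    nine biogeographic groups.

    Uses the population standard deviation (the nine groups are an
    exhaustive partition, not a sample).  The mean is strictly positive
    once frequencies are epsilon-filled.
    """
    values = np.array([
        diplotype_frequency(diplotype, group, freqs)
        for group in BIOGEOGRAPHIC_GROUPS
    ])
    if values.size < 2:
        raise UsageError("coefficient of variation needs >= 2 groups")
    mean = values.mean()
    if mean == 0:
        raise StateError("zero mean frequency; fill nulls before computing CV")
    return float(values.std(ddof=0) / mean)
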