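"""Shared builders for in-memory genes, frequency tables and genotypes."""
from __future__ import annotations

from typing import Mapping, Optional

import pytest

from pgxcall.kb import (
    AlleleDefinitionTable,
    FrequencyTable,
    GeneDefinition,
    HaplotypeDefinition,
    Knowledgebase,
)
from pgxcall.model import BIOGEOGRAPHIC_GROUPS, VariantKey
from pgxcall.vcf import GenotypeCall, GenotypeSet


def make_gene(
    gene: str,
    haplotypes: Mapping[str, Mapping[tuple[str, int], tuple[str, str]]],
    reference: str = "*1",
) -> GeneDefinition:
    """Build a GeneDefinition from {name: {locus: (ref, alt)}}.

    ``reference`` must map to an empty declared set.
    """
    defs = {}
    positions: set[tuple[str, int]] = set()
    ref_allele: dict[tuple[str, int], str] = {}
    for name, declared_spec in haplotypes.items():
        declared = {}
        for locus, (ref, alt) in declared_spec.items():
            vk = VariantKey(locus[0], locus[1], ref, alt)
            declared[locus] = vk
            positions.add(locus)
            assert ref_allele.setdefault(locus, ref) == ref
        defs[name] = HaplotypeDefinition(
            gene=gene, name=name, declared=declared,
            is_reference=(name == reference),
        )
    return GeneDefinition(
        gene=gene,
        haplotypes=defs,
        positions=tuple(sorted(positions)),
        ref_allele=ref_allele,
        reference_name=reference,
    )


def make_freqs(
    gene: str,
    per_hap: Mapping[str, float | Mapping[str, Optional[float]]],
    fill: bool = True,
) -> FrequencyTable:
    """Frequency table from {hap: value-for-all-groups | {group: value}}."""
    table = FrequencyTable()
    for hap, spec in per_hap.items():
        if isinstance(spec, Mapping):
            row = {g: spec.get(g) for g in BIOGEOGRAPHIC_GROUPS}
        else:
            row = {g: spec for g in BIOGEOGRAPHIC_GROUPS}
        table.set(gene, hap, row)
    return table.fill_nulls() if fill else table


def make_genotypes(
    gene_def: GeneDefinition,
    observed: Mapping[tuple[str, int], tuple[str, str]],
    missing: tuple[tuple[str, int], ...] = (),
    sample: str = "S1",
) -> GenotypeSet:
    """GenotypeSet over the gene's position set.

    Loci absent from ``observed`` and ``missing`` default to homozygous
    reference.
    """
    calls = {}
    for locus in gene_def.positions:
        if locus in missing:
            calls[locus] = GenotypeCall(locus, (), missing=True)
        elif locus in observed:
            calls[locus] = GenotypeCall(
                locus, tuple(sorted(observed[locus])))
        else:
            ref = gene_def.ref_allele[locus]
            calls[locus] = GenotypeCall(locus, (ref, ref))
    return GenotypeSet(sample=sample, calls=calls)


def make_kb(
    genes: list[GeneDefinition],
    freqs: FrequencyTable,
    guidelines=(), annotations=(), single_variant=(), hla=(),
) -> Knowledgebase:
    table = AlleleDefinitionTable()
    for gd in genes:
        table[gd.gene] = gd
    return Knowledgebase(
        alleles=table,
        frequencies=freqs,
        guidelines=list(guidelines),
        annotations=list(annotations),
        single_variant=list(single_variant),
        hla=list(hla),
    )


@pytest.fixture
def toy_gene() -> GeneDefinition:
    """Three haplotypes on two loci: *2 declares v, *3 declares v and w."""
    v = ("chr1", 100)
    w = ("chr1", 200)
    return make_gene("CYPX", {
        "*1": {},
        "*2": {v: ("A", "G")},
        "*3": {v: ("A", "G"), w: ("C", "T")},
    })


@pytest.fixture
def toy_kb(toy_gene) -> Knowledgebase:
    freqs = make_freqs("CYPX", {"*1": 0.7, "*2": 0.2, "*3": 0.1})
    return make_kb([toy_gene], freqs)
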