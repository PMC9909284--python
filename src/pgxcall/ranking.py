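"""Candidate-diplotype scoring and two-step ranking.

Every enumerable diplotype of a gene is a candidate.  Its expected
unphased genotype (combined definition) is compared position by
position with the sample's observed genotypes:

* at a *declared* locus (at least one constituent haplotype declares a
  variant there), a mismatch between the observed and expected allele
  pair disqualifies the candidate outright — the sample simply does not
  carry the alleles the diplotype requires;
* at an *undeclared* locus (expected homozygous reference), a mismatch
  costs a penalty of −1 — the sample carries something the candidate
  does not explain, which argues against it without ruling it out;
* missing loci are skipped entirely and counted, so an uncovered site
  neither penalizes nor disqualifies.

Qualified candidates are ranked first by total penalty (closest to
zero wins), then among the penalty ties by Hardy-Weinberg population
frequency in the sample's biogeographic group.  Residual ties — e.g.
members of one indistinguishable group with equal frequency — are all
returned in canonical order rather than broken arbitrarily.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .model import StateError, validate_group
from .kb import Knowledgebase, GeneDefinition
from .diplotypes import (
    CombinedDefinition,
    Diplotype,
    combined_definition,
    declared_loci,
    diplotype_frequency,
    enumerate_diplotypes,
)
from .vcf import GenotypeSet


@dataclass(frozen=True)
class DiplotypeScore:
    diplotype: Diplotype
    penalty_sum: int
    disqualified: bool
    positions_scored: int
    positions_skipped_missing: int
    declared_skipped_missing: int

    def __post_init__(self) -> None:
        if self.penalty_sum > 0:
            raise StateError("penalty sum can never be positive")


@dataclass(frozen=True)
class RankedCall:
    """Inference result for one gene."""

    gene: str
    top: tuple[Diplotype, ...]
    best_penalty: Optional[int]
    top_frequency: Optional[float]
    exact_match: bool
    candidates_total: int
    undeterminable: bool = False
    not_tested: bool = False
    scores: tuple[DiplotypeScore, ...] = field(default=(), repr=False)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(d.label for d in self.top)


def score_candidate(
    genotypes: GenotypeSet,
    combined: CombinedDefinition,
    declared: frozenset[tuple[str, int]],
    diplotype: Diplotype,
) -> DiplotypeScore:
    """Score one candidate against the observed genotypes."""
    penalty = 0
    disqualified = False
    scored = 0
    skipped = 0
    declared_skipped = 0
    for locus, expected in combined.items():
        call = genotypes.calls.get(locus)
        if call is None:
            raise StateError(
                f"locus {locus} of {diplotype.gene} absent from the "
                "genotype set; ingest must cover the full position set"
            )
        if call.missing:
            skipped += 1
            if locus in declared:
                declared_skipped += 1
            continue
        scored += 1
        if locus in declared:
            if call.alleles != expected:
                disqualified = True
        else:
            if call.alleles != expected:
                penalty -= 1
    return DiplotypeScore(
        diplotype=diplotype,
        penalty_sum=penalty,
        disqualified=disqualified,
        positions_scored=scored,
        positions_skipped_missing=skipped,
        declared_skipped_missing=declared_skipped,
    )


def _score_all(
    genotypes: GenotypeSet, gene_def: GeneDefinition
) -> list[DiplotypeScore]:
    out = []
    for dip in enumerate_diplotypes(gene_def):
        combined = combined_definition(dip, gene_def)
        declared = declared_loci(dip, gene_def)
        out.append(score_candidate(genotypes, combined, declared, dip))
    return out


def rank_diplotypes(
    genotypes: GenotypeSet,
    gene: str,
    group: str,
    kb: Knowledgebase,
) -> RankedCall:
    """Two-step ranking: best consistency, then highest frequency.

    Disqualified candidates are excluded first.  If every candidate is
    disqualified the call is flagged undeterminable (empty top) rather
    than raising.  If the gene has no covered locus at all it is
    flagged not tested.
    """
    validate_group(group)
    gene_def = kb.alleles[gene]
    scores = _score_all(genotypes, gene_def)
    total = len(scores)

    all_missing = all(
        genotypes.calls[locus].missing for locus in gene_def.positions
    ) if gene_def.positions else False
    if all_missing:
        return RankedCall(
            gene=gene, top=(), best_penalty=None, top_frequency=None,
            exact_match=False, candidates_total=total, not_tested=True,
            scores=tuple(scores),
        )

    qualified = [s for s in scores if not s.disqualified]
    if not qualified:
        return RankedCall(
            gene=gene, top=(), best_penalty=None, top_frequency=None,
            exact_match=False, candidates_total=total, undeterminable=True,
            scores=tuple(scores),
        )

    best_penalty = max(s.penalty_sum for s in qualified)
    tied = [s for s in qualified if s.penalty_sum == best_penalty]
    freqs = {
        s.diplotype: diplotype_frequency(s.diplotype, group, kb.frequencies)
        for s in tied
    }
    best_freq = max(freqs.values())
    # frequencies are derived deterministically from the table, so exact
    # equality is the intended tie criterion
    top = sorted(
        (s for s in tied if freqs[s.diplotype] == best_freq),
        key=lambda s: s.diplotype.label,
    )
    exact = best_penalty == 0 and all(
        s.declared_skipped_missing == 0 for s in top
    )
    return RankedCall(
        gene=gene,
        top=tuple(s.diplotype for s in top),
        best_penalty=best_penalty,
        top_frequency=best_freq,
        exact_match=exact,
        candidates_total=total,
        scores=tuple(scores),
    )


def infer_all(
    genotypes: GenotypeSet,
    group: str,
    kb: Knowledgebase,
    genes: Optional[Iterable[str]] = None,
) -> dict[str, RankedCall]:
    """Rank every multi-variant gene of the knowledgebase.

    ``genes`` defaults to all genes with allele definitions, sorted.
    Genes whose every locus is missing come back flagged not tested.
    """
    if genes is None:
        genes = sorted(kb.alleles)
    return {
        gene: rank_diplotypes(genotypes, gene, group, kb) for gene in genes
    }
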