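"""Consistency scoring and the two-step (penalty, frequency) ranking,
checked against an independent brute-force oracle."""
from __future__ import annotations

from random import Random

import pytest

from pgxcall.diplotypes import (
    Diplotype,
    combined_definition,
    declared_loci,
    enumerate_diplotypes,
    indistinguishable_groups,
)
from pgxcall.ranking import infer_all, rank_diplotypes, score_candidate
from pgxcall.vcf import GenotypeCall, GenotypeSet

from conftest import make_freqs, make_gene, make_genotypes, make_kb


# ---------------------------------------------------------------------------
# independent brute-force oracle: works directly on the raw declared
# dictionaries, never on the package's combined definitions or scorer

def brute_force_rank(haps, refs, calls, hap_freqs):
    """Score every unordered pair by direct comparison and take the
    argmax of (penalty, Hardy-Weinberg frequency); all ties returned.

    ``haps``: {name: {locus: alt}}; ``refs``: {locus: ref};
    ``calls``: {locus: tuple-of-two-alleles or None for missing};
    ``hap_freqs``: {name: frequency}.
    """
    names = sorted(haps)
    # only loci some haplotype declares are ever consulted
    position_set = sorted({loc for d in haps.values() for loc in d})
    if position_set and all(calls[loc] is None for loc in position_set):
        return []  # nothing measured: no call
    results = []
    for i, a in enumerate(names):
        for b in names[i:]:
            disqualified = False
            penalty = 0
            for locus in position_set:
                ref = refs[locus]
                obs = calls[locus]
                if obs is None:
                    continue
                expected = tuple(sorted((
                    haps[a].get(locus, ref), haps[b].get(locus, ref))))
                is_declared = locus in haps[a] or locus in haps[b]
                if tuple(sorted(obs)) != expected:
                    if is_declared:
                        disqualified = True
                    else:
                        penalty -= 1
            if not disqualified:
                p, q = hap_freqs[a], hap_freqs[b]
                freq = p * p if a == b else 2 * p * q
                results.append((f"{a}/{b}", penalty, freq))
    if not results:
        return []
    best_pen = max(r[1] for r in results)
    tied = [r for r in results if r[1] == best_pen]
    best_freq = max(r[2] for r in tied)
    return sorted(r[0] for r in tied if r[2] == best_freq)


def random_instance(rng: Random):
    """A random toy gene plus a random (possibly inconsistent) sample."""
    n_pos = rng.randint(2, 6)
    loci = [("chr1", 100 + i) for i in range(n_pos)]
    refs = {loc: rng.choice("ACGT") for loc in loci}
    alts = {loc: rng.choice([b for b in "ACGT" if b != refs[loc]])
            for loc in loci}
    n_haps = rng.randint(2, 12)
    raw = {"*1": {}}
    seen = {frozenset()}
    for k in range(2, n_haps + 1):
        for _ in range(50):
            chosen = frozenset(rng.sample(loci, rng.randint(1, n_pos)))
            if chosen not in seen:
                seen.add(chosen)
                raw[f"*{k}"] = {loc: alts[loc] for loc in chosen}
                break
    gene = make_gene("G", {
        name: {loc: (refs[loc], alt) for loc, alt in declared.items()}
        for name, declared in raw.items()
    })
    hap_freqs = {name: round(rng.random(), 3) for name in raw}
    freqs = make_freqs("G", hap_freqs)
    # genotypes only exist over the gene's position set (the union of
    # declared loci); anything else is outside the model's domain
    position_set = sorted({loc for d in raw.values() for loc in d})
    calls = {}
    for loc in position_set:
        u = rng.random()
        if u < 0.15:
            calls[loc] = None  # uncovered
        else:
            pool = [refs[loc], alts[loc]]
            calls[loc] = (rng.choice(pool), rng.choice(pool))
    return gene, raw, refs, calls, hap_freqs, freqs


def to_genotype_set(gene, calls):
    gs_calls = {}
    for loc in gene.positions:
        obs = calls[loc]
        if obs is None:
            gs_calls[loc] = GenotypeCall(loc, (), missing=True)
        else:
            gs_calls[loc] = GenotypeCall(loc, tuple(sorted(obs)))
    return GenotypeSet(sample="S1", calls=gs_calls)


class TestScoreCandidate:
    def _score(self, gene, genotypes, pair):
        dip = Diplotype(gene.gene, pair)
        return score_candidate(
            genotypes,
            combined_definition(dip, gene),
            declared_loci(dip, gene),
            dip,
        )

    def test_exact_match_scores_zero(self, toy_gene):
        gs = make_genotypes(toy_gene, {("chr1", 100): ("A", "G")})
        score = self._score(toy_gene, gs, ("*1", "*2"))
        assert score.penalty_sum == 0 and not score.disqualified

    def test_declared_mismatch_disqualifies(self, toy_gene):
        """A candidate requiring a homozygous alternate at a declared
        locus is ruled out by a heterozygous observation."""
        gs = make_genotypes(toy_gene, {("chr1", 100): ("A", "G")})
        score = self._score(toy_gene, gs, ("*2", "*2"))  # needs G/G
        assert score.disqualified

    def test_unexplained_variant_costs_one(self, toy_gene):
        """A variant at a locus the candidate does not declare costs a
        -1 penalty without disqualifying."""
        gs = make_genotypes(toy_gene, {("chr1", 200): ("C", "T")})
        score = self._score(toy_gene, gs, ("*1", "*1"))
        assert score.penalty_sum == -1 and not score.disqualified

    def test_missing_locus_skipped_and_counted(self, toy_gene):
        gs = make_genotypes(toy_gene, {}, missing=(("chr1", 100),))
        score = self._score(toy_gene, gs, ("*1", "*2"))
        assert not score.disqualified
        assert score.positions_skipped_missing == 1
        assert score.declared_skipped_missing == 1


class TestRankDiplotypes:
    def test_unique_zero_penalty_wins(self, toy_gene, toy_kb):
        gs = make_genotypes(toy_gene, {
            ("chr1", 100): ("G", "G"), ("chr1", 200): ("C", "T")})
        call = rank_diplotypes(gs, "CYPX", "EUR", toy_kb)
        assert call.labels == ("*2/*3",)
        assert call.best_penalty == 0 and call.exact_match

    def test_frequency_breaks_penalty_tie(self):
        """Two candidates fit equally well; the group-frequent one wins."""
        v, w = ("chr1", 100), ("chr1", 200)
        gene = make_gene("G", {
            "*1": {},
            "*2": {v: ("A", "G")},
            "*3": {w: ("C", "T")},
            "*4": {v: ("A", "G"), w: ("C", "T")},
        })
        freqs = make_freqs("G", {
            "*1": 0.5, "*2": 0.10, "*3": 0.2, "*4": 0.02})
        kb = make_kb([gene], freqs)
        gs = make_genotypes(gene, {v: ("A", "G"), w: ("C", "T")})
        call = rank_diplotypes(gs, "G", "EAS", kb)
        # 2 * 0.10 * 0.2 (*2/*3) > 2 * 0.5 * 0.02 (*1/*4)
        assert call.labels == ("*2/*3",)

    def test_all_disqualified_flags_undeterminable(self):
        # without a wild-type haplotype every candidate declares the
        # locus, so a contradictory genotype disqualifies them all
        v = ("chr1", 100)
        gene = make_gene("G", {
            "*2": {v: ("A", "G")},
            "*3": {v: ("A", "G"), ("chr1", 200): ("C", "T")},
        }, reference="<none>")
        freqs = make_freqs("G", {"*2": 0.6, "*3": 0.4})
        kb = make_kb([gene], freqs)
        gs = make_genotypes(gene, {v: ("A", "A")})
        call = rank_diplotypes(gs, "G", "EUR", kb)
        assert call.undeterminable and call.top == ()

    def test_residual_tie_returns_all_canonically(self):
        v, w = ("chr1", 100), ("chr1", 200)
        gene = make_gene("G", {
            "*1": {},
            "*2": {v: ("A", "G")},
            "*3": {w: ("C", "T")},
            "*4": {v: ("A", "G"), w: ("C", "T")},
        })
        # equal frequencies: *1/*4 and *2/*3 tie exactly
        freqs = make_freqs("G", {
            "*1": 0.25, "*2": 0.25, "*3": 0.25, "*4": 0.25})
        kb = make_kb([gene], freqs)
        gs = make_genotypes(gene, {v: ("A", "G"), w: ("C", "T")})
        call = rank_diplotypes(gs, "G", "EAS", kb)
        assert call.labels == ("*1/*4", "*2/*3")

    def test_oracle_equivalence_on_random_instances(self):
        """rank_diplotypes agrees with the brute-force oracle on random
        toy genes and genotype sets (H <= 12)."""
        rng = Random(20240917)
        for _ in range(150):
            gene, raw, refs, calls, hap_freqs, freqs = random_instance(rng)
            kb = make_kb([gene], freqs)
            gs = to_genotype_set(gene, calls)
            call = rank_diplotypes(gs, "G", "AME", kb)
            expected = brute_force_rank(raw, refs, calls, hap_freqs)
            assert list(call.labels) == expected

    def test_frequency_monotonicity(self):
        """Raising a tied candidate's frequency never drops it from top."""
        v, w = ("chr1", 100), ("chr1", 200)
        gene = make_gene("G", {
            "*1": {},
            "*2": {v: ("A", "G")},
            "*3": {w: ("C", "T")},
            "*4": {v: ("A", "G"), w: ("C", "T")},
        })
        gs = make_genotypes(gene, {v: ("A", "G"), w: ("C", "T")})
        for bump in (0.25, 0.3, 0.4):
            freqs = make_freqs("G", {
                "*1": 0.25, "*2": bump, "*3": 0.25, "*4": 0.25})
            kb = make_kb([gene], freqs)
            call = rank_diplotypes(gs, "G", "EAS", kb)
            assert "*2/*3" in call.labels

    def test_indistinguishable_members_score_identically(self):
        rng = Random(5)
        for _ in range(20):
            gene, raw, refs, calls, hap_freqs, freqs = random_instance(rng)
            groups = indistinguishable_groups(gene)
            if not groups:
                continue
            gs = to_genotype_set(gene, calls)
            kb = make_kb([gene], freqs)
            call = rank_diplotypes(gs, "G", "EUR", kb)
            by_dip = {s.diplotype: s for s in call.scores}
            for group in groups:
                first = by_dip[group[0]]
                for other in group[1:]:
                    s = by_dip[other]
                    assert s.penalty_sum == first.penalty_sum
                    assert s.disqualified == first.disqualified


class TestInferAll:
    def test_all_positions_missing_flags_not_tested(self, toy_gene, toy_kb):
        gs = make_genotypes(
            toy_gene, {}, missing=(("chr1", 100), ("chr1", 200)))
        result = infer_all(gs, "EUR", toy_kb)
        assert result["CYPX"].not_tested
        assert result["CYPX"].top == ()

    def test_one_call_per_gene(self, toy_gene, toy_kb):
        gs = make_genotypes(toy_gene, {})
        result = infer_all(gs, "EUR", toy_kb)
        assert set(result) == {"CYPX"}
        assert result["CYPX"].labels == ("*1/*1",)
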