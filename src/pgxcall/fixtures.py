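"""Synthetic knowledgebases and VCFs for fully offline testing.

The generator emulates the structure of a pharmacogenomic
knowledgebase — star-allele definition tables, per-population haplotype
frequencies, dosing guidelines, clinical annotations, single-variant
and HLA registries — and synthesizes single-sample VCFs from chosen
true diplotypes, optionally degraded by variant dropout (a target
position silently absent, as happens when sequencing does not cover a
site) and spurious heterozygous calls at positions the truth does not
declare (caller artifacts).  Spurious variants are only injected at
loci inside gene position sets: anywhere else they could never touch
the scoring.

One ``random.Random`` stream seeded once drives every decision, drawn
in a documented order (genes sorted, loci sorted; dropout before
spurious per locus), so a given seed reproduces files byte for byte.
"""
from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path
from random import Random
from typing import Mapping, Optional

from .model import BIOGEOGRAPHIC_GROUPS, UsageError
from .kb import KB_HEADER, Knowledgebase
from .diplotypes import Diplotype, combined_definition, enumerate_diplotypes

_BASES = "ACGT"
#: frequency denominator; dyadic so written frequencies are exact in
#: binary floating point and sum to exactly 1 per gene per group
_FREQ_DENOM = 1024


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study condition."""

    seed: int = 0
    genes: int = 3
    haplotypes_per_gene: tuple[int, int] = (3, 6)
    positions_per_gene: tuple[int, int] = (4, 8)
    ambiguity: bool = False
    dropout_rate: float = 0.0
    spurious_rate: float = 0.0
    null_rate: float = 0.0
    sample: str = "SAMPLE"

    def __post_init__(self) -> None:
        for name in ("dropout_rate", "spurious_rate", "null_rate"):
            rate = getattr(self, name)
            if not (0.0 <= rate <= 1.0):
                raise UsageError(f"{name} must lie in [0, 1], got {rate}")
        if self.genes < 1:
            raise UsageError("need at least one gene")
        lo, hi = self.haplotypes_per_gene
        if not (1 <= lo <= hi):
            raise UsageError("bad haplotypes_per_gene range")
        lo, hi = self.positions_per_gene
        if not (1 <= lo <= hi):
            raise UsageError("bad positions_per_gene range")


def _gene_name(i: int) -> str:
    return "GENE" + string.ascii_uppercase[i % 26] + (
        str(i // 26) if i >= 26 else "")


def _random_partition(rng: Random, parts: int, total: int) -> list[int]:
    """Split ``total`` into ``parts`` positive integers, uniformly over
    compositions (stars and bars via sorted cut points)."""
    if parts == 1:
        return [total]
    cuts = sorted(rng.sample(range(1, total), parts - 1))
    bounds = [0] + cuts + [total]
    return [bounds[i + 1] - bounds[i] for i in range(parts)]


def _declared_sets(
    rng: Random, n_haps: int, n_pos: int, ambiguity: bool
) -> list[frozenset[int]]:
    """Distinct declared position-index sets; index 0 is the reference
    (empty set).

    With ``ambiguity`` the first three non-reference haplotypes are
    {0}, {1}, {0, 1}: then *1/*4 and *2/*3 share every expected
    genotype, a guaranteed indistinguishable pair.
    """
    sets: list[frozenset[int]] = [frozenset()]
    if ambiguity:
        if n_haps < 4 or n_pos < 2:
            raise UsageError(
                "ambiguity needs >= 4 haplotypes and >= 2 positions"
            )
        sets += [frozenset({0}), frozenset({1}), frozenset({0, 1})]
    seen = set(sets)
    attempts = 0
    while len(sets) < n_haps:
        size = rng.randint(1, n_pos)
        cand = frozenset(rng.sample(range(n_pos), size))
        attempts += 1
        if cand in seen:
            if attempts > 1000 * n_haps:
                raise UsageError(
                    "cannot draw enough distinct haplotypes; increase "
                    "positions_per_gene"
                )
            continue
        seen.add(cand)
        sets.append(cand)
    return sets


def generate_toy_knowledgebase(
    spec: FixtureSpec, outdir: str | Path
) -> Path:
    """Write a complete six-file knowledgebase directory.

    Every gene gets exactly one reference haplotype (``*1``); haplotype
    frequencies per group are dyadic rationals summing to exactly 1
    (before any nulls are punched); guideline and annotation records
    reference only generated genes and diplotypes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = Random(spec.seed)

    allele_rows: list[str] = []
    freq_rows: list[str] = []
    gene_dips: dict[str, list[str]] = {}

    for gi in range(spec.genes):
        gene = _gene_name(gi)
        chrom = f"chr{(gi % 22) + 1}"
        n_pos = rng.randint(*spec.positions_per_gene)
        n_haps = rng.randint(*spec.haplotypes_per_gene)
        if spec.ambiguity and gi == 0:
            n_haps = max(n_haps, 4)
            n_pos = max(n_pos, 2)
        base = 1_000_000 * (gi + 1)
        offsets = sorted(rng.sample(range(1, 500_000), n_pos))
        positions = [base + off for off in offsets]
        refs = [rng.choice(_BASES) for _ in range(n_pos)]
        alts = [rng.choice([b for b in _BASES if b != r]) for r in refs]

        declared = _declared_sets(
            rng, n_haps, n_pos, spec.ambiguity and gi == 0)
        hap_names = [f"*{k + 1}" for k in range(n_haps)]
        for name, dset in zip(hap_names, declared):
            if not dset:
                allele_rows.append(
                    f"{gene}\t{name}\t\t\t\t\t1")
            else:
                for pi in sorted(dset):
                    allele_rows.append(
                        f"{gene}\t{name}\t{chrom}\t{positions[pi]}\t"
                        f"{refs[pi]}\t{alts[pi]}\t0")

        for name in hap_names:
            cells = []
            for _ in BIOGEOGRAPHIC_GROUPS:
                cells.append(None)  # placeholder, filled below
            freq_rows.append((gene, name, cells))
        # per group: dyadic weights summing to the denominator
        for gcol in range(len(BIOGEOGRAPHIC_GROUPS)):
            weights = _random_partition(rng, n_haps, _FREQ_DENOM)
            for hi, name in enumerate(hap_names):
                value: Optional[float] = weights[hi] / _FREQ_DENOM
                if spec.null_rate and rng.random() < spec.null_rate:
                    value = None
                freq_rows[len(freq_rows) - n_haps + hi][2][gcol] = value

        dips = [d.label for d in _toy_enumerate(hap_names)]
        gene_dips[gene] = dips

    genes = sorted(gene_dips)
    guideline_rows = []
    annotation_rows = []
    categories = ["avoid", "caution", "routine"]
    directions = ["decreased", "normal", "increased"]
    pheno_cats = ["toxicity", "dosage", "efficacy", "metabolism"]
    sources = ["CPIC", "DPWG", "CPNDS", "RNPGx"]
    levels = ["1A", "1B", "2A", "2B", "3"]  # level-3 rows exercise the drop
    drug_i = 0
    ann_i = 0
    for gene in genes:
        dips = gene_dips[gene]
        for j in range(min(3, len(dips))):
            drug = f"drug{drug_i}"
            drug_i += 1
            key = dips[rng.randrange(len(dips))]
            cat = categories[rng.randrange(3)]
            popdep = rng.random() < 0.25
            guideline_rows.append(
                f"{sources[rng.randrange(4)]}\t{drug}\t{gene}\t{key}\t"
                f"{cat}\t{int(popdep)}\t0\t"
                f"Synthetic recommendation for {gene} {key}."
            )
            for _ in range(rng.randint(1, 3)):
                ann_i += 1
                annotation_rows.append(
                    f"CA{ann_i:06d}\t{drug}\t{gene}\t{key}\t"
                    f"{levels[rng.randrange(5)]}\t"
                    f"{pheno_cats[rng.randrange(4)]}\t"
                    f"{directions[rng.randrange(3)]}"
                )

    # single-variant registry: one SNV gene, placed on its own contig
    sv_rows = ["SVGENE\trs9990001\tchr23\t500000\tC\tT"]
    hla_rows = ["HLA-B*57:01", "HLA-A*31:01"]

    def write(name: str, columns: str, rows: list[str]) -> None:
        with open(outdir / name, "w") as fh:
            fh.write(KB_HEADER + "\n")
            fh.write(columns + "\n")
            for row in rows:
                fh.write(row + "\n")

    write("alleles.tsv",
          "gene\thaplotype\tchromosome\tposition\tref\talt\tis_reference",
          allele_rows)
    freq_lines = []
    for gene, name, cells in freq_rows:
        rendered = "\t".join(
            "" if v is None else repr(v) for v in cells)
        freq_lines.append(f"{gene}\t{name}\t{rendered}")
    write("frequencies.tsv",
          "gene\thaplotype\t" + "\t".join(BIOGEOGRAPHIC_GROUPS),
          freq_lines)
    write("guidelines.tsv",
          "source\tdrug\tgene\tgenotype_key\tcategory\t"
          "population_dependent\tmulti_gene\ttext",
          guideline_rows)
    write("clinical_annotations.tsv",
          "annotation_id\tdrug\tgene\tgenotype_key\tevidence_level\t"
          "category\tdirection",
          annotation_rows)
    write("single_variant_alleles.tsv",
          "gene\trsid\tchromosome\tposition\tref\talt",
          sv_rows)
    write("hla_alleles.tsv", "allele", hla_rows)
    return outdir


def _toy_enumerate(names: list[str]) -> list[Diplotype]:
    from itertools import combinations_with_replacement
    dips = [Diplotype("_", (a, b))
            for a, b in combinations_with_replacement(sorted(names), 2)]
    return sorted(dips, key=lambda d: d.label)


def synthesize_vcf(
    kb: Knowledgebase,
    truth: Mapping[str, str],
    spec: FixtureSpec,
    out: str | Path,
    single_variant_alt_copies: Optional[Mapping[str, int]] = None,
) -> Path:
    """Write a single-sample VCF realizing ``truth`` diplotypes.

    ``truth`` maps gene symbol to a diplotype label (``"*1/*2"``).  One
    record is emitted per gene locus — homozygous reference where the
    truth declares nothing — then degraded: each target locus is
    independently dropped with ``spec.dropout_rate``, and at loci where
    the truth expects homozygous reference a spurious heterozygous call
    (using that locus's knowledgebase alternate) is injected with
    ``spec.spurious_rate``.  Single-variant registry loci are emitted
    as homozygous reference unless ``single_variant_alt_copies`` gives
    an alternate copy count per rsid.  The true diplotypes are written
    to a ``<out>.truth.json`` sidecar.
    """
    out = Path(out)
    rng = Random(spec.seed)
    records: list[tuple[str, int, str, str, str, str]] = []

    for gene in sorted(truth):
        if gene not in kb.alleles:
            raise UsageError(f"truth references unknown gene {gene!r}")
        gd = kb.alleles[gene]
        pair = tuple(truth[gene].split("/"))
        if len(pair) != 2 or any(p not in gd.haplotypes for p in pair):
            raise UsageError(
                f"truth references unknown haplotype in {truth[gene]!r} "
                f"for {gene}"
            )
        dip = Diplotype(gene, pair)
        combined = combined_definition(dip, gd)
        for locus in gd.positions:
            if rng.random() < spec.dropout_rate:
                continue
            chrom, pos = locus
            ref = gd.ref_allele[locus]
            expected = combined[locus]
            if expected == (ref, ref) and rng.random() < spec.spurious_rate:
                # spurious het using this locus's defined alternate
                alts = sorted({
                    hd.declared[locus].alt
                    for hd in gd.haplotypes.values()
                    if locus in hd.declared
                })
                records.append((chrom, pos, ref, alts[0], "0/1", "."))
                continue
            alt_alleles = sorted({a for a in expected if a != ref})
            if not alt_alleles:
                records.append((chrom, pos, ref,
                                _any_alt(gd, locus, ref), "0/0", "."))
            else:
                index = {a: i + 1 for i, a in enumerate(alt_alleles)}
                gt = "/".join(
                    str(index.get(a, 0))
                    for a in sorted(expected, key=lambda a: index.get(a, 0))
                )
                records.append((chrom, pos, ref,
                                ",".join(alt_alleles), gt, "."))

    sv_copies = dict(single_variant_alt_copies or {})
    for entry in sorted(kb.single_variant, key=lambda e: (e.gene, e.rsid)):
        copies = sv_copies.get(entry.rsid, 0)
        if copies not in (0, 1, 2):
            raise UsageError("alternate copy count must be 0, 1 or 2")
        gt = ["0/0", "0/1", "1/1"][copies]
        k = entry.key
        records.append(
            (k.chromosome, k.position, k.ref, k.alt, gt, entry.rsid))

    records.sort(key=lambda r: (r[0], r[1]))
    contigs = sorted({r[0] for r in records})
    with open(out, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##reference=GRCh38\n")
        for contig in contigs:
            fh.write(f"##contig=<ID={contig},length=250000000>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{spec.sample}\n")
        for chrom, pos, ref, alt, gt, rsid in records:
            fh.write(f"{chrom}\t{pos}\t{rsid}\t{ref}\t{alt}\t.\tPASS\t.\t"
                     f"GT\t{gt}\n")

    sidecar = out.with_suffix(out.suffix + ".truth.json")
    with open(sidecar, "w") as fh:
        json.dump({
            "sample": spec.sample,
            "seed": spec.seed,
            "truth": dict(sorted(truth.items())),
            "single_variant_alt_copies": sv_copies,
        }, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def _any_alt(gd, locus, ref: str) -> str:
    """A syntactically valid ALT for a homozygous-reference record."""
    for hd in gd.haplotypes.values():
        if locus in hd.declared:
            return hd.declared[locus].alt
    return next(b for b in _BASES if b != ref)


def random_truth(
    kb: Knowledgebase, rng: Random
) -> dict[str, str]:
    """Draw one diplotype per gene, uniformly over all candidates."""
    truth = {}
    for gene in sorted(kb.alleles):
        dips = enumerate_diplotypes(kb.alleles[gene])
        truth[gene] = dips[rng.randrange(len(dips))].label
    return truth


def identifiable_diplotypes(
    kb: Knowledgebase, gene: str, group: str
) -> list[Diplotype]:
    """Diplotypes recoverable from perfect unphased genotypes in
    ``group``.

    A diplotype sharing its combined definition with a strictly more
    frequent twin can never be output from unphased data — the
    frequency step exists precisely to prefer the twin.  Recoverable
    are the diplotypes that attain the maximal Hardy-Weinberg frequency
    within their indistinguishability class (distinguishable ones
    trivially do).
    """
    from .diplotypes import diplotype_frequency, indistinguishable_groups

    gd = kb.alleles[gene]
    twins: dict[Diplotype, list[Diplotype]] = {}
    for grp in indistinguishable_groups(gd):
        for d in grp:
            twins[d] = grp
    out = []
    for d in enumerate_diplotypes(gd):
        grp = twins.get(d)
        if grp is None:
            out.append(d)
            continue
        freqs = {t: diplotype_frequency(t, group, kb.frequencies)
                 for t in grp}
        if freqs[d] == max(freqs.values()):
            out.append(d)
    return out


def random_identifiable_truth(
    kb: Knowledgebase, rng: Random, group: str
) -> dict[str, str]:
    """Draw one recoverable diplotype per gene (see
    :func:`identifiable_diplotypes`)."""
    truth = {}
    for gene in sorted(kb.alleles):
        dips = identifiable_diplotypes(kb, gene, group)
        truth[gene] = dips[rng.randrange(len(dips))].label
    return truth
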