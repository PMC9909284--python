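"""Single-sample VCF ingestion.

Reads the germline VCF, normalizes each record (multi-allelic sites are
split per ALT and left-aligned), and assembles the sample's unordered
genotype at every knowledgebase locus.  Phase separators are ignored:
``0|1`` and ``0/1`` yield the same call, since the ranking model is
defined for unphased input.  Loci with no record or a ``./.`` genotype
are marked missing and later skipped in scoring — absence of evidence
is not evidence of a reference genotype.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pysam

from .model import InputError, UsageError, VariantKey, normalize_variant
from .kb import SingleVariantAllele

# re-exported for convenience; normalization is part of ingestion
__all__ = [
    "GenotypeCall", "GenotypeSet", "HlaCall", "SingleVariantCall",
    "normalize_variant", "read_genotypes", "call_single_variant_alleles",
    "extract_hla_calls",
]


@dataclass(frozen=True)
class GenotypeCall:
    """The sample's unordered allele pair at one locus."""

    locus: tuple[str, int]
    alleles: tuple[str, ...]  # empty when missing, else exactly two
    missing: bool = False

    def __post_init__(self) -> None:
        if self.missing and self.alleles:
            raise UsageError("missing call cannot carry alleles")
        if not self.missing and len(self.alleles) != 2:
            raise UsageError("a genotype call holds exactly two alleles")


@dataclass(frozen=True)
class HlaCall:
    allele: str
    copies: int

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise UsageError("HLA copy count must be >= 1 when present")


@dataclass
class GenotypeSet:
    """All knowledgebase-relevant genotypes of one sample."""

    sample: str
    calls: dict[tuple[str, int], GenotypeCall]
    hla: frozenset[HlaCall] = field(default_factory=frozenset)

    def call_at(self, locus: tuple[str, int]) -> GenotypeCall:
        return self.calls[locus]


@dataclass(frozen=True)
class SingleVariantCall:
    """Directly read diplotype of a single-variant gene."""

    gene: str
    rsid: str
    genotype: Optional[str]  # e.g. "C/T"; None when not tested

    @property
    def tested(self) -> bool:
        return self.genotype is not None


def _open_vcf(path: str | Path) -> pysam.VariantFile:
    try:
        return pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read VCF {path}: {exc}") from exc


def read_genotypes(
    vcf_path: str | Path,
    positions: Iterable[tuple[str, int]],
    sample: Optional[str] = None,
    respect_filter: bool = False,
) -> GenotypeSet:
    """Assemble the sample's genotype at every requested locus.

    Parameters
    ----------
    vcf_path
        Single- or multi-sample VCF (plain or bgzipped).
    positions
        The knowledgebase loci to genotype; every one receives a
        :class:`GenotypeCall`, missing-flagged when uncovered.
    sample
        Required when the VCF carries more than one sample.
    respect_filter
        When set, records with a non-PASS FILTER are ignored.  Off by
        default: upstream pipelines differ in how they populate FILTER.
    """
    wanted = set(positions)
    vf = _open_vcf(vcf_path)
    try:
        samples = list(vf.header.samples)
        if not samples:
            raise InputError(f"{vcf_path}: VCF has no sample columns")
        if sample is None:
            if len(samples) > 1:
                raise InputError(
                    f"{vcf_path}: multi-sample VCF; specify a sample "
                    f"(available: {', '.join(samples)})"
                )
            sample = samples[0]
        elif sample not in samples:
            raise InputError(
                f"sample {sample!r} absent from {vcf_path} "
                f"(available: {', '.join(samples)})"
            )

        observed: dict[tuple[str, int], tuple[str, ...]] = {}
        for rec in vf:
            if respect_filter and rec.filter.keys() not in ([], ["PASS"]):
                continue
            if rec.alts is None:
                continue
            gt = rec.samples[sample].get("GT")
            if gt is None or len(gt) != 2 or any(a is None for a in gt):
                continue
            # normalize each ALT separately (multi-allelic split); a GT
            # index then maps to an allele string per normalized locus
            alt_keys: dict[int, VariantKey] = {}
            for alt_index, alt in enumerate(rec.alts, start=1):
                if alt is None or alt.startswith("<"):
                    continue  # symbolic ALTs carry no sequence
                try:
                    alt_keys[alt_index] = normalize_variant(
                        rec.chrom, rec.pos, rec.ref, alt, rec.id)
                except UsageError:
                    continue
            loci_here: dict[tuple[str, int], str] = {}
            for key in alt_keys.values():
                loci_here.setdefault(key.locus, key.ref)
            for locus, ref in loci_here.items():
                if locus not in wanted:
                    continue
                pair = tuple(sorted(
                    alt_keys[a].alt
                    if a in alt_keys and alt_keys[a].locus == locus
                    else ref
                    for a in gt
                ))
                observed[locus] = pair
    finally:
        vf.close()

    calls = {}
    for locus in sorted(wanted):
        if locus in observed:
            calls[locus] = GenotypeCall(locus, observed[locus])
        else:
            calls[locus] = GenotypeCall(locus, (), missing=True)
    return GenotypeSet(sample=sample, calls=calls)


def call_single_variant_alleles(
    genotypes: GenotypeSet,
    registry: Iterable[SingleVariantAllele],
) -> list[SingleVariantCall]:
    """Report each single-variant gene's diplotype straight off the GT.

    Unmeasured positions are reported as not tested, never guessed —
    missingness is data here, not an error.
    """
    out = []
    for entry in sorted(registry, key=lambda e: (e.gene, e.rsid)):
        call = genotypes.calls.get(entry.key.locus)
        if call is None or call.missing:
            out.append(SingleVariantCall(entry.gene, entry.rsid, None))
        else:
            out.append(SingleVariantCall(
                entry.gene, entry.rsid, "/".join(call.alleles)))
    return out


def extract_hla_calls(
    vcf_path: Optional[str | Path] = None,
    sidecar: Optional[str | Path] = None,
) -> frozenset[HlaCall]:
    """Collect HLA presence/copy-number calls.

    HLA alleles cannot be typed from a germline VCF directly; results
    are accepted either as symbolic ALT entries (``<HLA-B*57:01>``,
    copies counted from the GT) or as a sidecar text file with lines
    ``allele<TAB>copies``.  Returns the empty set when nothing is
    provided.
    """
    calls: dict[str, int] = {}
    if vcf_path is not None:
        vf = _open_vcf(vcf_path)
        try:
            samples = list(vf.header.samples)
            for rec in vf:
                if rec.alts is None:
                    continue
                for alt_index, alt in enumerate(rec.alts, start=1):
                    if alt is None or not alt.startswith("<HLA-"):
                        continue
                    allele = alt[1:-1]
                    copies = 1
                    if samples:
                        gt = rec.samples[samples[0]].get("GT")
                        if gt is not None:
                            copies = sum(1 for a in gt if a == alt_index)
                    if copies >= 1:
                        calls[allele] = max(calls.get(allele, 0), copies)
        finally:
            vf.close()
    if sidecar is not None:
        with open(sidecar) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise InputError(
                        f"{sidecar} line {lineno}: expected "
                        "'allele<TAB>copies'"
                    )
                allele, copies_str = parts
                try:
                    copies = int(copies_str)
                except ValueError:
                    raise InputError(
                        f"{sidecar} line {lineno}: copy count "
                        f"{copies_str!r} is not an integer"
                    ) from None
                if copies < 1:
                    raise InputError(
                        f"{sidecar} line {lineno}: copy count must be >= 1"
                    )
                calls[allele] = max(calls.get(allele, 0), copies)
    return frozenset(HlaCall(a, c) for a, c in calls.items())
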