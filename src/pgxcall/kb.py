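"""Knowledgebase data model and loaders.

A knowledgebase is a directory of tab-separated files, each starting with
the header line ``#format=pgxkb-1 build=GRCh38``:

``alleles.tsv``
    gene, haplotype, chromosome, position, ref, alt, is_reference —
    one row per declared variant; the reference (wild-type) haplotype is
    a single row with empty chromosome/position/ref/alt and
    is_reference = 1.
``frequencies.tsv``
    gene, haplotype, then the nine biogeographic group codes; cells are
    frequencies in [0, 1] or empty (null = insufficient data, distinct
    from an observed zero).
``guidelines.tsv``
    source, drug, gene, genotype_key, category, population_dependent,
    multi_gene, text.
``clinical_annotations.tsv``
    annotation_id, drug, gene, genotype_key, evidence_level, category,
    direction.
``single_variant_alleles.tsv``
    gene, rsid, chromosome, position, ref, alt.
``hla_alleles.tsv``
    allele (registry of reportable HLA alleles).
"""
from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

from .model import (
    BIOGEOGRAPHIC_GROUPS,
    SchemaError,
    UsageError,
    VariantKey,
    normalize_variant,
)

logger = logging.getLogger(__name__)

KB_HEADER = "#format=pgxkb-1 build=GRCh38"

#: Default registry of genes whose star alleles are defined on more than
#: one variant and therefore require the ranking model (as opposed to
#: single-variant alleles read directly off the GT field).
DEFAULT_MULTI_VARIANT_GENES: tuple[str, ...] = (
    "CYP2B6", "CYP2C19", "CYP2C8", "CYP2C9", "CYP2D6", "CYP3A4",
    "CYP3A5", "CYP4F2", "DPYD", "NUDT15", "SLCO1B1", "TPMT", "UGT1A1",
)

GUIDELINE_SOURCES = ("CPIC", "DPWG", "CPNDS", "RNPGx")
GUIDELINE_CATEGORIES = ("avoid", "caution", "routine")
ANNOTATION_CATEGORIES = ("toxicity", "dosage", "efficacy", "metabolism")
ANNOTATION_DIRECTIONS = ("decreased", "normal", "increased")
EVIDENCE_LEVELS = ("1A", "1B", "2A", "2B")

DEFAULT_EPSILON = 1e-5


@dataclass(frozen=True)
class HaplotypeDefinition:
    """A named star allele: the variants it declares.

    The reference (wild-type) haplotype declares nothing; every
    undeclared position is assumed to carry the reference base.
    """

    gene: str
    name: str
    declared: Mapping[tuple[str, int], VariantKey]
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.is_reference != (len(self.declared) == 0):
            raise SchemaError(
                f"{self.gene} {self.name}: is_reference must hold exactly "
                "when the declared set is empty"
            )


@dataclass(frozen=True)
class GeneDefinition:
    """All haplotypes of one gene plus the union position set."""

    gene: str
    haplotypes: Mapping[str, HaplotypeDefinition]
    #: union of declared loci across haplotypes, sorted
    positions: tuple[tuple[str, int], ...]
    #: reference base at each locus (from the declaring VariantKeys)
    ref_allele: Mapping[tuple[str, int], str]
    reference_name: str


class AlleleDefinitionTable(dict):
    """Mapping gene symbol -> :class:`GeneDefinition`."""


@dataclass(frozen=True)
class GuidelineRecord:
    source: str
    drug: str
    gene: str
    genotype_key: str
    category: str
    population_dependent: bool
    multi_gene: bool
    text: str = ""

    def __post_init__(self) -> None:
        if self.source not in GUIDELINE_SOURCES:
            raise SchemaError(
                f"unknown guideline source {self.source!r}; expected one of "
                + ", ".join(GUIDELINE_SOURCES)
            )
        if self.category not in GUIDELINE_CATEGORIES:
            raise SchemaError(
                f"unknown guideline category {self.category!r}; expected one "
                "of " + ", ".join(GUIDELINE_CATEGORIES)
            )

    @property
    def effective_category(self) -> str:
        """Category after applying the conservative flag escalation.

        Population-dependent or multi-gene recommendations require at
        least caution even when the record itself says routine.
        """
        if self.category == "routine" and (
            self.population_dependent or self.multi_gene
        ):
            return "caution"
        return self.category


@dataclass(frozen=True)
class ClinicalAnnotationRecord:
    annotation_id: str
    drug: str
    gene: str
    genotype_key: str
    evidence_level: str
    category: str
    direction: str

    def __post_init__(self) -> None:
        if self.evidence_level not in EVIDENCE_LEVELS:
            raise SchemaError(
                f"evidence level {self.evidence_level!r} not representable; "
                "expected one of " + ", ".join(EVIDENCE_LEVELS)
            )
        if self.category not in ANNOTATION_CATEGORIES:
            raise SchemaError(
                f"unknown annotation category {self.category!r}"
            )
        if self.direction not in ANNOTATION_DIRECTIONS:
            raise SchemaError(
                f"unknown direction token {self.direction!r}; expected one "
                "of " + ", ".join(ANNOTATION_DIRECTIONS)
            )


@dataclass(frozen=True)
class SingleVariantAllele:
    """Registry entry for a gene typed by a single position (e.g. the
    VKORC1 promoter variant rs9923231)."""

    gene: str
    rsid: str
    key: VariantKey


class FrequencyTable:
    """Per-group haplotype frequencies; ``None`` marks insufficient data.

    A null is deliberately distinct from zero: zero means the population
    essentially cannot carry the haplotype, null means nobody measured
    it.  :meth:`fill_nulls` replaces nulls by a small epsilon while
    preserving zeros.
    """

    def __init__(
        self,
        entries: Optional[dict[tuple[str, str], dict[str, Optional[float]]]] = None,
        epsilon: float = DEFAULT_EPSILON,
        filled: bool = False,
    ) -> None:
        self.entries = entries if entries is not None else {}
        self.epsilon = epsilon
        self.filled = filled

    def get(self, gene: str, haplotype: str, group: str) -> Optional[float]:
        try:
            return self.entries[(gene, haplotype)][group]
        except KeyError:
            raise UsageError(
                f"no frequency entry for {gene} {haplotype}"
            ) from None

    def set(self, gene: str, haplotype: str,
            freqs: Mapping[str, Optional[float]]) -> None:
        row: dict[str, Optional[float]] = {}
        for group in BIOGEOGRAPHIC_GROUPS:
            value = freqs.get(group)
            if value is not None and not (0.0 <= value <= 1.0):
                raise SchemaError(
                    f"frequency {value} for {gene} {haplotype} [{group}] "
                    "outside [0, 1]"
                )
            row[group] = value
        self.entries[(gene, haplotype)] = row

    def fill_nulls(self, epsilon: Optional[float] = None) -> "FrequencyTable":
        """Return a copy with every null replaced by ``epsilon``.

        Non-null values, including exact zeros, are left untouched.
        """
        eps = self.epsilon if epsilon is None else epsilon
        if eps <= 0:
            raise UsageError(f"epsilon must be positive, got {eps}")
        filled = {
            key: {g: (eps if v is None else v) for g, v in row.items()}
            for key, row in self.entries.items()
        }
        return FrequencyTable(filled, epsilon=eps, filled=True)


def fill_null_frequencies(
    table: FrequencyTable, epsilon: float = DEFAULT_EPSILON
) -> FrequencyTable:
    """Functional alias for :meth:`FrequencyTable.fill_nulls`."""
    return table.fill_nulls(epsilon)


def haplotype_frequency_from_variant_frequencies(
    variant_freqs: Iterable[Mapping[str, Optional[float]]],
) -> dict[str, Optional[float]]:
    """Derive a haplotype's per-group frequency from its defining variants.

    The haplotype frequency in a group is the minimum of its defining
    variants' frequencies there — a haplotype cannot be more common than
    its rarest variant.  If any defining variant is unmeasured (null) in
    a group the result is null for that group: a minimum over partially
    known values would overstate confidence.
    """
    variant_freqs = list(variant_freqs)
    if not variant_freqs:
        raise UsageError("need at least one defining variant")
    out: dict[str, Optional[float]] = {}
    for group in BIOGEOGRAPHIC_GROUPS:
        values = [vf.get(group) for vf in variant_freqs]
        out[group] = None if any(v is None for v in values) else min(values)
    return out


# ---------------------------------------------------------------------------
# loaders

def _read_rows(path: Path, expected_columns: list[str]) -> list[dict[str, str]]:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"knowledgebase file not found: {path}")
    with open(path, newline="") as fh:
        header_line = fh.readline().rstrip("\n")
        if header_line != KB_HEADER:
            raise SchemaError(
                f"{path}: first line must be {KB_HEADER!r}, "
                f"got {header_line!r}"
            )
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: missing column header")
        missing = [c for c in expected_columns if c not in reader.fieldnames]
        if missing:
            raise SchemaError(
                f"{path}: missing columns {missing}; found {reader.fieldnames}"
            )
        return list(reader)


def load_allele_definitions(path: str | Path) -> AlleleDefinitionTable:
    """Load star-allele definitions from ``alleles.tsv``.

    Returns per-gene haplotype lists plus the union position set, and
    validates that every gene has exactly one reference haplotype.
    """
    rows = _read_rows(Path(path), [
        "gene", "haplotype", "chromosome", "position", "ref", "alt",
        "is_reference",
    ])
    per_hap: dict[tuple[str, str], list[VariantKey]] = {}
    is_ref: dict[tuple[str, str], bool] = {}
    order: list[tuple[str, str]] = []
    for i, row in enumerate(rows, start=3):
        gene, hap = row["gene"], row["haplotype"]
        key = (gene, hap)
        flag = row["is_reference"].strip() in ("1", "true", "True")
        if key not in per_hap:
            per_hap[key] = []
            is_ref[key] = flag
            order.append(key)
        elif flag != is_ref[key] or flag:
            raise SchemaError(
                f"{path} line {i}: duplicate rows for reference haplotype "
                f"({gene}, {hap})"
            )
        if row["position"].strip():
            if row["ref"].strip().upper() == row["alt"].strip().upper():
                raise SchemaError(
                    f"{path} line {i}: ref == alt for ({gene}, {hap})"
                )
            vk = normalize_variant(
                row["chromosome"], int(row["position"]),
                row["ref"], row["alt"],
            )
            if any(v.locus == vk.locus for v in per_hap[key]):
                raise SchemaError(
                    f"{path} line {i}: ({gene}, {hap}) declares more than "
                    f"one alt at {vk.chromosome}:{vk.position}"
                )
            per_hap[key].append(vk)
        elif not flag:
            raise SchemaError(
                f"{path} line {i}: non-reference haplotype ({gene}, {hap}) "
                "with no declared variant"
            )

    # detect duplicated (gene, haplotype) reference redefinition handled
    # above; a haplotype appearing with variants after being declared
    # reference is also a duplicate
    for key in order:
        if is_ref[key] and per_hap[key]:
            raise SchemaError(
                f"duplicate (gene, haplotype) pair {key}: reference "
                "haplotype also declares variants"
            )

    table = AlleleDefinitionTable()
    genes: dict[str, list[tuple[str, str]]] = {}
    for key in order:
        genes.setdefault(key[0], []).append(key)
    for gene, keys in genes.items():
        refs = [hap for (_, hap) in keys if is_ref[(gene, hap)]]
        if len(refs) != 1:
            raise SchemaError(
                f"gene {gene} must have exactly one reference haplotype, "
                f"found {len(refs)}"
            )
        haplotypes: dict[str, HaplotypeDefinition] = {}
        positions: set[tuple[str, int]] = set()
        ref_allele: dict[tuple[str, int], str] = {}
        for _, hap in keys:
            declared = {v.locus: v for v in per_hap[(gene, hap)]}
            for v in per_hap[(gene, hap)]:
                positions.add(v.locus)
                prior = ref_allele.get(v.locus)
                if prior is not None and prior != v.ref:
                    raise SchemaError(
                        f"gene {gene}: conflicting reference alleles "
                        f"{prior!r} vs {v.ref!r} at "
                        f"{v.chromosome}:{v.position}"
                    )
                ref_allele[v.locus] = v.ref
            haplotypes[hap] = HaplotypeDefinition(
                gene=gene, name=hap, declared=declared,
                is_reference=is_ref[(gene, hap)],
            )
        table[gene] = GeneDefinition(
            gene=gene,
            haplotypes=haplotypes,
            positions=tuple(sorted(positions)),
            ref_allele=ref_allele,
            reference_name=refs[0],
        )
    return table


def load_haplotype_frequencies(path: str | Path) -> FrequencyTable:
    """Load ``frequencies.tsv`` (nulls stored for empty cells)."""
    path = Path(path)
    with open(path, newline="") as fh:
        header_line = fh.readline().rstrip("\n")
        if header_line != KB_HEADER:
            raise SchemaError(
                f"{path}: first line must be {KB_HEADER!r}"
            )
        reader = csv.reader(fh, delimiter="\t")
        columns = next(reader, None)
        if columns is None or columns[:2] != ["gene", "haplotype"]:
            raise SchemaError(
                f"{path}: columns must start with gene, haplotype"
            )
        group_cols = columns[2:]
        bad = [c for c in group_cols if c not in BIOGEOGRAPHIC_GROUPS]
        if bad or sorted(group_cols) != sorted(BIOGEOGRAPHIC_GROUPS):
            raise SchemaError(
                f"{path}: frequency columns must be exactly the nine "
                f"biogeographic groups {BIOGEOGRAPHIC_GROUPS}; "
                f"offending columns: {bad or group_cols}"
            )
        table = FrequencyTable()
        for i, row in enumerate(reader, start=3):
            if not row:
                continue
            gene, hap = row[0], row[1]
            freqs: dict[str, Optional[float]] = {}
            for group, cell in zip(group_cols, row[2:]):
                cell = cell.strip()
                if cell == "":
                    freqs[group] = None
                    continue
                try:
                    value = float(cell)
                except ValueError:
                    raise SchemaError(
                        f"{path} line {i}: non-numeric frequency {cell!r}"
                    ) from None
                if not (0.0 <= value <= 1.0) or math.isnan(value):
                    raise SchemaError(
                        f"{path} line {i}: frequency {value} outside [0, 1]"
                    )
                freqs[group] = value
            table.set(gene, hap, freqs)
    return table


def _parse_flag(token: str, path: Path, line: int) -> bool:
    token = token.strip().lower()
    if token in ("1", "true", "yes"):
        return True
    if token in ("0", "false", "no", ""):
        return False
    raise SchemaError(f"{path} line {line}: bad boolean flag {token!r}")


def load_guidelines(path: str | Path) -> list[GuidelineRecord]:
    """Load dosing-guideline records from ``guidelines.tsv``."""
    path = Path(path)
    rows = _read_rows(path, [
        "source", "drug", "gene", "genotype_key", "category",
        "population_dependent", "multi_gene", "text",
    ])
    records = []
    for i, row in enumerate(rows, start=3):
        records.append(GuidelineRecord(
            source=row["source"].strip(),
            drug=row["drug"].strip(),
            gene=row["gene"].strip(),
            genotype_key=row["genotype_key"].strip(),
            category=row["category"].strip(),
            population_dependent=_parse_flag(
                row["population_dependent"], path, i),
            multi_gene=_parse_flag(row["multi_gene"], path, i),
            text=row.get("text", "") or "",
        ))
    return records


def load_clinical_annotations(path: str | Path) -> list[ClinicalAnnotationRecord]:
    """Load clinical-annotation records from ``clinical_annotations.tsv``.

    Rows whose evidence level is outside 1A/1B/2A/2B are dropped (the
    count is logged); lower levels are not considered reliable enough
    for phenotype integration.
    """
    rows = _read_rows(Path(path), [
        "annotation_id", "drug", "gene", "genotype_key", "evidence_level",
        "category", "direction",
    ])
    records = []
    dropped = 0
    for row in rows:
        level = row["evidence_level"].strip()
        if level not in EVIDENCE_LEVELS:
            dropped += 1
            continue
        records.append(ClinicalAnnotationRecord(
            annotation_id=row["annotation_id"].strip(),
            drug=row["drug"].strip(),
            gene=row["gene"].strip(),
            genotype_key=row["genotype_key"].strip(),
            evidence_level=level,
            category=row["category"].strip(),
            direction=row["direction"].strip(),
        ))
    if dropped:
        logger.info(
            "dropped %d clinical annotations below evidence level 2B",
            dropped,
        )
    return records


def load_single_variant_alleles(path: str | Path) -> list[SingleVariantAllele]:
    rows = _read_rows(Path(path), [
        "gene", "rsid", "chromosome", "position", "ref", "alt",
    ])
    registry = []
    for row in rows:
        registry.append(SingleVariantAllele(
            gene=row["gene"].strip(),
            rsid=row["rsid"].strip(),
            key=normalize_variant(
                row["chromosome"].strip(), int(row["position"]),
                row["ref"], row["alt"], rsid=row["rsid"].strip() or None,
            ),
        ))
    return registry


def load_hla_registry(path: str | Path) -> list[str]:
    rows = _read_rows(Path(path), ["allele"])
    return [row["allele"].strip() for row in rows if row["allele"].strip()]


# ---------------------------------------------------------------------------
# writers (round-trip partners of the loaders)

def _format_freq(value: Optional[float]) -> str:
    return "" if value is None else repr(value)


def write_allele_definitions(table: AlleleDefinitionTable,
                             path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(KB_HEADER + "\n")
        fh.write("gene\thaplotype\tchromosome\tposition\tref\talt\t"
                 "is_reference\n")
        for gene in sorted(table):
            gd = table[gene]
            for hap in sorted(gd.haplotypes):
                hd = gd.haplotypes[hap]
                if hd.is_reference:
                    fh.write(f"{gene}\t{hap}\t\t\t\t\t1\n")
                else:
                    for locus in sorted(hd.declared):
                        v = hd.declared[locus]
                        fh.write(
                            f"{gene}\t{hap}\t{v.chromosome}\t{v.position}"
                            f"\t{v.ref}\t{v.alt}\t0\n")


def write_haplotype_frequencies(table: FrequencyTable,
                                path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(KB_HEADER + "\n")
        fh.write("gene\thaplotype\t" + "\t".join(BIOGEOGRAPHIC_GROUPS) + "\n")
        for (gene, hap) in sorted(table.entries):
            row = table.entries[(gene, hap)]
            cells = "\t".join(
                _format_freq(row[g]) for g in BIOGEOGRAPHIC_GROUPS)
            fh.write(f"{gene}\t{hap}\t{cells}\n")


def write_guidelines(records: Iterable[GuidelineRecord],
                     path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(KB_HEADER + "\n")
        fh.write("source\tdrug\tgene\tgenotype_key\tcategory\t"
                 "population_dependent\tmulti_gene\ttext\n")
        for r in records:
            fh.write(
                f"{r.source}\t{r.drug}\t{r.gene}\t{r.genotype_key}\t"
                f"{r.category}\t{int(r.population_dependent)}\t"
                f"{int(r.multi_gene)}\t{r.text}\n")


def write_clinical_annotations(records: Iterable[ClinicalAnnotationRecord],
                               path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(KB_HEADER + "\n")
        fh.write("annotation_id\tdrug\tgene\tgenotype_key\t"
                 "evidence_level\tcategory\tdirection\n")
        for r in records:
            fh.write(
                f"{r.annotation_id}\t{r.drug}\t{r.gene}\t{r.genotype_key}"
                f"\t{r.evidence_level}\t{r.category}\t{r.direction}\n")


@dataclass
class Knowledgebase:
    """All six tables of one knowledgebase directory."""

    alleles: AlleleDefinitionTable
    frequencies: FrequencyTable
    guidelines: list[GuidelineRecord]
    annotations: list[ClinicalAnnotationRecord]
    single_variant: list[SingleVariantAllele]
    hla: list[str]

    @classmethod
    def load(cls, directory: str | Path,
             epsilon: float = DEFAULT_EPSILON) -> "Knowledgebase":
        """Load a knowledgebase directory and epsilon-fill frequencies."""
        d = Path(directory)
        return cls(
            alleles=load_allele_definitions(d / "alleles.tsv"),
            frequencies=load_haplotype_frequencies(
                d / "frequencies.tsv").fill_nulls(epsilon),
            guidelines=load_guidelines(d / "guidelines.tsv"),
            annotations=load_clinical_annotations(
                d / "clinical_annotations.tsv"),
            single_variant=load_single_variant_alleles(
                d / "single_variant_alleles.tsv"),
            hla=load_hla_registry(d / "hla_alleles.tsv"),
        )

    def all_positions(self) -> list[tuple[str, int]]:
        """Every locus the ingest step must genotype, sorted."""
        loci = {
            locus for gd in self.alleles.values() for locus in gd.positions
        }
        loci.update(sv.key.locus for sv in self.single_variant)
        return sorted(loci)
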