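"""Guideline-based drug classification and phenotype integration.

Classification is drug-centric and conservative.  A guideline record is
*triggered* when its (gene, genotype key) matches one of the sample's
calls — a ranked diplotype label for a multi-variant gene, a genotype
string for a single-variant gene, or an HLA allele.  Per drug the most
conservative triggered category wins (avoid > caution > routine), with
population-dependent or multi-gene recommendations escalated to at
least caution.

Phenotype integration then pools the matched clinical annotations per
(drug, category) across genes — one drug frequently has several
genotype associations — coding directions as 0.5 (decreased), 1
(normal) and 2 (increased) and averaging.  A mean below 1 predicts a
decreased phenotype, equal to 1 normal, above 1 increased.  Drugs
classified avoid-use are excluded from phenotype prediction entirely:
when a drug must not be given, predicting how it would behave is
clinically meaningless.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .model import UsageError
from .kb import (
    ANNOTATION_CATEGORIES,
    ClinicalAnnotationRecord,
    GuidelineRecord,
)
from .ranking import RankedCall
from .vcf import HlaCall, SingleVariantCall

DIRECTION_SCORES = {"decreased": 0.5, "normal": 1.0, "increased": 2.0}
_CATEGORY_RANK = {"routine": 0, "caution": 1, "avoid": 2}
#: tolerance for the mean == 1 comparison; scores are dyadic rationals
#: but the mean is accumulated in floating point
MEAN_EQ_TOL = 1e-9


@dataclass(frozen=True)
class PhenotypePrediction:
    direction: str  # decreased | normal | increased | not_predicted
    mean_score: Optional[float]
    records: tuple[ClinicalAnnotationRecord, ...] = ()


@dataclass(frozen=True)
class DrugReport:
    drug: str
    category: str
    guidelines: tuple[GuidelineRecord, ...]
    phenotypes: Mapping[str, PhenotypePrediction]

    def __post_init__(self) -> None:
        if self.category == "avoid":
            for pred in self.phenotypes.values():
                if pred.direction != "not_predicted":
                    raise UsageError(
                        "avoid-use drugs carry no phenotype prediction"
                    )


def call_keys(
    ranked: Mapping[str, RankedCall],
    single_variant: Iterable[SingleVariantCall] = (),
    hla: Iterable[HlaCall] = (),
) -> set[tuple[str, str]]:
    """The (gene, genotype key) pairs the sample's calls expose.

    Every member of a ranked top set contributes its label; residual
    ties are genuine ambiguity, so each tied diplotype can trigger
    records.
    """
    keys: set[tuple[str, str]] = set()
    for gene, call in ranked.items():
        for dip in call.top:
            keys.add((gene, dip.label))
    for sv in single_variant:
        if sv.tested:
            keys.add((sv.gene, sv.genotype))
    for h in hla:
        # HLA records key on the allele name; the gene is the allele's
        # locus prefix (e.g. HLA-B for HLA-B*57:01)
        gene = h.allele.split("*")[0]
        keys.add((gene, h.allele))
    return keys


def code_annotation(record: ClinicalAnnotationRecord) -> float:
    """Numeric code of a direction: 0.5 decreased, 1 normal, 2 increased."""
    try:
        return DIRECTION_SCORES[record.direction]
    except KeyError:
        raise UsageError(
            f"inadmissible direction {record.direction!r}"
        ) from None


def classify_drugs(
    keys: set[tuple[str, str]],
    guidelines: Iterable[GuidelineRecord],
) -> tuple[dict[str, str], dict[str, list[GuidelineRecord]]]:
    """Assign each drug with a triggered guideline its category.

    Returns the category map and the triggering records per drug.
    Drugs with no triggered record are absent — they are simply not
    reportable for this sample.
    """
    categories: dict[str, str] = {}
    triggered: dict[str, list[GuidelineRecord]] = {}
    for rec in guidelines:
        if (rec.gene, rec.genotype_key) not in keys:
            continue
        triggered.setdefault(rec.drug, []).append(rec)
        cat = rec.effective_category
        prev = categories.get(rec.drug)
        if prev is None or _CATEGORY_RANK[cat] > _CATEGORY_RANK[prev]:
            categories[rec.drug] = cat
    return categories, triggered


def match_annotations(
    keys: set[tuple[str, str]],
    annotations: Iterable[ClinicalAnnotationRecord],
    categories: Mapping[str, str],
) -> dict[tuple[str, str], list[ClinicalAnnotationRecord]]:
    """Match annotation records to calls, excluding avoid-use drugs and
    drugs without any triggered guideline."""
    matched: dict[tuple[str, str], list[ClinicalAnnotationRecord]] = {}
    for rec in annotations:
        cat = categories.get(rec.drug)
        if cat is None or cat == "avoid":
            continue
        if (rec.gene, rec.genotype_key) not in keys:
            continue
        matched.setdefault((rec.drug, rec.category), []).append(rec)
    return matched


def integrate_phenotypes(
    matched: Mapping[tuple[str, str], list[ClinicalAnnotationRecord]],
    categories: Mapping[str, str],
    triggered: Mapping[str, list[GuidelineRecord]],
) -> dict[str, DrugReport]:
    """Average the coded scores per (drug, category) into a direction."""
    reports: dict[str, DrugReport] = {}
    for drug in sorted(categories):
        category = categories[drug]
        phenotypes: dict[str, PhenotypePrediction] = {}
        for pheno_cat in ANNOTATION_CATEGORIES:
            records = matched.get((drug, pheno_cat), [])
            if category == "avoid" or not records:
                phenotypes[pheno_cat] = PhenotypePrediction(
                    "not_predicted", None)
                continue
            records = sorted(records, key=lambda r: r.annotation_id)
            mean = sum(code_annotation(r) for r in records) / len(records)
            if abs(mean - 1.0) <= MEAN_EQ_TOL:
                direction = "normal"
            elif mean < 1.0:
                direction = "decreased"
            else:
                direction = "increased"
            phenotypes[pheno_cat] = PhenotypePrediction(
                direction, mean, tuple(records))
        reports[drug] = DrugReport(
            drug=drug,
            category=category,
            guidelines=tuple(sorted(
                triggered.get(drug, []),
                key=lambda r: (r.source, r.gene, r.genotype_key),
            )),
            phenotypes=phenotypes,
        )
    return reports


def annotate(
    ranked: Mapping[str, RankedCall],
    single_variant: Iterable[SingleVariantCall],
    hla: Iterable[HlaCall],
    guidelines: Iterable[GuidelineRecord],
    annotations: Iterable[ClinicalAnnotationRecord],
) -> dict[str, DrugReport]:
    """Full annotation pass: classify, match, integrate."""
    keys = call_keys(ranked, single_variant, hla)
    categories, triggered = classify_drugs(keys, guidelines)
    matched = match_annotations(keys, annotations, categories)
    return integrate_phenotypes(matched, categories, triggered)
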