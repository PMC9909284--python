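"""Self-contained HTML report plus a machine-readable JSON twin.

The report has five sections, in order: Summary (drugs grouped into
avoid / caution / routine), Prescribing info (per-drug genes,
diplotypes and recommendations), Diplotype detail (per-gene defined vs
called alleles, single-variant genotypes), Phenotype prediction (the
four integrated directions per drug), and Clinical annotation (the
supporting records).  No remote assets; the timestamp is injected by
the caller so a rerun on the same inputs is byte-identical.
"""
from __future__ import annotations

import html
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .model import TemplateError
from .annotate import DrugReport
from .kb import ANNOTATION_CATEGORIES, Knowledgebase
from .ranking import RankedCall
from .vcf import HlaCall, SingleVariantCall

CATEGORY_TITLES = {
    "avoid": "Avoid use",
    "caution": "Use with caution",
    "routine": "Routine use",
}

#: blocks every template must provide a slot for
REQUIRED_BLOCKS = (
    "metadata", "summary", "prescribing_info", "diplotype_detail",
    "phenotype_prediction", "clinical_annotation",
)

DEFAULT_TEMPLATE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>Pharmacogenomic report</title>
<style>
body { font-family: sans-serif; margin: 2em auto; max-width: 60em; }
table { border-collapse: collapse; margin: 0.5em 0; }
th, td { border: 1px solid #999; padding: 0.25em 0.6em; text-align: left; }
h2 { border-bottom: 2px solid #444; padding-bottom: 0.2em; }
.meta { color: #555; }
</style>
</head>
<body>
{{metadata}}
<h2>Summary</h2>
{{summary}}
<h2>Prescribing info</h2>
{{prescribing_info}}
<h2>Diplotype detail</h2>
{{diplotype_detail}}
<h2>Phenotype prediction</h2>
{{phenotype_prediction}}
<h2>Clinical annotation</h2>
{{clinical_annotation}}
<p class="meta">{{footer}}</p>
</body>
</html>
"""


@dataclass
class ReportContext:
    sample: str
    group: str
    timestamp: str
    version: str
    ranked: Mapping[str, RankedCall] = field(default_factory=dict)
    single_variant: list[SingleVariantCall] = field(default_factory=list)
    hla: frozenset[HlaCall] = field(default_factory=frozenset)
    drugs: Mapping[str, DrugReport] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)
    kb: Optional[Knowledgebase] = None


def _esc(text: object) -> str:
    return html.escape(str(text))


def _anchor(drug: str) -> str:
    return "drug-" + "".join(
        c if c.isalnum() else "-" for c in drug.lower())


def _metadata_html(ctx: ReportContext) -> str:
    rows = [
        ("Sample", ctx.sample),
        ("Biogeographic group", ctx.group),
        ("Report time", ctx.timestamp),
        ("Tool version", ctx.version),
    ]
    cells = "".join(
        f"<tr><th>{_esc(k)}</th><td>{_esc(v)}</td></tr>" for k, v in rows)
    return f'<table class="meta">{cells}</table>'


def _summary_html(ctx: ReportContext) -> str:
    parts = []
    for cat in ("avoid", "caution", "routine"):
        drugs = sorted(d for d, r in ctx.drugs.items() if r.category == cat)
        items = "".join(
            f'<li><a href="#{_anchor(d)}">{_esc(d)}</a></li>' for d in drugs)
        parts.append(
            f"<h3>{CATEGORY_TITLES[cat]}</h3>"
            f"<ul>{items}</ul>"
        )
    return "".join(parts)


def _prescribing_html(ctx: ReportContext) -> str:
    if not ctx.drugs:
        return "<p>No drug with a triggered guideline.</p>"
    parts = []
    for drug in sorted(ctx.drugs):
        rep = ctx.drugs[drug]
        rows = []
        for g in rep.guidelines:
            call = ctx.ranked.get(g.gene)
            dips = ", ".join(call.labels) if call and call.top else "—"
            rows.append(
                f"<tr><td>{_esc(g.gene)}</td><td>{_esc(dips)}</td>"
                f"<td>{_esc(g.genotype_key)}</td><td>{_esc(g.source)}</td>"
                f"<td>{_esc(g.text)}</td></tr>"
            )
        parts.append(
            f'<section id="{_anchor(drug)}"><h3>{_esc(drug)} — '
            f"{CATEGORY_TITLES[rep.category]}</h3>"
            "<table><tr><th>Gene</th><th>Inferred diplotype</th>"
            "<th>Matched genotype</th><th>Source</th>"
            "<th>Recommendation</th></tr>"
            + "".join(rows) + "</table></section>"
        )
    return "".join(parts)


def _diplotype_detail_html(ctx: ReportContext) -> str:
    parts = []
    for gene in sorted(ctx.ranked):
        call = ctx.ranked[gene]
        if call.not_tested:
            status = "not tested"
        elif call.undeterminable:
            status = "undeterminable"
        else:
            status = ", ".join(call.labels)
        parts.append(f"<h3>{_esc(gene)}: {_esc(status)}</h3>")
        if ctx.kb is not None and gene in ctx.kb.alleles:
            gd = ctx.kb.alleles[gene]
            rows = []
            for locus in gd.positions:
                declared_alts = sorted({
                    hd.declared[locus].alt
                    for hd in gd.haplotypes.values() if locus in hd.declared
                })
                rows.append(
                    f"<tr><td>{_esc(locus[0])}:{locus[1]}</td>"
                    f"<td>{_esc(gd.ref_allele[locus])}</td>"
                    f"<td>{_esc(','.join(declared_alts))}</td></tr>"
                )
            parts.append(
                "<table><tr><th>Position</th><th>Reference</th>"
                "<th>Defined alternates</th></tr>"
                + "".join(rows) + "</table>"
            )
    sv_rows = "".join(
        f"<tr><td>{_esc(sv.gene)}</td><td>{_esc(sv.rsid)}</td>"
        f"<td>{_esc(sv.genotype if sv.tested else 'not tested')}</td></tr>"
        for sv in ctx.single_variant
    )
    parts.append(
        "<h3>Single-variant genotypes</h3>"
        "<table><tr><th>Gene</th><th>rsID</th><th>Genotype</th></tr>"
        + sv_rows + "</table>"
    )
    if ctx.hla:
        hla_rows = "".join(
            f"<tr><td>{_esc(h.allele)}</td><td>{h.copies}</td></tr>"
            for h in sorted(ctx.hla, key=lambda h: h.allele)
        )
        parts.append(
            "<h3>HLA alleles</h3>"
            "<table><tr><th>Allele</th><th>Copies</th></tr>"
            + hla_rows + "</table>"
        )
    if ctx.notes:
        parts.append("<ul>" + "".join(
            f"<li>{_esc(n)}</li>" for n in ctx.notes) + "</ul>")
    return "".join(parts)


def _phenotype_html(ctx: ReportContext) -> str:
    rows = []
    for drug in sorted(ctx.drugs):
        rep = ctx.drugs[drug]
        if rep.category == "avoid":
            continue
        cells = "".join(
            f"<td>{_esc(rep.phenotypes[c].direction)}</td>"
            for c in ANNOTATION_CATEGORIES
        )
        rows.append(f"<tr><td>{_esc(drug)}</td>{cells}</tr>")
    if not rows:
        return "<p>No phenotype predicted.</p>"
    header = "".join(f"<th>{c.capitalize()}</th>"
                     for c in ANNOTATION_CATEGORIES)
    return ("<table><tr><th>Drug</th>" + header + "</tr>"
            + "".join(rows) + "</table>")


def _clinical_annotation_html(ctx: ReportContext) -> str:
    rows = []
    for drug in sorted(ctx.drugs):
        rep = ctx.drugs[drug]
        for cat in ANNOTATION_CATEGORIES:
            for rec in rep.phenotypes[cat].records:
                rows.append(
                    f"<tr><td>{_esc(rec.annotation_id)}</td>"
                    f"<td>{_esc(drug)}</td><td>{_esc(rec.gene)}</td>"
                    f"<td>{_esc(rec.genotype_key)}</td>"
                    f"<td>{_esc(rec.evidence_level)}</td>"
                    f"<td>{_esc(cat)}</td>"
                    f"<td>{_esc(rec.direction)}</td></tr>"
                )
    if not rows:
        return "<p>No supporting clinical annotation.</p>"
    return (
        "<table><tr><th>ID</th><th>Drug</th><th>Gene</th>"
        "<th>Genotype</th><th>Evidence</th><th>Category</th>"
        "<th>Direction</th></tr>" + "".join(rows) + "</table>"
    )


def render_report(ctx: ReportContext, template: Optional[str] = None) -> str:
    """Render the HTML document.

    Raises
    ------
    TemplateError
        When a custom template lacks a slot for a required block; the
        message names the missing block.
    """
    tpl = DEFAULT_TEMPLATE if template is None else template
    for block in REQUIRED_BLOCKS:
        if "{{" + block + "}}" not in tpl:
            raise TemplateError(
                f"template is missing required block {block!r}"
            )
    blocks = {
        "metadata": _metadata_html(ctx),
        "summary": _summary_html(ctx),
        "prescribing_info": _prescribing_html(ctx),
        "diplotype_detail": _diplotype_detail_html(ctx),
        "phenotype_prediction": _phenotype_html(ctx),
        "clinical_annotation": _clinical_annotation_html(ctx),
        "footer": f"Generated by pgxcall {ctx.version} at {ctx.timestamp}.",
    }
    out = tpl
    for name, content in blocks.items():
        out = out.replace("{{" + name + "}}", content)
    return out


def render_json(ctx: ReportContext) -> str:
    """Machine-readable twin of the HTML report."""
    payload = {
        "sample": ctx.sample,
        "group": ctx.group,
        "timestamp": ctx.timestamp,
        "version": ctx.version,
        "diplotypes": {
            gene: {
                "top": list(call.labels),
                "best_penalty": call.best_penalty,
                "top_frequency": call.top_frequency,
                "exact_match": call.exact_match,
                "candidates_total": call.candidates_total,
                "undeterminable": call.undeterminable,
                "not_tested": call.not_tested,
            }
            for gene, call in sorted(ctx.ranked.items())
        },
        "single_variant": [
            {"gene": sv.gene, "rsid": sv.rsid,
             "genotype": sv.genotype, "tested": sv.tested}
            for sv in ctx.single_variant
        ],
        "hla": [
            {"allele": h.allele, "copies": h.copies}
            for h in sorted(ctx.hla, key=lambda h: h.allele)
        ],
        "drugs": {
            drug: {
                "category": rep.category,
                "phenotypes": {
                    cat: {
                        "direction": rep.phenotypes[cat].direction,
                        "mean_score": rep.phenotypes[cat].mean_score,
                        "annotation_ids": [
                            r.annotation_id
                            for r in rep.phenotypes[cat].records
                        ],
                    }
                    for cat in ANNOTATION_CATEGORIES
                },
                "guideline_sources": sorted(
                    {g.source for g in rep.guidelines}),
            }
            for drug, rep in sorted(ctx.drugs.items())
        },
        "notes": list(ctx.notes),
    }
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"
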