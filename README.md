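# pgxcall

Star-allele diplotype inference from an unphased germline VCF, with
population-frequency ranking and clinical pharmacogenomic annotation.

## The problem

Drug response is strongly shaped by germline variation in
pharmacogenes (CYP2D6, CYP2C19, TPMT, UGT1A1, ...).  The clinically
interpretable unit is the **diplotype**: the unordered pair of named
haplotypes — *star alleles* such as `*2` or `*28` — one on each
homologous chromosome.  Short-read sequencing delivers unphased
genotypes, so when a sample carries variants belonging to several
allele definitions, more than one haplotype pair can explain the same
VCF.  Some pairs are even *indistinguishable*: their combined,
unphased variant patterns are identical.

`pgxcall` resolves this with a two-step ranking over all candidate
diplotypes of a gene:

1. **Consistency.**  Each candidate's expected genotype is compared
   with the observations locus by locus.  At a locus the candidate
   *declares* (one of its haplotypes defines a variant there), any
   mismatch disqualifies the candidate.  At an undeclared locus
   (expected homozygous reference), a mismatch costs a penalty of −1.
   Uncovered loci are skipped.  Candidates are ranked by total
   penalty, closest to zero first.
2. **Population frequency.**  Penalty ties are broken by the
   candidate's expected frequency in the sample's biogeographic group
   (one of nine: AAC, AME, SAS, EAS, EUR, LAT, NEA, OCE, SSA), under
   Hardy–Weinberg equilibrium: `p²` for a homozygote, `2pq` for a
   heterozygote, from per-group haplotype frequencies.  Unknown
   haplotype frequencies are filled with ε = 10⁻⁵; observed zeros are
   kept as zeros.

Inferred diplotypes (plus directly read single-variant genotypes and
supplied HLA calls) are then matched against dosing-guideline records
(CPIC / DPWG / CPNDS / RNPGx style) to classify each drug as **avoid
use**, **use with caution**, or **routine use**, and against
evidence-graded clinical-annotation records to predict drug-response
phenotypes.  Directions are coded 0.5 (decreased), 1 (normal),
2 (increased); the per-drug, per-category mean translates to a
decreased (<1), normal (=1) or increased (>1) phenotype in each of
toxicity, dosage, efficacy and metabolism.  Avoid-use drugs get no
phenotype prediction.  Results are written as a self-contained HTML
report with a machine-readable JSON twin.

The package ships a synthetic-fixture generator (knowledgebase tables
and VCFs from chosen true diplotypes, with configurable dropout and
spurious-variant noise), so everything is testable offline.

## Worked example

Generate a two-gene synthetic knowledgebase and a sample VCF, then run
the full pipeline:

```sh
pgxcall fixtures --seed 2 --genes 2 --ambiguity -o demo
pgxcall run -i demo/SAMPLE.vcf -p EAS -k demo/kb -o demo/out
```

The run logs

```
INFO pgxcall: read 10/10 knowledgebase positions from demo/SAMPLE.vcf
INFO pgxcall: called 2/2 multi-variant genes
INFO pgxcall: drugs per category: {'avoid': 2, 'caution': 0, 'routine': 1}
```

and writes `demo/out.pgx.html` and `demo/out.pgx.json`.  The truth
sidecar (`demo/SAMPLE.vcf.truth.json`) says the sample was simulated
as `GENEA *1/*4`, `GENEB *4/*4`.  The JSON report contains:

```json
"GENEA": {"top": ["*2/*3"], "best_penalty": 0, "exact_match": true,
          "top_frequency": 0.07801437377929688, ...}
"GENEB": {"top": ["*4/*4"], "best_penalty": 0, "exact_match": true, ...}
```

`GENEB` is recovered exactly.  `GENEA` illustrates the core
phenomenon: `*1/*4` and `*2/*3` are indistinguishable from unphased
genotypes (both expect a heterozygous variant at each of the same two
loci), and `*2/*3` is the more frequent pair in EAS, so the ranking
reports it — penalty 0, frequency 0.078.  One triggered drug record
integrates two metabolism annotations with mean score
(0.5 + 2)/2 = 1.25 > 1, i.e. a predicted *increased* metabolism
phenotype:

```json
"drug5": {"category": "routine",
          "phenotypes": {"metabolism": {"direction": "increased",
                                        "mean_score": 1.25, ...}}}
```

## Knowledgebase format

A knowledgebase is a directory of six tab-separated files
(`alleles.tsv`, `frequencies.tsv`, `guidelines.tsv`,
`clinical_annotations.tsv`, `single_variant_alleles.tsv`,
`hla_alleles.tsv`), each starting with `#format=pgxkb-1 build=GRCh38`.
Schemas are documented in `pgxcall/kb.py`; the shipped default
registry of multi-variant genes covers the 13 pharmacogenes whose star
alleles are defined on more than one variant (CYP2B6, CYP2C19,
CYP2C8, CYP2C9, CYP2D6, CYP3A4, CYP3A5, CYP4F2, DPYD, NUDT15,
SLCO1B1, TPMT, UGT1A1).

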