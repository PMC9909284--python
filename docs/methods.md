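# Methods

## Model and procedure

### Diplotype space

A gene's star alleles are haplotype definitions: the reference
(wild-type) haplotype declares no variants; every other haplotype
declares one alternate allele at each of one or more positions.  The
gene's *position set* is the union of declared positions across its
haplotypes; positions outside it are never consulted.  With H
haplotypes there are H(H+1)/2 candidate diplotypes (unordered pairs
with repetition).  A diplotype's *combined definition* assigns every
position of the position set the unordered pair of alleles its two
haplotypes carry there, an undeclared haplotype contributing the
reference base.  Two diplotypes with equal combined definitions are
*indistinguishable*: no unphased genotype data can separate them.

### Consistency scoring

Observed genotypes are unordered allele pairs (phase separators in the
VCF are deliberately ignored; short reads cannot establish parental
origin, and the model is defined for unphased input).  For each
candidate, per position:

* position *declared* by the candidate (at least one constituent
  haplotype declares a variant there): observed pair equal to the
  expected pair → contributes 0; unequal → the candidate is
  **disqualified**.  A diplotype that requires, say, a homozygous
  alternate cannot be rescued by a heterozygous observation.
* position undeclared (expected homozygous reference): equal → 0;
  unequal → **−1**.  The sample carries something the candidate does
  not explain; that argues against it without ruling it out.
* position missing (no VCF record, or `./.`): skipped and counted.
  Absence of coverage is not evidence of a reference genotype;
  treating it as such would silently disqualify true calls.

The candidate's score is the penalty sum over non-missing positions
(always ≤ 0).

### Two-step ranking

Disqualified candidates are removed.  Among the rest, candidates with
the maximal penalty (closest to zero) are kept; among those, the ones
with the maximal Hardy–Weinberg frequency in the sample's
biogeographic group: `p²` for homozygotes, `2pq` for heterozygotes,
from the per-group haplotype frequency table.  Frequency comparison is
exact — frequencies are derived deterministically, so equality is
meaningful.  Residual ties (e.g. equal-frequency members of one
indistinguishable group) are all reported in canonical label order;
fabricating a unique answer would hide genuine ambiguity.  A call is
an *exact match* when its penalty is 0 and no declared position was
skipped for missingness.

Edge cases: if every position of a gene is missing the gene is
reported *not tested*; if every candidate is disqualified the call is
*undeterminable* (empty top set, not an exception).  The latter can
only occur for a gene without a wild-type haplotype, since the
reference homozygote declares nothing and can never be disqualified.

### Frequencies

Haplotype frequencies are stored per gene and per biogeographic group
(AAC, AME, SAS, EAS, EUR, LAT, NEA, OCE, SSA).  Where a haplotype
frequency must be derived from its defining variants' frequencies, the
minimum across variants is used — a haplotype cannot be more common
than its rarest defining variant — and a null (unmeasured) frequency
for any defining variant makes the haplotype's frequency null for that
group, since a minimum over partially known values would overstate
confidence.  Nulls are then filled with ε = 10⁻⁵ (configurable,
strictly positive).  An observed zero is information — the population
essentially cannot carry the haplotype — and is preserved, never
replaced by ε.  Frequencies are not renormalized per gene and group;
they are taken as recorded.

### Clinical annotation

A guideline or annotation record is *triggered*/*matched* when its
(gene, genotype key) equals one of the sample's call keys: any member
of a ranked top set (each residually tied diplotype can trigger
records), a single-variant genotype string such as `T/T`, or an HLA
allele name.  Drug classification is most-conservative across sources
(avoid > caution > routine), and a population-dependent or multi-gene
recommendation is escalated to at least caution even if its own
category is routine.  Phenotype integration pools matched annotation
records per (drug, category) across genes — the drug-centric
one-to-many view — codes directions 0.5 / 1 / 2, and averages without
evidence-level weighting (the mean is the stated statistic; weighting
would be an undocumented extension).  The mean is compared to 1 with a
1e-9 tolerance: the scores are dyadic rationals but the mean is
accumulated in floating point.  Avoid-use drugs are excluded from
phenotype prediction entirely.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `epsilon` | 1e-5 | fill value for null haplotype frequencies (dimensionless frequency) |
| `respect_filter` | off | drop non-PASS VCF records; off by default because upstream pipelines differ in FILTER usage |
| `dropout_rate` | 0.0 | fixture generator: per-locus probability that a target record is absent |
| `spurious_rate` | 0.0 | fixture generator: per-locus probability of an artifactual heterozygous call at a locus the truth does not declare |
| mean-equality tolerance | 1e-9 | threshold for calling an integrated phenotype "normal" |

## Synthetic study conditions

The fixture generator emulates the *structure* of a pharmacogenomic
knowledgebase, not its content: toy genes with one reference haplotype
and 3–6 alternates declaring 4–8 SNV positions (defaults; ranges are
configurable), per-group haplotype frequencies drawn as dyadic
rationals (denominator 1024) summing to exactly 1 per gene and group
so Hardy–Weinberg conservation is testable to 1e-12, and guideline and
annotation records keyed to generated diplotypes.  With
`ambiguity=True` the first gene receives haplotypes declaring {v},
{w} and {v,w}, which makes `*1/*4` and `*2/*3` a guaranteed
indistinguishable pair.  A single pseudo-random stream seeded once
drives every decision in documented order (genes sorted, loci sorted,
dropout before spurious per locus), so outputs are byte-reproducible.

What the generator does **not** emulate: linkage disequilibrium
between alleles (the UGT1A1-style haplotype co-occurrence that real
callers must reason about), CNV/SV-defined alleles, indel-rich repeat
regions, multi-variant noise correlated along reads, and realistic
frequency spectra.  Passing the recovery experiments therefore shows
that the ranking machinery is correct, not that real-sample
concordance would match any published benchmark.

### Recovery experiments and identifiability

With zero noise, a candidate scores penalty 0 and survives
disqualification exactly when its combined definition equals the
observed genotypes — that is, exactly the members of the truth's
indistinguishability class.  The frequency step then keeps the
class's most frequent member(s).  A truth that is *not*
frequency-maximal within its class is therefore unrecoverable in
principle; the method by design reports its more frequent twin.  The
recovery experiments draw truths from the identifiable set (the
method's range: distinguishable diplotypes plus frequency-maximal
class members) and assert 100% recovery over 200 seeded noiseless
replicates, with uniqueness whenever the combined definition is
unique.  A separate test pins the complementary behavior: a
non-maximal twin is called as its more frequent partner, and the call
never leaves the truth's class.  With spurious noise only (which by
construction lands at loci the truth does not declare), the truth is
penalized but never disqualified.

## Numerical and representational choices

* Variants are normalized to a left-aligned parsimonious form (shared
  suffix trimmed, then shared prefix with the position advanced); the
  operation is idempotent and SNVs pass through unchanged.
  Multi-allelic VCF records are split per ALT before matching.
* All coordinates are 1-based GRCh38, as in VCF; no 0-based
  conversion exists anywhere in the package.
* Diplotype labels are canonical `A/B` with A ≤ B lexicographically;
  every enumeration and report output is deterministically sorted.
* The cross-population coefficient of variation of a diplotype's
  frequency uses the population (n-denominator) standard deviation
  over exactly the nine groups — they are an exhaustive partition,
  not a sample — computed on ε-filled frequencies.
* Report timestamps are injected by the caller, never read from the
  clock inside the renderer, so identical inputs yield byte-identical
  HTML and JSON.
* The HTML renderer uses a minimal block-substitution template
  (`{{block}}` slots); a custom template missing a required block
  fails with an error naming the block.  A JSON twin is always
  emitted beside the HTML so downstream pipelines need not scrape
  markup.

## Known limitations

* Alleles defined on copy-number or structural variants are out of
  scope: they are not representable in typical germline VCFs.
* HLA alleles are consumed as provided calls (symbolic ALT entries or
  a sidecar file), never typed from reads.
* No linkage-disequilibrium reasoning: haplotype pairs are scored
  independently per gene.
* Disease/indication context is ignored in phenotype integration.
* Problem sizes in the shipped experiments (3 toy genes, up to 7
  haplotypes, 200 replicates; 500 random instances for oracle
  equivalence) were chosen to exercise every code path, including
  forced indistinguishable pairs, while keeping the suite quick to
  run.
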