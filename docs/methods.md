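# Methods

This note describes the models and procedures `zcrtools` implements, the
assumptions behind them, the design of the synthetic study the test suite
runs on, and the numerical choices that matter. Nothing here states an
empirical result the tests or `scripts/acceptance.py` do not themselves
compute.

## Coordinate model

Everything internal is 0-based, half-open. GFF3 (1-based, closed) is
converted on read and write; BED and bedGraph are native; VCF POS is
converted on read. A single convention removes the classic off-by-one bug
family; the round-trip property tests (`tests/test_io_formats.py`) verify
that read∘write is the identity on valid inputs.

## Zero-coverage regions (ZCRs)

A ZCR is a maximal run of reference bases at which a sample's coverage
track is zero, after masking assembly gaps, with run length ≥ `min_length`
(default 2000 bp, boundary inclusive — "at least 2 kb" reads as ≥). ZCRs
proxy for homozygous deletion or sequence so divergent that reads fail to
map; a coverage track cannot distinguish the two, and the package does not
try.

Gap handling: assembly gaps are runs of N in the reference, so no read can
map inside them and they must not count as evidence of absence. Two
semantics are implemented:

* **non-bridging** (default): a gap terminates a zero run. A ZCR is never
  called across a gap. This is the conservative choice — it cannot
  manufacture a ≥2 kb call out of two short flanking runs.
* **bridging** (`bridge_gaps=True`): zero runs separated only by gap bases
  merge; the qualifying length counts non-gap zero bases only, and the
  reported interval spans the gap.

The detector works by interval algebra (complement of positive-depth
intervals, minus gaps, length filter); its oracle in the test suite is a
literal per-base scan over numpy arrays, and the two are required to agree
exactly on randomized gappy tracks.

Genome ZCR fraction is 100 × ZCR bases / denominator. The default
denominator is full assembly length (including gaps); a non-gap denominator
is available because upstream gap-masking workflows make either reading
defensible.

## Gene flagging and gene-set summaries

A gene is ZCR-flagged when ≥ 1 base of ≥ 1 exon of its canonical
transcript intersects ≥ 1 ZCR (half-open intersection). Exons, not CDS and
not the gene span: intron-only overlap does not flag. Per-sample flags are
OR-ed into a combined list over a shared gene universe; per gene set the
flagged percentage is reported per sample and for the combined column, to
one decimal. The combined percentage is necessarily ≥ every per-sample
percentage (union monotonicity), which the tests assert.

Canonical transcript: an explicit `canonical`/`Ensembl_canonical` attribute
wins; otherwise the longest CDS; ties break to the lexicographically
smallest transcript id. Real annotations delegate this to the annotation
provider; the rule above makes the choice deterministic for annotations
that carry no tag. Flagging uses the canonical transcript's exons by
default; `read_gff3_genes(..., exon_union=True)` substitutes the merged
exon union over all transcripts, and `flag_genes_by_zcr(..., use_cds=True)`
restricts the intersection to coding segments.

## Variant metrics

Records are decomposed biallelic alleles (one per ALT); type is SNV
(|ref| = |alt| = 1), insertion/deletion (prefix rule), or other.
Hard filtering follows the GATK convention: a record is removed iff any
configured rule for its type fires; a record *missing* an annotation is
never failed by that rule. Default thresholds are GATK's generic germline
recommendations (SNV: QD < 2, FS > 60, MQ < 40, MQRankSum < −12.5,
ReadPosRankSum < −8; indel: QD < 2, FS > 200, ReadPosRankSum < −20) and are
fully user-overridable, since production pipelines tune these per study.
Hard filtering is idempotent and rule-monotone (removing a rule never
removes more records); both are tested.

Zygosity: over a sample's non-reference, non-missing genotypes,
heterozygous means exactly one copy of the record's alternate allele,
homozygous means two; `0/0` and missing contribute nothing. Haploid calls
carrying the alternate count as homozygous (logged). Density is the
per-sample count of carried records per kilobase of assembly (gaps
included by default, configurable).

## Composite per-gene dN/dS

The statistic is a raw count ratio, not a substitution-model estimate:
no site/branch models, no codon-frequency or opportunity normalisation.
For each decomposed SNV inside the canonical CDS, the affected codon is
built from the spliced CDS (reverse-complemented for minus-strand genes),
the alternate base substituted (complemented on minus strand), and both
codons translated with the standard genetic code. Same amino acid →
synonymous; different, including stop gain/loss → non-synonymous. Indels,
UTR/intron and intergenic alleles are `noncoding_or_other` and never enter
the counts.

Counts pool **distinct alternate alleles** across samples: an allele
carried by all three samples counts once (`per_occurrence=True` switches to
per-carrier counting). dN/dS is defined only when dS > 0; genes with
dN > 0, dS = 0 stay in the census without a ratio and are *not* called
positively selected (an optional add-one pseudo-count mode exists, off by
default). Positive selection is a strict dN/dS > 1; the "high" tier is
ratio ≥ 10 (boundary inclusive). The Manhattan-ready table reports
log10(dN/dS) per gene at the gene-span midpoint, excluding genes where the
log is undefined (dN = 0 or dS = 0); ratio 1 maps to 0, the neutral line.

The classifier is verified exhaustively: all 64 codons × 3 positions × 3
alternates (576 cases), against an independent hand-frozen codon table, on
both strands. A VEP-style TSV ingest path bypasses the internal classifier
for externally annotated data, mapping terms through an explicit editable
table (missense/stop_gained/stop_lost/start_lost → non-synonymous;
synonymous/stop_retained → synonymous; anything else → other).

## Enrichment and list comparison

Over-representation uses the one-sided upper-tail hypergeometric
probability P(X ≥ k) for drawing n query genes from a universe of N with K
term members, computed by `scipy.stats.hypergeom`; q-values are
Benjamini–Hochberg step-up over the tested terms (terms with k = 0 are
omitted). The universe defaults to all genes in the annotation; callers can
restrict it. Against enumeration the tail probability is exact for every
parameter combination with N ≤ 12 (tested). `compare_gene_sets` partitions
two lists into shared / A-only / B-only counts with percentages of the
union rounded to one decimal.

## Locus presence/absence and haplotype patterns

A locus (user-supplied named interval; gene spans or cluster segments are
typical) is called *absent* in a sample when that sample's ZCRs cover
≥ 50% of the locus (boundary inclusive; threshold configurable). This is a
declared operationalisation of what a human calls "missing" when reading a
coverage plot — there is no field-standard cutoff. Discordant loci have
non-constant call vectors across samples. Complementary pairs are loci
whose binary vectors are exact complements with neither vector constant:
the coverage signature of two alternative haplotypes assembled in tandem
in a composite reference, where each individual carries one or the other.

## The synthetic study

The generator emulates the study design the pipeline targets: deep
whole-genome resequencing of two clonal (parthenogenesis-derived,
effectively homozygous diploid) individuals and one outbred individual
against one reference.

Defaults (all configurable via `SyntheticConfig`):

| parameter | default | why |
|---|---|---|
| chromosomes | 2 Mb + 1 Mb + 0.5 Mb | full pipeline in seconds |
| genes | 200 (60 NLR-like, 20 MHC-like, 120 scattered) | enough for enrichment statistics |
| NLR-like cluster | 40% of the large chromosome's right arm | mirrors a chromosome-arm immune-gene expansion |
| MHC-like locus | compact 120 kb | mirrors a dense MHC-class locus |
| gaps | 3 per chromosome, 5–20 kb | exercises gap masking |
| mean depth | 50–60× | deep-coverage design |
| het fraction | 0.03 clonal / 0.60 outbred | clonal lines are nearly homozygous; outbred individuals are not |
| SNV density | 5.0/kb per sample | high-diversity genome |
| indel density | 1.2/kb per sample | ~4-fold below SNVs |
| selection classes | 30 positive, 40 purifying, 130 neutral | recovery testing at realistic imbalance |
| carrier probability | 0.65 | samples share most variation |

Because `snv_per_kb` is a *per-sample* density and each sample carries a
pool variant with probability 0.65, the shared pool is scaled by 1/0.65.

Coverage is piecewise-constant: 500 bp windows with zero-truncated Poisson
depths (at depth ≥ 30 the truncated mass is ~1e-20, so means are
unaffected). Planted absent blocks and gaps are simply omitted from the
track (bedGraph semantics: unlisted = 0). An optional noise process plants
sub-threshold zero runs (100–1500 bp < the 2 kb ZCR floor) to exercise the
length filter; noise runs are kept ≥ 2 kb away from block and gap edges so
they can never extend a planted run. Together these guarantees make
planted-block recovery exact — boundaries and all — for every seed,
noise on or off, which the acceptance checks rely on.

Planted absence structure: the MHC-like locus is split into two sub-loci
with complementary patterns (outbred sample lacks one, both clonal lines
lack the other); the NLR-like cluster gets an independent per-sample
patchwork (each 50 kb segment absent with probability 0.4); three
background blocks per sample land anywhere *outside* the clusters (so the
complementary pattern survives any seed) and may straddle gaps, in which
case the truth is trimmed to the non-gap remainder.

Coding variants are planted per gene to match its selection class
(positive: dN = 4·dS + extra with dS ≥ 1, so the ratio is well above 1;
neutral: dN, dS ~ Poisson(3); purifying: dS ≥ 3 ≫ dN), choosing random CDS
positions and alternate bases and keeping only candidates whose classified
effect matches the target — so truth labels are exact by construction, and
an independent exhaustive test keeps the classifier honest. Background
SNVs and indels avoid CDS so planted counts stay interpretable. Genotypes:
each sample carries each variant with probability 0.65 (at least one
carrier forced); carriers are heterozygous at the sample's het fraction,
else homozygous-alt. Site annotations are drawn so ~3% of records fail the
default QD hard filter.

Randomness: one master seed; per-stage and per-sample substreams are
derived from SHA-256 of the stage/sample name combined with the seed, so
adding a sample never perturbs the others and every artifact is
byte-reproducible.

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: read-level effects (mapping ambiguity,
sequencing error, GC bias), mappability structure, heterozygous deletions
(which produce *low*, not zero, coverage), linkage between coverage and
genotypes (a sample can carry a variant inside its own absent block),
divergence as distinct from absence, and realistic gene structure (UTRs,
alternative isoforms, overlapping genes). ZCR-based analysis is by design
insensitive to regional polymorphism that preserves some read mapping.

## Pipeline

`run_pipeline` wires the stages over files in the same formats a real
study provides (chrom.sizes + gaps BED + per-sample bedGraph, optionally
GFF3, FASTA, VCF, gene-set/term TSVs, loci BED4). Stages with missing
inputs are skipped with an explicit notice in the manifest; a failed run
removes its partial outputs (unless the output directory pre-existed with
content). Wall-clock timings go to the log, never into outputs, so reports
are byte-identical across reruns with the same seed. bigWig input is out
of scope for the core: the textual bedGraph equivalent is consumed
directly, and conversion belongs upstream of the CLI.

## Problem sizes used by the checks

The default synthetic scale — 3.5 Mb over three chromosomes, 200 genes,
three samples, ~27k pooled variant records — was chosen so that a full
generate-plus-pipeline cycle completes in a few seconds and the whole
suite in well under a minute of compute per run, while keeping every
statistic (binomial bounds on ~15k genotypes per sample, hypergeometric
recovery of 30/200 planted genes) far from small-sample noise.

## Known limitations

* Composite dN/dS on raw counts is biased relative to opportunity-corrected
  estimators (roughly 3× more non-synonymous sites per codon than
  synonymous); it is a screening statistic, and the >1 threshold inherits
  that bias.
* Heterozygous alleles count once, not per chromosome copy.
* The absence threshold (0.5) and the ZCR minimum length (2 kb) are
  step functions; loci near the boundary flip with small coverage changes.
* No GO DAG propagation or semantic summarisation; terms are flat sets.
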