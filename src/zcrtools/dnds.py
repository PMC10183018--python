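"""Composite per-gene dN/dS from variant consequences.

Coding single-nucleotide variants are classified as synonymous or
non-synonymous against the canonical transcript by substituting the
alternate base into the affected codon and translating both codons with the
standard genetic code (stop gain/loss counts as non-synonymous). Distinct
alternate alleles are pooled across samples into per-gene dN and dS counts;
the composite ratio dN/dS is defined only for genes with dS > 0, and a
ratio above 1 is read as evidence of positive selection.

This is a raw count ratio — no substitution model, no site or branch
models, no codon-frequency normalisation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .io_formats import GeneModel, GenomeLayout, VariantRecord, VariantTable
from .variant_metrics import SNV, classify_variant

log = logging.getLogger(__name__)

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
OTHER = "noncoding_or_other"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# VEP-style consequence terms accepted by the TSV ingest path.
VEP_TERM_MAP = {
    "missense_variant": NONSYNONYMOUS,
    "stop_gained": NONSYNONYMOUS,
    "stop_lost": NONSYNONYMOUS,
    "start_lost": NONSYNONYMOUS,
    "synonymous_variant": SYNONYMOUS,
    "stop_retained_variant": SYNONYMOUS,
}


class DataIntegrityError(ValueError):
    """Reference sequence disagrees with a variant's stated REF allele."""


@dataclass
class ConsequenceCall:
    gene_id: str
    transcript_id: str
    allele: tuple[str, int, str, str]
    klass: str


@dataclass
class GeneDnDs:
    """Per-gene pooled non-synonymous (dN) and synonymous (dS) counts."""

    gene_id: str
    dN: int
    dS: int

    @property
    def ratio(self) -> float | None:
        """dN/dS; undefined (None) when the gene has no synonymous variants."""
        if self.dS == 0:
            return None
        return self.dN / self.dS

    @property
    def log10_ratio(self) -> float | None:
        ratio = self.ratio
        if ratio is None or ratio == 0:
            return None
        return math.log10(ratio)


class _SplicedCDS:
    """Cached spliced CDS for one gene with genomic->CDS position mapping."""

    def __init__(self, gene: GeneModel, chrom_seq: str):
        self.gene = gene
        parts = [chrom_seq[s:e].upper() for s, e in gene.cds]
        plus = "".join(parts)
        self.length = len(plus)
        if gene.strand == "+":
            self.seq = plus
        else:
            self.seq = plus.translate(_COMPLEMENT)[::-1]

    def cds_index(self, pos0: int) -> int | None:
        """Index into the (stranded) spliced CDS, or None outside the CDS."""
        offset = 0
        for s, e in self.gene.cds:
            if s <= pos0 < e:
                plus_offset = offset + (pos0 - s)
                if self.gene.strand == "+":
                    return plus_offset
                return self.length - 1 - plus_offset
            offset += e - s
        return None


def classify_consequence(
    gene: GeneModel,
    ref_sequence: str,
    allele: VariantRecord,
    *,
    _cache: dict | None = None,
) -> ConsequenceCall:
    """Classify one decomposed allele against the gene's canonical CDS."""
    key = (gene.chrom, allele.pos0, allele.ref, allele.alt)
    if classify_variant(allele) != SNV:
        log.warning("non-SNV allele %s excluded from dN/dS", key)
        return ConsequenceCall(gene.gene_id, gene.transcript_id, key, OTHER)
    if ref_sequence[allele.pos0].upper() != allele.ref:
        raise DataIntegrityError(
            f"reference mismatch at {gene.chrom}:{allele.pos0}: "
            f"sequence has {ref_sequence[allele.pos0]!r}, record says {allele.ref!r}"
        )
    if _cache is not None and gene.gene_id in _cache:
        spliced = _cache[gene.gene_id]
    else:
        spliced = _SplicedCDS(gene, ref_sequence)
        if _cache is not None:
            _cache[gene.gene_id] = spliced
    idx = spliced.cds_index(allele.pos0)
    if idx is None:
        return ConsequenceCall(gene.gene_id, gene.transcript_id, key, OTHER)
    codon_start = (idx // 3) * 3
    within = idx % 3
    codon = spliced.seq[codon_start:codon_start + 3]
    alt_base = allele.alt if gene.strand == "+" else allele.alt.translate(_COMPLEMENT)
    new_codon = codon[:within] + alt_base + codon[within + 1:]
    old_aa = str(Seq(codon).translate())
    new_aa = str(Seq(new_codon).translate())
    klass = SYNONYMOUS if old_aa == new_aa else NONSYNONYMOUS
    return ConsequenceCall(gene.gene_id, gene.transcript_id, key, klass)


def count_gene_dnds(
    table: VariantTable,
    genes: list[GeneModel],
    ref_sequences: dict[str, str],
    *,
    per_occurrence: bool = False,
) -> list[GeneDnDs]:
    """Pool per-gene dN/dS counts over distinct alternate alleles.

    Each distinct (chrom, pos0, ref, alt) carried by at least one sample
    counts once per gene regardless of how many samples carry it; with
    ``per_occurrence=True`` it instead counts once per carrying sample.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for gene in genes:
        by_chrom.setdefault(gene.chrom, []).append(gene)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: g.span)

    cache: dict = {}
    counts: dict[str, list[int]] = {g.gene_id: [0, 0] for g in genes}
    seen: set[tuple] = set()
    for rec in table.records:
        if rec.key in seen:
            continue
        seen.add(rec.key)
        if classify_variant(rec) != SNV:
            continue  # indels/MNVs never enter dN/dS
        carriers = (
            sum(1 for s in table.samples if rec.alt_copies(s))
            if table.samples else 1
        )
        if table.samples and carriers == 0:
            continue
        weight = carriers if per_occurrence else 1
        for gene in by_chrom.get(rec.chrom, []):
            span = gene.span
            if not (span[0] <= rec.pos0 < span[1]):
                continue
            call = classify_consequence(
                gene, ref_sequences[rec.chrom], rec, _cache=cache
            )
            if call.klass == NONSYNONYMOUS:
                counts[gene.gene_id][0] += weight
            elif call.klass == SYNONYMOUS:
                counts[gene.gene_id][1] += weight
    return [
        GeneDnDs(gene_id=gid, dN=dn, dS=ds)
        for gid, (dn, ds) in counts.items()
        if dn or ds
    ]


def positive_selection_set(
    results: list[GeneDnDs], threshold: float = 1.0, high: float = 10.0,
    *, pseudocount: bool = False,
) -> tuple[set[str], set[str]]:
    """Genes with defined dN/dS strictly above ``threshold``; and >= ``high``.

    Genes with dS = 0 have no defined ratio and never enter either set.
    With ``pseudocount=True`` the ratio is (dN + 1) / (dS + 1) for every
    gene, which gives dS = 0 genes a (shrunken) ratio.
    """
    positive = set()
    high_ratio = set()
    for res in results:
        ratio = (res.dN + 1) / (res.dS + 1) if pseudocount else res.ratio
        if ratio is None:
            continue
        if ratio > threshold:
            positive.add(res.gene_id)
        if ratio >= high:
            high_ratio.add(res.gene_id)
    return positive, high_ratio


def manhattan_table(
    results: list[GeneDnDs], genes: list[GeneModel],
    layout: GenomeLayout | None = None,
) -> pd.DataFrame:
    """Plot-ready rows (chrom, midpoint, gene_id, log10 dN/dS).

    Genes with undefined ratio (dS = 0) or dN = 0 (log10 undefined) are
    excluded. A ratio of 1 maps to 0, the neutral line.
    """
    gene_map = {g.gene_id: g for g in genes}
    rows = []
    for res in results:
        log_ratio = res.log10_ratio
        if log_ratio is None:
            continue
        gene = gene_map[res.gene_id]
        span = gene.span
        rows.append(
            {
                "chrom": gene.chrom,
                "midpoint": (span[0] + span[1]) // 2,
                "gene_id": res.gene_id,
                "log10_ratio": log_ratio,
            }
        )
    df = pd.DataFrame(rows, columns=["chrom", "midpoint", "gene_id", "log10_ratio"])
    if layout is not None:
        order = {name: i for i, name in enumerate(layout.names)}
        df["_order"] = df["chrom"].map(order)
    else:
        df["_order"] = df["chrom"]
    df = df.sort_values(["_order", "midpoint"]).drop(columns="_order")
    return df.reset_index(drop=True)


def read_vep_consequences(path) -> list[ConsequenceCall]:
    """Ingest a VEP-style TSV (gene, transcript, chrom, pos0, ref, alt, term).

    Terms are mapped through :data:`VEP_TERM_MAP`; unmapped terms become
    noncoding_or_other. This path bypasses the internal codon classifier for
    real-data use where consequences were annotated externally.
    """
    calls = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene_id, tid, chrom, pos0, ref, alt, term = line.split("\t")[:7]
            calls.append(
                ConsequenceCall(
                    gene_id=gene_id, transcript_id=tid,
                    allele=(chrom, int(pos0), ref, alt),
                    klass=VEP_TERM_MAP.get(term, OTHER),
                )
            )
    return calls


def count_from_calls(calls: list[ConsequenceCall]) -> list[GeneDnDs]:
    """Accumulate GeneDnDs from pre-computed consequence calls (deduplicated)."""
    counts: dict[str, list[int]] = {}
    seen = set()
    for call in calls:
        dedup_key = (call.gene_id, call.allele)
        if dedup_key in seen:
            continue
        seen.add(dedup_key)
        if call.klass not in (SYNONYMOUS, NONSYNONYMOUS):
            continue
        slot = counts.setdefault(call.gene_id, [0, 0])
        slot[0 if call.klass == NONSYNONYMOUS else 1] += 1
    return [GeneDnDs(gene_id=g, dN=dn, dS=ds) for g, (dn, ds) in counts.items()]
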