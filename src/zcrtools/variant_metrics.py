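"""Hard filtering and per-sample variant summaries.

Implements the post-calling summarisation layer: type classification
(SNV / insertion / deletion), GATK-style hard filters on site annotations,
heterozygous/homozygous genotype partitions, and per-kilobase densities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .io_formats import GenomeLayout, VariantRecord, VariantTable

log = logging.getLogger(__name__)

SNV = "SNV"
INSERTION = "insertion"
DELETION = "deletion"
OTHER = "other"
INDEL = "indel"

_COMPARATORS = {
    "<": lambda value, threshold: value < threshold,
    ">": lambda value, threshold: value > threshold,
    "<=": lambda value, threshold: value <= threshold,
    ">=": lambda value, threshold: value >= threshold,
}

# GATK's generic germline hard-filter recommendations; fully overridable.
DEFAULT_SNV_RULES = [
    ("QD", "<", 2.0),
    ("FS", ">", 60.0),
    ("MQ", "<", 40.0),
    ("MQRankSum", "<", -12.5),
    ("ReadPosRankSum", "<", -8.0),
]
DEFAULT_INDEL_RULES = [
    ("QD", "<", 2.0),
    ("FS", ">", 200.0),
    ("ReadPosRankSum", "<", -20.0),
]


@dataclass
class FilterConfig:
    """Per-variant-type hard-filter rules; a record fails if any rule fires.

    Records missing an annotation are never failed by that rule (the GATK
    VariantFiltration convention).
    """

    snv_rules: list[tuple[str, str, float]] = field(
        default_factory=lambda: list(DEFAULT_SNV_RULES)
    )
    indel_rules: list[tuple[str, str, float]] = field(
        default_factory=lambda: list(DEFAULT_INDEL_RULES)
    )

    def __post_init__(self) -> None:
        for name, cmp, threshold in self.snv_rules + self.indel_rules:
            if cmp not in _COMPARATORS:
                raise ValueError(f"unknown comparator {cmp!r} in rule {name}")
            if not (threshold == threshold and abs(threshold) != float("inf")):
                raise ValueError(f"non-finite threshold in rule {name}")

    def rules_for(self, vtype: str) -> list[tuple[str, str, float]]:
        if vtype == SNV:
            return self.snv_rules
        if vtype in (INSERTION, DELETION):
            return self.indel_rules
        return []


@dataclass
class ZygosityCounts:
    sample_id: str
    n_het_snv: int = 0
    n_hom_snv: int = 0
    n_het_indel: int = 0
    n_hom_indel: int = 0

    @property
    def het_fraction_snv(self) -> float:
        total = self.n_het_snv + self.n_hom_snv
        return self.n_het_snv / total if total else 0.0

    @property
    def het_fraction_indel(self) -> float:
        total = self.n_het_indel + self.n_hom_indel
        return self.n_het_indel / total if total else 0.0


@dataclass
class DensityReport:
    sample_id: str
    n_snv: int
    n_indel: int
    genome_length: int

    @property
    def snv_per_kb(self) -> float:
        return self.n_snv / (self.genome_length / 1000.0)

    @property
    def indel_per_kb(self) -> float:
        return self.n_indel / (self.genome_length / 1000.0)


def classify_variant(record: VariantRecord) -> str:
    """SNV, insertion, deletion or other, from a decomposed biallelic record."""
    ref, alt = record.ref, record.alt
    if len(ref) == 1 and len(alt) == 1:
        return SNV
    if len(alt) > len(ref) and alt.startswith(ref):
        return INSERTION
    if len(ref) > len(alt) and ref.startswith(alt):
        return DELETION
    return OTHER


def hard_filter(table: VariantTable, config: FilterConfig | None = None) -> VariantTable:
    """Remove records for which any configured rule for their type fires."""
    if config is None:
        config = FilterConfig()
    kept = []
    for rec in table.records:
        rules = config.rules_for(classify_variant(rec))
        fails = False
        for name, cmp, threshold in rules:
            value = rec.info.get(name)
            if value is not None and _COMPARATORS[cmp](value, threshold):
                fails = True
                break
        if not fails:
            kept.append(rec)
    return VariantTable(samples=table.samples, records=kept)


def zygosity_partition(table: VariantTable, sample_id: str) -> ZygosityCounts:
    """Het/hom counts over the sample's non-reference, non-missing genotypes.

    Het = exactly one copy of the record's alternate allele; hom = two.
    Haploid genotypes carrying the alternate count as homozygous (logged).
    """
    if sample_id not in table.samples:
        raise ValueError(f"sample {sample_id!r} not in table")
    counts = ZygosityCounts(sample_id=sample_id)
    haploid_seen = 0
    for rec in table.records:
        gt = rec.genotypes.get(sample_id)
        if gt is None or any(a is None for a in gt):
            continue
        n_alt = sum(1 for a in gt if a == 1)
        if n_alt == 0:
            continue
        vtype = classify_variant(rec)
        if vtype == SNV:
            bucket = "snv"
        elif vtype in (INSERTION, DELETION):
            bucket = "indel"
        else:
            continue
        if len(gt) == 1:
            haploid_seen += 1
            zyg = "hom"
        else:
            zyg = "het" if n_alt == 1 else "hom"
        attr = f"n_{zyg}_{bucket}"
        setattr(counts, attr, getattr(counts, attr) + 1)
    if haploid_seen:
        log.info(
            "%s: %d haploid genotypes counted as homozygous", sample_id, haploid_seen
        )
    return counts


def variant_density(
    table: VariantTable, sample_id: str, layout: GenomeLayout,
    *, exclude_gaps: bool = False,
) -> DensityReport:
    """SNVs/kb and indels/kb for one sample over the assembly length.

    A sample contributes a record iff its genotype carries that record's
    alternate allele. Denominator defaults to the full assembly length
    including gaps.
    """
    genome_length = layout.total_length(exclude_gaps=exclude_gaps)
    if genome_length <= 0:
        raise ValueError("zero-length genome")
    n_snv = n_indel = 0
    for rec in table.records:
        copies = rec.alt_copies(sample_id)
        if not copies:
            continue
        vtype = classify_variant(rec)
        if vtype == SNV:
            n_snv += 1
        elif vtype in (INSERTION, DELETION):
            n_indel += 1
    return DensityReport(
        sample_id=sample_id, n_snv=n_snv, n_indel=n_indel,
        genome_length=genome_length,
    )


def density_table(
    table: VariantTable, layout: GenomeLayout, labels: dict[str, str] | None = None
) -> pd.DataFrame:
    """Variant-density summary rows (sample, genome label, SNVs/kb, InDels/kb)."""
    rows = []
    for sample in table.samples:
        report = variant_density(table, sample, layout)
        rows.append(
            {
                "sample": sample,
                "genome": (labels or {}).get(sample, ""),
                "snv_per_kb": round(report.snv_per_kb, 4),
                "indel_per_kb": round(report.indel_per_kb, 4),
                "n_snv": report.n_snv,
                "n_indel": report.n_indel,
                "genome_length": report.genome_length,
            }
        )
    return pd.DataFrame(rows)


def zygosity_table(table: VariantTable) -> pd.DataFrame:
    """Het/hom counts and percentages per sample and variant type."""
    rows = []
    for sample in table.samples:
        counts = zygosity_partition(table, sample)
        for vtype, het, hom in (
            (SNV, counts.n_het_snv, counts.n_hom_snv),
            (INDEL, counts.n_het_indel, counts.n_hom_indel),
        ):
            total = het + hom
            rows.append(
                {
                    "sample": sample,
                    "type": vtype,
                    "n_het": het,
                    "n_hom_alt": hom,
                    "pct_het": round(100.0 * het / total, 1) if total else 0.0,
                    "pct_hom": round(100.0 * hom / total, 1) if total else 0.0,
                }
            )
    return pd.DataFrame(rows)
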