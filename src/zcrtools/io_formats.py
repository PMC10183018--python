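"""Readers and writers for the genomic formats the pipeline touches.

Everything is normalised to a single internal coordinate convention:
0-based, half-open intervals. GFF3 (1-based, closed) is converted on read
and write; BED and bedGraph are native. VCF POS is converted to 0-based and
multi-allelic sites are decomposed into one record per alternate allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from . import _intervals

log = logging.getLogger(__name__)

Interval = tuple[int, int]


class FormatError(ValueError):
    """A file violates its format contract (overlap, bad value, bad column)."""


class MalformedAnnotationError(FormatError):
    """A gene model violates a structural invariant (e.g. CDS length % 3)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeLayout:
    """Chromosome names/lengths plus assembly-gap intervals.

    Gaps are runs of unknown bases (N) in the reference; no read can map
    inside them, so zero-coverage analysis must mask them.
    """

    chromosomes: list[tuple[str, int]]
    gaps: dict[str, list[Interval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        if len(lengths) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        for chrom, ivs in self.gaps.items():
            if chrom not in lengths:
                raise ValueError(f"gap chromosome {chrom} not in layout")
            _intervals.validate(ivs, bound=lengths[chrom])

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def total_length(self, *, exclude_gaps: bool = False) -> int:
        total = sum(length for _, length in self.chromosomes)
        if exclude_gaps:
            total -= sum(
                _intervals.total_length(ivs) for ivs in self.gaps.values()
            )
        return total

    def chrom_gaps(self, chrom: str) -> list[Interval]:
        return self.gaps.get(chrom, [])


@dataclass
class GeneModel:
    """A gene with its canonical transcript's exon and CDS intervals."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval]
    transcript_id: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"gene {self.gene_id}: unknown strand {self.strand!r}"
            )
        try:
            _intervals.validate(self.exons)
            _intervals.validate(self.cds)
        except ValueError as exc:
            raise MalformedAnnotationError(f"gene {self.gene_id}: {exc}") from exc
        if self.cds_length % 3 != 0:
            raise MalformedAnnotationError(
                f"gene {self.gene_id}: CDS length {self.cds_length} "
                "not divisible by 3"
            )
        if self.cds and self.exons:
            span = (self.exons[0][0], self.exons[-1][1])
            if self.cds[0][0] < span[0] or self.cds[-1][1] > span[1]:
                raise MalformedAnnotationError(
                    f"gene {self.gene_id}: CDS outside exon span"
                )

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def cds_length(self) -> int:
        return _intervals.total_length(self.cds)


@dataclass
class CoverageTrack:
    """Per-chromosome read depth over half-open intervals.

    Positions not covered by any stated interval have depth 0, matching
    bedGraph semantics where untracked bases default to zero.
    """

    intervals: dict[str, list[tuple[int, int, float]]]

    def __post_init__(self) -> None:
        for chrom, ivs in self.intervals.items():
            prev_end = -1
            for start, end, depth in ivs:
                if start >= end:
                    raise FormatError(f"{chrom}: empty interval ({start},{end})")
                if depth < 0:
                    raise FormatError(f"{chrom}: negative depth {depth}")
                if start < prev_end:
                    raise FormatError(
                        f"{chrom}: overlapping/unsorted intervals at {start}"
                    )
                prev_end = end

    def chroms(self) -> list[str]:
        return list(self.intervals)

    def positive_intervals(self, chrom: str) -> list[Interval]:
        """Merged intervals with depth strictly greater than zero."""
        return _intervals.merge(
            [(s, e) for s, e, d in self.intervals.get(chrom, []) if d > 0]
        )


@dataclass
class VariantRecord:
    """One decomposed (biallelic) variant allele.

    ``genotypes[sample]`` is a tuple of allele codes restricted to this
    record's alternate: 1 = this alt, 0 = any other allele, None = missing.
    """

    chrom: str
    pos0: int
    ref: str
    alt: str
    info: dict[str, float] = field(default_factory=dict)
    genotypes: dict[str, tuple | None] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos0, self.ref, self.alt)

    def alt_copies(self, sample: str) -> int | None:
        """Number of copies of this alt carried by the sample; None if missing."""
        gt = self.genotypes.get(sample)
        if gt is None or any(a is None for a in gt):
            return None
        return sum(1 for a in gt if a == 1)


@dataclass
class VariantTable:
    samples: list[str]
    records: list[VariantRecord]

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_CANONICAL_TAGS = ("Ensembl_canonical", "canonical")


def _transcript_sort_key(cds_len: int, transcript_id: str):
    # longest CDS wins; ties broken by lexicographically smallest id
    return (-cds_len, transcript_id)


def read_gff3_genes(path: str | Path, *, exon_union: bool = False) -> list[GeneModel]:
    """Parse gene models from GFF3, selecting one canonical transcript each.

    Canonical choice: a transcript carrying a ``canonical`` /
    ``Ensembl_canonical`` attribute wins; otherwise the longest CDS, ties
    broken by smallest transcript id. Coordinates are converted from GFF3's
    1-based closed convention to 0-based half-open. With ``exon_union=True``
    the exon set becomes the merged union over all of the gene's
    transcripts (the CDS stays canonical).
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        if gene.strand not in ("+", "-"):
            raise FormatError(
                f"gene {gene.id}: unknown strand symbol {gene.strand!r}"
            )
        candidates = []
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = sorted(
                (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
            )
            cds = sorted(
                (f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")
            )
            cds_len = sum(e - s for s, e in cds)
            tagged = any(tag in mrna.attributes for tag in _CANONICAL_TAGS)
            candidates.append((tagged, cds_len, mrna.id, exons, cds))
        if not candidates:
            continue
        tagged_set = [c for c in candidates if c[0]]
        pool = tagged_set or candidates
        pool.sort(key=lambda c: _transcript_sort_key(c[1], c[2]))
        _, _, tid, exons, cds = pool[0]
        if exon_union:
            exons = _intervals.merge(
                [iv for c in candidates for iv in c[3]]
            )
        genes.append(
            GeneModel(
                gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
                exons=exons, cds=cds, transcript_id=tid,
            )
        )
    return genes


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (1-based closed), one mRNA per gene."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start, end = g.span
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tzcrtools\tgene\t{start + 1}\t{end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chrom}\tzcrtools\tmRNA\t{start + 1}\t{end}\t.\t"
                f"{g.strand}\t.\tID={g.transcript_id};Parent={g.gene_id};"
                "canonical=1\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tzcrtools\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"Parent={g.transcript_id}\n"
                )
            for s, e in g.cds:
                fh.write(
                    f"{g.chrom}\tzcrtools\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"Parent={g.transcript_id}\n"
                )


# ---------------------------------------------------------------------------
# bedGraph / BED / chrom.sizes
# ---------------------------------------------------------------------------


def read_bedgraph(path: str | Path) -> CoverageTrack:
    """Read a bedGraph coverage track; unlisted positions have depth 0."""
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            chrom, start, end, value = parts
            try:
                s, e, v = int(start), int(end), float(value)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if v < 0:
                raise FormatError(f"{path}:{lineno}: negative value {v}")
            per_chrom.setdefault(chrom, []).append((s, e, v))
    for chrom, ivs in per_chrom.items():
        ivs.sort()
        prev_end = -1
        for s, e, _ in ivs:
            if s < prev_end:
                raise FormatError(f"{path}: overlapping intervals on {chrom}")
            prev_end = e
    return CoverageTrack(intervals=per_chrom)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, ivs in track.intervals.items():
            for s, e, v in ivs:
                v_str = f"{v:g}"
                fh.write(f"{chrom}\t{s}\t{e}\t{v_str}\n")


def read_bed_intervals(path: str | Path) -> dict[str, list[Interval]]:
    """Read 3+-column BED into per-chromosome sorted interval lists."""
    per_chrom: dict[str, list[Interval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            per_chrom.setdefault(chrom, []).append((start, end))
    for chrom, ivs in per_chrom.items():
        ivs.sort()
        _intervals.validate(ivs)
    return per_chrom


def write_bed(intervals: dict[str, list[Interval]], path: str | Path) -> None:
    """Write per-chromosome sorted non-overlapping intervals as BED3."""
    for chrom, ivs in intervals.items():
        try:
            _intervals.validate(ivs)
        except ValueError as exc:
            raise FormatError(f"{chrom}: {exc}") from exc
    with open(path, "w") as fh:
        for chrom, ivs in intervals.items():
            for s, e in ivs:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def read_chrom_sizes(path: str | Path) -> list[tuple[str, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            name, length = line.split()[:2]
            out.append((name, int(length)))
    return out


def write_chrom_sizes(chromosomes: list[tuple[str, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in chromosomes:
            fh.write(f"{name}\t{length}\n")


def read_layout(sizes_path: str | Path, gaps_bed: str | Path | None = None) -> GenomeLayout:
    chromosomes = read_chrom_sizes(sizes_path)
    gaps = read_bed_intervals(gaps_bed) if gaps_bed else {}
    return GenomeLayout(chromosomes=chromosomes, gaps=gaps)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_SYMBOLIC = set("<>[]*")
_BASES = set("ACGT")


def read_vcf(path: str | Path) -> VariantTable:
    """Read a VCF into decomposed per-alternate-allele records.

    Multi-allelic sites become one record per alternate allele; within each
    record, genotype alleles equal to that alternate are coded 1, all other
    called alleles 0, and missing alleles None. Symbolic alleles are skipped
    with a warning. Phased and unphased separators are both accepted
    (cyvcf2 handles either).
    """
    vcf = VCF(str(path))
    if "##FORMAT=<ID=GT" not in vcf.raw_header:
        raise FormatError(f"{path}: VCF has no GT FORMAT field")
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    seen: set[tuple[str, int, str, str]] = set()
    for variant in vcf:
        info = {
            k: float(v)
            for k, v in dict(variant.INFO).items()
            if isinstance(v, (int, float))
        }
        genotypes = variant.genotypes  # [allele_a, allele_b, phased] per sample
        for alt_idx, alt in enumerate(variant.ALT, start=1):
            ref = variant.REF
            if _SYMBOLIC & (set(alt) | set(ref)) or not (
                set(alt) <= _BASES and set(ref) <= _BASES
            ):
                log.warning(
                    "skipping symbolic/non-ACGT allele %s>%s at %s:%s",
                    ref, alt, variant.CHROM, variant.POS,
                )
                continue
            key = (variant.CHROM, variant.POS - 1, ref, alt)
            if key in seen:
                continue
            seen.add(key)
            gts: dict[str, tuple | None] = {}
            for sample, gt in zip(samples, genotypes):
                alleles = tuple(
                    None if a == -1 else (1 if a == alt_idx else 0)
                    for a in gt[:-1]
                )
                gts[sample] = alleles if alleles else None
            records.append(
                VariantRecord(
                    chrom=variant.CHROM, pos0=variant.POS - 1,
                    ref=ref, alt=alt, info=info, genotypes=gts,
                )
            )
    return VariantTable(samples=samples, records=records)


_INFO_DEFS = ["QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum"]


def write_vcf(
    table: VariantTable,
    path: str | Path,
    chromosomes: list[tuple[str, int]] | None = None,
) -> None:
    """Write biallelic records as a minimal VCF 4.2 with GT genotypes."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=zcrtools\n")
        if chromosomes:
            for name, length in chromosomes:
                fh.write(f"##contig=<ID={name},length={length}>\n")
        for key in _INFO_DEFS:
            fh.write(
                f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples) + "\n"
        )
        order = {name: i for i, (name, _) in enumerate(chromosomes or [])}
        for rec in sorted(
            table.records, key=lambda r: (order.get(r.chrom, 0), r.chrom, r.pos0)
        ):
            info = ";".join(
                f"{k}={rec.info[k]:.4g}" for k in _INFO_DEFS if k in rec.info
            ) or "."
            gt_strs = []
            for sample in table.samples:
                gt = rec.genotypes.get(sample)
                if gt is None:
                    gt_strs.append("./.")
                else:
                    gt_strs.append("/".join("." if a is None else str(a) for a in gt))
            fh.write(
                f"{rec.chrom}\t{rec.pos0 + 1}\t.\t{rec.ref}\t{rec.alt}\t.\t.\t"
                f"{info}\tGT\t" + "\t".join(gt_strs) + "\n"
            )


# ---------------------------------------------------------------------------
# simple TSV catalogs
# ---------------------------------------------------------------------------


def read_two_column_tsv(path: str | Path) -> dict[str, set[str]]:
    """Read gene_id <tab> group TSV into group -> set of gene ids."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene_id, group = line.split("\t")[:2]
            out.setdefault(group, set()).add(gene_id)
    return out


def write_two_column_tsv(groups: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for group in sorted(groups):
            for gene_id in sorted(groups[group]):
                fh.write(f"{gene_id}\t{group}\n")
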