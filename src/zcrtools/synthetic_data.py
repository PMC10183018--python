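"""Synthetic multi-sample resequencing study with planted ground truth.

Generates a toy reference genome (three chromosomes with assembly gaps),
gene models grouped into an MHC-like compact cluster and an NLR-like
cluster filling one chromosome arm, and three samples mirroring the study
design this package targets: two clonal lines whose variants are almost all
homozygous, and one outbred individual with a high heterozygous fraction.

Each sample carries planted "absent blocks" — regions with no mapped
coverage, standing in for homozygous deletions or highly divergent
haplotypes (the two are indistinguishable to a coverage track). The MHC-like
locus gets a complementary pattern: one sub-locus absent only in the outbred
sample, a neighbouring sub-locus absent only in the two clonal lines,
emulating alternative haplotypes assembled in tandem in the reference.

Coding variants are planted per gene according to an assigned selection
class (positive: dN >> dS; neutral; purifying: dS >> dN), with every planted
allele verified against the codon classifier so truth labels are exact.

All randomness flows from one master seed; per-sample and per-stage
substreams are derived from (seed, stage, sample) so adding a sample never
perturbs the others.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import _intervals
from .dnds import NONSYNONYMOUS, SYNONYMOUS, classify_consequence
from .io_formats import (
    CoverageTrack,
    GeneModel,
    GenomeLayout,
    VariantRecord,
    VariantTable,
    write_bed,
    write_bedgraph,
    write_chrom_sizes,
    write_fasta,
    write_gff3,
    write_two_column_tsv,
    write_vcf,
)

Interval = tuple[int, int]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class ConfigurationError(ValueError):
    """The requested synthetic layout cannot be realised (e.g. genes do not fit)."""


def _rng(seed: int, *stream: str) -> np.random.Generator:
    """Deterministic substream derived from (seed, stage names)."""
    digest = hashlib.sha256("/".join(stream).encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class ClusterSpec:
    name: str
    chrom: str
    interval: Interval
    n_genes: int


@dataclass
class SampleSpec:
    """Study-design parameters for one sample (absent blocks are planted later)."""

    sample_id: str
    mean_depth: float
    het_fraction: float
    clonal: bool


@dataclass
class SyntheticConfig:
    """Defaults emulate the study design at desk scale.

    Three chromosomes (2 Mb / 1 Mb / 0.5 Mb); 200 genes of which 60 fill an
    NLR-like cluster spanning 40% of the large chromosome's right arm and
    20 form an MHC-like compact locus; two clonal deep-coverage samples and
    one outbred sample; ~5 SNVs/kb and ~1.2 indels/kb.
    """

    chromosomes: list[tuple[str, int]] = field(
        default_factory=lambda: [
            ("chr1", 2_000_000), ("chr2", 1_000_000), ("chr3", 500_000)
        ]
    )
    clusters: list[ClusterSpec] = field(
        default_factory=lambda: [
            ClusterSpec("nlr_like", "chr1", (1_200_000, 2_000_000), 60),
            ClusterSpec("mhc_like", "chr2", (400_000, 520_000), 20),
        ]
    )
    n_scattered_genes: int = 120
    n_gaps_per_chrom: int = 3
    gap_length: tuple[int, int] = (5_000, 20_000)
    exon_count: tuple[int, int] = (2, 4)
    exon_length: tuple[int, int] = (150, 500)
    intron_length: tuple[int, int] = (200, 1_000)
    n_positive: int = 30
    n_purifying: int = 40
    snv_per_kb: float = 5.0
    indel_per_kb: float = 1.2
    carrier_prob: float = 0.65
    coverage_window: int = 500
    noise_runs_per_mb: float = 2.0
    noise_length: tuple[int, int] = (100, 1_500)
    min_zcr_length: int = 2_000
    samples: list[SampleSpec] = field(
        default_factory=lambda: [
            SampleSpec("cg1", mean_depth=55.0, het_fraction=0.03, clonal=True),
            SampleSpec("cg2", mean_depth=60.0, het_fraction=0.03, clonal=True),
            SampleSpec("ab3", mean_depth=50.0, het_fraction=0.60, clonal=False),
        ]
    )


@dataclass
class SampleProfile:
    """One sample's coverage profile, including planted absent blocks."""

    sample_id: str
    absent_blocks: dict[str, list[Interval]]
    mean_depth: float
    het_fraction: float
    clonal: bool

    def __post_init__(self) -> None:
        if not 0 <= self.het_fraction <= 1:
            raise ValueError("het_fraction must lie in [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        for chrom, blocks in self.absent_blocks.items():
            _intervals.validate(blocks)


@dataclass
class ReferenceBundle:
    layout: GenomeLayout
    sequences: dict[str, str]
    genes: list[GeneModel]
    gene_sets: dict[str, set[str]]
    term_map: dict[str, set[str]]
    named_loci: list[tuple[str, str, int, int]]


@dataclass
class TruthBundle:
    """Planted ground truth for recovery tests."""

    planted_zcr_truth: dict[str, dict[str, list[Interval]]]
    gene_omega_class: dict[str, str]
    variant_truth_class: dict[tuple[str, int, str, str], str]


@dataclass
class StudyBundle:
    config: SyntheticConfig
    seed: int
    reference: ReferenceBundle
    profiles: list[SampleProfile]
    tracks: dict[str, CoverageTrack]
    variants: VariantTable
    truth: TruthBundle


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------


def _place_interval(
    rng: np.random.Generator,
    region: Interval,
    length: int,
    occupied: list[Interval],
    margin: int = 50,
    retries: int = 500,
) -> Interval:
    lo, hi = region
    if hi - lo < length:
        raise ConfigurationError(f"region {region} too small for length {length}")
    for _ in range(retries):
        start = int(rng.integers(lo, hi - length + 1))
        candidate = (start - margin, start + length + margin)
        if not any(s < candidate[1] and candidate[0] < e for s, e in occupied):
            return (start, start + length)
    raise ConfigurationError(
        f"could not place an interval of {length} bp in {region} "
        f"after {retries} attempts"
    )


def _make_gene(
    rng: np.random.Generator, gene_id: str, chrom: str, region: Interval,
    occupied: list[Interval], config: SyntheticConfig,
) -> GeneModel:
    n_exons = int(rng.integers(config.exon_count[0], config.exon_count[1] + 1))
    exon_lens = rng.integers(
        config.exon_length[0], config.exon_length[1] + 1, n_exons
    ).tolist()
    rem = sum(exon_lens) % 3
    exon_lens[-1] -= rem
    intron_lens = rng.integers(
        config.intron_length[0], config.intron_length[1] + 1, max(n_exons - 1, 0)
    ).tolist()
    span_len = sum(exon_lens) + sum(intron_lens)
    start, _ = _place_interval(rng, region, span_len, occupied)
    exons = []
    cursor = start
    for i, ex_len in enumerate(exon_lens):
        exons.append((cursor, cursor + ex_len))
        cursor += ex_len
        if i < len(intron_lens):
            cursor += intron_lens[i]
    strand = "+" if rng.random() < 0.5 else "-"
    occupied.append((exons[0][0], exons[-1][1]))
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand,
        exons=exons, cds=list(exons), transcript_id=f"{gene_id}.t1",
    )


def generate_reference(
    config: SyntheticConfig | None = None, seed: int = 0
) -> ReferenceBundle:
    """Deterministic toy reference: layout, sequences, genes and catalogs."""
    if config is None:
        config = SyntheticConfig()
    lengths = dict(config.chromosomes)
    cluster_regions: dict[str, list[Interval]] = {}
    for cluster in config.clusters:
        if cluster.chrom not in lengths:
            raise ConfigurationError(f"cluster on unknown chromosome {cluster.chrom}")
        cluster_regions.setdefault(cluster.chrom, []).append(cluster.interval)

    # assembly gaps, placed outside cluster regions
    gap_rng = _rng(seed, "gaps")
    gaps: dict[str, list[Interval]] = {}
    for chrom, length in config.chromosomes:
        occupied = list(cluster_regions.get(chrom, []))
        placed = []
        for _ in range(config.n_gaps_per_chrom):
            gap_len = int(
                gap_rng.integers(config.gap_length[0], config.gap_length[1] + 1)
            )
            iv = _place_interval(
                gap_rng, (0, length), gap_len, occupied, margin=5_000
            )
            occupied.append(iv)
            placed.append(iv)
        gaps[chrom] = sorted(placed)
    layout = GenomeLayout(chromosomes=list(config.chromosomes), gaps=gaps)

    # genes: cluster members first, then scattered genes outside clusters
    gene_rng = _rng(seed, "genes")
    occupied_by_chrom: dict[str, list[Interval]] = {
        chrom: list(gaps[chrom]) for chrom, _ in config.chromosomes
    }
    genes: list[GeneModel] = []
    gene_sets: dict[str, set[str]] = {}
    for cluster in config.clusters:
        members = set()
        for i in range(cluster.n_genes):
            gene = _make_gene(
                gene_rng, f"{cluster.name}_{i + 1:03d}", cluster.chrom,
                cluster.interval, occupied_by_chrom[cluster.chrom], config,
            )
            genes.append(gene)
            members.add(gene.gene_id)
        gene_sets[cluster.name] = members
    chrom_weights = np.array([length for _, length in config.chromosomes], float)
    chrom_weights /= chrom_weights.sum()
    for i in range(config.n_scattered_genes):
        chrom_idx = int(gene_rng.choice(len(config.chromosomes), p=chrom_weights))
        chrom, length = config.chromosomes[chrom_idx]
        region = (0, length)
        # scattered genes stay outside the clusters
        occupied = occupied_by_chrom[chrom] + cluster_regions.get(chrom, [])
        gene = _make_gene(
            gene_rng, f"gene_{i + 1:03d}", chrom, region, occupied, config
        )
        occupied_by_chrom[chrom].append(gene.span)
        genes.append(gene)

    # sequences: random bases, N over gaps
    seq_rng = _rng(seed, "sequence")
    sequences: dict[str, str] = {}
    for chrom, length in config.chromosomes:
        arr = _BASES[seq_rng.integers(0, 4, length)]
        for s, e in gaps[chrom]:
            arr[s:e] = b"N"
        sequences[chrom] = arr.tobytes().decode()

    # annotation terms: an immune-like term covering the clusters, plus
    # random terms so enrichment has a background
    term_rng = _rng(seed, "terms")
    all_ids = [g.gene_id for g in genes]
    term_map: dict[str, set[str]] = {
        "immune_like": set().union(*gene_sets.values())
    }
    for i in range(8):
        size = min(int(term_rng.integers(15, 41)), len(all_ids))
        term_map[f"term_{i + 1:02d}"] = set(
            term_rng.choice(all_ids, size=size, replace=False).tolist()
        )

    named_loci = _default_loci(config)
    return ReferenceBundle(
        layout=layout, sequences=sequences, genes=genes,
        gene_sets=gene_sets, term_map=term_map, named_loci=named_loci,
    )


def _mhc_subloci(config: SyntheticConfig) -> tuple[ClusterSpec, Interval, Interval] | None:
    for cluster in config.clusters:
        if cluster.name == "mhc_like":
            start, end = cluster.interval
            width = end - start
            locus_a = (start, start + int(0.45 * width))
            locus_b = (start + int(0.55 * width), end)
            return cluster, locus_a, locus_b
    return None


def _default_loci(config: SyntheticConfig) -> list[tuple[str, str, int, int]]:
    """Named loci for haplotype-pattern comparison."""
    loci: list[tuple[str, str, int, int]] = []
    mhc = _mhc_subloci(config)
    if mhc is not None:
        cluster, locus_a, locus_b = mhc
        loci.append(("mhc2dab_like_locus", cluster.chrom, *locus_a))
        loci.append(("mhc2dgb_like_locus", cluster.chrom, *locus_b))
    for cluster in config.clusters:
        if cluster.name == "nlr_like":
            start, end = cluster.interval
            seg = 50_000
            for i, pos in enumerate(range(start, end, seg)):
                loci.append(
                    (f"nlr_segment_{i + 1:02d}", cluster.chrom, pos, min(pos + seg, end))
                )
    return loci


# ---------------------------------------------------------------------------
# sample profiles (planted absent blocks)
# ---------------------------------------------------------------------------


def generate_profiles(
    reference: ReferenceBundle, config: SyntheticConfig, seed: int
) -> list[SampleProfile]:
    """Plant per-sample absent blocks: complementary MHC-like sub-loci,
    a per-sample patchwork over the NLR-like cluster, and a few random
    background blocks."""
    profiles = []
    mhc = _mhc_subloci(config)
    nlr = next((c for c in config.clusters if c.name == "nlr_like"), None)
    for spec in config.samples:
        rng = _rng(seed, "absent", spec.sample_id)
        blocks: dict[str, list[Interval]] = {c: [] for c, _ in config.chromosomes}
        if mhc is not None:
            cluster, locus_a, locus_b = mhc
            # outbred sample lacks sub-locus A; clonal lines lack sub-locus B
            blocks[cluster.chrom].append(locus_b if spec.clonal else locus_a)
        if nlr is not None:
            start, end = nlr.interval
            seg = 50_000
            for pos in range(start, end, seg):
                if rng.random() < 0.4:
                    blocks[nlr.chrom].append((pos, min(pos + seg, end)))
        # background blocks (may straddle gaps; truth is trimmed). They are
        # kept out of the cluster regions so the planted MHC-like
        # complementary pattern stays intact for every seed.
        lengths = reference.layout.lengths
        chroms = reference.layout.names
        cluster_by_chrom: dict[str, list[Interval]] = {}
        for cluster in config.clusters:
            cluster_by_chrom.setdefault(cluster.chrom, []).append(cluster.interval)
        for _ in range(3):
            for _attempt in range(100):
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                block_len = int(rng.integers(5_000, 30_001))
                pos = int(rng.integers(0, lengths[chrom] - block_len))
                candidate = (pos, pos + block_len)
                if not _intervals.overlaps_any(
                    [candidate], sorted(cluster_by_chrom.get(chrom, []))
                ):
                    blocks[chrom].append(candidate)
                    break
        merged = {c: _intervals.merge(v) for c, v in blocks.items() if v}
        profiles.append(
            SampleProfile(
                sample_id=spec.sample_id, absent_blocks=merged,
                mean_depth=spec.mean_depth, het_fraction=spec.het_fraction,
                clonal=spec.clonal,
            )
        )
    return profiles


def planted_zcr_truth(
    profile: SampleProfile, layout: GenomeLayout, min_length: int
) -> dict[str, list[Interval]]:
    """Non-gap sub-runs of the planted absent blocks of at least min_length.

    These are exactly the intervals a correct ZCR caller must report when
    coverage noise is disabled.
    """
    truth: dict[str, list[Interval]] = {}
    for chrom, blocks in profile.absent_blocks.items():
        gaps = layout.chrom_gaps(chrom)
        length = layout.lengths[chrom]
        clipped = _intervals.intersect(blocks, [(0, length)])
        runs = [
            iv
            for iv in _intervals.subtract(clipped, gaps)
            if iv[1] - iv[0] >= min_length
        ]
        if runs:
            truth[chrom] = runs
    return truth


# ---------------------------------------------------------------------------
# coverage simulation
# ---------------------------------------------------------------------------


def simulate_sample_coverage(
    layout: GenomeLayout,
    profile: SampleProfile,
    seed: int,
    *,
    window: int = 500,
    noise_runs_per_mb: float = 0.0,
    noise_length: tuple[int, int] = (100, 1_500),
    min_zcr_length: int = 2_000,
) -> CoverageTrack:
    """Piecewise-constant Poisson coverage with planted zero blocks.

    Depth over each ``window``-bp tile is a zero-truncated Poisson draw
    around ``mean_depth`` (truncation guarantees that the only zero runs are
    the planted absent blocks and, optionally, short noise runs; at the
    default depths the truncated mass is ~1e-20, so means are unaffected).
    Absent blocks and assembly gaps are simply omitted from the track, which
    leaves them at depth 0. Optional noise runs are shorter than
    ``min_zcr_length`` and are kept clear of block and gap boundaries so
    they can never extend a planted run.
    """
    rng = _rng(seed, "coverage", profile.sample_id)
    lengths = layout.lengths
    track: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, length in layout.chromosomes:
        blocks = profile.absent_blocks.get(chrom, [])
        for s, e in blocks:
            if s < 0 or e > length:
                raise ValueError(
                    f"absent block ({s},{e}) outside chromosome {chrom}"
                )
        masked = _intervals.merge(list(layout.chrom_gaps(chrom)) + list(blocks))
        available = _intervals.complement(masked, length)
        # optional sub-threshold zero-noise runs, away from masked edges
        noise: list[Interval] = []
        n_noise = int(round(noise_runs_per_mb * length / 1e6))
        guard = min_zcr_length
        for _ in range(n_noise):
            run_len = int(rng.integers(noise_length[0], min(noise_length[1], min_zcr_length - 1) + 1))
            candidates = [
                (s + guard, e - guard - run_len)
                for s, e in available
                if e - s > 2 * guard + run_len
            ]
            if not candidates:
                continue
            lo, hi = candidates[int(rng.integers(0, len(candidates)))]
            start = int(rng.integers(lo, hi + 1))
            noise.append((start, start + run_len))
        covered = _intervals.subtract(available, _intervals.merge(noise))
        ivs: list[tuple[int, int, float]] = []
        for s, e in covered:
            pos = s
            n_win = (e - s + window - 1) // window
            depths = rng.poisson(profile.mean_depth, n_win)
            depths = np.maximum(depths, 1)  # zero-truncation
            for d in depths:
                win_end = min(pos + window, e)
                ivs.append((pos, win_end, float(d)))
                pos = win_end
        track[chrom] = ivs
    return CoverageTrack(intervals=track)


# ---------------------------------------------------------------------------
# variant simulation
# ---------------------------------------------------------------------------

POSITIVE = "positive"
NEUTRAL = "neutral"
PURIFYING = "purifying"


@dataclass
class EvolutionConfig:
    """Per-class (dN, dS) count distributions, as Poisson rates/offsets."""

    positive_ds_base: int = 1
    positive_ds_lam: float = 0.5
    positive_dn_factor: int = 4
    positive_dn_extra: float = 2.0
    neutral_lam: float = 3.0
    purifying_dn_lam: float = 0.5
    purifying_ds_base: int = 3
    purifying_ds_lam: float = 3.0


def assign_omega_classes(
    reference: ReferenceBundle, config: SyntheticConfig, seed: int
) -> dict[str, str]:
    """Assign selection classes; positive genes concentrate in the NLR-like
    cluster (two thirds), mirroring the expectation that one chromosome arm
    shows the positive-selection trend."""
    rng = _rng(seed, "omega")
    all_ids = [g.gene_id for g in reference.genes]
    nlr_ids = sorted(reference.gene_sets.get("nlr_like", set()))
    n_pos_nlr = min(2 * config.n_positive // 3, len(nlr_ids))
    positive = set(rng.choice(nlr_ids, size=n_pos_nlr, replace=False).tolist())
    remaining = [g for g in all_ids if g not in positive]
    extra = config.n_positive - n_pos_nlr
    positive |= set(rng.choice(remaining, size=extra, replace=False).tolist())
    remaining = [g for g in all_ids if g not in positive]
    purifying = set(
        rng.choice(remaining, size=config.n_purifying, replace=False).tolist()
    )
    classes = {}
    for gid in all_ids:
        if gid in positive:
            classes[gid] = POSITIVE
        elif gid in purifying:
            classes[gid] = PURIFYING
        else:
            classes[gid] = NEUTRAL
    return classes


def _draw_class_counts(
    rng: np.random.Generator, klass: str, evo: EvolutionConfig
) -> tuple[int, int]:
    if klass == POSITIVE:
        ds = evo.positive_ds_base + int(rng.poisson(evo.positive_ds_lam))
        dn = evo.positive_dn_factor * ds + int(rng.poisson(evo.positive_dn_extra))
        return dn, ds
    if klass == PURIFYING:
        return (
            int(rng.poisson(evo.purifying_dn_lam)),
            evo.purifying_ds_base + int(rng.poisson(evo.purifying_ds_lam)),
        )
    return int(rng.poisson(evo.neutral_lam)), int(rng.poisson(evo.neutral_lam))


def _plant_coding_variant(
    rng: np.random.Generator,
    gene: GeneModel,
    seq: str,
    target_class: str,
    used: set[tuple[str, int]],
    retries: int = 400,
) -> VariantRecord | None:
    """Pick a CDS position and alt base whose translated effect matches
    ``target_class``, verified with the codon classifier."""
    cds_positions = [
        pos for s, e in gene.cds for pos in range(s, e)
    ]
    for _ in range(retries):
        pos0 = cds_positions[int(rng.integers(0, len(cds_positions)))]
        if (gene.chrom, pos0) in used:
            continue
        ref = seq[pos0]
        if ref not in "ACGT":
            continue
        alt = "ACGT"[int(rng.integers(0, 4))]
        if alt == ref:
            continue
        rec = VariantRecord(chrom=gene.chrom, pos0=pos0, ref=ref, alt=alt)
        call = classify_consequence(gene, seq, rec)
        if call.klass == target_class:
            used.add((gene.chrom, pos0))
            return rec
    return None


def simulate_variants(
    reference: ReferenceBundle,
    profiles: list[SampleProfile],
    seed: int,
    *,
    config: SyntheticConfig | None = None,
    evo: EvolutionConfig | None = None,
    omega_classes: dict[str, str] | None = None,
) -> tuple[VariantTable, TruthBundle]:
    """Plant coding variants per gene class plus background SNVs and indels.

    Genotypes: every variant is carried by each sample independently with
    ``carrier_prob`` (at least one carrier guaranteed); carriers are
    heterozygous at the sample's ``het_fraction``, otherwise homozygous-alt.
    Site annotations (QD, FS, MQ, rank sums) are drawn so that a small
    fraction of records fails standard hard filters.
    """
    if config is None:
        config = SyntheticConfig()
    if evo is None:
        evo = EvolutionConfig()
    if omega_classes is None:
        omega_classes = assign_omega_classes(reference, config, seed)

    rng = _rng(seed, "variants")
    used: set[tuple[str, int]] = set()
    records: list[VariantRecord] = []
    truth_class: dict[tuple[str, int, str, str], str] = {}

    # coding variants per gene, class-targeted
    for gene in reference.genes:
        klass = omega_classes[gene.gene_id]
        dn, ds = _draw_class_counts(rng, klass, evo)
        seq = reference.sequences[gene.chrom]
        for target, count in ((NONSYNONYMOUS, dn), (SYNONYMOUS, ds)):
            planted = 0
            while planted < count:
                rec = _plant_coding_variant(rng, gene, seq, target, used)
                if rec is None:
                    break  # gene too short/saturated; accept fewer
                records.append(rec)
                truth_class[rec.key] = target
                planted += 1

    # background (non-CDS) SNVs and indels
    cds_by_chrom: dict[str, list[Interval]] = {}
    for gene in reference.genes:
        cds_by_chrom.setdefault(gene.chrom, []).extend(gene.cds)
    for chrom in cds_by_chrom:
        cds_by_chrom[chrom] = _intervals.merge(cds_by_chrom[chrom])

    # snv_per_kb/indel_per_kb are per-sample densities; each sample carries
    # a variant with carrier_prob, so the shared pool is scaled up accordingly
    total_len = reference.layout.total_length()
    scale = 1.0 / config.carrier_prob
    n_snv_target = int(round(total_len / 1000 * config.snv_per_kb * scale))
    n_indel_target = int(round(total_len / 1000 * config.indel_per_kb * scale))
    n_background_snv = max(n_snv_target - len(records), 0)

    chrom_names = reference.layout.names
    lengths = reference.layout.lengths
    weights = np.array([lengths[c] for c in chrom_names], float)
    weights /= weights.sum()

    def _sample_position(span: int = 1) -> tuple[str, int] | None:
        for _ in range(50):
            chrom = chrom_names[int(rng.choice(len(chrom_names), p=weights))]
            pos0 = int(rng.integers(0, lengths[chrom] - span))
            if (chrom, pos0) in used:
                continue
            seq = reference.sequences[chrom]
            segment = seq[pos0:pos0 + span]
            if "N" in segment:
                continue
            cds = cds_by_chrom.get(chrom, [])
            if _intervals.overlaps_any([(pos0, pos0 + span)], cds):
                continue
            return chrom, pos0
        return None

    for _ in range(n_background_snv):
        hit = _sample_position()
        if hit is None:
            continue
        chrom, pos0 = hit
        ref = reference.sequences[chrom][pos0]
        alt = "ACGT"[int(rng.integers(0, 4))]
        while alt == ref:
            alt = "ACGT"[int(rng.integers(0, 4))]
        used.add((chrom, pos0))
        rec = VariantRecord(chrom=chrom, pos0=pos0, ref=ref, alt=alt)
        records.append(rec)
        truth_class[rec.key] = "noncoding"

    for _ in range(n_indel_target):
        indel_len = int(rng.integers(1, 6))
        is_deletion = rng.random() < 0.5
        span = 1 + indel_len if is_deletion else 1
        hit = _sample_position(span)
        if hit is None:
            continue
        chrom, pos0 = hit
        seq = reference.sequences[chrom]
        used.add((chrom, pos0))
        if is_deletion:
            ref = seq[pos0:pos0 + 1 + indel_len]
            alt = ref[0]
        else:
            ref = seq[pos0]
            alt = ref + "".join(
                "ACGT"[int(rng.integers(0, 4))] for _ in range(indel_len)
            )
        rec = VariantRecord(chrom=chrom, pos0=pos0, ref=ref, alt=alt)
        records.append(rec)
        truth_class[rec.key] = "noncoding"

    # genotypes and site annotations
    geno_rng = {
        p.sample_id: _rng(seed, "genotypes", p.sample_id) for p in profiles
    }
    info_rng = _rng(seed, "annotations")
    n = len(records)
    qd_fail = info_rng.random(n) < 0.03
    qd = np.where(
        qd_fail, info_rng.uniform(0.0, 1.9, n), info_rng.uniform(10.0, 35.0, n)
    )
    fs = np.abs(info_rng.normal(8.0, 10.0, n))
    mq = info_rng.normal(55.0, 3.0, n)
    mqrs = info_rng.normal(0.0, 2.0, n)
    rprs = info_rng.normal(0.0, 2.0, n)
    for i, rec in enumerate(records):
        rec.info = {
            "QD": round(float(qd[i]), 3),
            "FS": round(float(fs[i]), 3),
            "MQ": round(float(mq[i]), 3),
            "MQRankSum": round(float(mqrs[i]), 3),
            "ReadPosRankSum": round(float(rprs[i]), 3),
        }
        carriers = []
        for profile in profiles:
            if geno_rng[profile.sample_id].random() < config.carrier_prob:
                carriers.append(profile.sample_id)
        if not carriers:
            idx = int(info_rng.integers(0, len(profiles)))
            carriers = [profiles[idx].sample_id]
        gts: dict[str, tuple | None] = {}
        for profile in profiles:
            if profile.sample_id in carriers:
                het = geno_rng[profile.sample_id].random() < profile.het_fraction
                gts[profile.sample_id] = (0, 1) if het else (1, 1)
            else:
                gts[profile.sample_id] = (0, 0)
        rec.genotypes = gts

    order = {c: i for i, c in enumerate(chrom_names)}
    records.sort(key=lambda r: (order[r.chrom], r.pos0, r.alt))
    table = VariantTable(
        samples=[p.sample_id for p in profiles], records=records
    )
    truth = TruthBundle(
        planted_zcr_truth={},
        gene_omega_class=dict(omega_classes),
        variant_truth_class=truth_class,
    )
    return table, truth


# ---------------------------------------------------------------------------
# whole-study orchestration
# ---------------------------------------------------------------------------


def generate_study(
    config: SyntheticConfig | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
    *,
    noise: bool = True,
) -> StudyBundle:
    """Generate the full study: reference, profiles, coverage, variants, truth.

    With ``outdir`` set, writes every artifact in the same file formats the
    real-data path consumes (FASTA, GFF3, gap BED, chrom.sizes, per-sample
    bedGraph, one joint VCF, gene-set and gene-to-term TSVs) plus truth
    tables.
    """
    if config is None:
        config = SyntheticConfig()
    reference = generate_reference(config, seed)
    profiles = generate_profiles(reference, config, seed)
    noise_rate = config.noise_runs_per_mb if noise else 0.0
    tracks = {
        p.sample_id: simulate_sample_coverage(
            reference.layout, p, seed,
            window=config.coverage_window,
            noise_runs_per_mb=noise_rate,
            noise_length=config.noise_length,
            min_zcr_length=config.min_zcr_length,
        )
        for p in profiles
    }
    variants, truth = simulate_variants(
        reference, profiles, seed, config=config
    )
    truth = replace(
        truth,
        planted_zcr_truth={
            p.sample_id: planted_zcr_truth(
                p, reference.layout, config.min_zcr_length
            )
            for p in profiles
        },
    )
    bundle = StudyBundle(
        config=config, seed=seed, reference=reference, profiles=profiles,
        tracks=tracks, variants=variants, truth=truth,
    )
    if outdir is not None:
        write_study(bundle, outdir)
    return bundle


def write_study(bundle: StudyBundle, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = bundle.reference
    paths = {
        "fasta": outdir / "reference.fa",
        "gff3": outdir / "genes.gff3",
        "gaps": outdir / "gaps.bed",
        "sizes": outdir / "chrom.sizes",
        "vcf": outdir / "variants.vcf",
        "gene_sets": outdir / "gene_sets.tsv",
        "gene_terms": outdir / "gene_terms.tsv",
    }
    write_fasta(ref.sequences, paths["fasta"])
    write_gff3(ref.genes, paths["gff3"])
    write_bed(ref.layout.gaps, paths["gaps"])
    write_chrom_sizes(ref.layout.chromosomes, paths["sizes"])
    write_vcf(bundle.variants, paths["vcf"], chromosomes=ref.layout.chromosomes)
    write_two_column_tsv(ref.gene_sets, paths["gene_sets"])
    write_two_column_tsv(ref.term_map, paths["gene_terms"])
    for sample_id, track in bundle.tracks.items():
        path = outdir / f"{sample_id}.bedgraph"
        write_bedgraph(track, path)
        paths[f"bedgraph_{sample_id}"] = path
    with open(outdir / "loci.bed", "w") as fh:
        for name, chrom, start, end in ref.named_loci:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
    paths["loci"] = outdir / "loci.bed"
    # truth tables (synthetic ground truth, not pipeline output)
    with open(outdir / "truth_omega.tsv", "w") as fh:
        for gid in sorted(bundle.truth.gene_omega_class):
            fh.write(f"{gid}\t{bundle.truth.gene_omega_class[gid]}\n")
    with open(outdir / "truth_variants.tsv", "w") as fh:
        for key in sorted(bundle.truth.variant_truth_class):
            chrom, pos0, r, a = key
            fh.write(
                f"{chrom}\t{pos0}\t{r}\t{a}\t"
                f"{bundle.truth.variant_truth_class[key]}\n"
            )
    for sample_id, per_chrom in bundle.truth.planted_zcr_truth.items():
        write_bed(per_chrom, outdir / f"truth_zcr_{sample_id}.bed")
    return paths
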