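"""Locus-level presence/absence calls and haplotype patterns; pipeline driver.

A locus (a gene span, a cluster segment, any named interval) is called
"absent" in a sample when ZCRs cover at least a threshold fraction (default
0.5) of its length. Discordant loci differ between samples; complementary
locus pairs — where exactly the samples lacking one locus carry the other —
are the coverage signature of alternative haplotypes assembled in tandem in
the reference.
"""

from __future__ import annotations

import json
import logging
import shutil
import time
from dataclasses import dataclass
from importlib.metadata import version as _pkg_version
from pathlib import Path

import pandas as pd

from . import _intervals
from .dnds import count_gene_dnds, manhattan_table, positive_selection_set
from .enrichment import compare_gene_sets, hypergeom_enrichment
from .gene_overlap import combine_flags, flag_genes_by_zcr, geneset_zcr_summary
from .io_formats import (
    GenomeLayout,
    read_bedgraph,
    read_fasta,
    read_gff3_genes,
    read_layout,
    read_two_column_tsv,
    read_vcf,
)
from .variant_metrics import density_table, hard_filter, zygosity_table
from .zcr import ZCRSet, detect_zcrs, genome_zcr_fraction

log = logging.getLogger(__name__)

Locus = tuple[str, str, int, int]  # name, chrom, start, end


@dataclass
class PresenceAbsenceMatrix:
    """Per (locus, sample) ZCR-covered fraction and binary absence call."""

    loci: list[Locus]
    samples: list[str]
    fractions: pd.DataFrame  # index=locus name, columns=samples
    threshold: float

    @property
    def absent(self) -> pd.DataFrame:
        return self.fractions >= self.threshold


def locus_absence_matrix(
    zcrs_by_sample: dict[str, ZCRSet],
    loci: list[Locus],
    threshold: float = 0.5,
) -> PresenceAbsenceMatrix:
    """Fraction of each locus covered by each sample's ZCRs; absent at >= threshold."""
    if len(zcrs_by_sample) < 2:
        raise ValueError("need at least two samples")
    samples = list(zcrs_by_sample)
    data = {}
    for name, chrom, start, end in loci:
        if end <= start:
            raise ValueError(f"zero-length locus {name}")
        row = {}
        for sample in samples:
            hit = _intervals.intersect(
                [(start, end)], zcrs_by_sample[sample].chrom_intervals(chrom)
            )
            row[sample] = _intervals.total_length(hit) / (end - start)
        data[name] = row
    fractions = pd.DataFrame.from_dict(data, orient="index", columns=samples)
    fractions = fractions.reindex([l[0] for l in loci])
    return PresenceAbsenceMatrix(
        loci=loci, samples=samples, fractions=fractions, threshold=threshold
    )


def discordant_loci(matrix: PresenceAbsenceMatrix) -> list[str]:
    """Loci whose binary absence call differs between samples."""
    absent = matrix.absent
    return [
        name for name in absent.index
        if absent.loc[name].nunique() > 1
    ]


def complementary_pairs(matrix: PresenceAbsenceMatrix) -> list[tuple[str, str]]:
    """Locus pairs whose absence vectors are exact complements.

    Constant vectors (all samples absent, or all present) carry no
    between-sample signal and are excluded.
    """
    absent = matrix.absent
    names = list(absent.index)
    vectors = {name: tuple(absent.loc[name]) for name in names}
    pairs = []
    for i, a in enumerate(names):
        va = vectors[a]
        if len(set(va)) < 2:
            continue
        for b in names[i + 1:]:
            vb = vectors[b]
            if len(set(vb)) < 2:
                continue
            if all(x != y for x, y in zip(va, vb)):
                pairs.append((a, b))
    return pairs


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineInputs:
    """Resolved input paths for one run; any stage whose inputs are missing
    is skipped with an explicit notice."""

    sizes: Path
    gaps: Path | None
    bedgraphs: dict[str, Path]
    gff3: Path | None = None
    fasta: Path | None = None
    vcf: Path | None = None
    gene_sets: Path | None = None
    gene_terms: Path | None = None
    loci: Path | None = None


def _read_loci_bed(path: Path) -> list[Locus]:
    loci = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            loci.append((name, chrom, start, end))
    return loci


def run_pipeline(
    inputs: PipelineInputs,
    outdir: str | Path,
    *,
    min_zcr_length: int = 2000,
    absence_threshold: float = 0.5,
    seed: int = 0,
) -> dict:
    """Run detect -> flag -> summarize -> variant metrics -> dN/dS ->
    enrichment -> set comparison -> haplotype patterns, writing TSV/BED
    outputs plus a run manifest. Deterministic given the inputs and seed;
    partial outputs are removed on failure."""
    outdir = Path(outdir)
    preexisting = outdir.exists() and any(outdir.iterdir())
    if preexisting:
        log.info("output directory %s is not empty; files may be overwritten", outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.monotonic()
    manifest: dict = {
        "seed": seed,
        "min_zcr_length": min_zcr_length,
        "absence_threshold": absence_threshold,
        "version": _pkg_version("zcrtools"),
        "stages": {},
        "notices": [],
    }
    try:
        return _run_stages(inputs, outdir, manifest, min_zcr_length,
                           absence_threshold, t0)
    except Exception:
        # leave no partial report behind, but never delete a directory the
        # caller already had content in
        if not preexisting:
            shutil.rmtree(outdir, ignore_errors=True)
        raise


def _stage_done(manifest: dict, name: str, t_start: float) -> None:
    manifest["stages"][name] = round(time.monotonic() - t_start, 3)
    log.info("stage %s finished in %.2fs", name, manifest["stages"][name])


def _run_stages(
    inputs: PipelineInputs, outdir: Path, manifest: dict,
    min_zcr_length: int, absence_threshold: float, t0: float,
) -> dict:
    results: dict = {"outdir": outdir, "manifest": manifest}

    for required in [inputs.sizes, *inputs.bedgraphs.values()]:
        if not Path(required).exists():
            raise FileNotFoundError(f"missing input: {required}")
    for optional in (inputs.gff3, inputs.fasta, inputs.vcf, inputs.gene_sets,
                     inputs.gene_terms, inputs.loci, inputs.gaps):
        if optional is not None and not Path(optional).exists():
            raise FileNotFoundError(f"missing input: {optional}")

    layout = read_layout(inputs.sizes, inputs.gaps)

    # --- ZCR detection
    t = time.monotonic()
    zcrs_by_sample: dict[str, ZCRSet] = {}
    frac_rows = []
    for sample, path in inputs.bedgraphs.items():
        track = read_bedgraph(path)
        zcrs = detect_zcrs(track, layout, min_zcr_length, sample_id=sample)
        zcrs.to_bed(outdir / f"zcr_{sample}.bed")
        zcrs_by_sample[sample] = zcrs
        frac_rows.append(
            {
                "sample": sample,
                "n_zcr": sum(len(v) for v in zcrs.intervals.values()),
                "zcr_bases": zcrs.total_bases(),
                "pct_genome": round(genome_zcr_fraction(zcrs, layout), 4),
            }
        )
    pd.DataFrame(frac_rows).to_csv(outdir / "zcr_fractions.tsv", sep="\t", index=False)
    results["zcrs"] = zcrs_by_sample
    _stage_done(manifest, "zcr", t)

    # --- gene flagging + gene-set summary
    genes = None
    if inputs.gff3 is not None:
        t = time.monotonic()
        genes = read_gff3_genes(inputs.gff3)
        per_sample = {
            sample: flag_genes_by_zcr(zcrs, genes)
            for sample, zcrs in zcrs_by_sample.items()
        }
        flags = combine_flags(per_sample)
        flag_df = pd.DataFrame(
            {
                "gene_id": sorted(flags.combined),
                **{
                    s: [flags.per_sample[s][g] for g in sorted(flags.combined)]
                    for s in flags.samples
                },
                "combined": [flags.combined[g] for g in sorted(flags.combined)],
            }
        )
        flag_df.to_csv(outdir / "gene_flags.tsv", sep="\t", index=False)
        catalog = {"all_genes": {g.gene_id for g in genes}}
        if inputs.gene_sets is not None:
            catalog.update(read_two_column_tsv(inputs.gene_sets))
        summary = geneset_zcr_summary(flags, catalog)
        summary.to_csv(outdir / "geneset_zcr_summary.tsv", sep="\t", index=False)
        results["flags"] = flags
        results["geneset_summary"] = summary
        _stage_done(manifest, "gene_overlap", t)
    else:
        manifest["notices"].append("no GFF3: gene flagging skipped")

    # --- variant metrics + dN/dS
    positive_set: set[str] = set()
    if inputs.vcf is not None:
        t = time.monotonic()
        table = hard_filter(read_vcf(inputs.vcf))
        density_table(table, layout).to_csv(
            outdir / "variant_density.tsv", sep="\t", index=False
        )
        zygosity_table(table).to_csv(
            outdir / "zygosity.tsv", sep="\t", index=False
        )
        results["variants"] = table
        _stage_done(manifest, "variant_metrics", t)

        if genes is not None and inputs.fasta is not None:
            t = time.monotonic()
            sequences = read_fasta(inputs.fasta)
            dnds_results = count_gene_dnds(table, genes, sequences)
            rows = []
            for res in sorted(dnds_results, key=lambda r: r.gene_id):
                rows.append(
                    {
                        "gene_id": res.gene_id, "dN": res.dN, "dS": res.dS,
                        "ratio": "" if res.ratio is None else round(res.ratio, 4),
                    }
                )
            pd.DataFrame(rows).to_csv(
                outdir / "gene_dnds.tsv", sep="\t", index=False
            )
            manhattan_table(dnds_results, genes, layout).to_csv(
                outdir / "manhattan.tsv", sep="\t", index=False
            )
            positive_set, high_set = positive_selection_set(dnds_results)
            results["dnds"] = dnds_results
            results["positive_set"] = positive_set
            results["high_ratio_set"] = high_set
            _stage_done(manifest, "dnds", t)
        else:
            manifest["notices"].append(
                "no GFF3/FASTA: dN/dS skipped"
            )
    else:
        manifest["notices"].append("no VCF: variant stages skipped")

    # --- enrichment + set comparison
    if genes is not None and inputs.gene_terms is not None:
        t = time.monotonic()
        term_map = read_two_column_tsv(inputs.gene_terms)
        universe = {g.gene_id for g in genes}
        zcr_genes = results["flags"].flagged_genes() if "flags" in results else set()
        if zcr_genes:
            enr = hypergeom_enrichment(zcr_genes, term_map, universe)
            enr.to_csv(outdir / "enrichment_zcr.tsv", sep="\t", index=False)
            results["enrichment_zcr"] = enr
        if positive_set:
            enr = hypergeom_enrichment(positive_set, term_map, universe)
            enr.to_csv(outdir / "enrichment_positive.tsv", sep="\t", index=False)
            results["enrichment_positive"] = enr
        if zcr_genes and positive_set:
            part = compare_gene_sets(zcr_genes, positive_set)
            pd.DataFrame(
                [
                    {
                        "n_shared": part.n_shared,
                        "n_zcr_only": part.n_a_only,
                        "n_positive_only": part.n_b_only,
                        "pct_shared": part.pct_shared,
                        "pct_zcr_only": part.pct_a_only,
                        "pct_positive_only": part.pct_b_only,
                    }
                ]
            ).to_csv(outdir / "set_partition.tsv", sep="\t", index=False)
            results["set_partition"] = part
        _stage_done(manifest, "enrichment", t)

    # --- haplotype patterns
    if inputs.loci is not None:
        t = time.monotonic()
        loci = _read_loci_bed(Path(inputs.loci))
        matrix = locus_absence_matrix(
            zcrs_by_sample, loci, threshold=absence_threshold
        )
        matrix.fractions.round(4).to_csv(outdir / "locus_absence.tsv", sep="\t")
        discordant = discordant_loci(matrix)
        pairs = complementary_pairs(matrix)
        with open(outdir / "discordant_loci.tsv", "w") as fh:
            for name in discordant:
                fh.write(name + "\n")
        with open(outdir / "complementary_pairs.tsv", "w") as fh:
            for a, b in pairs:
                fh.write(f"{a}\t{b}\n")
        results["matrix"] = matrix
        results["discordant"] = discordant
        results["complementary_pairs"] = pairs
        _stage_done(manifest, "haplotypes", t)

    log.info("pipeline finished in %.2fs", time.monotonic() - t0)
    # timings go to the log only, so reports are byte-identical across runs
    manifest_out = {k: v for k, v in manifest.items() if k != "stages"}
    manifest_out["stages_run"] = sorted(manifest["stages"])
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest_out, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return results


def run_synthetic_pipeline(
    seed: int,
    outdir: str | Path,
    config=None,
    *,
    noise: bool = True,
) -> dict:
    """Generate the default synthetic study and run the full pipeline on its
    files, exactly as a real-data run would consume them."""
    from .synthetic_data import generate_study

    outdir = Path(outdir)
    data_dir = outdir / "data"
    bundle = generate_study(config, seed, outdir=data_dir, noise=noise)
    inputs = PipelineInputs(
        sizes=data_dir / "chrom.sizes",
        gaps=data_dir / "gaps.bed",
        bedgraphs={
            p.sample_id: data_dir / f"{p.sample_id}.bedgraph"
            for p in bundle.profiles
        },
        gff3=data_dir / "genes.gff3",
        fasta=data_dir / "reference.fa",
        vcf=data_dir / "variants.vcf",
        gene_sets=data_dir / "gene_sets.tsv",
        gene_terms=data_dir / "gene_terms.tsv",
        loci=data_dir / "loci.bed",
    )
    results = run_pipeline(
        inputs, outdir / "results",
        min_zcr_length=bundle.config.min_zcr_length, seed=seed,
    )
    results["bundle"] = bundle
    return results
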