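"""Locus presence/absence calls, haplotype patterns, and the pipeline driver."""

from __future__ import annotations

import hashlib
import itertools

import numpy as np
import pytest

from zcrtools.haplotypes import (
    PipelineInputs,
    complementary_pairs,
    discordant_loci,
    locus_absence_matrix,
    run_pipeline,
    run_synthetic_pipeline,
)
from zcrtools.zcr import ZCRSet


def zcrs_for(sample, intervals):
    return ZCRSet(sample_id=sample, intervals=intervals)


class TestAbsenceMatrix:
    def test_no_overlap_all_present(self):
        matrix = locus_absence_matrix(
            {
                "s1": zcrs_for("s1", {}),
                "s2": zcrs_for("s2", {}),
            },
            [("locus", "chrA", 0, 10_000)],
        )
        assert (matrix.fractions.to_numpy() == 0).all()
        assert not matrix.absent.to_numpy().any()

    def test_fraction_from_interval_intersection(self):
        matrix = locus_absence_matrix(
            {
                "s1": zcrs_for("s1", {"chrA": [(0, 80_000)]}),
                "s2": zcrs_for("s2", {"chrA": [(90_000, 95_000)]}),
            },
            [("locus", "chrA", 0, 100_000)],
        )
        assert matrix.fractions.loc["locus", "s1"] == pytest.approx(0.8)
        assert matrix.fractions.loc["locus", "s2"] == pytest.approx(0.05)
        assert matrix.absent.loc["locus", "s1"]
        assert not matrix.absent.loc["locus", "s2"]

    def test_boundary_fraction_is_absent(self):
        matrix = locus_absence_matrix(
            {
                "s1": zcrs_for("s1", {"chrA": [(0, 5_000)]}),
                "s2": zcrs_for("s2", {}),
            },
            [("locus", "chrA", 0, 10_000)],
        )
        assert matrix.fractions.loc["locus", "s1"] == 0.5
        assert matrix.absent.loc["locus", "s1"]

    def test_zero_length_locus_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            locus_absence_matrix(
                {"s1": zcrs_for("s1", {}), "s2": zcrs_for("s2", {})},
                [("bad", "chrA", 5, 5)],
            )

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="two samples"):
            locus_absence_matrix({"s1": zcrs_for("s1", {})}, [])


def matrix_from_calls(calls: dict[str, tuple[int, ...]], n_samples=3):
    """Build a matrix directly from binary call vectors."""
    samples = [f"s{i}" for i in range(n_samples)]
    zcrs = {}
    loci = []
    size = 10_000
    for idx, (name, vector) in enumerate(calls.items()):
        start = idx * size
        loci.append((name, "chrA", start, start + size))
    for j, sample in enumerate(samples):
        intervals = []
        for idx, (name, vector) in enumerate(calls.items()):
            if vector[j]:
                intervals.append((idx * size, idx * size + size))
        zcrs[sample] = zcrs_for(sample, {"chrA": intervals} if intervals else {})
    return locus_absence_matrix(zcrs, loci)


class TestPatterns:
    def test_discordance(self):
        matrix = matrix_from_calls(
            {"uniform": (0, 0, 0), "mixed": (1, 0, 0), "all_absent": (1, 1, 1)}
        )
        assert discordant_loci(matrix) == ["mixed"]

    def test_complementary_pair_detected(self):
        matrix = matrix_from_calls(
            {"a": (1, 0, 0), "b": (0, 1, 1), "c": (1, 0, 0)}
        )
        pairs = complementary_pairs(matrix)
        assert ("a", "b") in pairs
        assert ("b", "c") in pairs
        assert ("a", "c") not in pairs  # identical, not complementary

    def test_constant_vectors_excluded(self):
        matrix = matrix_from_calls({"none": (0, 0, 0), "all": (1, 1, 1)})
        assert complementary_pairs(matrix) == []

    def test_pairs_symmetric_irreflexive_and_discordant(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            calls = {
                f"l{i}": tuple(int(b) for b in rng.integers(0, 2, 3))
                for i in range(6)
            }
            matrix = matrix_from_calls(calls)
            pairs = complementary_pairs(matrix)
            discordant = set(discordant_loci(matrix))
            for a, b in pairs:
                assert a != b
                assert {a, b} <= discordant
            # no duplicate unordered pairs
            assert len({frozenset(p) for p in pairs}) == len(pairs)
            # oracle: complementary by direct vector comparison
            expected = {
                frozenset((x, y))
                for x, y in itertools.combinations(calls, 2)
                if all(calls[x][j] != calls[y][j] for j in range(3))
                and len(set(calls[x])) > 1
            }
            assert {frozenset(p) for p in pairs} == expected


def _digest(path):
    h = hashlib.sha256()
    for f in sorted(p for p in path.rglob("*") if p.is_file()):
        h.update(f.name.encode())
        h.update(f.read_bytes())
    return h.hexdigest()


class TestPipeline:
    def test_deterministic_reports(self, small_config, tmp_path):
        run_synthetic_pipeline(17, tmp_path / "one", small_config)
        run_synthetic_pipeline(17, tmp_path / "two", small_config)
        assert _digest(tmp_path / "one" / "results") == _digest(
            tmp_path / "two" / "results"
        )

    def test_missing_input_fails_before_any_stage(self, tmp_path):
        inputs = PipelineInputs(
            sizes=tmp_path / "missing.sizes", gaps=None, bedgraphs={}
        )
        with pytest.raises(FileNotFoundError):
            run_pipeline(inputs, tmp_path / "out")
        assert not (tmp_path / "out").exists()

    def test_vcf_omitted_skips_variant_stages(self, small_config, tmp_path):
        from zcrtools.synthetic_data import generate_study

        data = tmp_path / "data"
        bundle = generate_study(small_config, seed=23, outdir=data)
        inputs = PipelineInputs(
            sizes=data / "chrom.sizes",
            gaps=data / "gaps.bed",
            bedgraphs={
                p.sample_id: data / f"{p.sample_id}.bedgraph"
                for p in bundle.profiles
            },
            gff3=data / "genes.gff3",
        )
        results = run_pipeline(inputs, tmp_path / "out")
        notices = results["manifest"]["notices"]
        assert any("VCF" in n for n in notices)
        assert "variants" not in results
        assert (tmp_path / "out" / "zcr_fractions.tsv").exists()
        assert not (tmp_path / "out" / "variant_density.tsv").exists()

    def test_planted_absent_genes_all_flagged(self, study, tmp_path):
        """Every gene with an exon inside a planted ZCR-scale absent run
        appears in the combined flagged list of a full pipeline run."""
        from zcrtools import _intervals
        from zcrtools.synthetic_data import write_study

        bundle = study
        data = tmp_path / "data"
        write_study(bundle, data)
        inputs = PipelineInputs(
            sizes=data / "chrom.sizes",
            gaps=data / "gaps.bed",
            bedgraphs={
                p.sample_id: data / f"{p.sample_id}.bedgraph"
                for p in bundle.profiles
            },
            gff3=data / "genes.gff3",
            fasta=data / "reference.fa",
            vcf=data / "variants.vcf",
            gene_sets=data / "gene_sets.tsv",
            gene_terms=data / "gene_terms.tsv",
            loci=data / "loci.bed",
        )
        results = run_pipeline(inputs, tmp_path / "out")
        combined = results["flags"].flagged_genes()
        planted = set()
        for sample, truth in bundle.truth.planted_zcr_truth.items():
            for gene in bundle.reference.genes:
                if _intervals.overlaps_any(gene.exons, truth.get(gene.chrom, [])):
                    planted.add(gene.gene_id)
        assert planted <= combined
        # the complementary MHC-like pair is recovered
        assert ("mhc2dab_like_locus", "mhc2dgb_like_locus") in [
            tuple(sorted(p)) for p in results["complementary_pairs"]
        ]
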