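"""Codon consequence classification (exhaustive, both strands), dN/dS
pooling rules and positive-selection thresholds."""

from __future__ import annotations

import math

import pytest

from _oracles import CODON_TABLE, codon_effect, revcomp
from zcrtools.dnds import (
    NONSYNONYMOUS,
    OTHER,
    SYNONYMOUS,
    DataIntegrityError,
    GeneDnDs,
    classify_consequence,
    count_from_calls,
    count_gene_dnds,
    manhattan_table,
    positive_selection_set,
    read_vep_consequences,
)
from zcrtools.io_formats import GeneModel, GenomeLayout, VariantRecord, VariantTable

BASES = "ACGT"


def plus_gene(chrom_seq_len=60):
    return GeneModel(
        gene_id="g+", chrom="chrA", strand="+",
        exons=[(10, 13)], cds=[(10, 13)], transcript_id="g+.t1",
    )


def make_record(pos0, ref, alt):
    return VariantRecord(chrom="chrA", pos0=pos0, ref=ref, alt=alt)


def test_exhaustive_codon_substitutions_both_strands():
    """All 64 codons x 3 positions x 3 alternates agree with the frozen
    codon-table oracle, and the minus-strand mirror gives the same class."""
    for codon in CODON_TABLE:
        plus_seq = "AAAAAAAAAA" + codon + "AAAAAAAAAA"
        gene_plus = GeneModel(
            gene_id="gp", chrom="c", strand="+",
            exons=[(10, 13)], cds=[(10, 13)], transcript_id="gp.t1",
        )
        # minus-strand gene: genomic sequence holds the reverse complement
        minus_seq = "AAAAAAAAAA" + revcomp(codon) + "AAAAAAAAAA"
        gene_minus = GeneModel(
            gene_id="gm", chrom="c", strand="-",
            exons=[(10, 13)], cds=[(10, 13)], transcript_id="gm.t1",
        )
        for position in range(3):
            ref_base = codon[position]
            for alt_base in BASES:
                if alt_base == ref_base:
                    continue
                expected = codon_effect(codon, position, alt_base)
                call = classify_consequence(
                    gene_plus, plus_seq,
                    make_record(10 + position, ref_base, alt_base),
                )
                assert call.klass == expected, (codon, position, alt_base)
                # mirror: genomic position 12 - position carries the
                # complement of the codon base; substitute the complement
                minus_pos = 12 - position
                call_m = classify_consequence(
                    gene_minus, minus_seq,
                    make_record(
                        minus_pos,
                        minus_seq[minus_pos],
                        revcomp(alt_base),
                    ),
                )
                assert call_m.klass == expected, ("minus", codon, position, alt_base)


def test_minus_strand_genomic_example():
    # genomic [100,103) reads TTT, so the minus-strand CDS codon is AAA;
    # genomic T>C at pos0=102 makes the CDS codon GAA (Lys -> Glu)
    seq = "G" * 100 + "TTT" + "G" * 10
    gene = GeneModel(
        gene_id="g", chrom="chrA", strand="-",
        exons=[(100, 103)], cds=[(100, 103)], transcript_id="g.t1",
    )
    call = classify_consequence(gene, seq, make_record(102, "T", "C"))
    assert call.klass == NONSYNONYMOUS


def test_stop_gain_is_nonsynonymous():
    seq = "A" * 10 + "TAC" + "A" * 10
    gene = GeneModel(
        gene_id="g", chrom="chrA", strand="+",
        exons=[(10, 13)], cds=[(10, 13)], transcript_id="g.t1",
    )
    call = classify_consequence(gene, seq, make_record(12, "C", "A"))
    assert call.klass == NONSYNONYMOUS  # TAC (Tyr) -> TAA (stop)


def test_positions_outside_cds_are_other():
    seq = "A" * 30
    gene = GeneModel(
        gene_id="g", chrom="chrA", strand="+",
        exons=[(5, 8), (12, 18)], cds=[(12, 18)], transcript_id="g.t1",
    )
    call = classify_consequence(gene, seq, make_record(6, "A", "G"))
    assert call.klass == OTHER


def test_indel_excluded_with_warning(caplog):
    seq = "A" * 30
    gene = plus_gene()
    with caplog.at_level("WARNING"):
        call = classify_consequence(gene, seq, make_record(10, "A", "AT"))
    assert call.klass == OTHER
    assert "excluded" in caplog.text


def test_reference_mismatch_raises():
    seq = "A" * 30
    with pytest.raises(DataIntegrityError, match="mismatch"):
        classify_consequence(plus_gene(), seq, make_record(10, "C", "G"))


def test_spliced_codon_spanning_two_cds_segments():
    # codon split across an intron: CDS [10,12) + [20,21) spells A A A
    seq = "C" * 10 + "AA" + "C" * 8 + "A" + "C" * 10
    gene = GeneModel(
        gene_id="g", chrom="chrA", strand="+",
        exons=[(10, 12), (20, 21)], cds=[(10, 12), (20, 21)],
        transcript_id="g.t1",
    )
    # third codon base at genomic 20: AAA -> AAG stays Lys
    call = classify_consequence(gene, seq, make_record(20, "A", "G"))
    assert call.klass == SYNONYMOUS


class TestCounting:
    def setup_method(self):
        # one gene with codons AAA AAA (positions 10..16)
        self.seq = "C" * 10 + "AAAAAA" + "C" * 10
        self.gene = GeneModel(
            gene_id="g1", chrom="chrA", strand="+",
            exons=[(10, 16)], cds=[(10, 16)], transcript_id="g1.t1",
        )

    def table(self, records, samples=("s1", "s2", "s3")):
        return VariantTable(samples=list(samples), records=records)

    def test_planted_counts(self):
        records = [
            # nonsynonymous: first codon positions 10, 11; second codon 13
            VariantRecord("chrA", 10, "A", "G", genotypes={"s1": (1, 1)}),
            VariantRecord("chrA", 11, "A", "C", genotypes={"s1": (0, 1)}),
            VariantRecord("chrA", 13, "A", "T", genotypes={"s2": (1, 1)}),
            # synonymous: third base of codon 1 (AAA->AAG)
            VariantRecord("chrA", 12, "A", "G", genotypes={"s3": (0, 1)}),
        ]
        (res,) = count_gene_dnds(
            self.table(records), [self.gene], {"chrA": self.seq}
        )
        assert (res.dN, res.dS) == (3, 1)
        assert res.ratio == pytest.approx(3.0)

    def test_shared_allele_counts_once(self):
        shared = VariantRecord(
            "chrA", 12, "A", "G",
            genotypes={"s1": (1, 1), "s2": (1, 1), "s3": (0, 1)},
        )
        (res,) = count_gene_dnds(
            self.table([shared]), [self.gene], {"chrA": self.seq}
        )
        assert res.dS == 1
        (res_occ,) = count_gene_dnds(
            self.table([shared]), [self.gene], {"chrA": self.seq},
            per_occurrence=True,
        )
        assert res_occ.dS == 3

    def test_uncarried_allele_ignored(self):
        silent = VariantRecord(
            "chrA", 12, "A", "G",
            genotypes={"s1": (0, 0), "s2": (0, 0), "s3": (0, 0)},
        )
        assert count_gene_dnds(
            self.table([silent]), [self.gene], {"chrA": self.seq}
        ) == []

    def test_ds_zero_has_no_ratio_but_stays_in_census(self):
        records = [
            VariantRecord("chrA", 10, "A", "G", genotypes={"s1": (1, 1)}),
            VariantRecord("chrA", 11, "A", "C", genotypes={"s1": (1, 1)}),
        ]
        (res,) = count_gene_dnds(
            self.table(records), [self.gene], {"chrA": self.seq}
        )
        assert (res.dN, res.dS) == (2, 0)
        assert res.ratio is None
        positive, _ = positive_selection_set([res])
        assert positive == set()


class TestSelectionSets:
    def test_threshold_strict_and_high_inclusive(self):
        results = [
            GeneDnDs("g1", 3, 1),   # ratio 3
            GeneDnDs("g2", 1, 2),   # ratio 0.5
            GeneDnDs("g3", 2, 2),   # ratio 1.0, boundary excluded
            GeneDnDs("g4", 10, 1),  # ratio 10, in high set
        ]
        positive, high = positive_selection_set(results)
        assert positive == {"g1", "g4"}
        assert high == {"g4"}

    def test_empty_input(self):
        assert positive_selection_set([]) == (set(), set())

    def test_pseudocount_mode_rescues_ds_zero_genes(self):
        results = [GeneDnDs("g1", 4, 0), GeneDnDs("g2", 0, 4)]
        assert positive_selection_set(results)[0] == set()
        positive, _ = positive_selection_set(results, pseudocount=True)
        assert positive == {"g1"}  # (4+1)/(0+1) = 5


class TestManhattan:
    def test_log_ratio_values_and_exclusions(self):
        genes = [
            GeneModel("g1", "chrA", "+", [(0, 300)], [(0, 300)], "t1"),
            GeneModel("g2", "chrA", "+", [(400, 700)], [(400, 700)], "t2"),
            GeneModel("g3", "chrA", "+", [(800, 1100)], [(800, 1100)], "t3"),
        ]
        results = [
            GeneDnDs("g1", 3, 1),  # log10(3)
            GeneDnDs("g2", 2, 2),  # log10(1) = 0
            GeneDnDs("g3", 0, 2),  # dN=0: excluded
        ]
        df = manhattan_table(results, genes)
        assert list(df["gene_id"]) == ["g1", "g2"]
        assert df["log10_ratio"].iloc[0] == pytest.approx(math.log10(3), abs=1e-4)
        assert df["log10_ratio"].iloc[1] == 0.0
        assert list(df["midpoint"]) == [150, 550]

    def test_rows_sorted_by_layout_order(self):
        layout = GenomeLayout(chromosomes=[("chr2", 1000), ("chr1", 1000)])
        genes = [
            GeneModel("a", "chr1", "+", [(0, 300)], [(0, 300)], "ta"),
            GeneModel("b", "chr2", "+", [(0, 300)], [(0, 300)], "tb"),
        ]
        results = [GeneDnDs("a", 2, 1), GeneDnDs("b", 2, 1)]
        df = manhattan_table(results, genes, layout)
        assert list(df["gene_id"]) == ["b", "a"]


def test_vep_style_ingest_counts(tmp_path):
    path = tmp_path / "vep.tsv"
    path.write_text(
        "g1\tg1.t1\tchrA\t10\tA\tG\tmissense_variant\n"
        "g1\tg1.t1\tchrA\t12\tA\tG\tsynonymous_variant\n"
        "g1\tg1.t1\tchrA\t12\tA\tG\tsynonymous_variant\n"  # duplicate allele
        "g1\tg1.t1\tchrA\t14\tA\tG\tintron_variant\n"      # unmapped term
        "g2\tg2.t1\tchrA\t50\tC\tT\tstop_gained\n"
    )
    results = {r.gene_id: r for r in count_from_calls(read_vep_consequences(path))}
    assert (results["g1"].dN, results["g1"].dS) == (1, 1)
    assert (results["g2"].dN, results["g2"].dS) == (1, 0)


def test_planted_selection_classes_recovered(study):
    """Genes planted as positive-selection are recovered by the composite
    ratio far beyond chance (hypergeometric enrichment)."""
    from _oracles import hypergeom_upper_tail

    bundle = study
    results = count_gene_dnds(
        bundle.variants, bundle.reference.genes, bundle.reference.sequences
    )
    positive, _ = positive_selection_set(results)
    planted = {
        g for g, c in bundle.truth.gene_omega_class.items() if c == "positive"
    }
    k = len(positive & planted)
    N = len(bundle.reference.genes)
    p = hypergeom_upper_tail(k, len(positive), len(planted), N)
    assert k >= 25
    assert p < 1e-6
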