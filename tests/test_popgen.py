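from __future__ import annotations

import pytest

from trhkit.errors import FormatError, ValidationError
from trhkit.popgen import (
    GenotypeCall,
    cohort_stats,
    gene_diversity_from_frequencies,
    genotype_matrix,
    locus_stats,
    population_summary,
    read_pop_map,
    read_tr_vcf,
    stats_table,
)

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=END,Number=1,Type=Integer,Description="End">
##INFO=<ID=MOTIF,Number=1,Type=String,Description="Motif">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AL,Number=2,Type=Integer,Description="Allele lengths">
##contig=<ID=chr1,length=10000>
##contig=<ID=chr2,length=10000>
"""


def vcf_text(samples, rows):
    header = VCF_HEADER + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
    header += "\t".join(samples) + "\n"
    return header + "".join(row + "\n" for row in rows)


FOUR_SAMPLE = vcf_text(
    ["s1", "s2", "s3", "s4"],
    [
        "chr1\t101\ttr1\tACACAC\tACACACAC\t.\tPASS\tEND=106;MOTIF=AC\tGT:AL\t"
        "0/0:6,6\t0/1:6,8\t1/1:8,8\t0/1:6,8"
    ],
)


class TestReadTrVcf:
    def test_calls_resolved_from_gt(self, vcf_file):
        data = read_tr_vcf(vcf_file(FOUR_SAMPLE))
        assert data.samples == ["s1", "s2", "s3", "s4"]
        calls = data.calls["tr1"]
        assert [c.allele_indices for c in calls] == [(0, 0), (0, 1), (1, 1), (0, 1)]
        assert calls[1].allele_sequences == ("ACACAC", "ACACACAC")
        assert calls[1].allele_lengths == (6, 8)

    def test_missing_genotype(self, vcf_file):
        text = vcf_text(
            ["s1", "s2"],
            ["chr1\t101\ttr1\tACAC\tACACAC\t.\tPASS\tEND=104;MOTIF=AC\tGT\t./.\t0/1"],
        )
        data = read_tr_vcf(vcf_file(text))
        calls = data.calls["tr1"]
        assert calls[0].missing and not calls[1].missing

    def test_empty_body(self, vcf_file):
        data = read_tr_vcf(vcf_file(vcf_text(["s1"], [])))
        assert data.loci == [] and data.calls == {}

    def test_locus_id_fallback_to_coordinates(self, vcf_file):
        text = vcf_text(
            ["s1"],
            ["chr1\t101\t.\tACAC\t.\t.\tPASS\tEND=104;MOTIF=AC\tGT\t0/0"],
        )
        data = read_tr_vcf(vcf_file(text))
        assert data.loci[0][0] == "chr1_101"

    def test_no_gt_format_rejected(self, vcf_file):
        text = (
            VCF_HEADER.replace(
                '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n', ""
            )
            + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            + "chr1\t101\ttr1\tACAC\t.\t.\tPASS\tEND=104\tAL\t4,4\n"
        )
        with pytest.raises(FormatError):
            read_tr_vcf(vcf_file(text))

    def test_haploid_rejected(self, vcf_file):
        text = vcf_text(
            ["s1"], ["chr1\t101\ttr1\tACAC\tACACAC\t.\tPASS\tEND=104\tGT\t1"]
        )
        with pytest.raises(ValidationError, match="diploid"):
            read_tr_vcf(vcf_file(text))

    def test_phased_equivalent_to_unphased(self, vcf_file):
        text = vcf_text(
            ["s1"], ["chr1\t101\ttr1\tACAC\tACACAC\t.\tPASS\tEND=104\tGT\t0|1"]
        )
        data = read_tr_vcf(vcf_file(text))
        assert data.calls["tr1"][0].allele_indices == (0, 1)
        assert data.calls["tr1"][0].heterozygous


def call(sample, seqs, locus="tr1"):
    if seqs is None:
        return GenotypeCall(sample, locus, None, None, None)
    indices = (0, 0) if seqs[0] == seqs[1] else (0, 1)
    return GenotypeCall(sample, locus, indices, seqs, (len(seqs[0]), len(seqs[1])))


class TestLocusStats:
    def test_hand_toy(self):
        # GTs {0/0, 0/1, 1/1, 0/1} with alleles of lengths 6 and 8:
        # obs_het = 2/4; p = (0.5, 0.5); He = (8/7)(1 - 0.5)
        calls = [
            call("s1", ("ACACAC", "ACACAC")),
            call("s2", ("ACACAC", "ACACACAC")),
            call("s3", ("ACACACAC", "ACACACAC")),
            call("s4", ("ACACAC", "ACACACAC")),
        ]
        stats = locus_stats("tr1", calls)
        assert stats.n_called == 4
        assert stats.obs_het == pytest.approx(0.5)
        assert stats.gene_diversity == pytest.approx((8 / 7) * 0.5)
        assert stats.n_unique_alleles == 2
        assert (stats.min_allele_len, stats.max_allele_len) == (6, 8)

    def test_biased_estimator(self):
        calls = [call("s1", ("AC", "ACAC")), call("s2", ("AC", "ACAC"))]
        stats = locus_stats("tr1", calls, unbiased=False)
        assert stats.gene_diversity == pytest.approx(0.5)

    def test_monomorphic(self):
        calls = [call(f"s{i}", ("ACAC", "ACAC")) for i in range(5)]
        stats = locus_stats("tr1", calls)
        assert stats.obs_het == 0.0
        assert stats.gene_diversity == 0.0
        assert stats.n_unique_alleles == 1

    def test_missing_excluded_from_denominators(self):
        calls = [
            call("s1", ("AC", "ACAC")),
            call("s2", None),
            call("s3", ("AC", "AC")),
        ]
        stats = locus_stats("tr1", calls)
        assert stats.n_called == 2
        assert stats.obs_het == pytest.approx(0.5)

    def test_all_missing_gives_null_stats(self):
        stats = locus_stats("tr1", [call("s1", None)])
        assert stats.n_called == 0
        assert stats.obs_het is None and stats.gene_diversity is None

    def test_by_length_collapses_composition_variants(self):
        # same length, different sequence
        calls = [call("s1", ("ACAC", "AGAC"))]
        assert locus_stats("tr1", calls).obs_het == 1.0
        assert locus_stats("tr1", calls, by_length=True).obs_het == 0.0

    def test_closed_form_oracle(self):
        assert gene_diversity_from_frequencies([0.5, 0.5]) == pytest.approx(0.5)
        assert gene_diversity_from_frequencies([0.5, 0.5], n_diploid=4) == pytest.approx(
            (8 / 7) * 0.5
        )
        assert gene_diversity_from_frequencies([1.0]) == 0.0
        with pytest.raises(ValidationError):
            gene_diversity_from_frequencies([0.5, 0.4])


class TestPopulationSummary:
    def test_single_population_equals_global(self, vcf_file):
        data = read_tr_vcf(vcf_file(FOUR_SAMPLE))
        pop_map = {s: "all" for s in data.samples}
        summary = population_summary(data, pop_map)
        het = summary[
            (summary.statistic == "obs_het") & (summary.population == "all")
        ].value.iloc[0]
        assert het == pytest.approx(0.5)

    def test_wahlund_style_partition(self, vcf_file):
        # two populations each monomorphic for a different allele
        text = vcf_text(
            ["a1", "a2", "b1", "b2"],
            [
                "chr1\t101\ttr1\tACAC\tACACAC\t.\tPASS\tEND=104;MOTIF=AC\tGT\t"
                "0/0\t0/0\t1/1\t1/1"
            ],
        )
        data = read_tr_vcf(vcf_file(text))
        summary = population_summary(data, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        het = summary[summary.statistic == "obs_het"]
        assert (het.value == 0.0).all()
        global_stats = cohort_stats(data)[0]
        assert global_stats.gene_diversity > 0.0

    def test_strict_mode_rejects_unmapped_sample(self, vcf_file):
        data = read_tr_vcf(vcf_file(FOUR_SAMPLE))
        with pytest.raises(ValidationError, match="s4"):
            population_summary(data, {"s1": "A", "s2": "A", "s3": "A"})

    def test_lenient_mode_drops_with_warning(self, vcf_file):
        data = read_tr_vcf(vcf_file(FOUR_SAMPLE))
        with pytest.warns(UserWarning):
            summary = population_summary(
                data, {"s1": "A", "s2": "A", "s3": "A"}, strict=False
            )
        assert set(summary.population) == {"A"}

    def test_per_population_n_called_sums_to_global(self, vcf_file):
        data = read_tr_vcf(vcf_file(FOUR_SAMPLE))
        summary = population_summary(
            data, {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}
        )
        n_called = summary[summary.statistic == "n_called"].value.sum()
        assert n_called == cohort_stats(data)[0].n_called


class TestGenotypeMatrix:
    def test_shape_and_cells(self, vcf_file):
        data = read_tr_vcf(vcf_file(FOUR_SAMPLE))
        matrix = genotype_matrix(data)
        assert matrix.shape == (1, 4)
        assert matrix.loc["tr1", "s2"] == "6/8"

    def test_missing_rendered(self, vcf_file):
        text = vcf_text(
            ["s1", "s2"],
            ["chr1\t101\ttr1\tACAC\tACACAC\t.\tPASS\tEND=104\tGT\t./.\t1/0"],
        )
        matrix = genotype_matrix(read_tr_vcf(vcf_file(text)))
        assert matrix.loc["tr1", "s1"] == "./."
        # GT order preserved (unphased rendering)
        assert matrix.loc["tr1", "s2"] == "6/4"

    def test_rows_sorted_by_coordinate(self, vcf_file):
        text = vcf_text(
            ["s1"],
            [
                "chr2\t11\tlate\tACAC\t.\t.\tPASS\tEND=14\tGT\t0/0",
                "chr1\t501\tmid\tACAC\t.\t.\tPASS\tEND=504\tGT\t0/0",
                "chr1\t101\tearly\tACAC\t.\t.\tPASS\tEND=104\tGT\t0/0",
            ],
        )
        matrix = genotype_matrix(read_tr_vcf(vcf_file(text)))
        assert list(matrix.index) == ["early", "mid", "late"]


class TestPropertyBounds:
    def test_bounds_on_random_cohort(self, small_spec, small_bundle, vcf_file, tmp_path):
        from trhkit.synthetic_fixtures import make_cohort_vcf

        cohort = make_cohort_vcf(small_spec, small_bundle.catalog_a)
        data = read_tr_vcf(vcf_file(cohort.vcf_text))
        for stats in cohort_stats(data):
            if stats.n_called == 0:
                continue
            assert 0.0 <= stats.obs_het <= 1.0
            assert 0.0 <= stats.gene_diversity <= 1.0
            assert stats.min_allele_len <= stats.max_allele_len
            if stats.n_unique_alleles == 1:
                assert stats.obs_het == 0.0 and stats.gene_diversity == 0.0

    def test_locus_independence(self, vcf_file):
        rows = [
            "chr1\t101\ttr1\tACAC\tACACAC\t.\tPASS\tEND=104\tGT\t0/1\t0/0",
            "chr1\t501\ttr2\tGTGT\t.\t.\tPASS\tEND=504\tGT\t0/0\t0/0",
        ]
        full = read_tr_vcf(vcf_file(vcf_text(["s1", "s2"], rows)))
        partial_path = vcf_file(vcf_text(["s1", "s2"], rows[:1]))
        partial = read_tr_vcf(partial_path)
        assert stats_table(cohort_stats(full)).iloc[0].equals(
            stats_table(cohort_stats(partial)).iloc[0]
        )


class TestPopMap:
    def test_read(self, tmp_path):
        path = tmp_path / "pops.tsv"
        path.write_text("# comment\ns1\tAFR\ns2\tEAS\n")
        assert read_pop_map(path) == {"s1": "AFR", "s2": "EAS"}

    def test_bad_line(self, tmp_path):
        path = tmp_path / "pops.tsv"
        path.write_text("just-one-column\n")
        with pytest.raises(FormatError):
            read_pop_map(path)
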