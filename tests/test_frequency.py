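"""Frequency-table construction: parsing, GC, profiling, estimation, IO."""

from __future__ import annotations

import random

import pytest

from varigen import (
    FragmentProfile,
    VariantClass,
    VariantRecord,
    bin_profiles,
    build_fragment_profiles,
    build_frequency_table,
    compute_gc,
    estimate_size_distribution,
    estimate_snv_matrix,
    parse_variants,
    read_frequency_table,
    write_frequency_table,
)
from varigen.frequency import DEFAULT_BIN_EDGES

from conftest import write_fasta_plain


GVF_HEADER = "##gvf-version 1.10\n"


def gvf_line(chrom, so_type, start, end, attrs):
    return f"{chrom}\tsrc\t{so_type}\t{start}\t{end}\t.\t+\t.\t{attrs}\n"


class TestComputeGC:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ATAT", 0.0),
            ("GCGC", 1.0),
            ("ACGTNNNN", 0.5),
            ("acgt", 0.5),
            ("GgCcAaTt", 0.5),
        ],
    )
    def test_values(self, seq, expected):
        assert compute_gc(seq) == pytest.approx(expected)

    def test_all_ambiguous_is_undefined(self):
        assert compute_gc("NNNN") is None

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            compute_gc("")


class TestParseVariants:
    def _write_gvf(self, path, lines):
        path.write_text(GVF_HEADER + "".join(lines))

    def test_dedup_and_tag_filter(self, tmp_path):
        """5 records, 2 identical at one locus, 4 matching the tag -> 3 unique."""
        lines = [
            gvf_line("chr1", "SNV", 100, 100,
                     "ID=a;Reference_seq=C;Variant_seq=T;validation_status=1000Genomes"),
            gvf_line("chr1", "SNV", 100, 100,
                     "ID=b;Reference_seq=C;Variant_seq=T;validation_status=1000Genomes"),
            gvf_line("chr1", "deletion", 200, 205,
                     "ID=c;validation_status=1000Genomes,HapMap"),
            gvf_line("chr1", "SNV", 300, 300,
                     "ID=d;Reference_seq=A;Variant_seq=G;validation_status=HapMap"),
            gvf_line("chr1", "SNV", 400, 400,
                     "ID=e;Reference_seq=G;Variant_seq=A;validation_status=1000Genomes"),
        ]
        path = tmp_path / "v.gvf"
        self._write_gvf(path, lines)
        records = parse_variants(path, "GVF", {"1000Genomes"})
        assert len(records) == 3
        starts = sorted(r.start for r in records)
        assert starts == [100, 200, 400]

    def test_empty_file(self, tmp_path):
        path = tmp_path / "v.gvf"
        self._write_gvf(path, [])
        assert parse_variants(path, "GVF", {"1000Genomes"}) == []

    def test_no_matching_tags(self, tmp_path):
        path = tmp_path / "v.gvf"
        self._write_gvf(path, [
            gvf_line("chr1", "SNV", 10, 10,
                     "ID=a;Reference_seq=C;Variant_seq=T;validation_status=COSMIC"),
        ])
        assert parse_variants(path, "GVF", {"1000Genomes"}) == []

    def test_unsupported_class_dropped(self, tmp_path):
        path = tmp_path / "v.gvf"
        self._write_gvf(path, [
            gvf_line("chr1", "copy_number_gain", 10, 500, "ID=a;validation_status=x"),
            gvf_line("chr1", "inversion", 600, 650, "ID=b;validation_status=x"),
        ])
        records = parse_variants(path, "GVF", {"x"})
        assert [r.variant_class for r in records] == [VariantClass.INVERSION]
        assert records[0].size == 51

    def test_insertion_size_from_variant_seq(self, tmp_path):
        path = tmp_path / "v.gvf"
        self._write_gvf(path, [
            gvf_line("chr1", "insertion", 50, 50,
                     "ID=a;Reference_seq=-;Variant_seq=ACGTA;validation_status=x"),
        ])
        (rec,) = parse_variants(path, "GVF", {"x"})
        assert rec.variant_class is VariantClass.INSERTION and rec.size == 5

    def test_unparseable_line_names_line_number(self, tmp_path):
        path = tmp_path / "v.gvf"
        path.write_text(GVF_HEADER + "chr1\tonly-three\tfields\n")
        with pytest.raises(ValueError, match="line 2"):
            parse_variants(path, "GVF", None)

    def test_unknown_dialect(self, tmp_path):
        path = tmp_path / "v.gvf"
        self._write_gvf(path, [])
        with pytest.raises(ValueError, match="dialect"):
            parse_variants(path, "BED", None)

    def test_vcf_multiallelic_split(self, tmp_path):
        vcf = tmp_path / "v.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=VS,Number=.,Type=String,Description="tags">\n'
            "##contig=<ID=chr1,length=10000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t150\t.\tC\tT,G\t.\t.\tVS=1000Genomes\n"
            "chr1\t300\t.\tGAAAA\tG\t.\t.\tVS=1000Genomes\n"
        )
        records = parse_variants(vcf, "VCF", {"1000Genomes"})
        snvs = [r for r in records if r.variant_class is VariantClass.SNV]
        dels = [r for r in records if r.variant_class is VariantClass.DELETION]
        assert len(snvs) == 2 and {r.alt_base for r in snvs} == {"T", "G"}
        assert len(dels) == 1 and dels[0].start == 301 and dels[0].size == 4


def snv(chrom, start, ref="C", alt="T"):
    return VariantRecord(chrom, start, VariantClass.SNV, 1, ref, alt)


def var(chrom, start, cls, size):
    return VariantRecord(chrom, start, cls, size)


class TestFragmentProfiles:
    def test_window_tiling_and_partial_final(self, tmp_path):
        ref = {"chr1": "ACGT" * 625}  # 2500 bp
        profiles = build_fragment_profiles([], ref, 1000)
        assert [p.fragment_index for p in profiles] == [0, 1, 2]

    def test_variant_assigned_by_start_position(self, tmp_path):
        ref = {"chr1": "ACGT" * 625}
        profiles = build_fragment_profiles([snv("chr1", 1500)], ref, 1000)
        assert profiles[1].count(VariantClass.SNV) == 1
        assert profiles[0].total() == 0 and profiles[2].total() == 0

    def test_hand_tally(self):
        ref = {"chr1": "ACGT" * 500}
        variants = [snv("chr1", i * 7 + 1) for i in range(10)] + [
            var("chr1", 900, VariantClass.DELETION, 5),
            var("chr1", 950, VariantClass.DELETION, 3),
        ]
        profiles = build_fragment_profiles(variants, ref, 1000)
        assert profiles[0].counts == {VariantClass.SNV: 10, VariantClass.DELETION: 2}

    def test_variant_beyond_end_skipped(self, caplog):
        ref = {"chr1": "ACGT" * 250}
        with caplog.at_level("WARNING"):
            profiles = build_fragment_profiles([snv("chr1", 5000)], ref, 1000)
        assert all(p.total() == 0 for p in profiles)
        assert "skipped 1" in caplog.text

    def test_missing_chromosome_errors(self):
        with pytest.raises(ValueError, match="chrX"):
            build_fragment_profiles([snv("chrX", 1)], {"chr1": "ACGT" * 100}, 1000)

    def test_short_fragment_length_rejected(self):
        with pytest.raises(ValueError):
            build_fragment_profiles([], {"chr1": "ACGT" * 100}, 50)

    def test_high_ambiguity_fragment_has_undefined_gc(self):
        ref = {"chr1": "N" * 950 + "ACGTACGTAC" * 5}
        (profile,) = build_fragment_profiles([], ref, 1000)
        assert profile.gc_fraction is None


class TestBinProfiles:
    def test_custom_edges_reproduce_quarter_bin(self):
        """A GC of 0.30 lands in a configured 25-35% bin."""
        p = FragmentProfile("chr4", 0, 0.30)
        binned = bin_profiles([p], [0.0, 0.25, 0.35, 1.0])
        assert binned["chr4"][1] == [p]

    def test_gc_one_in_last_closed_bin(self):
        p = FragmentProfile("chr1", 0, 1.0)
        binned = bin_profiles([p], DEFAULT_BIN_EDGES)
        assert binned["chr1"][9] == [p]

    def test_all_same_gc_one_bin(self):
        profiles = [FragmentProfile("chr1", i, 0.5) for i in range(100)]
        binned = bin_profiles(profiles, DEFAULT_BIN_EDGES)
        assert len(binned["chr1"][5]) == 100
        assert all(not binned["chr1"][j] for j in range(10) if j != 5)

    def test_undefined_gc_excluded(self):
        profiles = [FragmentProfile("chr1", 0, None), FragmentProfile("chr1", 1, 0.4)]
        binned = bin_profiles(profiles, DEFAULT_BIN_EDGES)
        assert sum(len(b) for b in binned["chr1"]) == 1

    def test_conservation_per_chromosome(self, small_reference):
        _, ref = small_reference
        profiles = build_fragment_profiles([], ref, 1000)
        binned = bin_profiles(profiles, DEFAULT_BIN_EDGES)
        for chrom in ref:
            defined = sum(
                1 for p in profiles if p.chrom == chrom and p.gc_fraction is not None
            )
            assert sum(len(b) for b in binned[chrom]) == defined

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError):
            bin_profiles([], [0.1, 0.5, 1.0])


class TestSizeDistribution:
    def test_two_bin_deletion_probabilities(self):
        variants = [var("chr1", i + 1, VariantClass.DELETION, 5) for i in range(96)]
        variants += [var("chr1", 500 + i, VariantClass.DELETION, 50) for i in range(4)]
        dist = estimate_size_distribution(
            variants, {VariantClass.DELETION: [(1, 10), (11, 100)]}
        )
        bins = dist.bins[VariantClass.DELETION]
        assert bins[0].probability == pytest.approx(0.96)
        assert bins[1].probability == pytest.approx(0.04)

    def test_single_bin_all_mass(self):
        variants = [var("chr1", i + 1, VariantClass.INSERTION, 5) for i in range(7)]
        dist = estimate_size_distribution(variants, {VariantClass.INSERTION: [(1, 10)]})
        assert dist.bins[VariantClass.INSERTION][0].probability == 1.0

    def test_even_split(self):
        variants = [var("chr1", i + 1, VariantClass.DELETION, 2) for i in range(5)]
        variants += [var("chr1", 100 + i, VariantClass.DELETION, 20) for i in range(5)]
        dist = estimate_size_distribution(
            variants, {VariantClass.DELETION: [(1, 10), (11, 100)]}
        )
        probs = [b.probability for b in dist.bins[VariantClass.DELETION]]
        assert probs == [0.5, 0.5]

    def test_size_outside_spec_errors(self):
        variants = [var("chr1", 1, VariantClass.DELETION, 500)]
        with pytest.raises(ValueError, match="500"):
            estimate_size_distribution(variants, {VariantClass.DELETION: [(1, 100)]})

    def test_no_observations_errors(self):
        with pytest.raises(ValueError):
            estimate_size_distribution([], {VariantClass.DELETION: [(1, 10)]})


class TestSnvMatrix:
    def test_printed_c_row_rates(self):
        variants = (
            [snv("chr1", i + 1, "C", "T") for i in range(69)]
            + [snv("chr1", 100 + i, "C", "A") for i in range(16)]
            + [snv("chr1", 200 + i, "C", "G") for i in range(15)]
            + [snv("chr1", 300 + i, "A", "G") for i in range(5)]
            + [snv("chr1", 400 + i, "G", "A") for i in range(5)]
            + [snv("chr1", 500 + i, "T", "C") for i in range(5)]
        )
        matrix = estimate_snv_matrix(variants)
        assert matrix.rows["C"] == pytest.approx({"T": 0.69, "A": 0.16, "G": 0.15})

    def test_single_snv_row(self):
        matrix = estimate_snv_matrix(
            [snv("chr1", 1, "A", "G"), snv("chr1", 2, "C", "T"),
             snv("chr1", 3, "G", "C"), snv("chr1", 4, "T", "A")]
        )
        assert matrix.rows["A"] == {"G": 1.0, "C": 0.0, "T": 0.0}

    def test_missing_base_uniform_fallback(self, caplog):
        variants = [snv("chr1", 1, "A", "G"), snv("chr1", 2, "C", "T"),
                    snv("chr1", 3, "G", "C")]
        with caplog.at_level("WARNING"):
            matrix = estimate_snv_matrix(variants)
        assert matrix.rows["T"] == pytest.approx({"A": 1 / 3, "C": 1 / 3, "G": 1 / 3})
        assert "base T" in caplog.text


class TestRoundTrip:
    def _example_table(self, small_reference):
        _, ref = small_reference
        variants = (
            [snv("chr1", 100 * i + 1, "C", "T") for i in range(50)]
            + [snv("chr1", 37 * i + 3, "A", "G") for i in range(30)]
            + [snv("chr2", 53 * i + 7, "G", "A") for i in range(20)]
            + [snv("chr2", 71 * i + 11, "T", "C") for i in range(10)]
            + [var("chr1", 13 * i + 5, VariantClass.DELETION, 1 + i % 20) for i in range(25)]
            + [var("chr2", 17 * i + 9, VariantClass.INSERTION, 1 + i % 9) for i in range(15)]
            + [var("chr1", 29 * i + 2, VariantClass.SEQUENCE_ALTERATION, 1 + i % 5) for i in range(10)]
            + [var("chr1", 4000 + 97 * i, VariantClass.INVERSION, 20) for i in range(5)]
            + [var("chr2", 5000 + 89 * i, VariantClass.TANDEM_DUPLICATION, 12) for i in range(5)]
        )
        return variants, build_frequency_table(variants, ref, provenance="round trip")

    def test_write_read_identity(self, tmp_path, small_reference):
        _, table = self._example_table(small_reference)
        write_frequency_table(table, tmp_path / "freq")
        loaded = read_frequency_table(tmp_path / "freq")
        assert loaded == table

    def test_empty_bins_preserved(self, tmp_path, small_reference):
        _, table = self._example_table(small_reference)
        empties = {
            chrom: [i for i, b in enumerate(bins) if not b]
            for chrom, bins in table.profiles.items()
        }
        assert any(empties.values())  # the fixture does have empty bins
        write_frequency_table(table, tmp_path / "freq")
        loaded = read_frequency_table(tmp_path / "freq")
        for chrom, idxs in empties.items():
            for i in idxs:
                assert loaded.profiles[chrom][i] == []

    def test_missing_file_errors(self, tmp_path, small_reference):
        _, table = self._example_table(small_reference)
        write_frequency_table(table, tmp_path / "freq")
        (tmp_path / "freq" / "snv_matrix.tsv").unlink()
        with pytest.raises(FileNotFoundError, match="snv_matrix"):
            read_frequency_table(tmp_path / "freq")

    def test_estimators_invariant_to_input_order(self, small_reference):
        variants, table = self._example_table(small_reference)
        _, ref = small_reference
        shuffled = list(variants)
        random.Random(99).shuffle(shuffled)
        table2 = build_frequency_table(shuffled, ref, provenance="round trip")
        assert table2.size_dist == table.size_dist
        assert table2.snv_matrix == table.snv_matrix
        # profiles are set-equal per bin (order within a bin is by fragment index)
        for chrom in table.profiles:
            for b1, b2 in zip(table.profiles[chrom], table2.profiles[chrom]):
                assert sorted(p.fragment_index for p in b1) == sorted(
                    p.fragment_index for p in b2
                )
                assert {p.fragment_index: p.counts for p in b1} == {
                    p.fragment_index: p.counts for p in b2
                }
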