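import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frceval import (
    ANALYSIS_COLUMNS,
    RAW_COLUMNS,
    Assembly,
    Contig,
    CountingConfig,
    FeatureKind,
    FeatureRecord,
    FeatureType,
    analysis_column,
    build_matrix,
    count_feature,
    count_features,
    n50,
    parse_contigs,
    parse_feature_file,
)


class TestTaxonomy:
    def test_twelve_raw_types(self):
        assert len(FeatureType) == 12
        assert set(RAW_COLUMNS) == {t.name for t in FeatureType}

    def test_point_extent_split(self):
        points = {t for t in FeatureType if t.extent_kind is FeatureKind.POINT}
        assert points == {FeatureType.BREAKPOINT, FeatureType.HIGH_SNP}

    def test_eleven_analysis_columns_after_collapse(self):
        assert len(ANALYSIS_COLUMNS) == 11
        collapsed = {analysis_column(t) for t in FeatureType}
        assert collapsed == set(ANALYSIS_COLUMNS)
        assert analysis_column(FeatureType.HIGH_LINKING_CVG) == "HIGH_SPANNING_CVG"
        assert analysis_column(FeatureType.HIGH_LINKING_CVG, collapse=False) == (
            "HIGH_LINKING_CVG"
        )


class TestParsing:
    def test_point_widening(self):
        recs = parse_feature_file(io.StringIO("ctg1 HIGH_SNP 500 500\n"))
        assert recs == [FeatureRecord("ctg1", FeatureType.HIGH_SNP, 500, 501)]

    def test_extent_passthrough_and_comments(self):
        text = "# comment\nctg1\tKMER_COV\t100\t25100\tnote text\n"
        (rec,) = parse_feature_file(io.StringIO(text))
        assert (rec.start, rec.end, rec.note) == (100, 25100, "note text")

    def test_unknown_token_strict_vs_lenient(self):
        with pytest.raises(ValueError, match="unknown feature type"):
            parse_feature_file(io.StringIO("ctg1 BOGUS 1 2\n"), strict=True)
        with pytest.warns(UserWarning, match="BOGUS"):
            assert parse_feature_file(io.StringIO("ctg1 BOGUS 1 2\n")) == []

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError, match="end"):
            parse_feature_file(io.StringIO("ctg1 KMER_COV 10 5\n"))

    def test_contigs_fasta_counts_sequence_length(self):
        (ctg,) = parse_contigs(io.StringIO(">a desc\nACGT\nAC\n"), format="fasta")
        assert ctg == Contig("a", 6)

    def test_contigs_tsv(self):
        assert parse_contigs(io.StringIO("a\t100\n"), format="tsv") == [Contig("a", 100)]
        with pytest.raises(ValueError):
            parse_contigs(io.StringIO("a\t0\n"), format="tsv")
        with pytest.raises(ValueError, match="duplicate"):
            parse_contigs(io.StringIO("a\t5\na\t6\n"), format="tsv")


class TestCounting:
    @pytest.mark.parametrize(
        "ftype,start,end,expected",
        [
            (FeatureType.HIGH_SNP, 100, 101, 1),          # point counts once
            (FeatureType.BREAKPOINT, 0, 5000, 1),          # point, span irrelevant
            (FeatureType.KMER_COV, 100, 25_100, 3),        # ceil(25000/10000)
            (FeatureType.KMER_COV, 0, 4000, 1),            # floor at one
            (FeatureType.LOW_GOOD_CVG, 0, 10_000, 1),      # exact window
            (FeatureType.LOW_GOOD_CVG, 0, 10_001, 2),
        ],
    )
    def test_count_feature(self, ftype, start, end, expected):
        rec = FeatureRecord("c", ftype, start, end)
        assert count_feature(rec, CountingConfig()) == expected

    def test_linking_spanning_collapse(self):
        asm = Assembly(
            "a",
            [Contig("ctg1", 50_000)],
            [
                FeatureRecord("ctg1", FeatureType.HIGH_LINKING_CVG, 0, 100),
                FeatureRecord("ctg1", FeatureType.HIGH_SPANNING_CVG, 200, 300),
                FeatureRecord("ctg1", FeatureType.HIGH_SPANNING_CVG, 400, 500),
            ],
        )
        table = count_features(asm, CountingConfig())
        assert table.counts.loc["ctg1", "HIGH_SPANNING_CVG"] == 3
        raw = count_features(asm, CountingConfig(collapse_linking_spanning=False))
        assert raw.counts.loc["ctg1", "HIGH_LINKING_CVG"] == 1
        assert raw.counts.loc["ctg1", "HIGH_SPANNING_CVG"] == 2
        # collapsing merges columns, never drops counts
        assert raw.totals.sum() == table.totals.sum()

    def test_no_features_gives_zero_table(self):
        asm = Assembly("a", [Contig("c1", 10), Contig("c2", 20)])
        table = count_features(asm)
        assert (table.counts == 0).all().all()
        assert list(table.counts.index) == ["c1", "c2"]

    def test_matches_per_record_loop_oracle(self, rng):
        contigs = [Contig(f"c{i}", 100_000) for i in range(5)]
        types = list(FeatureType)
        feats = []
        for _ in range(200):
            ftype = types[rng.integers(len(types))]
            start = int(rng.integers(0, 90_000))
            feats.append(
                FeatureRecord(
                    f"c{rng.integers(5)}", ftype, start,
                    start + int(rng.integers(1, 9999)),
                )
            )
        cfg = CountingConfig()
        table = count_features(Assembly("a", contigs, feats), cfg)
        expected = sum(count_feature(f, cfg) for f in feats)
        assert table.totals.sum() == expected

    def test_total_invariant_under_record_order(self, rng):
        contigs = [Contig("c1", 50_000), Contig("c2", 50_000)]
        feats = [
            FeatureRecord("c1", FeatureType.KMER_COV, 0, int(rng.integers(1, 30_000)))
            for _ in range(20)
        ]
        t1 = count_features(Assembly("a", contigs, feats))
        perm = [feats[i] for i in rng.permutation(len(feats))]
        t2 = count_features(Assembly("a", contigs, perm))
        assert t1.counts.equals(t2.counts)

    @given(
        length=st.integers(min_value=1, max_value=200_000),
        window=st.integers(min_value=1, max_value=50_000),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_doubling_window_never_increases_count(self, length, window):
        rec = FeatureRecord("c", FeatureType.KMER_COV, 0, length)
        small = count_feature(rec, CountingConfig(extent_window=window))
        big = count_feature(rec, CountingConfig(extent_window=2 * window))
        assert big <= small
        assert small == max(1, math.ceil(length / window))


class TestN50:
    @pytest.mark.parametrize(
        "lengths,expected",
        [([10, 8, 5, 3], 8), ([7], 7), ([5, 5], 5), ([1, 1, 1, 1], 1)],
    )
    def test_assembly_total_denominator(self, lengths, expected):
        assert n50(lengths) == expected

    def test_ng50_uses_genome_size(self):
        # half of genome 40 is 20; need 10+8+5 >= 20 -> 5
        assert n50([10, 8, 5, 3], genome_size=40) == 5

    def test_errors(self):
        with pytest.raises(ValueError):
            n50([])
        with pytest.raises(ValueError):
            n50([10], genome_size=1000)  # cannot reach half the genome

    @given(st.lists(st.integers(min_value=1, max_value=10_000), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_value_is_an_input_length_and_covers_half(self, lengths):
        value = n50(lengths)
        assert value in lengths
        assert sum(x for x in lengths if x >= value) >= sum(lengths) / 2


class TestMatrix:
    def _assemblies(self):
        a = Assembly(
            "asm_a",
            [Contig("c1", 1000), Contig("c2", 500)],
            [FeatureRecord("c1", FeatureType.HIGH_SNP, 10, 11)],
        )
        b = Assembly("asm_b", [Contig("c1", 800)], [])
        return [a, b]

    def test_shape_with_and_without_metrics(self):
        m_full = build_matrix(self._assemblies())
        assert m_full.shape == (2, 13)
        assert list(m_full.columns[-2:]) == ["N50", "NUM_CONTIG"]
        m_bare = build_matrix(
            self._assemblies(), include_n50=False, include_num_contig=False
        )
        assert m_bare.shape == (2, 11)
        assert list(m_bare.columns) == list(ANALYSIS_COLUMNS)

    def test_values(self):
        m = build_matrix(self._assemblies())
        assert m.loc["asm_a", "HIGH_SNP"] == 1
        assert m.loc["asm_a", "N50"] == 1000
        assert m.loc["asm_b", "NUM_CONTIG"] == 1
        assert (m.loc["asm_b", list(ANALYSIS_COLUMNS)] == 0).all()

    def test_row_sums_match_loop_oracle(self, rng):
        assemblies = []
        cfg = CountingConfig()
        for j in range(3):
            contigs = [Contig(f"c{i}", 20_000) for i in range(4)]
            feats = []
            for _ in range(30):
                ftype = list(FeatureType)[rng.integers(12)]
                start = int(rng.integers(0, 15_000))
                feats.append(
                    FeatureRecord(f"c{rng.integers(4)}", ftype, start,
                                  start + int(rng.integers(1, 4000)))
                )
            assemblies.append(Assembly(f"a{j}", contigs, feats))
        m = build_matrix(assemblies, cfg, include_n50=False, include_num_contig=False)
        for asm in assemblies:
            expected = sum(count_feature(f, cfg) for f in asm.features)
            assert m.loc[asm.label].sum() == expected

    def test_requires_two_assemblies(self):
        with pytest.raises(ValueError):
            build_matrix(self._assemblies()[:1])
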