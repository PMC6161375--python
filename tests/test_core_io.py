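import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pmdscape import intervals as iv
from pmdscape.core_io import (
    GenomeSpec,
    Methylome,
    SegmentSet,
    SignalTrack,
    bin_genome,
    merge_strands,
    read_methylome,
    read_segments,
    weighted_mean_methylation,
    write_segments,
)
from tests.conftest import make_segments


class TestReadMethylome:
    def test_coverage_filter(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("chr1\t100\t+\t4\t2\nchr1\t200\t+\t5\t5\nchr1\t300\t+\t9\t0\n")
        m = read_methylome(path, min_coverage=5)
        assert m.df["pos"].tolist() == [200, 300]
        assert read_methylome(path, min_coverage=0).df["pos"].tolist() == [100, 200, 300]

    def test_filter_idempotent(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("chr1\t100\t+\t4\t2\nchr1\t200\t+\t7\t5\n")
        once = read_methylome(path, min_coverage=5)
        twice = once.filter_coverage(5)
        pd.testing.assert_frame_equal(once.df, twice.df)

    def test_malformed_and_inconsistent_rows_rejected(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("chr1\tnotanumber\t+\t5\t2\n")
        with pytest.raises(ValueError, match="unparseable"):
            read_methylome(bad)
        worse = tmp_path / "worse.tsv"
        worse.write_text("chr1\t100\t+\t5\t7\n")
        with pytest.raises(ValueError, match="methylated > coverage"):
            read_methylome(worse)


class TestMergeStrands:
    def test_dyad_merge_sums_counts(self):
        df = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "pos": [100, 101],
                "strand": ["+", "-"],
                "coverage": [3, 5],
                "methylated": [2, 4],
            }
        )
        merged = merge_strands(Methylome(df))
        assert len(merged.df) == 1
        row = merged.df.iloc[0]
        assert (row["pos"], row["coverage"], row["methylated"]) == (100, 8, 6)
        assert merged.levels[0] == pytest.approx(0.75)

    def test_plus_only_input_unchanged(self, toy_methylome):
        merged = merge_strands(toy_methylome)
        pd.testing.assert_frame_equal(merged.df, toy_methylome.df)

    def test_orphan_minus_anchored_upstream(self):
        df = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [101], "strand": ["-"], "coverage": [5], "methylated": [1]}
        )
        merged = merge_strands(Methylome(df))
        assert merged.df.iloc[0]["pos"] == 100

    def test_conserves_totals(self, rng):
        n = 200
        pos = np.sort(rng.choice(10_000, n, replace=False))
        cov = rng.integers(1, 40, n)
        df = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": pos,
                "strand": rng.choice(["+", "-"], n),
                "coverage": cov,
                "methylated": rng.integers(0, cov + 1),
            }
        )
        m = Methylome(df)
        merged = merge_strands(m)
        assert merged.df["coverage"].sum() == m.df["coverage"].sum()
        assert merged.df["methylated"].sum() == m.df["methylated"].sum()


class TestWeightedMean:
    def test_weighted_mean_definition(self, toy_methylome):
        # CpGs (cov 10, meth 5) and (cov 30, meth 30) -> 35/40
        assert weighted_mean_methylation(toy_methylome, "chr1", 0, 200) == pytest.approx(0.875)

    def test_single_cpg_is_its_level(self, toy_methylome):
        assert weighted_mean_methylation(toy_methylome, "chr1", 200, 300) == pytest.approx(0.5)

    def test_no_covered_cpgs_is_missing_not_zero(self, toy_methylome):
        assert np.isnan(weighted_mean_methylation(toy_methylome, "chr1", 500, 600))

    def test_disjoint_union_combines_by_coverage(self, toy_methylome):
        a = weighted_mean_methylation(toy_methylome, "chr1", 0, 200)
        b = weighted_mean_methylation(toy_methylome, "chr1", 200, 300)
        union = weighted_mean_methylation(toy_methylome, "chr1", 0, 300)
        assert union == pytest.approx((a * 40 + b * 20) / 60)


class TestBinGenome:
    def test_truncated_tiling(self, genome_2chr):
        bins = bin_genome(genome_2chr, 1000)
        chr1 = bins[bins["chrom"] == "chr1"]
        assert list(zip(chr1["start"], chr1["end"])) == [(0, 1000), (1000, 2000), (2000, 2500)]

    def test_excluded_chromosome_contributes_no_bins(self, genome_2chr):
        bins = bin_genome(genome_2chr, 1000)
        assert "chrX" not in set(bins["chrom"])

    def test_covers_every_base_exactly_once(self, genome_2chr):
        bins = bin_genome(genome_2chr, 700)
        for chrom, length in [("chr1", 2500), ("chr2", 1000)]:
            sub = bins[bins["chrom"] == chrom]
            assert (sub["end"] - sub["start"]).sum() == length
            assert (sub["start"].to_numpy()[1:] == sub["end"].to_numpy()[:-1]).all()

    def test_bad_width_rejected(self, genome_2chr):
        with pytest.raises(ValueError):
            bin_genome(genome_2chr, 0)


class TestSegmentsIO:
    def test_round_trip(self, tmp_path):
        s = make_segments([("chr1", 0, 100, "PMD"), ("chr2", 50, 80, "HMD")])
        path = tmp_path / "s.bed"
        write_segments(s, path)
        back = read_segments(path)
        pd.testing.assert_frame_equal(
            back.df[["chrom", "start", "end", "label"]],
            s.df[["chrom", "start", "end", "label"]],
        )

    def test_bed4_line_parses(self, tmp_path):
        path = tmp_path / "s.bed"
        path.write_text("chr1\t0\t100\tPMD\n")
        s = read_segments(path)
        r = s.df.iloc[0]
        assert (r["chrom"], r["start"], r["end"], r["label"]) == ("chr1", 0, 100, "PMD")

    def test_invalid_records_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            make_segments([("chr1", 100, 100, "PMD")])
        with pytest.raises(ValueError, match="negative"):
            make_segments([("chr1", -5, 100, "PMD")])


class TestSignalTrack:
    def test_exact_step_means(self):
        t = SignalTrack(
            pd.DataFrame(
                {"chrom": ["chr1"] * 2, "start": [0, 100], "end": [100, 200], "value": [1.0, 3.0]}
            )
        )
        assert t.mean("chr1", [0], [200])[0] == pytest.approx(2.0)
        assert t.mean("chr1", [50], [150])[0] == pytest.approx(2.0)
        assert t.mean("chr1", [0], [100])[0] == pytest.approx(1.0)

    def test_uncovered_is_missing(self):
        t = SignalTrack(
            pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200], "value": [5.0]})
        )
        assert np.isnan(t.mean("chr1", [0], [100])[0])
        assert np.isnan(t.mean("chr2", [0], [100])[0])


class TestIntervalOps:
    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.tuples(st.integers(0, 950), st.integers(1, 50)), min_size=0, max_size=20),
        st.lists(st.tuples(st.integers(0, 950), st.integers(1, 50)), min_size=0, max_size=20),
    )
    def test_against_bitmap_oracle(self, a, b):
        """merge/intersect/subtract agree with a per-bp bitmap on a 1 kb toy."""
        a_s = np.array([x for x, _ in a], dtype=np.int64)
        a_e = np.array([x + w for x, w in a], dtype=np.int64)
        b_s = np.array([x for x, _ in b], dtype=np.int64)
        b_e = np.array([x + w for x, w in b], dtype=np.int64)
        bm_a = np.zeros(1000, dtype=bool)
        bm_b = np.zeros(1000, dtype=bool)
        for s, e in zip(a_s, a_e):
            bm_a[s:e] = True
        for s, e in zip(b_s, b_e):
            bm_b[s:e] = True

        def bp(pair):
            s, e = pair
            return int(np.sum(e - s))

        assert bp(iv.merge(a_s, a_e)) == bm_a.sum()
        assert bp(iv.intersect(a_s, a_e, b_s, b_e)) == (bm_a & bm_b).sum()
        assert bp(iv.subtract(a_s, a_e, b_s, b_e)) == (bm_a & ~bm_b).sum()

    def test_overlap_per_interval_matches_bitmap(self, rng):
        r_s = np.sort(rng.choice(900, 10, replace=False))
        r_e = r_s + rng.integers(5, 80, 10)
        bm = np.zeros(1200, dtype=bool)
        for s, e in zip(r_s, r_e):
            bm[s:e] = True
        q_s = np.arange(0, 1000, 100)
        q_e = q_s + 100
        got = iv.overlap_per_interval(q_s, q_e, r_s, r_e)
        expected = [int(bm[s:e].sum()) for s, e in zip(q_s, q_e)]
        assert got.tolist() == expected


def test_genome_spec_validates_lengths():
    with pytest.raises(ValueError):
        GenomeSpec({"chr1": 0})
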