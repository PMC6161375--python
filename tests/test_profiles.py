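import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from pmdscape.core_io import Methylome, SegmentSet, SignalTrack, GenomeSpec, bin_genome
from pmdscape.profiles import (
    BinMethMatrix,
    assign_genes_to_segments,
    bin_methylation_matrix,
    cluster_pmds_across_samples,
    kmeans_bin_clusters,
    log_fpkm,
    scale_regions_matrix,
    stratify_dmrs,
)
from tests.conftest import make_segments


def constant_track(value, length=1_000_000, chrom="chr1"):
    return SignalTrack(
        pd.DataFrame({"chrom": [chrom], "start": [0], "end": [length], "value": [value]})
    )


class TestScaleRegions:
    def test_constant_track_gives_constant_matrix(self):
        regions = make_segments([("chr1", 100_000, 300_000, "PMD")])
        rsm = scale_regions_matrix(constant_track(2.5), regions, 50_000, 20_000, 10_000)
        assert np.allclose(rsm.values, 2.5)
        assert rsm.values.shape == (1, 9)  # 2 + 5 + 2 bins

    def test_step_track_body_averaging(self):
        """Left half 0, right half 2: body bins split 0 / 2 with mid bin 1."""
        track = SignalTrack(
            pd.DataFrame(
                {
                    "chrom": ["chr1", "chr1"],
                    "start": [0, 150_000],
                    "end": [150_000, 300_000],
                    "value": [0.0, 2.0],
                }
            )
        )
        regions = make_segments([("chr1", 100_000, 200_000, "PMD")])
        rsm = scale_regions_matrix(track, regions, body_len=50_000, flank_len=0, bin_size=10_000)
        assert np.allclose(rsm.values[0], [0, 0, 1, 2, 2])

    def test_per_bp_oracle_on_random_step_track(self, rng):
        """Matrix cells agree with naive per-bp averaging to 1e-9."""
        edges = np.sort(rng.choice(np.arange(1, 10_000), 30, replace=False))
        starts = np.concatenate([[0], edges])
        ends = np.concatenate([edges, [10_000]])
        vals = rng.random(len(starts))
        track = SignalTrack(
            pd.DataFrame({"chrom": "chr1", "start": starts, "end": ends, "value": vals})
        )
        per_bp = np.repeat(vals, ends - starts)
        regions = make_segments([("chr1", 1_000, 9_000, "x")])
        rsm = scale_regions_matrix(track, regions, body_len=4_000, flank_len=1_000, bin_size=500)
        # flank bins lie in true coordinates
        for j in range(2):
            lo, hi = 0 + 500 * j, 500 * (j + 1)
            assert rsm.values[0, j] == pytest.approx(per_bp[lo:hi].mean(), abs=1e-9)
        # body bins map linearly: 8000 bp body onto 4000 bp, 500-bp bins
        for j in range(8):
            lo = 1_000 + 1_000 * j
            assert rsm.values[0, 2 + j] == pytest.approx(per_bp[lo : lo + 1_000].mean(), abs=1e-9)

    def test_flank_beyond_chromosome_start_is_missing(self):
        regions = make_segments([("chr1", 0, 100_000, "PMD")])
        rsm = scale_regions_matrix(constant_track(1.0), regions, 50_000, 20_000, 10_000)
        assert np.isnan(rsm.values[0, :2]).all()
        assert np.allclose(rsm.values[0, 2:], 1.0)

    def test_region_shorter_than_bin_gets_row_mean(self):
        regions = make_segments([("chr1", 100, 600, "tiny")])
        rsm = scale_regions_matrix(constant_track(3.0), regions, 10_000, 0, 1_000)
        assert np.allclose(rsm.values[0], 3.0)


class TestKmeansBins:
    def make_matrix(self, rng, n_per=60, k=6, n_samples=4, sep=5.0):
        centers = rng.normal(0.5, 0.2, (k, n_samples))
        centers += sep * 0.04 * np.arange(k)[:, None]
        rows, truth = [], []
        for c in range(k):
            rows.append(centers[c] + rng.normal(0, 0.04 / np.sqrt(2), (n_per, n_samples)))
            truth += [c] * n_per
        values = np.concatenate(rows)
        bins = pd.DataFrame(
            {"chrom": "chr1", "start": np.arange(len(values)) * 10_000,
             "end": (1 + np.arange(len(values))) * 10_000}
        )
        return BinMethMatrix(bins, [f"s{i}" for i in range(n_samples)], values), truth

    def test_planted_cluster_recovery(self, rng):
        m, truth = self.make_matrix(rng)
        labels, _ = kmeans_bin_clusters(m, k=6, seed=0)
        assert adjusted_rand_score(truth, labels) >= 0.95

    def test_clusters_ordered_by_decreasing_methylation(self, rng):
        m, _ = self.make_matrix(rng)
        labels, _ = kmeans_bin_clusters(m, k=6, seed=0)
        means = [m.values[labels == c].mean() for c in range(6)]
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_duplicated_rows_leave_centroids_unchanged(self, rng):
        m, _ = self.make_matrix(rng, n_per=30, k=3)
        labels1, _ = kmeans_bin_clusters(m, k=3, seed=0)
        dup = BinMethMatrix(
            pd.concat([m.bins, m.bins], ignore_index=True),
            m.samples,
            np.concatenate([m.values, m.values]),
        )
        labels2, _ = kmeans_bin_clusters(dup, k=3, seed=0)
        c1 = [m.values[labels1 == c].mean() for c in range(3)]
        c2 = [dup.values[labels2 == c].mean() for c in range(3)]
        assert np.allclose(sorted(c1), sorted(c2), atol=1e-8)

    def test_too_few_complete_rows_rejected(self):
        values = np.full((4, 2), np.nan)
        bins = pd.DataFrame({"chrom": "chr1", "start": range(4), "end": range(1, 5)})
        with pytest.raises(ValueError):
            kmeans_bin_clusters(BinMethMatrix(bins, ["a", "b"], values), k=2)


class TestBinMethMatrix:
    def test_weighted_bin_means_and_annotation(self, toy_methylome, genome_2chr):
        bins = bin_genome(genome_2chr, 1000)
        segs = make_segments([("chr1", 0, 1000, "PMD")])
        m = bin_methylation_matrix([toy_methylome], bins, [segs])
        # chr1 bin 0: (5+30+10)/(10+30+20)
        assert m.values[0, 0] == pytest.approx(45 / 60)
        assert np.isnan(m.values[1, 0])
        assert m.annotations[0, 0] == "PMD"


class TestErosionClasses:
    def test_short_pmds_filtered_and_planted_patterns_recovered(self, rng):
        # 30 PMDs of 40 kb (plus one 19 kb that must be excluded)
        n = 30
        starts = 50_000 + np.arange(n) * 100_000
        rows = [("chr1", int(s), int(s + 40_000), "PMD") for s in starts]
        rows.append(("chr1", 3_500_000, 3_519_000, "PMD"))
        pmds = make_segments(rows)
        truth = np.arange(n) % 3  # 0: high/high/low, 1: high/mid/low, 2: high/low/low
        profile = {0: (0.6, 0.6, 0.1), 1: (0.6, 0.35, 0.1), 2: (0.6, 0.1, 0.1)}
        methylomes = []
        for k in range(3):
            frames = []
            for i, s in enumerate(starts):
                pos = np.arange(s, s + 40_000, 200)
                level = profile[truth[i]][k]
                cov = np.full(len(pos), 30)
                meth = rng.binomial(cov, np.clip(level + rng.normal(0, 0.03, len(pos)), 0, 1))
                frames.append(
                    pd.DataFrame(
                        {"chrom": "chr1", "pos": pos, "strand": "+",
                         "coverage": cov, "methylated": meth}
                    )
                )
            methylomes.append(Methylome(pd.concat(frames, ignore_index=True), f"m{k}"))
        out, X = cluster_pmds_across_samples(
            pmds, methylomes, min_len=20_000, norm_len=30_000, bin_size=1_000, seed=0
        )
        assert len(out) == n  # the 19 kb PMD is gone
        assert adjusted_rand_score(truth, out["cls"]) == 1.0
        # class 1 = least eroded in the last sample: here all end low, so
        # ordering is driven by the middle sample through the last-sample tie
        assert set(out["cls"]) == {1, 2, 3}


class TestGeneAssignment:
    def test_80_percent_rule(self):
        segs = make_segments([("chr1", 0, 850, "PMD"), ("chr1", 850, 2000, "HMD")])
        genes = make_segments([("chr1", 0, 1000, "geneA")])
        out = assign_genes_to_segments(genes, segs)
        assert out.iloc[0]["label"] == "PMD"
        assert out.iloc[0]["overlap_frac"] == pytest.approx(0.85)

    def test_below_threshold_unassigned(self):
        segs = make_segments([("chr1", 0, 790, "PMD")])
        genes = make_segments([("chr1", 0, 1000, "geneA")])
        assert assign_genes_to_segments(genes, segs).iloc[0]["label"] == "unassigned"

    def test_fully_contained_gene_assigned(self):
        segs = make_segments([("chr1", 0, 5000, "HMD")])
        genes = make_segments([("chr1", 1000, 2000, "geneA")])
        assert assign_genes_to_segments(genes, segs).iloc[0]["label"] == "HMD"

    def test_exclusive_single_label(self):
        segs = make_segments([("chr1", 0, 900, "PMD"), ("chr1", 900, 1000, "HMD")])
        genes = make_segments([("chr1", 0, 1000, "geneA")])
        out = assign_genes_to_segments(genes, segs)
        assert len(out) == 1 and out.iloc[0]["label"] == "PMD"


class TestLogFpkm:
    @pytest.mark.parametrize("x,expected", [(0, 0.0), (9, 1.0), (99, 2.0)])
    def test_pseudocount_log10(self, x, expected):
        assert log_fpkm([x])[0] == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_fpkm([-1.0])


class TestStratifyDmrs:
    segs = make_segments([("chr1", 0, 100_000, "PMD"), ("chr1", 100_000, 200_000, "HMD")])
    gl = {"PMD": -0.15, "HMD": 0.0}

    def make_dmrs(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "delta"])

    def test_zero_deviation_filtered(self):
        out = stratify_dmrs(self.make_dmrs([("chr1", 10, 500, -0.15)]), self.segs, self.gl, 0.1)
        assert out.iloc[0]["status"] == "filtered"

    def test_gain_against_global_loss_retained(self):
        out = stratify_dmrs(self.make_dmrs([("chr1", 10, 500, 0.10)]), self.segs, self.gl, 0.1)
        assert out.iloc[0]["status"] == "retained"
        assert out.iloc[0]["direction"] == "gain"

    def test_tol_zero_retains_any_deviation(self):
        out = stratify_dmrs(
            self.make_dmrs([("chr1", 10, 500, -0.1500001)]), self.segs, self.gl, 0.0
        )
        assert out.iloc[0]["status"] == "retained"

    def test_unassigned_kept_unfiltered_and_partition(self):
        dmrs = self.make_dmrs(
            [("chr2", 0, 100, 0.5), ("chr1", 0, 100, -0.5), ("chr1", 150_000, 150_100, 0.01)]
        )
        out = stratify_dmrs(dmrs, self.segs, self.gl, 0.1)
        assert len(out) == len(dmrs)
        assert set(out["status"]) <= {"retained", "filtered"}
        assert out[out["label"] == "unassigned"].iloc[0]["status"] == "retained"
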