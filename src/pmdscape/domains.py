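"""PMD / TAD topology comparison.

Tests whether TAD borders track PMD borders (nearest-border distances
against a count-matched uniform-random null, two-sided rank-sum test),
splits TADs into a heterochromatic and a euchromatic class from broad
histone-mark means, and accounts base-pair overlap between PMDs and
heterochromatic TADs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu
from sklearn.cluster import KMeans

from pmdscape import intervals as iv
from pmdscape.core_io import GenomeSpec, SegmentSet, SignalTrack

HETEROCHROMATIC_MARKS = ("H3K27me3", "H3K9me3")
EUCHROMATIC_MARK = "H3K36me3"


@dataclass
class BorderSet:
    """Sorted, deduplicated border positions (segment starts and ends)."""

    positions: dict[str, np.ndarray]  # chrom -> sorted bp

    @staticmethod
    def from_segments(s: SegmentSet) -> "BorderSet":
        out = {}
        for chrom, ss, ee in s.per_chrom():
            out[chrom] = np.unique(np.concatenate([ss, ee]))
        return BorderSet(out)

    def total(self) -> int:
        return sum(len(v) for v in self.positions.values())


@dataclass
class BorderTestResult:
    observed: np.ndarray  # TAD-border -> nearest PMD-border distances
    null: np.ndarray  # TAD-border -> nearest random-border distances
    p_value: float
    statistic: float


@dataclass
class OverlapReport:
    shared_bp: int
    pmd_only_bp: int
    het_tad_only_bp: int

    @property
    def union_bp(self) -> int:
        return self.shared_bp + self.pmd_only_bp + self.het_tad_only_bp

    @property
    def pmd_covered_fraction(self) -> float:
        denom = self.shared_bp + self.pmd_only_bp
        return self.shared_bp / denom if denom else float("nan")


def _nearest_distances(query: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Distance from each query position to the nearest reference position."""
    idx = np.searchsorted(ref, query)
    left = np.where(idx > 0, np.abs(query - ref[np.maximum(idx - 1, 0)]), np.iinfo(np.int64).max)
    right = np.where(idx < len(ref), np.abs(ref[np.minimum(idx, len(ref) - 1)] - query),
                     np.iinfo(np.int64).max)
    return np.minimum(left, right)


def border_distance_test(
    tad_borders: BorderSet,
    pmd_borders: BorderSet,
    genome: GenomeSpec,
    n_random: int | None = None,
    seed: int = 0,
) -> BorderTestResult:
    """Rank-sum comparison of TAD->PMD border distances against a random null.

    The null border set is drawn uniformly per chromosome, matched in count
    to the PMD borders of that chromosome (``n_random`` overrides the
    per-chromosome count when given).  Distances are pooled over
    chromosomes; borders on different chromosomes are never paired.
    """
    if tad_borders.total() == 0 or pmd_borders.total() == 0:
        raise ValueError("empty border set")
    rng = np.random.default_rng(seed)
    obs_parts, null_parts = [], []
    for chrom, tads in tad_borders.positions.items():
        pmds = pmd_borders.positions.get(chrom)
        if pmds is None or not len(pmds):
            continue
        length = genome.chrom_lengths[chrom]
        n = n_random if n_random is not None else len(pmds)
        random_borders = np.sort(rng.integers(0, length, size=n))
        obs_parts.append(_nearest_distances(tads, pmds))
        null_parts.append(_nearest_distances(tads, random_borders))
    observed = np.concatenate(obs_parts)
    null = np.concatenate(null_parts)
    stat, p = mannwhitneyu(observed, null, alternative="two-sided")
    return BorderTestResult(observed, null, float(p), float(stat))


def classify_tads(
    tads: SegmentSet,
    histone_tracks: dict[str, SignalTrack],
    seed: int = 0,
) -> np.ndarray:
    """Two-class k-means over per-TAD mean mark signals.

    Features are the mean H3K27me3, H3K9me3 and H3K36me3 over each TAD; the
    cluster with the larger (H3K27me3 + H3K9me3) - H3K36me3 contrast is
    labelled "heterochromatic", the other "euchromatic", regardless of
    cluster index.
    """
    if len(tads) < 2:
        raise ValueError("need at least 2 TADs to classify")
    marks = list(HETEROCHROMATIC_MARKS) + [EUCHROMATIC_MARK]
    feats = np.empty((len(tads), len(marks)))
    for j, mark in enumerate(marks):
        track = histone_tracks[mark]
        vals = np.empty(len(tads))
        for i, r in enumerate(tads.df.itertuples()):
            vals[i] = track.mean(r.chrom, [r.start], [r.end])[0]
        feats[:, j] = vals
    feats = np.where(np.isnan(feats), np.nanmean(feats, axis=0, keepdims=True), feats)
    if np.allclose(feats, feats[0]):
        raise ValueError("degenerate clustering: all TADs have identical mark means")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    raw = km.fit_predict(feats)
    contrast = km.cluster_centers_[:, 0] + km.cluster_centers_[:, 1] - km.cluster_centers_[:, 2]
    het_cluster = int(np.argmax(contrast))
    return np.where(raw == het_cluster, "heterochromatic", "euchromatic")


def overlap_bp(pmds: SegmentSet, het_tads: SegmentSet) -> OverlapReport:
    """Exact bp intersection accounting between PMDs and heterochromatic TADs."""
    shared = pmd_only = het_only = 0
    chroms = set(pmds.df["chrom"]) | set(het_tads.df["chrom"])
    for chrom in chroms:
        p = pmds.df[pmds.df["chrom"] == chrom]
        t = het_tads.df[het_tads.df["chrom"] == chrom]
        ps, pe = iv.merge(p["start"].to_numpy(np.int64), p["end"].to_numpy(np.int64))
        ts, te = iv.merge(t["start"].to_numpy(np.int64), t["end"].to_numpy(np.int64))
        is_, ie = iv.intersect(ps, pe, ts, te)
        inter = int(np.sum(ie - is_)) if len(is_) else 0
        shared += inter
        pmd_only += iv.total_bp(ps, pe) - inter
        het_only += iv.total_bp(ts, te) - inter
    return OverlapReport(shared, pmd_only, het_only)
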