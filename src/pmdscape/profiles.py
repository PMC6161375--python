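"""Signal aggregation over regions and downstream clustering utilities.

`scale_regions_matrix` reproduces deepTools' scale-regions semantics: each
region body is linearly rescaled to a common length and flanked by fixed
windows in true coordinates; every output bin holds the length-weighted
mean of a bedGraph track over its source interval.  On top of that sit the
methylation-bin k-means, the cross-sample PMD erosion classes, the 80%
gene-to-segment assignment rule, and DMR stratification against the global
per-compartment methylation change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from pmdscape import intervals as iv
from pmdscape.core_io import Methylome, SegmentSet, SignalTrack

logger = logging.getLogger(__name__)


@dataclass
class RegionSignalMatrix:
    """Regions x bins mean-signal matrix (flank | scaled body | flank)."""

    regions: pd.DataFrame  # chrom, start, end (row order preserved)
    values: np.ndarray  # (n_regions, n_cols), NaN = missing
    bin_size: int
    body_len: int
    flank_len: int

    @property
    def n_flank_bins(self) -> int:
        return self.flank_len // self.bin_size

    @property
    def n_body_bins(self) -> int:
        return self.body_len // self.bin_size

    def body(self) -> np.ndarray:
        f = self.n_flank_bins
        return self.values[:, f : f + self.n_body_bins]


def scale_regions_matrix(
    track: SignalTrack,
    regions: SegmentSet,
    body_len: int = 500_000,
    flank_len: int = 250_000,
    bin_size: int = 1_000,
) -> RegionSignalMatrix:
    """Mean track signal per region in scale-regions layout.

    Body bins map linearly onto the region; flank bins are taken in true
    coordinates.  Bins whose source interval carries no track coverage
    (including bins beyond chromosome ends) are NaN, never zero.  Regions
    shorter than one source bin get their overall mean in every body bin.
    """
    if body_len % bin_size or flank_len % bin_size:
        raise ValueError("body_len and flank_len must be multiples of bin_size")
    n_body = body_len // bin_size
    n_flank = flank_len // bin_size
    n_cols = n_body + 2 * n_flank
    reg = regions.df.reset_index(drop=True)
    values = np.full((len(reg), n_cols), np.nan)
    for i, r in enumerate(reg.itertuples()):
        length = r.end - r.start
        # upstream flank, true coordinates (negative positions stay NaN)
        if n_flank:
            edges = r.start - flank_len + bin_size * np.arange(n_flank + 1, dtype=float)
            ok = edges[:-1] >= 0
            if ok.any():
                vals = track.mean(r.chrom, edges[:-1][ok], edges[1:][ok])
                values[i, :n_flank][ok] = vals
        # body, linearly mapped source bins
        if length < bin_size:
            logger.info(
                "region %s:%d-%d shorter than one bin; using its mean", r.chrom, r.start, r.end
            )
            values[i, n_flank : n_flank + n_body] = track.mean(r.chrom, [r.start], [r.end])[0]
        else:
            frac = np.arange(n_body + 1, dtype=float) / n_body
            edges = r.start + frac * length
            values[i, n_flank : n_flank + n_body] = track.mean(r.chrom, edges[:-1], edges[1:])
        # downstream flank
        if n_flank:
            edges = r.end + bin_size * np.arange(n_flank + 1, dtype=float)
            values[i, n_flank + n_body :] = track.mean(r.chrom, edges[:-1], edges[1:])
    return RegionSignalMatrix(reg, values, bin_size, body_len, flank_len)


@dataclass
class BinMethMatrix:
    """Genome bins x samples mean methylation with per-(bin, sample) labels."""

    bins: pd.DataFrame
    samples: list[str]
    values: np.ndarray  # (n_bins, n_samples), NaN = missing
    annotations: np.ndarray | None = None  # object array of labels or None


def bin_methylation_matrix(
    methylomes: list[Methylome],
    bins: pd.DataFrame,
    segment_sets: list[SegmentSet] | None = None,
) -> BinMethMatrix:
    """Per-bin weighted mean methylation for each sample; bins annotated with
    the majority-overlap segment label when segment sets are supplied."""
    samples = [m.sample_id for m in methylomes]
    values = np.full((len(bins), len(samples)), np.nan)
    chroms = bins["chrom"].to_numpy()
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    for j, m in enumerate(methylomes):
        for chrom in dict.fromkeys(chroms):
            sel = np.flatnonzero(chroms == chrom)
            sub = m.subset(chrom)
            if not len(sub):
                continue
            pos = sub["pos"].to_numpy()
            cov = sub["coverage"].to_numpy(float)
            meth = sub["methylated"].to_numpy(float)
            ccov = np.concatenate([[0.0], np.cumsum(cov)])
            cmeth = np.concatenate([[0.0], np.cumsum(meth)])
            lo = np.searchsorted(pos, starts[sel])
            hi = np.searchsorted(pos, ends[sel])
            c = ccov[hi] - ccov[lo]
            with np.errstate(invalid="ignore", divide="ignore"):
                values[sel, j] = np.where(c > 0, (cmeth[hi] - cmeth[lo]) / c, np.nan)
    annotations = None
    if segment_sets is not None:
        annotations = np.full((len(bins), len(samples)), None, dtype=object)
        for j, segs in enumerate(segment_sets):
            for chrom in dict.fromkeys(chroms):
                sel = np.flatnonzero(chroms == chrom)
                if not len(sel):
                    continue
                best = np.zeros(len(sel), dtype=np.int64)
                for label in segs.labels:
                    sub = segs.with_label(label).df
                    sub = sub[sub["chrom"] == chrom]
                    ov = iv.overlap_per_interval(
                        starts[sel], ends[sel], sub["start"].to_numpy(), sub["end"].to_numpy()
                    )
                    upd = ov > best
                    annotations[sel[upd], j] = label
                    best = np.maximum(best, ov)
    return BinMethMatrix(bins.reset_index(drop=True), samples, values, annotations)


def kmeans_bin_clusters(
    m: BinMethMatrix, k: int = 6, seed: int = 0
) -> tuple[np.ndarray, pd.DataFrame | None]:
    """k-means over complete bin rows, clusters ordered by decreasing mean
    methylation; returns (per-bin labels with -1 for dropped rows,
    annotation fractions per cluster and sample or None)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    complete = ~np.isnan(m.values).any(axis=1)
    n_complete = int(complete.sum())
    if n_complete < k:
        raise ValueError(f"only {n_complete} complete rows for k={k}")
    dropped = len(complete) - n_complete
    if dropped:
        logger.info("kmeans_bin_clusters: dropped %d incomplete bins", dropped)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(m.values[complete])
    order = np.argsort(-km.cluster_centers_.mean(axis=1), kind="stable")
    remap = np.empty(k, dtype=np.int64)
    remap[order] = np.arange(k)
    labels = np.full(len(m.bins), -1, dtype=np.int64)
    labels[complete] = remap[raw]
    fractions = None
    if m.annotations is not None:
        rows = []
        for c in range(k):
            for j, s in enumerate(m.samples):
                ann = m.annotations[labels == c, j]
                ann = ann[ann != None]  # noqa: E711
                total = len(ann)
                for lab in sorted({a for a in ann}):
                    rows.append((c, s, lab, float(np.sum(ann == lab) / total)))
        fractions = pd.DataFrame(rows, columns=["cluster", "sample", "label", "fraction"])
    return labels, fractions


def cluster_pmds_across_samples(
    ref_pmds: SegmentSet,
    methylomes: list[Methylome],
    min_len: int = 20_000,
    norm_len: int = 150_000,
    bin_size: int = 1_000,
    k: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Erosion classes of reference PMDs across a sample series.

    PMDs shorter than ``min_len`` are discarded; each remaining PMD gives
    one methylation profile per sample (body normalized to ``norm_len``,
    no flanks), the profiles are concatenated and clustered by k-means.
    Classes are numbered by decreasing mean methylation of the *last*
    sample, so class 1 is the least eroded.  Returns the retained PMD
    table with a ``cls`` column and the (n_pmds, k_samples) profile matrix.
    """
    keep = ref_pmds.df[(ref_pmds.df["end"] - ref_pmds.df["start"]) >= min_len]
    kept = SegmentSet(keep.reset_index(drop=True))
    blocks = []
    for m in methylomes:
        track = SignalTrack.from_methylome(m)
        rsm = scale_regions_matrix(track, kept, body_len=norm_len, flank_len=0, bin_size=bin_size)
        blocks.append(rsm.values)
    X = np.concatenate(blocks, axis=1)
    row_mean = np.nanmean(X, axis=1, keepdims=True)
    X = np.where(np.isnan(X), row_mean, X)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(X)
    sizes = np.bincount(raw, minlength=k)
    if (sizes < max(2, len(X) // (10 * k))).any():
        logger.warning("cluster_pmds_across_samples: near-empty erosion class %s", sizes)
    last = blocks[-1]
    last_mean = np.array([np.nanmean(last[raw == c]) for c in range(k)])
    order = np.argsort(-last_mean, kind="stable")
    remap = np.empty(k, dtype=np.int64)
    remap[order] = np.arange(1, k + 1)
    out = kept.df.copy()
    out["cls"] = remap[raw]
    return out, X


def assign_genes_to_segments(
    genes: SegmentSet, segments: SegmentSet, min_frac: float = 0.8
) -> pd.DataFrame:
    """Label each gene with the segment class covering >= ``min_frac`` of it.

    The candidate label is the one with the largest overlap (ties broken by
    the leftmost segment label order); genes under the threshold are
    ``unassigned``.  Returns (chrom, start, end, gene, label, overlap_frac).
    """
    rows = []
    for g in genes.df.itertuples():
        length = g.end - g.start
        best_label, best_ov = "unassigned", 0
        for label in segments.labels:
            sub = segments.with_label(label).df
            sub = sub[sub["chrom"] == g.chrom]
            ov = int(
                iv.overlap_per_interval(
                    np.array([g.start]), np.array([g.end]),
                    sub["start"].to_numpy(), sub["end"].to_numpy(),
                )[0]
            )
            if ov > best_ov:
                best_label, best_ov = label, ov
        frac = best_ov / length
        label = best_label if frac >= min_frac else "unassigned"
        rows.append((g.chrom, g.start, g.end, g.label, label, frac))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gene", "label", "overlap_frac"]
    )


def log_fpkm(values) -> np.ndarray:
    """log10(FPKM + 1); the pseudocount keeps zero-expression genes at 0."""
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("FPKM values must be non-negative")
    return np.log10(arr + 1.0)


def stratify_dmrs(
    dmrs: pd.DataFrame,
    segments: SegmentSet,
    global_deltas: dict[str, float],
    tol: float = 0.1,
) -> pd.DataFrame:
    """Screen DMRs by deviation from the global per-compartment change.

    Each DMR (chrom, start, end, delta) is assigned the host label covering
    the majority of it; it is retained iff |delta - global_delta(label)| >
    tol, and split into "gain"/"loss" relative to the global change.  DMRs
    over unlabeled ground are kept unfiltered as "unassigned".
    """
    rows = []
    for d in dmrs.itertuples():
        length = d.end - d.start
        best_label, best_ov = None, 0
        for label in segments.labels:
            sub = segments.with_label(label).df
            sub = sub[sub["chrom"] == d.chrom]
            ov = int(
                iv.overlap_per_interval(
                    np.array([d.start]), np.array([d.end]),
                    sub["start"].to_numpy(), sub["end"].to_numpy(),
                )[0]
            )
            if ov > best_ov:
                best_label, best_ov = label, ov
        if best_label is None or best_ov * 2 < length:
            rows.append((d.chrom, d.start, d.end, d.delta, "unassigned", "retained", "unassigned"))
            continue
        g = global_deltas[best_label]
        dev = d.delta - g
        if abs(dev) > tol:
            rows.append(
                (d.chrom, d.start, d.end, d.delta, best_label, "retained",
                 "gain" if dev > 0 else "loss")
            )
        else:
            rows.append((d.chrom, d.start, d.end, d.delta, best_label, "filtered", "none"))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "delta", "label", "status", "direction"]
    )
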