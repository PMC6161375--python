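"""Data model, file I/O and elementary methylome operations.

Coordinates are 0-based half-open throughout.  A methylome is a table of
per-CpG bisulfite calls (chrom, pos, strand, coverage, methylated); segments
are labelled half-open intervals (BED semantics); continuous signals are
bedGraph-style step functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from pmdscape import intervals as iv

logger = logging.getLogger(__name__)

MISSING = float("nan")

#: default chromosomes excluded from all analyses (sex chromosomes)
DEFAULT_EXCLUDED = ("chrX", "chrY", "X", "Y")

METHYLOME_COLUMNS = ["chrom", "pos", "strand", "coverage", "methylated"]
SEGMENT_COLUMNS = ["chrom", "start", "end", "label", "score"]


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosome sizes plus the analysis exclusion list."""

    chrom_lengths: dict[str, int]
    excluded_chroms: frozenset[str] = frozenset(DEFAULT_EXCLUDED)

    def __post_init__(self):
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def analysis_chroms(self) -> list[str]:
        return [c for c in self.chrom_lengths if c not in self.excluded_chroms]


@dataclass
class Methylome:
    """Per-CpG calls sorted by (chrom, pos), one sample.

    ``df`` has columns chrom, pos, strand, coverage, methylated.
    """

    df: pd.DataFrame
    sample_id: str = "sample"

    def __post_init__(self):
        missing = [c for c in METHYLOME_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"methylome table lacks columns {missing}")
        bad = self.df["methylated"] > self.df["coverage"]
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"methylated > coverage at row {i} "
                f"({self.df.iloc[i]['chrom']}:{self.df.iloc[i]['pos']})"
            )
        self.df = self.df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    @property
    def levels(self) -> np.ndarray:
        """Per-CpG methylation fraction; NaN where coverage is zero."""
        cov = self.df["coverage"].to_numpy(dtype=float)
        meth = self.df["methylated"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, meth / cov, np.nan)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def subset(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    def filter_coverage(self, min_coverage: int) -> "Methylome":
        kept = self.df[self.df["coverage"] >= min_coverage].reset_index(drop=True)
        return Methylome(kept, self.sample_id)


@dataclass
class SegmentSet:
    """Labelled half-open intervals; ``df`` has chrom, start, end, label, score."""

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df.copy()
        if "label" not in df.columns:
            df["label"] = "."
        if "score" not in df.columns:
            df["score"] = np.nan
        df = df[SEGMENT_COLUMNS]
        bad = df["start"] >= df["end"]
        if bad.any():
            rec = df[bad].iloc[0]
            raise ValueError(f"degenerate segment {rec['chrom']}:{rec['start']}-{rec['end']}")
        if (df["start"] < 0).any():
            rec = df[df["start"] < 0].iloc[0]
            raise ValueError(f"negative start in segment {rec['chrom']}:{rec['start']}-{rec['end']}")
        self.df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def labels(self) -> list[str]:
        return sorted(self.df["label"].unique())

    def with_label(self, label: str) -> "SegmentSet":
        return SegmentSet(self.df[self.df["label"] == label].reset_index(drop=True))

    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def total_bp(self) -> int:
        out = 0
        for _, sub in self.df.groupby("chrom"):
            out += iv.total_bp(sub["start"].to_numpy(), sub["end"].to_numpy())
        return out

    def per_chrom(self):
        for chrom, sub in self.df.groupby("chrom", sort=True):
            yield chrom, sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)

    @staticmethod
    def from_arrays(chrom, starts, ends, label="segment", score=None) -> "SegmentSet":
        n = len(starts)
        chroms = [chrom] * n if isinstance(chrom, str) else list(chrom)
        return SegmentSet(
            pd.DataFrame(
                {
                    "chrom": chroms,
                    "start": np.asarray(starts, dtype=np.int64),
                    "end": np.asarray(ends, dtype=np.int64),
                    "label": label,
                    "score": np.nan if score is None else score,
                }
            )
        )

    @staticmethod
    def concat(sets: list["SegmentSet"]) -> "SegmentSet":
        frames = [s.df for s in sets if len(s)]
        if not frames:
            return SegmentSet(pd.DataFrame(columns=SEGMENT_COLUMNS))
        return SegmentSet(pd.concat(frames, ignore_index=True))


@dataclass
class SignalTrack:
    """bedGraph-style step function: non-overlapping intervals with a value.

    Means over arbitrary sub-intervals are evaluated from the cumulative
    integral of the step function, which is exact and O(log n) per query.
    Uncovered bases are treated as missing, not zero.
    """

    df: pd.DataFrame
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        df = self.df[["chrom", "start", "end", "value"]].copy()
        if not np.isfinite(df["value"]).all():
            raise ValueError("signal track contains non-finite values")
        self.df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        self._index = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            s = sub["start"].to_numpy(dtype=float)
            e = sub["end"].to_numpy(dtype=float)
            v = sub["value"].to_numpy(dtype=float)
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"overlapping track intervals on {chrom}")
            # breakpoints of the step function and cumulative integrals at them
            xs = np.empty(2 * len(s))
            xs[0::2], xs[1::2] = s, e
            seg_int = v * (e - s)
            val_cum = np.zeros_like(xs)
            val_cum[1::2] = seg_int
            cov_cum = np.zeros_like(xs)
            cov_cum[1::2] = e - s
            self._index[chrom] = (xs, np.cumsum(val_cum), np.cumsum(cov_cum))

    def mean(self, chrom: str, starts, ends) -> np.ndarray:
        """Mean value over each [start, end); NaN where nothing is covered."""
        starts = np.atleast_1d(np.asarray(starts, dtype=float))
        ends = np.atleast_1d(np.asarray(ends, dtype=float))
        if chrom not in self._index:
            return np.full(starts.shape, np.nan)
        xs, val_cum, cov_cum = self._index[chrom]
        val = np.interp(ends, xs, val_cum) - np.interp(starts, xs, val_cum)
        cov = np.interp(ends, xs, cov_cum) - np.interp(starts, xs, cov_cum)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(cov > 0, val / cov, np.nan)
        return out

    @staticmethod
    def from_methylome(m: Methylome) -> "SignalTrack":
        """Methylation levels as a 1-bp step track (zero-coverage CpGs dropped)."""
        df = m.df[m.df["coverage"] > 0]
        return SignalTrack(
            pd.DataFrame(
                {
                    "chrom": df["chrom"].to_numpy(),
                    "start": df["pos"].to_numpy(np.int64),
                    "end": df["pos"].to_numpy(np.int64) + 1,
                    "value": df["methylated"].to_numpy(float) / df["coverage"].to_numpy(float),
                }
            )
        )


# ---------------------------------------------------------------------------
# file I/O


def read_methylome(path, min_coverage: int = 0, sample_id: str | None = None) -> Methylome:
    """Read a CpG call TSV (chrom, pos, strand, coverage, methylated).

    Rows with coverage below ``min_coverage`` are dropped.  Malformed rows
    raise with the offending line number.
    """
    if min_coverage < 0:
        raise ValueError("min_coverage must be >= 0")
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=METHYLOME_COLUMNS,
            dtype={"chrom": str, "strand": str},
        )
        df["pos"] = pd.to_numeric(df["pos"], errors="raise").astype(np.int64)
        df["coverage"] = pd.to_numeric(df["coverage"], errors="raise").astype(np.int64)
        df["methylated"] = pd.to_numeric(df["methylated"], errors="raise").astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable methylome row in {path}: {exc}") from exc
    if (df["coverage"] < 0).any() or (df["methylated"] < 0).any():
        line = int((df["coverage"] < 0).idxmax() if (df["coverage"] < 0).any() else (df["methylated"] < 0).idxmax())
        raise ValueError(f"negative count at line {line + 1} of {path}")
    bad = df["methylated"] > df["coverage"]
    if bad.any():
        raise ValueError(f"methylated > coverage at line {int(bad.idxmax()) + 1} of {path}")
    df = df[df["coverage"] >= min_coverage].reset_index(drop=True)
    name = sample_id if sample_id is not None else str(path)
    return Methylome(df, name)


def write_methylome(m: Methylome, path) -> None:
    m.df[METHYLOME_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_segments(path) -> SegmentSet:
    """Read BED3/4/5 into a SegmentSet (column 4 = label, column 5 = score)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype={0: str})
    df = df.rename(columns=dict(enumerate(["chrom", "start", "end", "label", "score"])))
    return SegmentSet(df)


def write_segments(s: SegmentSet, path) -> None:
    out = s.df.copy()
    if out["score"].isna().all():
        out = out[["chrom", "start", "end", "label"]]
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_bedgraph(path) -> SignalTrack:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["chrom", "start", "end", "value"], dtype={"chrom": str}
    )
    return SignalTrack(df)


def write_bedgraph(t: SignalTrack, path) -> None:
    t.df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# elementary operations


def merge_strands(m: Methylome) -> Methylome:
    """Aggregate plus/minus calls of each CpG dyad at the plus-strand position.

    A minus-strand call at position p is assigned to the dyad anchored at
    p - 1; counts of the two strands are summed.  Minus-strand calls with no
    plus partner are kept, anchored at p - 1 (logged).
    """
    df = m.df.copy()
    minus = df["strand"] == "-"
    anchor = df["pos"].to_numpy(np.int64).copy()
    anchor[minus.to_numpy()] -= 1
    df["pos"] = anchor
    plus_pos = set(df.loc[~minus, "pos"].to_numpy())
    orphans = int((~df.loc[minus, "pos"].isin(plus_pos)).sum())
    if orphans:
        logger.info("merge_strands: %d minus-strand calls had no plus partner", orphans)
    merged = (
        df.groupby(["chrom", "pos"], as_index=False, sort=True)
        .agg(coverage=("coverage", "sum"), methylated=("methylated", "sum"))
        .assign(strand="+")
    )
    return Methylome(merged[METHYLOME_COLUMNS], m.sample_id)


def weighted_mean_methylation(m: Methylome, chrom: str, start: int, end: int) -> float:
    """Coverage-weighted mean methylation of CpGs in [start, end); NaN if none."""
    sub = m.subset(chrom)
    pos = sub["pos"].to_numpy()
    mask = (pos >= start) & (pos < end)
    cov = sub["coverage"].to_numpy()[mask]
    meth = sub["methylated"].to_numpy()[mask]
    total = cov.sum()
    if total == 0:
        return MISSING
    return float(meth.sum() / total)


def bin_genome(genome: GenomeSpec, width_bp: int) -> pd.DataFrame:
    """Half-open tiling of every non-excluded chromosome.

    Returns a DataFrame (chrom, start, end) in genome order; the last bin of
    each chromosome is truncated at the chromosome end.
    """
    if width_bp <= 0:
        raise ValueError("bin width must be positive")
    frames = []
    for chrom in genome.analysis_chroms:
        length = genome.chrom_lengths[chrom]
        starts = np.arange(0, length, width_bp, dtype=np.int64)
        ends = np.minimum(starts + width_bp, length)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(frames, ignore_index=True)
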