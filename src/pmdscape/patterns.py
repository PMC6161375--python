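"""Read-level 4-CpG methylation pattern statistics.

Within each sequencing read carrying at least four CpG calls, sliding
windows of four consecutive CpGs are classified as fully methylated
(1111), fully unmethylated (0000) or mixed.  The three fractions separate
gradual, replication-coupled demethylation (fully-methylated mass moving
into fully-unmethylated with a stable mixed fraction) from disordered
erosion.  Summaries can be stratified by segment label (PMD/HMD/...),
attributing each window to the label under its midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pmdscape.core_io import SegmentSet

CATEGORIES = ("fully_methylated", "fully_unmethylated", "mixed")


@dataclass
class ReadCpGCalls:
    """One read: ordered CpG positions and their binary methylation calls."""

    read_id: str
    chrom: str
    positions: np.ndarray
    calls: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if len(self.positions) != len(self.calls):
            raise ValueError(f"read {self.read_id}: positions/calls length mismatch")
        if len(self.positions) > 1 and not (np.diff(self.positions) > 0).all():
            raise ValueError(f"read {self.read_id}: CpG positions not strictly increasing")
        if not np.isin(self.calls, [0, 1]).all():
            raise ValueError(f"read {self.read_id}: calls must be 0/1")


@dataclass
class PatternSummary:
    """Counts and fractions of the three 4-CpG window categories."""

    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in CATEGORIES}
    )

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float]:
        t = self.total
        if t == 0:
            return {c: float("nan") for c in CATEGORIES}
        return {c: self.counts[c] / t for c in CATEGORIES}

    def add(self, category: str, n: int = 1) -> None:
        self.counts[category] += n


def _window_categories(calls: np.ndarray, window: int, step: int) -> np.ndarray:
    """Category per sliding window: 0 full-meth, 1 full-unmeth, 2 mixed."""
    n = len(calls) - window + 1
    if n <= 0:
        return np.empty(0, dtype=np.int8)
    idx = np.arange(0, n, step)
    sums = np.cumsum(np.concatenate([[0], calls.astype(np.int64)]))
    wsum = sums[idx + window] - sums[idx]
    out = np.full(len(idx), 2, dtype=np.int8)
    out[wsum == window] = 0
    out[wsum == 0] = 1
    return out


def extract_patterns(
    reads: list[ReadCpGCalls], window: int = 4, step: int = 1
) -> PatternSummary:
    """Aggregate window categories over all reads with >= ``window`` CpGs."""
    summary = PatternSummary()
    for read in reads:
        cats = _window_categories(read.calls, window, step)
        for code, name in enumerate(CATEGORIES):
            summary.add(name, int(np.sum(cats == code)))
    return summary


def patterns_by_region(
    reads: list[ReadCpGCalls],
    segments: SegmentSet,
    window: int = 4,
    step: int = 1,
) -> dict[str, PatternSummary]:
    """Per-label pattern summaries; each window is attributed to the segment
    label covering the midpoint between its first and last CpG.  Windows
    over unlabeled ground fall into the "unassigned" stratum."""
    by_chrom: dict[str, pd.DataFrame] = {
        chrom: sub.sort_values("start") for chrom, sub in segments.df.groupby("chrom")
    }
    out: dict[str, PatternSummary] = {}
    for read in reads:
        cats = _window_categories(read.calls, window, step)
        if not len(cats):
            continue
        idx = np.arange(0, len(read.calls) - window + 1, step)
        mid = (read.positions[idx] + read.positions[idx + window - 1]) // 2
        sub = by_chrom.get(read.chrom)
        for m, c in zip(mid, cats):
            label = "unassigned"
            if sub is not None:
                hit = sub[(sub["start"] <= m) & (m < sub["end"])]
                if len(hit):
                    label = hit.iloc[0]["label"]
            out.setdefault(label, PatternSummary()).add(CATEGORIES[c])
    return out


def read_reads_tsv(path) -> list[ReadCpGCalls]:
    """Read the reads TSV: read_id, chrom, comma-separated positions, calls."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["read_id", "chrom", "positions", "calls"], dtype=str)
    out = []
    for r in df.itertuples():
        out.append(
            ReadCpGCalls(
                r.read_id,
                r.chrom,
                np.array([int(x) for x in r.positions.split(",")], dtype=np.int64),
                np.array([int(x) for x in r.calls.split(",")], dtype=np.int64),
            )
        )
    return out


def write_reads_tsv(reads: list[ReadCpGCalls], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            pos = ",".join(map(str, r.positions))
            calls = ",".join(map(str, r.calls))
            fh.write(f"{r.read_id}\t{r.chrom}\t{pos}\t{calls}\n")
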