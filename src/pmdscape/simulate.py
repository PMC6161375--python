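"""Synthetic multi-sample methylome cohorts with planted ground truth.

The generator emulates the qualitative structure of consortium WGBS
cohorts at desk scale: genomes partitioned into megabase-scale blocks that
are PMDs in every sample group (shared), PMDs in exactly one group
(cell-type-specific) or HMDs everywhere; disordered intermediate
methylation inside PMDs versus uniformly high methylation in HMDs; short
planted UMRs/LMRs; heterochromatic histone marks (H3K27me3/H3K9me3)
enriched over PMDs and the transcription-coupled H3K36me3 over HMDs;
Repli-seq phase signals that differ across three replication-timing
classes; reads carrying several consecutive CpG calls; and TADs whose
borders track PMD borders up to jitter.

Every draw flows from a single integer seed through
``numpy.random.default_rng``; identical seeds give identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pmdscape.core_io import GenomeSpec, Methylome, SegmentSet, SignalTrack
from pmdscape.patterns import ReadCpGCalls
from pmdscape.repli import CLASS_NAMES, PHASES

HMD_STATE = 0

# phase-profile means per replication class (G1, S1, S2, S3, S4, G2)
DEFAULT_REPLI_PROFILES = {
    "early/mid S": (0.5, 2.0, 2.0, 0.8, 0.3, 0.2),
    "mid/late S": (0.3, 0.5, 1.0, 2.0, 1.5, 0.4),
    "late S/G2": (0.2, 0.3, 0.4, 0.8, 2.0, 1.8),
}

# histone mark means (H3K27me3, H3K36me3, H3K9me3) per compartment
DEFAULT_MARK_MEANS = {
    "PMD": {"H3K27me3": 2.0, "H3K9me3": 2.0, "H3K36me3": 0.5},
    "HMD": {"H3K27me3": 0.5, "H3K9me3": 0.5, "H3K36me3": 2.0},
}

# class-specific mark means for the replication classifier benchmark
DEFAULT_CLASS_MARK_MEANS = {
    "early/mid S": {"H3K27me3": 4.0, "H3K9me3": 0.5, "H3K36me3": 0.5},
    "mid/late S": {"H3K27me3": 2.0, "H3K9me3": 2.0, "H3K36me3": 0.5},
    "late S/G2": {"H3K27me3": 0.5, "H3K9me3": 4.0, "H3K36me3": 0.5},
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic cohort."""

    seed: int
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 30_000_000, "chr2": 20_000_000}
    )
    # CpG spacing: geometric with this mean inter-CpG distance (bp)
    cpg_spacing_mean: float = 100.0
    # state-map architecture
    n_groups: int = 3
    n_shared_pmd_states: int = 1
    n_group_states_per_group: int = 1
    shared_pmd_fraction: float = 0.26
    specific_pmd_fraction: float = 0.08  # per group
    mean_pmd_block_bp: int = 600_000
    mean_hmd_block_bp: int = 800_000
    min_block_bp: int = 350_000  # keeps planted domains above the 300 kb scale
    # per-label methylation emission: mean and Beta concentration (a+b)
    label_means: dict[str, float] = field(
        default_factory=lambda: {"HMD": 0.9, "PMD": 0.5, "LMR": 0.25, "UMR": 0.05}
    )
    label_concentration: dict[str, float] = field(
        default_factory=lambda: {"HMD": 30.0, "PMD": 8.0, "LMR": 10.0, "UMR": 10.0}
    )
    # negative-binomial read coverage
    coverage_mean: float = 30.0
    coverage_size: float = 10.0
    # planted short regulatory regions per 10 Mb of HMD
    umr_per_10mb: float = 4.0
    lmr_per_10mb: float = 8.0
    umr_len_bp: int = 5_000
    lmr_len_bp: int = 1_000
    # signal tracks
    track_bin_bp: int = 5_000
    track_noise_frac: float = 0.1  # sd as a fraction of the class peak
    # reads
    read_cpgs: int = 6
    # TADs
    tad_jitter_sd_bp: float = 5_000.0
    tad_extra_border_per_mb: float = 0.2

    def genome(self) -> GenomeSpec:
        return GenomeSpec(dict(self.chrom_lengths), excluded_chroms=frozenset())


@dataclass
class SimTruth:
    """Planted state map: blocks, the state/group PMD design and the genome."""

    genome: GenomeSpec
    blocks: pd.DataFrame  # chrom, start, end, state
    state_is_pmd: np.ndarray  # (n_states, n_groups) bool
    n_groups: int

    @property
    def n_states(self) -> int:
        return len(self.state_is_pmd)

    def pmd_segments(self, group: int) -> SegmentSet:
        """True PMD intervals of one sample group (adjacent blocks merged)."""
        pmd_states = np.flatnonzero(self.state_is_pmd[:, group])
        sel = self.blocks[self.blocks["state"].isin(pmd_states)]
        rows = []
        for chrom, sub in sel.groupby("chrom"):
            sub = sub.sort_values("start")
            cur_s = cur_e = None
            for r in sub.itertuples():
                if cur_e is not None and r.start == cur_e:
                    cur_e = r.end
                else:
                    if cur_e is not None:
                        rows.append((chrom, cur_s, cur_e, "PMD"))
                    cur_s, cur_e = r.start, r.end
            if cur_e is not None:
                rows.append((chrom, cur_s, cur_e, "PMD"))
        return SegmentSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))

    def state_per_bin(self, bins: pd.DataFrame) -> np.ndarray:
        """Generating state of each genome bin (by bin start position)."""
        out = np.empty(len(bins), dtype=np.int64)
        for chrom, sub in self.blocks.groupby("chrom"):
            sub = sub.sort_values("start")
            sel = bins["chrom"].to_numpy() == chrom
            starts = bins["start"].to_numpy()[sel]
            idx = np.searchsorted(sub["start"].to_numpy(), starts, side="right") - 1
            out[sel] = sub["state"].to_numpy()[idx]
        return out

    def pmd_fraction(self, shared_only: bool = True) -> float:
        """bp fraction of the genome that is PMD in every group (or any)."""
        agg = self.state_is_pmd.all(axis=1) if shared_only else self.state_is_pmd.any(axis=1)
        lens = (self.blocks["end"] - self.blocks["start"]).to_numpy()
        sel = agg[self.blocks["state"].to_numpy()]
        return float(lens[sel].sum() / lens.sum())


def simulate_state_map(cfg: SimConfig) -> SimTruth:
    """Sample the block-wise state map.

    States: 0 = shared HMD, then ``n_shared_pmd_states`` shared-PMD states,
    then ``n_group_states_per_group`` states per group that are PMD in that
    group only.  Blocks draw a state from the configured genome fractions
    and a length from an exponential law truncated at ``min_block_bp``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_shared = cfg.n_shared_pmd_states
    n_spec = cfg.n_group_states_per_group
    n_states = 1 + n_shared + n_spec * cfg.n_groups
    state_is_pmd = np.zeros((n_states, cfg.n_groups), dtype=bool)
    state_is_pmd[1 : 1 + n_shared, :] = True
    for g in range(cfg.n_groups):
        lo = 1 + n_shared + g * n_spec
        state_is_pmd[lo : lo + n_spec, g] = True

    probs = np.empty(n_states)
    probs[0] = 1.0 - cfg.shared_pmd_fraction - cfg.n_groups * cfg.specific_pmd_fraction
    if probs[0] <= 0:
        raise ValueError("PMD fractions exceed the genome")
    probs[1 : 1 + n_shared] = cfg.shared_pmd_fraction / n_shared
    for g in range(cfg.n_groups):
        lo = 1 + n_shared + g * n_spec
        probs[lo : lo + n_spec] = cfg.specific_pmd_fraction / n_spec
    # convert bp fractions to block-draw probabilities: a state's bp share
    # equals draw probability times its expected block length E[max(m, Exp)]
    mean_len = np.where(state_is_pmd.any(axis=1), cfg.mean_pmd_block_bp, cfg.mean_hmd_block_bp)
    exp_len = cfg.min_block_bp + mean_len * np.exp(-cfg.min_block_bp / mean_len)
    draw_p = probs / exp_len
    draw_p /= draw_p.sum()

    rows = []
    for chrom, length in cfg.chrom_lengths.items():
        pos = 0
        while pos < length:
            state = int(rng.choice(n_states, p=draw_p))
            block = int(max(cfg.min_block_bp, rng.exponential(mean_len[state])))
            end = min(pos + block, length)
            # adjacent same-state draws merge into one block
            if rows and rows[-1][0] == chrom and rows[-1][3] == state and rows[-1][2] == pos:
                rows[-1] = (chrom, rows[-1][1], end, state)
            else:
                rows.append((chrom, pos, end, state))
            pos = end
    blocks = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
    return SimTruth(cfg.genome(), blocks, state_is_pmd, cfg.n_groups)


def _beta_params(mean: float, conc: float) -> tuple[float, float]:
    return mean * conc, (1.0 - mean) * conc


@dataclass
class SimulatedMethylome:
    methylome: Methylome
    regulatory: SegmentSet  # planted UMR/LMR intervals
    cpg_labels: np.ndarray  # per-CpG generating label (object array)
    cpg_levels: np.ndarray  # per-CpG true methylation probability


def simulate_methylome(
    truth: SimTruth,
    cfg: SimConfig,
    group: int,
    seed: int,
    sample_id: str | None = None,
) -> SimulatedMethylome:
    """One sample's CpG call table from the planted state map.

    CpG positions follow geometric spacing; each CpG draws a true level
    from the Beta law of its label (HMD/PMD block, or a planted UMR/LMR
    within HMDs) and methylated counts from Binomial(coverage, level) with
    negative-binomial coverage.
    """
    rng = np.random.default_rng(seed)
    pmd = truth.pmd_segments(group)
    chrom_lengths = truth.genome.chrom_lengths

    # plant UMR/LMR intervals inside HMD ground
    reg_rows = []
    for chrom, length in chrom_lengths.items():
        hmd_bp = length - sum(
            int(r.end - r.start) for r in pmd.df[pmd.df["chrom"] == chrom].itertuples()
        )
        for label, per10, reg_len in (
            ("UMR", cfg.umr_per_10mb, cfg.umr_len_bp),
            ("LMR", cfg.lmr_per_10mb, cfg.lmr_len_bp),
        ):
            n = rng.poisson(per10 * hmd_bp / 1e7)
            for _ in range(n):
                s = int(rng.integers(0, length - reg_len))
                reg_rows.append((chrom, s, s + reg_len, label))
    regulatory = SegmentSet(
        pd.DataFrame(reg_rows, columns=["chrom", "start", "end", "label"])
    )
    # keep only regulatory intervals fully outside PMDs
    if len(regulatory):
        keep = []
        for r in regulatory.df.itertuples():
            sub = pmd.df[pmd.df["chrom"] == r.chrom]
            if not ((sub["start"] < r.end) & (r.start < sub["end"])).any():
                keep.append(r.Index)
        regulatory = SegmentSet(regulatory.df.loc[keep].reset_index(drop=True))

    frames, labels_all, levels_all = [], [], []
    p_geom = 1.0 / cfg.cpg_spacing_mean
    for chrom, length in chrom_lengths.items():
        n_approx = int(1.2 * length * p_geom) + 100
        gaps = rng.geometric(p_geom, size=n_approx)
        pos = np.cumsum(gaps)
        pos = pos[pos < length]
        labels = np.full(len(pos), "HMD", dtype=object)
        sub = pmd.df[pmd.df["chrom"] == chrom]
        for r in sub.itertuples():
            labels[(pos >= r.start) & (pos < r.end)] = "PMD"
        sub = regulatory.df[regulatory.df["chrom"] == chrom]
        for r in sub.itertuples():
            labels[(pos >= r.start) & (pos < r.end)] = r.label
        levels = np.empty(len(pos))
        for label in ("HMD", "PMD", "LMR", "UMR"):
            mask = labels == label
            if mask.any():
                a, b = _beta_params(cfg.label_means[label], cfg.label_concentration[label])
                levels[mask] = rng.beta(a, b, size=int(mask.sum()))
        size = cfg.coverage_size
        p_nb = size / (size + cfg.coverage_mean)
        coverage = rng.negative_binomial(size, p_nb, size=len(pos))
        methylated = rng.binomial(coverage, levels)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos.astype(np.int64),
                    "strand": "+",
                    "coverage": coverage.astype(np.int64),
                    "methylated": methylated.astype(np.int64),
                }
            )
        )
        labels_all.append(labels)
        levels_all.append(levels)
    name = sample_id or f"group{group}_seed{seed}"
    return SimulatedMethylome(
        Methylome(pd.concat(frames, ignore_index=True), name),
        regulatory,
        np.concatenate(labels_all),
        np.concatenate(levels_all),
    )


def _noisy_track(
    genome: GenomeSpec,
    region_means: list[tuple[str, int, int, float]],
    bin_bp: int,
    noise_sd: float,
    rng: np.random.Generator,
) -> SignalTrack:
    """Step track: per-bin value = mean of the covering region + noise."""
    frames = []
    for chrom, length in genome.chrom_lengths.items():
        starts = np.arange(0, length, bin_bp, dtype=np.int64)
        ends = np.minimum(starts + bin_bp, length)
        vals = np.zeros(len(starts))
        for c, s, e, mu in region_means:
            if c != chrom:
                continue
            sel = (starts < e) & (ends > s)
            vals[sel] = mu
        vals = np.clip(vals + rng.normal(0, noise_sd, len(vals)), 0, None)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "value": vals}))
    return SignalTrack(pd.concat(frames, ignore_index=True))


def simulate_histone_tracks(
    truth: SimTruth, cfg: SimConfig, group: int, seed: int
) -> dict[str, SignalTrack]:
    """H3K27me3/H3K9me3 enriched over the group's PMDs, H3K36me3 over HMDs."""
    rng = np.random.default_rng(seed)
    pmd = truth.pmd_segments(group)
    out = {}
    peak = max(max(v.values()) for v in DEFAULT_MARK_MEANS.values())
    for mark in ("H3K27me3", "H3K9me3", "H3K36me3"):
        regions = [
            (r.chrom, r.start, r.end, DEFAULT_MARK_MEANS["PMD"][mark])
            for r in pmd.df.itertuples()
        ]
        # background = HMD level genome-wide, PMD regions overwrite it
        base = DEFAULT_MARK_MEANS["HMD"][mark]
        out[mark] = _noisy_track(
            truth.genome,
            [(c, 0, truth.genome.chrom_lengths[c], base) for c in truth.genome.chrom_names]
            + regions,
            cfg.track_bin_bp,
            cfg.track_noise_frac * peak,
            rng,
        )
    return out


def plant_replication_classes(
    pmds: SegmentSet, cfg: SimConfig, seed: int
) -> np.ndarray:
    """Assign each PMD a replication class uniformly at random (balanced)."""
    rng = np.random.default_rng(seed)
    n = len(pmds)
    classes = np.array(CLASS_NAMES, dtype=object)[np.arange(n) % 3]
    return rng.permutation(classes)


def simulate_repli_tracks(
    pmds: SegmentSet,
    classes: np.ndarray,
    genome: GenomeSpec,
    cfg: SimConfig,
    seed: int,
) -> dict[str, SignalTrack]:
    """Six phase tracks whose PMD-internal means follow the class profiles."""
    rng = np.random.default_rng(seed)
    peak = max(max(v) for v in DEFAULT_REPLI_PROFILES.values())
    out = {}
    for pi, phase in enumerate(PHASES):
        regions = [
            (r.chrom, r.start, r.end, DEFAULT_REPLI_PROFILES[cls][pi])
            for r, cls in zip(pmds.df.itertuples(), classes)
        ]
        base = 0.5  # background replication signal outside PMDs
        out[phase] = _noisy_track(
            genome,
            [(c, 0, genome.chrom_lengths[c], base) for c in genome.chrom_names] + regions,
            cfg.track_bin_bp,
            cfg.track_noise_frac * peak,
            rng,
        )
    return out


def simulate_class_histone_tracks(
    pmds: SegmentSet,
    classes: np.ndarray,
    genome: GenomeSpec,
    cfg: SimConfig,
    seed: int,
) -> dict[str, SignalTrack]:
    """Histone tracks whose PMD-internal means depend on the planted
    replication class (>= 4:1 contrast between extreme classes)."""
    rng = np.random.default_rng(seed)
    peak = max(max(v.values()) for v in DEFAULT_CLASS_MARK_MEANS.values())
    out = {}
    for mark in ("H3K27me3", "H3K9me3", "H3K36me3"):
        regions = [
            (r.chrom, r.start, r.end, DEFAULT_CLASS_MARK_MEANS[cls][mark])
            for r, cls in zip(pmds.df.itertuples(), classes)
        ]
        base = 0.5
        out[mark] = _noisy_track(
            genome,
            [(c, 0, genome.chrom_lengths[c], base) for c in genome.chrom_names] + regions,
            cfg.track_bin_bp,
            cfg.track_noise_frac * peak,
            rng,
        )
    return out


def simulate_reads(
    sim: SimulatedMethylome,
    cfg: SimConfig,
    n_reads: int,
    seed: int,
    erosion_q: float = 0.0,
) -> list[ReadCpGCalls]:
    """Reads of ``cfg.read_cpgs`` consecutive CpGs with Bernoulli calls.

    ``erosion_q`` applies an independent per-CpG demethylation probability
    on top of the true levels, emulating replication-coupled methylation
    loss during clonal expansion.
    """
    rng = np.random.default_rng(seed)
    df = sim.methylome.df
    chroms = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    levels = sim.cpg_levels
    n_cpg = len(df)
    out = []
    k = cfg.read_cpgs
    for i in range(n_reads):
        start = int(rng.integers(0, n_cpg - k))
        if len(set(chroms[start : start + k])) > 1:
            continue  # read would span a chromosome break; skip
        p = levels[start : start + k] * (1.0 - erosion_q)
        calls = rng.binomial(1, p)
        out.append(
            ReadCpGCalls(f"read_{i}", chroms[start], pos[start : start + k], calls)
        )
    return out


def perturb_segments(
    segs: SegmentSet,
    genome: GenomeSpec,
    seed: int,
    border_jitter_sd: float = 10_000.0,
    drop_prob: float = 0.02,
) -> SegmentSet:
    """Sample-level variation on a segment set: jittered borders, rare drops.

    Emulates the call-to-call variability of per-sample segmentations of
    replicate methylomes without re-running the segmenter.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for r in segs.df.itertuples():
        if rng.random() < drop_prob:
            continue
        length = genome.chrom_lengths[r.chrom]
        s = int(np.clip(r.start + rng.normal(0, border_jitter_sd), 0, length - 2))
        e = int(np.clip(r.end + rng.normal(0, border_jitter_sd), s + 1, length))
        rows.append((r.chrom, s, e, r.label))
    return SegmentSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))


def simulate_tads(
    truth: SimTruth, cfg: SimConfig, group: int, seed: int
) -> SegmentSet:
    """TAD intervals whose borders are jittered PMD borders plus extras."""
    rng = np.random.default_rng(seed)
    pmd = truth.pmd_segments(group)
    rows = []
    for chrom, length in truth.genome.chrom_lengths.items():
        sub = pmd.df[pmd.df["chrom"] == chrom]
        borders = np.unique(
            np.concatenate([sub["start"].to_numpy(), sub["end"].to_numpy()])
        ).astype(float)
        borders = borders + rng.normal(0, cfg.tad_jitter_sd_bp, len(borders))
        n_extra = rng.poisson(cfg.tad_extra_border_per_mb * length / 1e6)
        extra = rng.uniform(0, length, n_extra)
        all_b = np.unique(np.clip(np.concatenate([borders, extra]), 0, length).astype(np.int64))
        all_b = np.concatenate([[0], all_b, [length]])
        all_b = np.unique(all_b)
        for s, e in zip(all_b[:-1], all_b[1:]):
            if e - s >= 10_000:
                rows.append((chrom, int(s), int(e), "TAD"))
    return SegmentSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))
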