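"""Single-sample methylome segmentation into UMR / LMR / PMD / HMD.

The PMD caller is a two-state hidden Markov model over per-CpG (smoothed)
methylation levels: a foreground state with high methylation (HMD) and a
background state with low/intermediate methylation (PMD).  Emissions are
Beta distributions fitted by EM; decoding is per-CpG maximum posterior.
Hypomethylated segments shorter than 300 kb are filtered out and absorbed
into the flanking highly methylated domain.

Short hypomethylated regions (UMRs and LMRs) are called outside PMDs as
runs of CpGs whose smoothed level falls below 0.5, with an empirical FDR
estimated by re-detecting candidates on within-chromosome permutations of
the CpG levels.  Surviving regions with more than 30 CpGs are UMRs
(promoter-like), the rest LMRs (enhancer-like).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln

from pmdscape import _hmm
from pmdscape import intervals as iv
from pmdscape.core_io import Methylome, SegmentSet, weighted_mean_methylation

logger = logging.getLogger(__name__)

EPS = 1e-3  # levels clamped to (EPS, 1-EPS) before Beta evaluation


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the full four-label segmentation."""

    min_coverage: int = 5  # reads per CpG
    meth_threshold: float = 0.5  # hypomethylation cut on smoothed levels
    fdr_max: float = 0.05
    min_cpgs_lmr: int = 4
    window_cpgs: int = 101  # minimum CpGs per chromosome to attempt the HMM
    smooth_cpgs: int = 3
    umr_lmr_split: int = 30  # CpG count above which a region is a UMR
    n_permutations: int = 20

    def __post_init__(self):
        if not (0 < self.meth_threshold < 1 and 0 < self.fdr_max < 1):
            raise ValueError("meth_threshold and fdr_max must lie in (0,1)")


@dataclass
class TwoStateHMMParams:
    """Two-state Beta-emission HMM configuration.

    State 0 is the foreground (highly methylated) state, state 1 the
    background (PMD/hypomethylated) state.
    """

    mean_high: float = 0.9
    mean_low: float = 0.45
    concentration: float = 10.0  # initial Beta concentration (a+b) per state
    self_transition: float = 0.999
    min_region_bp: int = 300_000
    max_iter: int = 200
    tol: float = 1e-4  # absolute log-likelihood gain per CpG
    fit: bool = True  # EM-fit parameters (False: decode with the fixed ones)

    # populated after fitting
    state_means_: tuple[float, float] | None = field(default=None, compare=False)
    loglik_path_: list[float] = field(default_factory=list, compare=False)

    def __post_init__(self):
        if not self.mean_high > self.mean_low:
            raise ValueError("foreground mean must exceed background mean")


def smooth_methylation(m: Methylome, k: int = 3) -> np.ndarray:
    """Running mean of per-CpG levels over k consecutive CpGs per chromosome.

    Edge CpGs use truncated windows; chromosome boundaries are not crossed.
    Zero-coverage CpGs contribute NaN and are ignored within a window.
    """
    if k % 2 == 0 or k < 1:
        raise ValueError("smoothing window k must be odd and positive")
    levels = m.levels
    out = np.empty_like(levels)
    chroms = m.df["chrom"].to_numpy()
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        x = levels[idx]
        if k == 1:
            out[idx] = x
            continue
        h = k // 2
        valid = np.isfinite(x)
        vals = np.where(valid, x, 0.0)
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        ccnt = np.concatenate([[0], np.cumsum(valid.astype(int))])
        n = len(x)
        lo = np.maximum(np.arange(n) - h, 0)
        hi = np.minimum(np.arange(n) + h + 1, n)
        cnt = ccnt[hi] - ccnt[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            out[idx] = np.where(cnt > 0, (csum[hi] - csum[lo]) / cnt, np.nan)
    return out


# ---------------------------------------------------------------------------
# Beta-emission EM


def _beta_loglik_matrix(x: np.ndarray, params: np.ndarray) -> np.ndarray:
    """(T, K) log-likelihoods of levels under each state's Beta(a, b)."""
    a, b = params[:, 0], params[:, 1]
    return (
        np.outer(np.log(x), a - 1.0)
        + np.outer(np.log1p(-x), b - 1.0)
        - betaln(a, b)[None, :]
    )

def _fit_beta_weighted(x: np.ndarray, w: np.ndarray, init: tuple[float, float]) -> tuple[float, float]:
    """Weighted maximum-likelihood Beta fit via L-BFGS on log-parameters."""
    wsum = w.sum()
    if wsum <= 0:
        return init
    mlx = float(np.dot(w, np.log(x)) / wsum)
    ml1x = float(np.dot(w, np.log1p(-x)) / wsum)

    def nll(theta):
        a, b = np.exp(theta)
        val = betaln(a, b) - (a - 1.0) * mlx - (b - 1.0) * ml1x
        from scipy.special import digamma

        dab = digamma(a + b)
        grad_a = a * (digamma(a) - dab - mlx)
        grad_b = b * (digamma(b) - dab - ml1x)
        return val, np.array([grad_a, grad_b])

    res = minimize(nll, np.log(np.maximum(init, 1e-2)), jac=True, method="L-BFGS-B")
    a, b = np.exp(res.x)
    return float(np.clip(a, 1e-2, 1e4)), float(np.clip(b, 1e-2, 1e4))


def _runs_to_segments(chrom, pos, states, chrom_end=None):
    """Convert a per-CpG state path into bp segments.

    Boundaries between runs fall at the midpoint of the flanking CpGs; the
    first segment starts at the first CpG and the last ends one base past
    the final CpG (or at the chromosome end when given).
    """
    change = np.flatnonzero(np.diff(states)) + 1
    run_starts = np.concatenate([[0], change])
    run_ends = np.concatenate([change, [len(states)]])
    seg_starts, seg_ends, seg_states = [], [], []
    for rs, re in zip(run_starts, run_ends):
        start = int(pos[rs]) if rs == 0 else (int(pos[rs - 1]) + int(pos[rs]) + 1) // 2
        if re == len(states):
            end = int(pos[-1]) + 1 if chrom_end is None else int(chrom_end)
        else:
            end = (int(pos[re - 1]) + int(pos[re]) + 1) // 2
        seg_starts.append(start)
        seg_ends.append(end)
        seg_states.append(int(states[rs]))
    return seg_starts, seg_ends, seg_states


def segment_two_state(
    m: Methylome,
    p: TwoStateHMMParams | None = None,
    seed: int = 0,
    genome=None,
) -> SegmentSet:
    """Two-state HMM segmentation into HMD and PMD/hypomethylated regions.

    The methylome should already be coverage-filtered.  Levels are smoothed
    over 3 CpGs, clamped into (0, 1) and modelled with per-state Beta
    emissions.  Background-state segments shorter than ``min_region_bp``
    are removed and absorbed into the flanking HMD.
    """
    p = p or TwoStateHMMParams()
    levels = smooth_methylation(m, 3)
    chroms = m.df["chrom"].to_numpy()
    pos_all = m.df["pos"].to_numpy()

    chains = []  # (chrom, pos, clamped levels)
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        x = levels[idx]
        ok = np.isfinite(x)
        if ok.sum() < 2 * 101:
            logger.warning("chromosome %s has too few CpGs (%d); skipped", chrom, ok.sum())
            continue
        chains.append((chrom, pos_all[idx][ok], np.clip(x[ok], EPS, 1 - EPS)))
    if not chains:
        return SegmentSet(pd.DataFrame(columns=["chrom", "start", "end", "label", "score"]))

    # initial parameters: Beta means at the configured state means
    conc = p.concentration
    params = np.array(
        [
            [p.mean_high * conc, (1 - p.mean_high) * conc],
            [p.mean_low * conc, (1 - p.mean_low) * conc],
        ]
    )
    A = np.full((2, 2), 1 - p.self_transition)
    np.fill_diagonal(A, p.self_transition)
    pi = np.array([0.5, 0.5])

    p.loglik_path_ = []
    n_iter = p.max_iter if p.fit else 1
    n_obs = sum(len(c[2]) for c in chains)
    for it in range(n_iter):
        ll = 0.0
        gam_all, xi = [], np.zeros((2, 2))
        pi_acc = np.zeros(2)
        for _, _, x in chains:
            B = np.exp(_beta_loglik_matrix(x, params))
            g, x2, l = _hmm.forward_backward(pi, A, np.ascontiguousarray(B))
            gam_all.append(g)
            xi += x2
            pi_acc += g[0]
            ll += l
        p.loglik_path_.append(ll)
        if not p.fit:
            break
        if it > 0 and ll - p.loglik_path_[-2] < p.tol * n_obs / 100:
            break
        # M-step
        A = xi / xi.sum(axis=1, keepdims=True)
        pi = pi_acc / pi_acc.sum()
        xs = np.concatenate([c[2] for c in chains])
        gs = np.concatenate(gam_all, axis=0)
        for k in range(2):
            a, b = _fit_beta_weighted(xs, gs[:, k], tuple(params[k]))
            params[k] = (a, b)
        # keep state 0 the high-methylation state
        means = params[:, 0] / params.sum(axis=1)
        if means[0] < means[1]:
            params = params[::-1]
            A = A[::-1][:, ::-1]
            pi = pi[::-1]
    means = params[:, 0] / params.sum(axis=1)
    p.state_means_ = (float(means[0]), float(means[1]))
    # one-state data: EM collapses both states onto (nearly) the same Beta,
    # so the posterior split is arbitrary — emit a single label instead
    degenerate = abs(means[0] - means[1]) < 0.1

    # decode and convert runs to segments
    rows = []
    for chrom, pos, x in chains:
        if degenerate:
            states = np.zeros(len(x), dtype=np.int64) if x.mean() >= 0.5 else np.ones(
                len(x), dtype=np.int64
            )
        else:
            B = np.exp(_beta_loglik_matrix(x, params))
            g, _, _ = _hmm.forward_backward(pi, A, np.ascontiguousarray(B))
            states = np.argmax(g, axis=1)  # ties: lowest state index
        chrom_end = genome.chrom_lengths.get(chrom) if genome is not None else None
        ss, ee, st = _runs_to_segments(chrom, pos, states, chrom_end)
        for s, e, k in zip(ss, ee, st):
            rows.append((chrom, s, e, "PMD" if k == 1 else "HMD"))
    seg = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])

    # filter runs shorter than min_region_bp, absorbing them into their
    # flanks (runs of a two-state decode alternate, so interior neighbours
    # always agree); shortest runs are absorbed first
    out = []
    for chrom, sub in seg.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        runs = list(zip(sub["start"], sub["end"], sub["label"]))
        while len(runs) > 1:
            lengths = [e - s for s, e, _ in runs]
            short = [i for i, L in enumerate(lengths) if L < p.min_region_bp]
            if not short:
                break
            i = min(short, key=lambda j: lengths[j])
            lab = runs[i + 1][2] if i == 0 else runs[i - 1][2]
            runs[i] = (runs[i][0], runs[i][1], lab)
            merged = [runs[0]]
            for s, e, la in runs[1:]:
                if la == merged[-1][2] and s == merged[-1][1]:
                    merged[-1] = (merged[-1][0], e, la)
                else:
                    merged.append((s, e, la))
            runs = merged
        for s, e, lab in runs:
            out.append((chrom, int(s), int(e), lab))
    result = SegmentSet(pd.DataFrame(out, columns=["chrom", "start", "end", "label"]))
    scores = [
        weighted_mean_methylation(m, r.chrom, r.start, r.end) for r in result.df.itertuples()
    ]
    result.df["score"] = scores
    return result


# ---------------------------------------------------------------------------
# UMR / LMR detection


def _find_candidates(pos, smoothed, threshold, min_cpgs):
    """Maximal runs of CpGs with smoothed level below threshold."""
    below = smoothed < threshold
    out = []  # (first_idx, last_idx, n_cpgs, mean_level)
    change = np.flatnonzero(np.diff(below.astype(int)))
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [len(below)]])
    for s, e in zip(starts, ends):
        if below[s] and e - s >= min_cpgs:
            out.append((s, e, e - s, float(np.mean(smoothed[s:e]))))
    return out


def call_umr_lmr(
    m: Methylome,
    pmd_mask: SegmentSet | None,
    p: SegmentationParams | None = None,
    seed: int = 0,
) -> SegmentSet:
    """Detect UMRs/LMRs outside PMDs with a permutation-based FDR control.

    Candidates are runs of >= ``min_cpgs_lmr`` CpGs whose smoothed level is
    below ``meth_threshold``.  The minimum-CpG acceptance cut is raised
    until the empirical FDR — the mean number of candidates detected on
    within-chromosome permutations of the levels, relative to the observed
    number — drops to ``fdr_max``.  Surviving regions with more than
    ``umr_lmr_split`` CpGs are labelled UMR, the others LMR.
    """
    p = p or SegmentationParams()
    rng = np.random.default_rng(seed)
    chroms = m.df["chrom"].to_numpy()
    pos_all = m.df["pos"].to_numpy()
    levels_all = m.levels

    def smooth_seq(x: np.ndarray, k: int) -> np.ndarray:
        if k == 1 or len(x) == 0:
            return x
        h = k // 2
        csum = np.concatenate([[0.0], np.cumsum(x)])
        n = len(x)
        lo = np.maximum(np.arange(n) - h, 0)
        hi = np.minimum(np.arange(n) + h + 1, n)
        return (csum[hi] - csum[lo]) / (hi - lo)

    obs = []  # (chrom, first_pos, last_pos, n_cpgs, mean)
    perm_counts: dict[int, float] = {}
    obs_counts: dict[int, int] = {}
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        raw = levels_all[idx]
        pos = pos_all[idx]
        ok = np.isfinite(raw)
        raw, pos = raw[ok], pos[ok]
        if pmd_mask is not None and len(pmd_mask):
            sub = pmd_mask.df[pmd_mask.df["chrom"] == chrom]
            inside = np.zeros(len(pos), dtype=bool)
            for r in sub.itertuples():
                inside |= (pos >= r.start) & (pos < r.end)
            raw, pos = raw[~inside], pos[~inside]
        if len(raw) < p.min_cpgs_lmr:
            continue
        x = smooth_seq(raw, p.smooth_cpgs)
        for s, e, n, mean in _find_candidates(pos, x, p.meth_threshold, p.min_cpgs_lmr):
            obs.append((chrom, int(pos[s]), int(pos[e - 1]), n, mean))
            obs_counts[n] = obs_counts.get(n, 0) + 1
        # null: permute the raw levels, then smooth, so the null carries the
        # same smoothing-induced autocorrelation as the observed scan
        for _ in range(p.n_permutations):
            xp = smooth_seq(rng.permutation(raw), p.smooth_cpgs)
            for s, e, n, _ in _find_candidates(pos, xp, p.meth_threshold, p.min_cpgs_lmr):
                perm_counts[n] = perm_counts.get(n, 0.0) + 1.0 / p.n_permutations

    if not obs:
        return SegmentSet(pd.DataFrame(columns=["chrom", "start", "end", "label", "score"]))

    # raise the CpG-count cut until the tail FDR is controlled
    cut = p.min_cpgs_lmr
    max_n = max(obs_counts)
    while cut <= max_n:
        obs_tail = sum(c for n, c in obs_counts.items() if n >= cut)
        perm_tail = sum(c for n, c in perm_counts.items() if n >= cut)
        if obs_tail == 0:
            break
        if perm_tail / obs_tail <= p.fdr_max:
            break
        cut += 1

    rows = []
    for chrom, first, last, n, mean in obs:
        if n < cut:
            continue
        label = "UMR" if n > p.umr_lmr_split else "LMR"
        rows.append((chrom, first, last + 1, label, mean))
    return SegmentSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "label", "score"]))


def segment_full(
    m: Methylome,
    p: SegmentationParams | None = None,
    hmm_params: TwoStateHMMParams | None = None,
    gaps: SegmentSet | None = None,
    genome=None,
    seed: int = 0,
) -> SegmentSet:
    """Full four-label segmentation: PMD/HMD by HMM, then UMR/LMR outside PMDs.

    The four labels partition the non-gap portion of the covered genome;
    assembly gaps (if supplied) carry no label.
    """
    p = p or SegmentationParams()
    m = m.filter_coverage(p.min_coverage)
    two = segment_two_state(m, hmm_params, seed=seed, genome=genome)
    pmds = two.with_label("PMD")
    short = call_umr_lmr(m, pmds, p, seed=seed)

    frames = []
    for chrom in dict.fromkeys(two.df["chrom"]):
        g_s, g_e = (np.array([], dtype=np.int64),) * 2
        if gaps is not None and len(gaps):
            sub = gaps.df[gaps.df["chrom"] == chrom]
            g_s, g_e = sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)
        carved: list[tuple[np.ndarray, np.ndarray, str]] = []
        # PMDs minus gaps
        sub = pmds.df[pmds.df["chrom"] == chrom]
        ps, pe = iv.subtract(sub["start"].to_numpy(), sub["end"].to_numpy(), g_s, g_e)
        carved.append((ps, pe, "PMD"))
        # UMR/LMR minus gaps (they were called outside PMDs)
        taken_s, taken_e = ps.copy(), pe.copy()
        for lab in ("UMR", "LMR"):
            sub = short.df[(short.df["chrom"] == chrom) & (short.df["label"] == lab)]
            ls, le = iv.subtract(sub["start"].to_numpy(), sub["end"].to_numpy(), g_s, g_e)
            ls, le = iv.subtract(ls, le, taken_s, taken_e)
            carved.append((ls, le, lab))
            taken_s, taken_e = iv.merge(
                np.concatenate([taken_s, ls]), np.concatenate([taken_e, le])
            )
        # HMD = everything else within the HMM's footprint
        sub = two.df[two.df["chrom"] == chrom]
        fs, fe = iv.merge(sub["start"].to_numpy(), sub["end"].to_numpy())
        hs, he = iv.subtract(fs, fe, g_s, g_e)
        hs, he = iv.subtract(hs, he, taken_s, taken_e)
        carved.append((hs, he, "HMD"))
        for ss, ee, lab in carved:
            if len(ss):
                frames.append(
                    pd.DataFrame({"chrom": chrom, "start": ss, "end": ee, "label": lab})
                )
    if not frames:
        return SegmentSet(pd.DataFrame(columns=["chrom", "start", "end", "label", "score"]))
    out = SegmentSet(pd.concat(frames, ignore_index=True))
    out.df["score"] = [
        weighted_mean_methylation(m, r.chrom, r.start, r.end) for r in out.df.itertuples()
    ]
    return out


def fuse_and_filter(
    s: SegmentSet, fuse_gap_bp: int = 50_000, min_len_bp: int = 300_000
) -> SegmentSet:
    """Fuse same-label segments closer than ``fuse_gap_bp``; keep those longer
    than ``min_len_bp``.  Idempotent."""
    labels = s.df["label"].unique()
    if len(labels) > 1:
        raise ValueError("fuse_and_filter expects a single-label segment set")
    rows = []
    label = labels[0] if len(labels) else "segment"
    for chrom, ss, ee in s.per_chrom():
        ms, me = iv.merge(ss, ee, gap=fuse_gap_bp)
        keep = (me - ms) > min_len_bp
        for a, b in zip(ms[keep], me[keep]):
            rows.append((chrom, int(a), int(b), label))
    return SegmentSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))
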