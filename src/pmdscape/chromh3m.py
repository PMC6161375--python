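"""ChromH3M meta-segmentation of PMD calls across many samples.

Per-sample PMD (or UMR/LMR) calls are binarized on a 1 kb genome grid and
modelled jointly with a multi-state HMM whose emissions are products of
independent per-sample Bernoullis — each hidden state is a combinatorial
PMD pattern (shared PMD, group-specific PMD, shared HMD, ...).  The fitted
emission matrix is hierarchically clustered (Ward on Euclidean distances)
to relate samples, with cluster uncertainty assessed by multiscale
bootstrap (AU p-values).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import norm
from sklearn.cluster import KMeans

from pmdscape import _hmm
from pmdscape.core_io import SegmentSet
from pmdscape import intervals as iv

logger = logging.getLogger(__name__)

MISSING_CODE = -1  # bins with undefined PMD status (marginalized out)


@dataclass
class BinaryBinMatrix:
    """0/1 PMD occupancy per (genome bin, sample).

    ``values`` is int8 with -1 marking missing bins; ``bins`` is the
    (chrom, start, end) table from :func:`pmdscape.core_io.bin_genome`.
    HMM chains break at chromosome boundaries.
    """

    bins: pd.DataFrame
    samples: list[str]
    values: np.ndarray

    def __post_init__(self):
        if self.values.shape != (len(self.bins), len(self.samples)):
            raise ValueError("values shape must be (n_bins, n_samples)")
        if not np.isin(self.values, [-1, 0, 1]).all():
            raise ValueError("values must be 0, 1 or -1 (missing)")
        self.values = self.values.astype(np.int8)

    def chain_slices(self) -> list[slice]:
        """One contiguous slice per chromosome, in bin order."""
        chroms = self.bins["chrom"].to_numpy()
        change = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
        bounds = np.concatenate([[0], change, [len(chroms)]])
        return [slice(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


@dataclass
class MetaHMM:
    """Multi-track Bernoulli-emission HMM over binarized PMD calls."""

    startprob: np.ndarray  # (K,)
    transmat: np.ndarray  # (K, K)
    emissions: np.ndarray  # (K, S): P(bin is PMD | state), per sample
    samples: list[str]
    loglik_path_: list[float] = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return len(self.startprob)


@dataclass
class StateMap:
    """Decoded per-bin state with per-state genome fractions."""

    bins: pd.DataFrame
    states: np.ndarray
    n_states: int

    @property
    def fractions(self) -> np.ndarray:
        return np.bincount(self.states, minlength=self.n_states) / len(self.states)

    def to_segments(self) -> SegmentSet:
        rows = []
        chroms = self.bins["chrom"].to_numpy()
        starts = self.bins["start"].to_numpy()
        ends = self.bins["end"].to_numpy()
        change = np.flatnonzero(
            (self.states[1:] != self.states[:-1]) | (chroms[1:] != chroms[:-1])
        )
        run_start = np.concatenate([[0], change + 1])
        run_end = np.concatenate([change, [len(self.states) - 1]])
        for a, b in zip(run_start, run_end):
            rows.append((chroms[a], int(starts[a]), int(ends[b]), f"state_{self.states[a] + 1}"))
        return SegmentSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))


@dataclass
class ClusterTreeAU:
    """Ward dendrogram(s) over samples/states with optional AU support."""

    sample_linkage: np.ndarray
    state_linkage: np.ndarray | None
    samples: list[str]
    au: dict[frozenset, float] | None = None  # clade (leaf-index set) -> AU in [0, 100]
    bp: dict[frozenset, float] | None = None

    def cut_samples(self, k: int) -> np.ndarray:
        return fcluster(self.sample_linkage, k, criterion="maxclust")


# ---------------------------------------------------------------------------


def binarize_segments(
    sample_segments: dict[str, SegmentSet],
    bins: pd.DataFrame,
    label: str = "PMD",
) -> BinaryBinMatrix:
    """1 iff a bin overlaps (>= 1 bp) a segment of ``label`` in that sample."""
    samples = list(sample_segments)
    values = np.zeros((len(bins), len(samples)), dtype=np.int8)
    chroms = bins["chrom"].to_numpy()
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    for j, name in enumerate(samples):
        segs = sample_segments[name].with_label(label)
        if not len(segs):
            logger.warning("sample %s has zero %s segments; all-zero column", name, label)
            continue
        for chrom, ss, ee in segs.per_chrom():
            sel = np.flatnonzero(chroms == chrom)
            if not len(sel):
                continue
            ov = iv.overlap_per_interval(starts[sel], ends[sel], ss, ee)
            values[sel[ov > 0], j] = 1
    return BinaryBinMatrix(bins.reset_index(drop=True), samples, values)


def _emission_loglik(values: np.ndarray, E: np.ndarray) -> np.ndarray:
    E = np.clip(E, 1e-10, 1 - 1e-10)
    obs = values != MISSING_CODE
    x1 = ((values == 1) & obs).astype(np.float64)
    x0 = ((values == 0) & obs).astype(np.float64)
    return x1 @ np.log(E).T + x0 @ np.log(1 - E).T


def train_meta_hmm(
    x: BinaryBinMatrix,
    n_states: int = 15,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> MetaHMM:
    """Baum-Welch fit of the product-Bernoulli HMM.

    Initial emissions come from k-means centroids over bin vectors (plus a
    little seeded jitter); transitions start sticky.  EM stops when the
    log-likelihood gain falls below ``tol`` per 1e6 bin-observations, or at
    ``max_iter``.  The log-likelihood is non-decreasing across iterations.
    """
    rng = np.random.default_rng(seed)
    values = x.values
    T, S = values.shape
    distinct = len(np.unique(values, axis=0))
    if n_states > distinct:
        logger.warning(
            "n_states=%d exceeds the %d distinct bin patterns; states may be degenerate",
            n_states,
            distinct,
        )

    filled = np.where(values == MISSING_CODE, 0, values).astype(float)
    km = KMeans(n_clusters=min(n_states, max(distinct, 1)), n_init=3, random_state=seed)
    km.fit(filled)
    E = np.full((n_states, S), 0.5)
    E[: km.n_clusters] = km.cluster_centers_
    E = np.clip(E + rng.normal(0, 0.02, E.shape), 0.02, 0.98)

    A = np.full((n_states, n_states), 0.05 / max(n_states - 1, 1))
    np.fill_diagonal(A, 0.95)
    pi = np.full(n_states, 1.0 / n_states)

    chains = x.chain_slices()
    tol_total = tol * (T * S) / 1e6
    loglik_path: list[float] = []
    for it in range(max_iter):
        logB_all = _emission_loglik(values, E)
        shift = logB_all.max(axis=1, keepdims=True)
        B_all = np.exp(logB_all - shift)
        ll = float(shift.sum())
        xi = np.zeros((n_states, n_states))
        pi_acc = np.zeros(n_states)
        g_num = np.zeros((n_states, S))
        g_den = np.zeros((n_states, S))
        obs = values != MISSING_CODE
        x1 = ((values == 1) & obs).astype(np.float64)
        for sl in chains:
            g, xx, l = _hmm.forward_backward(pi, A, np.ascontiguousarray(B_all[sl]))
            ll += l
            xi += xx
            pi_acc += g[0]
            g_num += g.T @ x1[sl]
            g_den += g.T @ obs[sl].astype(np.float64)
        loglik_path.append(ll)
        if it > 0 and ll - loglik_path[-2] < tol_total:
            break
        A = xi / np.maximum(xi.sum(axis=1, keepdims=True), 1e-300)
        pi = pi_acc / pi_acc.sum()
        E = g_num / np.maximum(g_den, 1e-300)
        E = np.clip(E, 1e-6, 1 - 1e-6)
    model = MetaHMM(pi, A, E, list(x.samples))
    model.loglik_path_ = loglik_path
    return model


def forward_loglik(model: MetaHMM, x: BinaryBinMatrix) -> float:
    """Total scaled-forward log-likelihood across all chromosome chains."""
    logB = _emission_loglik(x.values, model.emissions)
    shift = logB.max(axis=1, keepdims=True)
    B = np.exp(logB - shift)
    ll = float(shift.sum())
    pi = np.ascontiguousarray(model.startprob)
    A = np.ascontiguousarray(model.transmat)
    for sl in x.chain_slices():
        _, _, l = _hmm.forward_scaled(pi, A, np.ascontiguousarray(B[sl]))
        ll += l
    return ll


def decode_states(model: MetaHMM, x: BinaryBinMatrix) -> StateMap:
    """Per-bin maximum-posterior state (ties: lowest state index)."""
    if list(x.samples) != list(model.samples):
        raise ValueError("sample set of matrix does not match the trained model")
    logB = _emission_loglik(x.values, model.emissions)
    B = np.exp(logB - logB.max(axis=1, keepdims=True))
    states = np.empty(len(x.bins), dtype=np.int64)
    for sl in x.chain_slices():
        g, _, _ = _hmm.forward_backward(
            model.startprob, model.transmat, np.ascontiguousarray(B[sl])
        )
        states[sl] = np.argmax(g, axis=1)
    return StateMap(x.bins, states, model.n_states)


def cluster_emissions(model: MetaHMM) -> ClusterTreeAU:
    """Ward dendrograms of samples (on state profiles) and states (on sample
    profiles), both on Euclidean distances of raw emission probabilities."""
    sample_link = linkage(pdist(model.emissions.T), method="ward")
    state_link = linkage(pdist(model.emissions), method="ward")
    return ClusterTreeAU(sample_link, state_link, list(model.samples))


# ---------------------------------------------------------------------------
# multiscale bootstrap (AU p-values)


def _clades(link: np.ndarray, n: int) -> list[frozenset]:
    members: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    out = []
    for i, (a, b, _, _) in enumerate(link):
        cl = members[int(a)] | members[int(b)]
        members[n + i] = cl
        out.append(cl)
    return out


def au_bootstrap(
    data: np.ndarray,
    names: list[str],
    n_boot: int = 10_000,
    scales: np.ndarray | None = None,
    seed: int = 0,
) -> ClusterTreeAU:
    """Multiscale-bootstrap cluster support for Ward/Euclidean clustering.

    ``data`` is (n_features, n_objects); features (rows) are resampled with
    replacement at scale factors r (default 0.5 ... 1.4 in 10 steps).  For
    every clade of the observed dendrogram, the recovery frequency at each
    scale is converted to a z-value and fitted against
    ``z(r) = v*sqrt(r) + c/sqrt(r)`` by weighted least squares; the
    approximately unbiased support is ``AU = 100 * (1 - Phi(v - c))``.
    """
    data = np.asarray(data, dtype=float)
    n_feat, n_obj = data.shape
    if n_feat < 2:
        raise ValueError("need at least 2 features to bootstrap")
    if scales is None:
        scales = np.linspace(0.5, 1.4, 10)
    rng = np.random.default_rng(seed)

    obs_link = linkage(pdist(data.T), method="ward")
    obs_clades = _clades(obs_link, n_obj)
    counts = np.zeros((len(scales), len(obs_clades)))
    clade_index = {cl: i for i, cl in enumerate(obs_clades)}
    actual_r = np.empty(len(scales))
    for si, r in enumerate(scales):
        m = max(2, int(round(r * n_feat)))
        actual_r[si] = m / n_feat
        for _ in range(n_boot):
            idx = rng.integers(0, n_feat, size=m)
            bl = linkage(pdist(data[idx].T), method="ward")
            for cl in _clades(bl, n_obj):
                j = clade_index.get(cl)
                if j is not None:
                    counts[si, j] += 1

    au: dict[frozenset, float] = {}
    bp_out: dict[frozenset, float] = {}
    sq = np.sqrt(actual_r)
    X = np.column_stack([sq, 1.0 / sq])
    for j, cl in enumerate(obs_clades):
        bp = counts[:, j] / n_boot
        bp_out[cl] = float(bp[np.argmin(np.abs(actual_r - 1.0))])
        if np.all(counts[:, j] >= n_boot):
            au[cl] = 100.0
            continue
        if np.all(counts[:, j] == 0):
            au[cl] = 0.0
            continue
        bp_c = np.clip(bp, 0.5 / n_boot, 1 - 0.5 / n_boot)
        z = -norm.ppf(bp_c)
        var = bp_c * (1 - bp_c) / (n_boot * norm.pdf(z) ** 2)
        W = np.diag(1.0 / var)
        beta, *_ = np.linalg.lstsq(
            np.sqrt(W) @ X, np.sqrt(W) @ z, rcond=None
        )
        v, c = beta
        au[cl] = float(100.0 * (1.0 - norm.cdf(v - c)))

    tree = ClusterTreeAU(obs_link, None, list(names), au=au, bp=bp_out)
    return tree
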