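"""Planted-truth recovery benchmarks on synthetic cohorts.

Each function generates its own inputs from a seed, runs the corresponding
pipeline stage, and returns the measured recovery quantities.  These are
the package's verification surface: the headline consortium-scale numbers
cannot be recomputed at desk scale, so correctness is demonstrated by
oracle equivalence and planted-parameter recovery instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import kstest
from sklearn.metrics import adjusted_rand_score

from pmdscape import _hmm
from pmdscape import chromh3m as ch
from pmdscape import domains as dom
from pmdscape import intervals as iv
from pmdscape import simulate as sim
from pmdscape.core_io import GenomeSpec, Methylome, SegmentSet, bin_genome
from pmdscape.patterns import CATEGORIES, extract_patterns
from pmdscape.repli import (
    build_histone_features,
    cluster_replication_timing,
    train_replication_classifier,
)
from pmdscape.segmentation import (
    SegmentationParams,
    TwoStateHMMParams,
    segment_full,
    segment_two_state,
)


def _bin_matrix(values, chrom="chr1"):
    values = np.asarray(values, dtype=np.int8)
    bins = pd.DataFrame(
        {
            "chrom": chrom,
            "start": 1000 * np.arange(len(values)),
            "end": 1000 * (1 + np.arange(len(values))),
        }
    )
    return ch.BinaryBinMatrix(bins, [f"s{i}" for i in range(values.shape[1])], values)


def hmm_forward_oracle(seed: int, n_toys: int = 5) -> float:
    """Max relative error of the scaled forward log-likelihood against
    brute-force enumeration over all state paths on small toys."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_toys):
        T = int(rng.integers(3, 9))
        K = int(rng.integers(2, 4))
        S = int(rng.integers(1, 4))
        pi = rng.dirichlet(np.ones(K))
        A = rng.dirichlet(np.ones(K), size=K)
        E = rng.uniform(0.1, 0.9, size=(K, S))
        X = rng.integers(0, 2, size=(T, S)).astype(np.int8)
        model = ch.MetaHMM(pi, A, E, [f"s{i}" for i in range(S)])
        ll = ch.forward_loglik(model, _bin_matrix(X))
        bf = _hmm.brute_force_loglik(pi, A, np.exp(ch._emission_loglik(X, E)))
        worst = max(worst, abs(ll - bf) / abs(bf))
    return worst


def meta_hmm_recovery(seed: int, n_bins: int = 50_000, n_samples: int = 4) -> dict:
    """Fit the meta-HMM to data simulated from a known 2-state model."""
    rng = np.random.default_rng(seed)
    E_true = np.array([[0.9] * n_samples, [0.1] * n_samples])
    A_true = np.array([[0.99, 0.01], [0.01, 0.99]])
    states = np.empty(n_bins, dtype=np.int64)
    states[0] = 0
    for t in range(1, n_bins):
        states[t] = rng.choice(2, p=A_true[states[t - 1]])
    X = (rng.random((n_bins, n_samples)) < E_true[states]).astype(np.int8)
    mat = _bin_matrix(X)
    model = ch.train_meta_hmm(mat, n_states=2, seed=seed)
    order = np.argsort(-model.emissions.mean(axis=1))
    emission_err = float(np.abs(model.emissions[order] - E_true).max())
    decoded = ch.decode_states(model, mat).states
    accuracy = float((order.argsort()[decoded] == states).mean())
    return {"emission_max_abs_err": emission_err, "decode_accuracy": accuracy}


def chromh3m_end_to_end(
    seed: int,
    n_groups: int = 3,
    samples_per_group: int = 4,
    chrom_lengths: dict | None = None,
) -> dict:
    """Full binarize -> train -> decode -> cluster pipeline on a synthetic
    cohort with shared and group-specific PMD states."""
    cfg = sim.SimConfig(
        seed=seed,
        chrom_lengths=chrom_lengths or {"chr1": 30_000_000, "chr2": 20_000_000},
        n_groups=n_groups,
    )
    truth = sim.simulate_state_map(cfg)
    bins = bin_genome(truth.genome, 1000)
    segs, groups = {}, []
    for g in range(n_groups):
        base = truth.pmd_segments(g)
        for r in range(samples_per_group):
            name = f"g{g}_s{r}"
            segs[name] = sim.perturb_segments(
                base, truth.genome, seed=seed * 1000 + g * 10 + r
            )
            groups.append(g)
    mat = ch.binarize_segments(segs, bins)
    model = ch.train_meta_hmm(mat, n_states=truth.n_states, seed=seed)
    smap = ch.decode_states(model, mat)
    state_ari = float(adjusted_rand_score(truth.state_per_bin(bins), smap.states))
    tree = ch.cluster_emissions(model)
    sample_ari = float(adjusted_rand_score(groups, tree.cut_samples(n_groups)))
    return {"sample_cluster_ari": sample_ari, "state_map_ari": state_ari}


def segmentation_recovery(seed: int, chrom_len: int = 10_000_000) -> dict:
    """Planted PMD/HMD methylome (means 0.5 / 0.9): bp-level label agreement
    of the full segmentation, plus a direct check that a planted 250 kb
    hypomethylated region is removed by the 300 kb filter."""
    cfg = sim.SimConfig(seed=seed, chrom_lengths={"chr1": chrom_len})
    truth = sim.simulate_state_map(cfg)
    s = sim.simulate_methylome(truth, cfg, group=0, seed=seed + 1)
    seg = segment_full(
        s.methylome, SegmentationParams(), TwoStateHMMParams(), genome=truth.genome,
        seed=seed,
    )
    true_pmd = truth.pmd_segments(0)
    ts, te = true_pmd.df["start"].to_numpy(), true_pmd.df["end"].to_numpy()
    called = seg.with_label("PMD")
    ss, ee = called.df["start"].to_numpy(), called.df["end"].to_numpy()
    is_, ie_ = iv.intersect(ss, ee, ts, te)
    inter = int(np.sum(ie_ - is_)) if len(is_) else 0
    disagree = (int((ee - ss).sum()) - inter) + (int((te - ts).sum()) - inter)
    agreement = 1.0 - disagree / chrom_len

    # planted 250 kb hypomethylated region under the 300 kb filter
    rng = np.random.default_rng(seed)
    levels = np.concatenate(
        [rng.beta(27, 3, 4000), rng.beta(0.45 * 8, 0.55 * 8, 2500), rng.beta(27, 3, 4000)]
    )
    pos = 100 * (1 + np.arange(len(levels)))
    cov = np.full(len(levels), 20)
    m = Methylome(
        pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": pos,
                "strand": "+",
                "coverage": cov,
                "methylated": rng.binomial(cov, levels),
            }
        )
    )
    two = segment_two_state(m, TwoStateHMMParams(min_region_bp=300_000))
    removed = float((two.df["label"] == "PMD").sum() == 0)
    return {"bp_label_agreement": agreement, "short_region_removed": removed}


def replication_benchmark(seed: int, n_pmds: int = 300) -> dict:
    """Planted 3-class Repli-seq / histone simulation: clustering ARI,
    classifier average one-vs-all accuracy, and the permuted-label control."""
    starts = 200_000 + np.arange(n_pmds) * 300_000
    ends = starts + 120_000
    L = int(ends[-1] + 200_000)
    pmds = SegmentSet(
        pd.DataFrame({"chrom": "chr1", "start": starts, "end": ends, "label": "PMD"})
    )
    genome = GenomeSpec({"chr1": L}, excluded_chroms=frozenset())
    cfg = sim.SimConfig(seed=seed, chrom_lengths={"chr1": L})
    classes = sim.plant_replication_classes(pmds, cfg, seed=seed + 1)
    phases = sim.simulate_repli_tracks(pmds, classes, genome, cfg, seed=seed + 2)
    marks = sim.simulate_class_histone_tracks(pmds, classes, genome, cfg, seed=seed + 3)
    labels, _ = cluster_replication_timing(
        pmds, phases, seed=seed, body_len=100_000, flank_len=50_000, bin_size=10_000
    )
    cluster_ari = float(adjusted_rand_score(classes, labels))
    feats = build_histone_features(
        pmds, marks, body_len=100_000, flank_len=50_000, bin_size=10_000
    )
    report = train_replication_classifier(feats, labels, seed=seed)
    rng = np.random.default_rng(seed + 4)
    permuted = train_replication_classifier(feats, rng.permutation(labels), seed=seed)
    return {
        "cluster_ari": cluster_ari,
        "avg_one_vs_all_accuracy": report.average_accuracy,
        "permuted_accuracy": permuted.average_accuracy,
    }


def _brute_force_patterns(reads, window=4, step=1):
    counts = {c: 0 for c in CATEGORIES}
    for r in reads:
        for i in range(0, len(r.calls) - window + 1, step):
            w = list(r.calls[i : i + window])
            if all(c == 1 for c in w):
                counts["fully_methylated"] += 1
            elif all(c == 0 for c in w):
                counts["fully_unmethylated"] += 1
            else:
                counts["mixed"] += 1
    return counts


def pattern_benchmark(seed: int, n_reads: int = 1000) -> dict:
    """Exact agreement with a loop-based window classifier, and the
    closed-form (1-q)^4 erosion expectation in standard-error units."""
    from pmdscape.patterns import ReadCpGCalls

    rng = np.random.default_rng(seed)
    reads = []
    for i in range(n_reads):
        n = int(rng.integers(1, 15))
        pos = np.cumsum(rng.integers(2, 50, n))
        reads.append(ReadCpGCalls(f"r{i}", "chr1", pos, rng.integers(0, 2, n)))
    got = extract_patterns(reads).counts
    expected = _brute_force_patterns(reads)
    mismatches = sum(abs(got[c] - expected[c]) for c in CATEGORIES)

    q = 0.3
    n_eroded = 4000
    eroded = []
    for i in range(n_eroded):
        calls = rng.binomial(1, (1 - q) * np.ones(4))
        eroded.append(ReadCpGCalls(f"e{i}", "chr1", 10 * (1 + np.arange(4)), calls))
    s = extract_patterns(eroded)
    max_z = 0.0
    for frac, p in [
        (s.fractions["fully_methylated"], (1 - q) ** 4),
        (s.fractions["fully_unmethylated"], q**4),
    ]:
        se = np.sqrt(p * (1 - p) / n_eroded)
        max_z = max(max_z, abs(frac - p) / se)
    return {"window_count_mismatches": float(mismatches), "erosion_max_z": float(max_z)}


def border_test_benchmark(
    seed: int, n_planted: int = 100, n_null: int = 200, chrom_lengths: dict | None = None
) -> dict:
    """Power against jittered planted borders and calibration under the
    uniform null (KS test of the p-value distribution).

    Uses the generator's default two-chromosome genome so the pooled
    rank-sum test sees a realistic number of domain borders.
    """
    cfg = (
        sim.SimConfig(seed=seed)
        if chrom_lengths is None
        else sim.SimConfig(seed=seed, chrom_lengths=chrom_lengths)
    )
    truth = sim.simulate_state_map(cfg)
    genome = truth.genome
    pmd_borders = dom.BorderSet.from_segments(truth.pmd_segments(0))
    rejected = 0
    for i in range(n_planted):
        tads = sim.simulate_tads(truth, cfg, 0, seed=seed * 7919 + i)
        res = dom.border_distance_test(
            dom.BorderSet.from_segments(tads), pmd_borders, genome, seed=seed + i
        )
        rejected += res.p_value < 0.01
    rng = np.random.default_rng(seed + 13)
    pvals = []
    for i in range(n_null):
        random_pmds = dom.BorderSet(
            {
                chrom: np.sort(rng.integers(0, genome.chrom_lengths[chrom], len(pos)))
                for chrom, pos in pmd_borders.positions.items()
            }
        )
        tads = sim.simulate_tads(truth, cfg, 0, seed=seed * 104729 + i)
        res = dom.border_distance_test(
            dom.BorderSet.from_segments(tads), random_pmds, genome, seed=seed + 500 + i
        )
        pvals.append(res.p_value)
    ks_p = float(kstest(pvals, "uniform").pvalue)
    return {"planted_reject_rate": rejected / n_planted, "null_ks_pvalue": ks_p}
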