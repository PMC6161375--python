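import itertools

import numpy as np
import pandas as pd
import pytest

from pmdscape import _hmm
from pmdscape import chromh3m as ch
from pmdscape.core_io import GenomeSpec, bin_genome
from tests.conftest import make_segments


def matrix_from(values, chrom="chr1"):
    values = np.asarray(values, dtype=np.int8)
    bins = pd.DataFrame(
        {
            "chrom": chrom,
            "start": 1000 * np.arange(len(values)),
            "end": 1000 * (1 + np.arange(len(values))),
        }
    )
    return ch.BinaryBinMatrix(bins, [f"s{i}" for i in range(values.shape[1])], values)


def simulate_chain(E, A, T, rng):
    K = len(E)
    states = np.empty(T, dtype=int)
    states[0] = rng.integers(K)
    for t in range(1, T):
        states[t] = rng.choice(K, p=A[states[t - 1]])
    X = (rng.random((T, E.shape[1])) < E[states]).astype(np.int8)
    return states, X


class TestBinarize:
    def test_one_bp_overlap_is_enough(self):
        genome = GenomeSpec({"chr1": 3000}, excluded_chroms=frozenset())
        bins = bin_genome(genome, 1000)
        segs = {"a": make_segments([("chr1", 500, 2000, "PMD")])}
        mat = ch.binarize_segments(segs, bins)
        assert mat.values[:, 0].tolist() == [1, 1, 0]

    def test_segment_equal_to_bin(self):
        genome = GenomeSpec({"chr1": 2000}, excluded_chroms=frozenset())
        bins = bin_genome(genome, 1000)
        segs = {"a": make_segments([("chr1", 1000, 2000, "PMD")])}
        assert ch.binarize_segments(segs, bins).values[:, 0].tolist() == [0, 1]

    def test_sample_without_segments_gives_zero_column(self):
        genome = GenomeSpec({"chr1": 2000}, excluded_chroms=frozenset())
        bins = bin_genome(genome, 1000)
        segs = {"a": make_segments([("chr1", 0, 10, "HMD")])}  # wrong label
        assert ch.binarize_segments(segs, bins).values.sum() == 0


class TestForwardOracle:
    @pytest.mark.parametrize("T,K,S,seed", [(5, 2, 2, 0), (8, 3, 3, 1), (6, 2, 3, 2)])
    def test_forward_equals_path_enumeration(self, T, K, S, seed):
        """Scaled forward log-likelihood matches brute-force enumeration."""
        rng = np.random.default_rng(seed)
        pi = rng.dirichlet(np.ones(K))
        A = rng.dirichlet(np.ones(K), size=K)
        E = rng.uniform(0.1, 0.9, size=(K, S))
        X = rng.integers(0, 2, size=(T, S)).astype(np.int8)
        model = ch.MetaHMM(pi, A, E, [f"s{i}" for i in range(S)])
        ll = ch.forward_loglik(model, matrix_from(X))
        logB = ch._emission_loglik(X, E)
        bf = _hmm.brute_force_loglik(pi, A, np.exp(logB))
        assert abs(ll - bf) / abs(bf) < 1e-10


class TestTraining:
    def test_saturated_single_state(self):
        mat = matrix_from(np.ones((50, 3)))
        model = ch.train_meta_hmm(mat, n_states=1, seed=0)
        assert np.allclose(model.emissions, 1.0, atol=1e-5)

    def test_parameter_recovery_two_states(self):
        rng = np.random.default_rng(7)
        E = np.array([[0.9] * 4, [0.1] * 4])
        A = np.array([[0.99, 0.01], [0.01, 0.99]])
        states, X = simulate_chain(E, A, 20_000, rng)
        mat = matrix_from(X)
        model = ch.train_meta_hmm(mat, n_states=2, seed=0)
        order = np.argsort(-model.emissions.mean(axis=1))
        assert np.abs(model.emissions[order] - E).max() < 0.05
        assert np.all(np.diff(model.loglik_path_) >= -1e-6)
        decoded = ch.decode_states(model, mat).states
        acc = (order.argsort()[decoded] == states).mean()
        assert acc >= 0.98

    def test_missing_bins_marginalized(self):
        rng = np.random.default_rng(3)
        E = np.array([[0.9] * 3, [0.1] * 3])
        A = np.array([[0.98, 0.02], [0.02, 0.98]])
        _, X = simulate_chain(E, A, 5_000, rng)
        Xm = X.copy()
        mask = rng.random(Xm.shape) < 0.1
        Xm[mask] = ch.MISSING_CODE
        model = ch.train_meta_hmm(matrix_from(Xm), n_states=2, seed=0)
        order = np.argsort(-model.emissions.mean(axis=1))
        assert np.abs(model.emissions[order] - E).max() < 0.07

    def test_excess_states_warns(self, caplog):
        mat = matrix_from(np.ones((20, 2)))
        with caplog.at_level("WARNING"):
            ch.train_meta_hmm(mat, n_states=5, seed=0, max_iter=5)
        assert any("distinct" in r.message for r in caplog.records)


class TestDecode:
    def test_fraction_counting(self):
        rng = np.random.default_rng(0)
        E = np.array([[0.95, 0.95], [0.05, 0.05]])
        A = np.array([[0.9, 0.1], [0.15, 0.85]])
        model = ch.MetaHMM(np.array([0.5, 0.5]), A, E, ["s0", "s1"])
        X = np.array([[1, 1]] * 4 + [[0, 0]] * 6, dtype=np.int8)
        smap = ch.decode_states(model, matrix_from(X))
        assert smap.fractions.tolist() == [0.4, 0.6]
        assert smap.fractions.sum() == pytest.approx(1.0)

    def test_sample_mismatch_rejected(self):
        model = ch.MetaHMM(
            np.array([1.0]), np.array([[1.0]]), np.array([[0.5, 0.5]]), ["a", "b"]
        )
        with pytest.raises(ValueError):
            ch.decode_states(model, matrix_from(np.ones((5, 2))))

    def test_state_relabeling_leaves_partition_invariant(self):
        rng = np.random.default_rng(1)
        E = np.array([[0.9, 0.1], [0.1, 0.9]])
        A = np.array([[0.95, 0.05], [0.05, 0.95]])
        _, X = simulate_chain(E, A, 2_000, rng)
        mat = matrix_from(X)
        model = ch.train_meta_hmm(mat, n_states=2, seed=0)
        flipped = ch.MetaHMM(
            model.startprob[::-1],
            model.transmat[::-1][:, ::-1],
            model.emissions[::-1],
            model.samples,
        )
        a = ch.decode_states(model, mat).states
        b = ch.decode_states(flipped, mat).states
        assert np.array_equal(a, 1 - b)


class TestClustering:
    def test_identical_columns_merge_at_zero_height(self):
        E = np.array([[0.9, 0.9, 0.1], [0.2, 0.2, 0.8]])
        model = ch.MetaHMM(np.array([0.5, 0.5]), np.eye(2), E, ["a", "b", "c"])
        tree = ch.cluster_emissions(model)
        first = tree.sample_linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(5)
        E = rng.random((4, 6))
        model = ch.MetaHMM(np.full(4, 0.25), np.eye(4), E, [f"s{i}" for i in range(6)])
        tree = ch.cluster_emissions(model)
        perm = [3, 1, 5, 0, 2, 4]
        model_p = ch.MetaHMM(model.startprob, model.transmat, E[:, perm],
                             [model.samples[i] for i in perm])
        tree_p = ch.cluster_emissions(model_p)
        labels = tree.cut_samples(3)
        labels_p = tree_p.cut_samples(3)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels[perm], labels_p) == 1.0


class TestAuBootstrap:
    def test_perfectly_supported_node_gets_au_100(self):
        # two tight groups: every bootstrap recovers the split
        rng = np.random.default_rng(0)
        data = np.concatenate(
            [np.zeros((20, 3)), np.ones((20, 3))], axis=1
        ) + rng.normal(0, 0.01, (20, 6))
        tree = ch.au_bootstrap(data, [f"s{i}" for i in range(6)], n_boot=200, seed=1)
        group_a = frozenset([0, 1, 2])
        assert tree.au[group_a] == pytest.approx(100.0)

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        data = rng.random((30, 5))
        t1 = ch.au_bootstrap(data, list("abcde"), n_boot=100, seed=9)
        t2 = ch.au_bootstrap(data, list("abcde"), n_boot=100, seed=9)
        assert t1.au == t2.au

    def test_too_few_features_rejected(self):
        with pytest.raises(ValueError):
            ch.au_bootstrap(np.ones((1, 4)), list("abcd"), n_boot=10, seed=0)
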