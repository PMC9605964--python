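import numpy as np
import pytest

from microcolony import _hmm
from microcolony.lineage import HIGH, LOW, BinaryClassification
from microcolony.switching import (
    NOT_SIG,
    SIG_LARGE,
    SIG_SMALL,
    NoSequencesError,
    StateSequence,
    baum_welch_fit,
    binarize_lineages,
    transition_randomization_test,
)

from conftest import make_tree, obs


def seq(symbols, lid="s"):
    return StateSequence(lid, [HIGH if s == "H" else LOW for s in symbols])


def classification_for(tree, threshold):
    cls = BinaryClassification(threshold=threshold, gmm_params=[])
    for cid, cell in tree.cells.items():
        for o in cell.observations:
            if not o.placeholder:
                cls.per_observation_class[(cid, o.frame)] = (
                    HIGH if o.atp_mM > threshold else LOW
                )
    return cls


class TestBinarize:
    def test_single_cell_trace(self):
        tree = make_tree({"a": (None, [obs(0, 0.0, atp=1.0), obs(1, 1.0, atp=9.0),
                                       obs(2, 2.0, atp=1.0)])})
        seqs = binarize_lineages(tree, classification_for(tree, 4.0))
        assert len(seqs) == 1
        assert seqs[0].states == [LOW, HIGH, LOW]

    def test_one_sequence_per_root_to_leaf_path(self):
        tree = make_tree({
            "a": (None, [obs(0, 0.0, atp=1.0), obs(1, 1.0, atp=1.0)]),
            "a0": ("a", [obs(2, 2.0, atp=9.0), obs(3, 3.0, atp=9.0)]),
            "a1": ("a", [obs(2, 2.0, atp=1.0), obs(3, 3.0, atp=1.0)]),
        })
        seqs = binarize_lineages(tree, classification_for(tree, 4.0))
        assert len(seqs) == 2
        assert all(len(s.states) == 4 for s in seqs)

    def test_placeholder_frames_skipped(self):
        tree = make_tree({"a": (None, [obs(0, 0.0, atp=1.0),
                                       obs(1, 1.0, atp=9.0, placeholder=True),
                                       obs(2, 2.0, atp=9.0)])})
        seqs = binarize_lineages(tree, classification_for(tree, 4.0))
        assert seqs[0].states == [LOW, HIGH]

    def test_all_placeholder_is_error(self):
        tree = make_tree({"a": (None, [obs(0, 0.0, atp=1.0, placeholder=True),
                                       obs(1, 1.0, atp=1.0, placeholder=True)])})
        with pytest.warns(UserWarning):
            with pytest.raises(NoSequencesError):
                binarize_lineages(tree, classification_for(tree, 4.0))

    def test_empty_tree_is_error(self):
        from microcolony.lineage import LineageTree
        with pytest.raises(NoSequencesError):
            binarize_lineages(LineageTree(), BinaryClassification(1.0, []))


class TestBaumWelch:
    def test_fair_coin_fit_implies_memoryless_symbols(self, rng):
        # with free emissions the hidden chain of the ML fit is not
        # identifiable on iid data, but the fitted model's *symbol process*
        # must match the data: P(HIGH) near 1/2 and no lag-1 memory
        seqs = [StateSequence(str(k), [HIGH if v else LOW
                                       for v in rng.integers(0, 2, 50)])
                for k in range(20)]
        res = baum_welch_fit(seqs, seed=3)
        A, B = res.transition, res.emission
        evals, evecs = np.linalg.eig(A.T)
        pi = np.real(evecs[:, np.argmax(np.real(evals))])
        pi = pi / pi.sum()
        p_high = pi @ B[:, 1]
        joint_hh = sum(pi[i] * B[i, 1] * A[i, j] * B[j, 1]
                       for i in range(2) for j in range(2))
        autocorr = (joint_hh - p_high**2) / (p_high * (1 - p_high))
        assert abs(p_high - 0.5) < 0.05
        assert abs(autocorr) < 0.1

    def test_observable_markov_chain_recovered(self, rng):
        A = np.array([[0.9, 0.1], [0.2, 0.8]])
        seqs = []
        for k in range(50):
            s = rng.integers(0, 2)
            out = []
            for _ in range(100):
                out.append(HIGH if s == 1 else LOW)
                s = rng.choice(2, p=A[s])
            seqs.append(StateSequence(str(k), out))
        res = baum_welch_fit(seqs, seed=3)
        assert np.all(np.abs(res.transition - A) < 0.05)
        # canonical ordering: state 1 is the HIGH-emitting state
        assert res.emission[1, 1] > res.emission[0, 1]

    def test_log_likelihood_monotone_over_iterations(self, rng):
        seqs = [rng.integers(0, 2, 30).astype(np.int8) for _ in range(5)]
        obs_arr, mask = _hmm.pack_sequences(seqs)
        A0, B0, pi0 = _hmm.random_params(np.random.default_rng(0), 3)
        _, _, _, _, hist = _hmm.baum_welch_batch(
            obs_arr[None], mask, A0, B0, pi0, max_iter=50
        )
        assert np.all(np.diff(hist, axis=0) > -1e-7)

    def test_numba_and_numpy_backends_agree(self, rng):
        seqs = [rng.integers(0, 2, 40).astype(np.int8) for _ in range(8)]
        obs_arr, mask = _hmm.pack_sequences(seqs)
        out = {}
        for backend in ("numba", "numpy"):
            A, B, pi, ll = _hmm.fit_best_of_restarts(
                obs_arr[None], mask, np.random.SeedSequence(5),
                n_restarts=5, max_iter=300, tol=1e-8, backend=backend,
            )
            out[backend] = (A, ll)
        assert np.allclose(out["numba"][0], out["numpy"][0], atol=1e-3)
        assert np.allclose(out["numba"][1], out["numpy"][1], atol=1e-3)

    def test_agrees_with_hmmlearn_reference(self, rng):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        A = np.array([[0.85, 0.15], [0.3, 0.7]])
        seqs = []
        for k in range(30):
            s = rng.integers(0, 2)
            out = []
            for _ in range(80):
                out.append(s)
                s = rng.choice(2, p=A[s])
            seqs.append(np.array(out))
        res = baum_welch_fit(
            [StateSequence(str(i), [HIGH if v else LOW for v in s])
             for i, s in enumerate(seqs)], seed=0,
        )
        X = np.concatenate(seqs).reshape(-1, 1)
        best = None
        for rs in range(5):
            m = hmmlearn.CategoricalHMM(n_components=2, n_iter=300, tol=1e-6,
                                        random_state=rs, init_params="ste")
            m.fit(X, [len(s) for s in seqs])
            if best is None or m.score(X, [len(s) for s in seqs]) > best[0]:
                best = (m.score(X, [len(s) for s in seqs]), m)
        m = best[1]
        order = np.argsort(m.emissionprob_[:, 1])
        ref_A = m.transmat_[np.ix_(order, order)]
        assert np.allclose(res.transition, ref_A, atol=0.05)

    def test_degenerate_constant_symbols_warn(self):
        with pytest.warns(UserWarning, match="unidentifiable"):
            baum_welch_fit([seq("HHHHHH")], seed=0)

    def test_rows_stochastic(self, rng):
        seqs = [StateSequence(str(k), [HIGH if v else LOW
                                       for v in rng.integers(0, 2, 20)])
                for k in range(5)]
        res = baum_welch_fit(seqs, seed=1)
        assert np.allclose(res.transition.sum(axis=1), 1, atol=1e-9)
        assert np.allclose(res.emission.sum(axis=1), 1, atol=1e-9)
        assert res.initial.sum() == pytest.approx(1, abs=1e-9)


class TestRandomizationTest:
    def test_alternating_sequences_have_large_offdiagonals(self):
        seqs = [seq("HL" * 20, str(k)) for k in range(10)]
        res = transition_randomization_test(seqs, n_shuffles=500, seed=1)
        assert res.edge_significance[(LOW, HIGH)] == SIG_LARGE
        assert res.edge_significance[(HIGH, LOW)] == SIG_LARGE

    def test_long_runs_have_large_diagonals(self):
        seqs = [seq("H" * 30 + "L" * 30, str(k)) for k in range(15)]
        res = transition_randomization_test(seqs, n_shuffles=500, seed=1)
        assert res.edge_significance[(LOW, LOW)] == SIG_LARGE
        assert res.edge_significance[(HIGH, HIGH)] == SIG_LARGE

    def test_deterministic_for_fixed_seed(self, rng):
        seqs = [StateSequence(str(k), [HIGH if v else LOW
                                       for v in rng.integers(0, 2, 30)])
                for k in range(6)]
        r1 = transition_randomization_test(seqs, n_shuffles=200, seed=9)
        r2 = transition_randomization_test(seqs, n_shuffles=200, seed=9)
        assert np.array_equal(r1.null_p5, r2.null_p5)
        assert np.array_equal(r1.null_p95, r2.null_p95)
        assert r1.edge_significance == r2.edge_significance

    def test_few_shuffles_warn(self):
        with pytest.warns(UserWarning, match="percentile"):
            transition_randomization_test([seq("HLHL")], n_shuffles=50, seed=0)

    def test_verdicts_cover_all_edges(self):
        seqs = [seq("HL" * 10, str(k)) for k in range(4)]
        res = transition_randomization_test(seqs, n_shuffles=200, seed=2)
        assert set(res.edge_significance) == {
            (LOW, LOW), (LOW, HIGH), (HIGH, LOW), (HIGH, HIGH)
        }
        assert all(v in (SIG_LARGE, SIG_SMALL, NOT_SIG)
                   for v in res.edge_significance.values())
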