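"""Two-HMM detector: forward oracle, Baum-Welch behavior, classification."""

import itertools

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from eegvigil import (AttentionState, Decision, GaussianHMM, LabeledWindow,
                      TwoHMMDetector, classify_baseline, classify_window,
                      fit_hmm, forward_loglik, train_baseline, train_detector)
from eegvigil.detection import DetectionResult


def brute_force_loglik(hmm: GaussianHMM, x: np.ndarray) -> float:
    """Likelihood by exhaustive summation over all hidden state paths."""
    t, s = x.shape[0], hmm.n_states
    total = 0.0
    for path in itertools.product(range(s), repeat=t):
        p = hmm.startprob[path[0]]
        for a, b in zip(path, path[1:]):
            p *= hmm.transmat[a, b]
        for k, state in enumerate(path):
            cov = (np.diag(hmm.covars[state])
                   if hmm.covars.ndim == 2 else hmm.covars[state])
            p *= multivariate_normal.pdf(x[k], hmm.means[state], cov)
        total += p
    return float(np.log(total))


def random_hmm(rng, n_states, n_dims, covariance_type="diag"):
    pi = rng.dirichlet(np.ones(n_states))
    a = rng.dirichlet(np.ones(n_states), size=n_states)
    means = rng.standard_normal((n_states, n_dims)) * 2
    if covariance_type == "diag":
        covars = rng.uniform(0.3, 2.0, (n_states, n_dims))
    else:
        covars = np.empty((n_states, n_dims, n_dims))
        for s in range(n_states):
            m = rng.standard_normal((n_dims, n_dims))
            covars[s] = m @ m.T + np.eye(n_dims)
    return GaussianHMM(startprob=pi, transmat=a, means=means, covars=covars)


class TestForwardLoglik:
    def test_matches_exhaustive_enumeration(self, rng):
        for n_states in (1, 2, 3):
            for t in (1, 3, 6):
                for cov in ("diag", "full"):
                    hmm = random_hmm(rng, n_states, 2, cov)
                    x = rng.standard_normal((t, 2))
                    assert forward_loglik(hmm, x) == pytest.approx(
                        brute_force_loglik(hmm, x), abs=1e-8)

    def test_single_state_collapses_to_gaussian_sum(self, rng):
        hmm = random_hmm(rng, 1, 4)
        x = rng.standard_normal((20, 4))
        expected = sum(
            multivariate_normal.logpdf(row, hmm.means[0],
                                       np.diag(hmm.covars[0]))
            for row in x)
        assert forward_loglik(hmm, x) == pytest.approx(expected, abs=1e-8)

    def test_length_one_closed_form(self, rng):
        hmm = random_hmm(rng, 3, 2)
        x = rng.standard_normal((1, 2))
        expected = np.log(sum(
            hmm.startprob[s] * multivariate_normal.pdf(
                x[0], hmm.means[s], np.diag(hmm.covars[s]))
            for s in range(3)))
        assert forward_loglik(hmm, x) == pytest.approx(expected, abs=1e-10)

    def test_matches_reference_scorer(self, rng):
        # cross-check against the hmmlearn forward implementation
        from hmmlearn.hmm import GaussianHMM as RefHMM
        hmm = random_hmm(rng, 3, 4)
        x = rng.standard_normal((50, 4))
        ref = RefHMM(n_components=3, covariance_type="diag", init_params="")
        ref.startprob_ = hmm.startprob
        ref.transmat_ = hmm.transmat
        ref.means_ = hmm.means
        ref.covars_ = hmm.covars
        assert forward_loglik(hmm, x) == pytest.approx(ref.score(x), abs=1e-6)

    def test_dimension_mismatch_raises(self, rng):
        hmm = random_hmm(rng, 2, 3)
        with pytest.raises(ValueError, match="dimension"):
            forward_loglik(hmm, np.zeros((5, 2)))

    def test_empty_sequence_raises(self, rng):
        hmm = random_hmm(rng, 2, 3)
        with pytest.raises(ValueError, match="non-empty"):
            forward_loglik(hmm, np.zeros((0, 3)))


def _hmm_samples(rng, n, means=(0.0, 10.0), sd=1.0):
    """Sample a 1-D two-state chain with sticky transitions."""
    a = np.array([[0.9, 0.1], [0.1, 0.9]])
    states = [0]
    for _ in range(n - 1):
        states.append(rng.choice(2, p=a[states[-1]]))
    x = np.array([[means[s] + sd * rng.standard_normal()] for s in states])
    return x, np.array(states)


class TestFitHMM:
    def test_recovers_separated_state_means(self, rng):
        x, _ = _hmm_samples(rng, 2000)
        hmm, info = fit_hmm([x], n_states=2, seed=0)
        got = np.sort(hmm.means.ravel())
        assert abs(got[0] - 0.0) < 0.5 and abs(got[1] - 10.0) < 0.5

    def test_loglik_trace_monotone_nondecreasing(self, rng):
        x = rng.standard_normal((500, 3))
        _, info = fit_hmm([x], n_states=3, seed=1, n_restarts=3)
        for trace in info["loglik_traces"]:
            diffs = np.diff(trace)
            assert np.all(diffs >= -1e-6)

    def test_refit_from_fixed_point_moves_little(self, rng):
        x, _ = _hmm_samples(rng, 1000)
        tol = 1e-4
        hmm, info = fit_hmm([x], n_states=2, seed=2, tol=tol, max_iter=500)
        _, info2 = fit_hmm([x], n_states=2, seed=2, tol=tol, max_iter=500,
                           init=hmm)
        trace = info2["loglik_traces"][0]
        assert abs(trace[-1] - trace[0]) < 10 * tol

    def test_deterministic_under_seed(self, rng):
        x = rng.standard_normal((300, 2))
        a, _ = fit_hmm([x], n_states=2, seed=3)
        b, _ = fit_hmm([x], n_states=2, seed=3)
        assert np.allclose(a.means, b.means)
        assert np.allclose(a.transmat, b.transmat)

    def test_rejects_empty_input(self):
        with pytest.raises(ValueError, match="no training sequences"):
            fit_hmm([], n_states=2)


def _windows_from(rng, hmm_a, hmm_b, n_each, length=30):
    """Labeled windows whose features are drawn from two known HMMs."""
    from hmmlearn.hmm import GaussianHMM as RefHMM

    def sampler(hmm, seed):
        ref = RefHMM(n_components=hmm.n_states, covariance_type="diag",
                     init_params="", random_state=seed)
        ref.startprob_ = hmm.startprob
        ref.transmat_ = hmm.transmat
        ref.means_ = hmm.means
        ref.covars_ = hmm.covars
        return ref

    wins = []
    for k in range(n_each):
        xa, _ = sampler(hmm_a, 100 + k).sample(length)
        wins.append(LabeledWindow(window=(0, length),
                                  label=AttentionState.ATTENTION,
                                  var_alt=0.0, var_vel=0.0, features=xa))
        xb, _ = sampler(hmm_b, 200 + k).sample(length)
        wins.append(LabeledWindow(window=(0, length),
                                  label=AttentionState.INATTENTION,
                                  var_alt=1.0, var_vel=1.0, features=xb))
    return wins


@pytest.fixture(scope="module")
def separated_models():
    rng = np.random.default_rng(0)
    att = random_hmm(rng, 2, 2)
    ina = GaussianHMM(startprob=att.startprob, transmat=att.transmat,
                      means=att.means + 8.0, covars=att.covars)
    return att, ina


class TestClassifyWindow:
    def test_identical_models_tie_to_inattention(self, separated_models, rng):
        att, _ = separated_models
        det = TwoHMMDetector(attention_hmm=att, inattention_hmm=att)
        res = classify_window(det, rng.standard_normal((10, 2)))
        assert res.decision is Decision.INATTENTION
        assert res.loglik_attention == res.loglik_inattention

    def test_own_generative_windows_classified_correctly(self,
                                                         separated_models):
        att, ina = separated_models
        det = TwoHMMDetector(attention_hmm=att, inattention_hmm=ina)
        wins = _windows_from(np.random.default_rng(1), att, ina, 100, 10)
        correct = 0
        for w in wins:
            res = classify_window(det, w.features)
            want = (Decision.INATTENTION
                    if w.label is AttentionState.INATTENTION
                    else Decision.ATTENTION)
            correct += res.decision is want
        assert correct / len(wins) > 0.95

    def test_logliks_finite_and_consistent(self, separated_models, rng):
        att, ina = separated_models
        det = TwoHMMDetector(attention_hmm=att, inattention_hmm=ina)
        for _ in range(20):
            res = classify_window(det, rng.standard_normal((12, 2)))
            assert np.isfinite(res.loglik_attention)
            assert np.isfinite(res.loglik_inattention)
            expected = (Decision.INATTENTION
                        if res.loglik_inattention >= res.loglik_attention
                        else Decision.ATTENTION)
            assert res.decision is expected

    def test_result_invariant_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            DetectionResult(window=(0, 1), loglik_attention=-5.0,
                            loglik_inattention=-1.0,
                            decision=Decision.ATTENTION)


class TestTrainDetector:
    def test_swapped_labels_invert_decisions(self, separated_models):
        att, ina = separated_models
        wins = _windows_from(np.random.default_rng(2), att, ina, 40, 15)
        swapped = [LabeledWindow(window=w.window,
                                 label=(AttentionState.ATTENTION
                                        if w.label is AttentionState.INATTENTION
                                        else AttentionState.INATTENTION),
                                 var_alt=w.var_alt, var_vel=w.var_vel,
                                 features=w.features)
                   for w in wins]
        held = _windows_from(np.random.default_rng(3), att, ina, 20, 15)
        kw = dict(n_states=2, seed=0, n_restarts=2, max_iter=50,
                  covariance_type="diag")
        det = train_detector(wins, **kw)
        det_swapped = train_detector(swapped, **kw)
        flips = 0
        for w in held:
            a = classify_window(det, w.features).decision
            b = classify_window(det_swapped, w.features).decision
            flips += a is not b
        assert flips / len(held) > 0.9

    def test_single_class_training_raises(self, separated_models):
        att, ina = separated_models
        wins = [w for w in
                _windows_from(np.random.default_rng(4), att, ina, 10, 10)
                if w.label is AttentionState.INATTENTION]
        with pytest.raises(ValueError, match="attention"):
            train_detector(wins, n_states=2, seed=0)

    def test_serialization_roundtrip_bit_identical(self, separated_models):
        att, ina = separated_models
        wins = _windows_from(np.random.default_rng(5), att, ina, 30, 12)
        det = train_detector(wins, n_states=2, seed=1, n_restarts=2,
                             max_iter=30, covariance_type="full")
        clone = TwoHMMDetector.from_dict(det.to_dict())
        assert np.array_equal(clone.attention_hmm.means,
                              det.attention_hmm.means)
        assert np.array_equal(clone.inattention_hmm.covars,
                              det.inattention_hmm.covars)
        assert clone.metadata == det.metadata

    def test_component_reordering_invariance(self, separated_models, rng):
        # a common orthonormal re-ordering of the feature axes applied to
        # both emission models leaves every decision unchanged
        att, ina = separated_models
        det = TwoHMMDetector(attention_hmm=att, inattention_hmm=ina)
        perm = np.array([1, 0])

        def permute(h):
            return GaussianHMM(startprob=h.startprob, transmat=h.transmat,
                               means=h.means[:, perm],
                               covars=h.covars[:, perm])

        det_p = TwoHMMDetector(attention_hmm=permute(att),
                               inattention_hmm=permute(ina))
        for _ in range(20):
            x = rng.standard_normal((8, 2))
            a = classify_window(det, x).decision
            b = classify_window(det_p, x[:, perm]).decision
            assert a is b


class TestBaseline:
    def _toy(self, rng, n=40):
        wins = []
        for k in range(n):
            lab = AttentionState.INATTENTION if k % 2 else AttentionState.ATTENTION
            offset = 10.0 if k % 2 else 0.0
            feats = offset + rng.standard_normal((12, 3))
            wins.append(LabeledWindow(window=(k, k + 12), label=lab,
                                      var_alt=0.0, var_vel=0.0,
                                      features=feats))
        return wins

    def test_separable_clusters_perfect_training_accuracy(self, rng):
        wins = self._toy(rng)
        clf = train_baseline(wins, seed=0)
        preds = classify_baseline(clf, wins)
        want = [Decision.INATTENTION if w.label is AttentionState.INATTENTION
                else Decision.ATTENTION for w in wins]
        assert preds == want

    def test_deterministic_under_seed(self, rng):
        wins = self._toy(rng)
        a = classify_baseline(train_baseline(wins, seed=3), wins)
        b = classify_baseline(train_baseline(wins, seed=3), wins)
        assert a == b

    def test_single_class_raises(self, rng):
        wins = [w for w in self._toy(rng)
                if w.label is AttentionState.ATTENTION]
        with pytest.raises(ValueError, match="both classes"):
            train_baseline(wins, seed=0)
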