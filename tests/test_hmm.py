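"""Hidden-Markov engine: Baum-Welch, chain summaries, FIFO windows."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srckit.hmm import (
    HMMSpec,
    ObservationWindow,
    baum_welch,
    expected_visits,
    first_passage,
    loglikelihood,
    parse_seqobs,
    recurrent_hmm_update,
    stationary,
    summarize_chain,
)
from srckit.io import default_hmm_prior


def _random_spec(rng, n=3, m=3):
    a = rng.dirichlet(np.ones(n) * 2, size=n)
    b = rng.dirichlet(np.ones(m) * 2, size=n)
    pi = rng.dirichlet(np.ones(n))
    labels = tuple(f"H{k}" for k in range(n))
    symbols = tuple(f"O{k}" for k in range(m))
    return HMMSpec(labels, symbols, a, b, pi)


class TestWindow:
    def test_parse_seqobs(self):
        assert parse_seqobs("1111112311") == [1, 1, 1, 1, 1, 1, 2, 3, 1, 1]
        with pytest.raises(ValueError):
            parse_seqobs("12a4")
        with pytest.raises(ValueError):
            parse_seqobs("")

    def test_fifo_shift_at_capacity(self):
        w = ObservationWindow(symbols=tuple(parse_seqobs("1111112311")))
        assert "".join(map(str, w.push(2).symbols)) == "1111123112"
        assert len(w.push(2).symbols) == 10

    def test_two_pushes_equal_double_shift(self):
        w = ObservationWindow(symbols=tuple(parse_seqobs("1111112311")))
        assert w.push(2).push(4).symbols == w.symbols[2:] + (2, 4)

    def test_partial_window_grows(self):
        w = ObservationWindow(symbols=(1, 2))
        assert w.push(3).symbols == (1, 2, 3)

    def test_over_capacity_rejected(self):
        with pytest.raises(ValueError):
            ObservationWindow(symbols=tuple(range(1, 13)))


class TestBaumWelch:
    def test_forward_loglik_matches_hmmlearn(self):
        """Independent oracle: hmmlearn's forward score on the same spec."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        spec = default_hmm_prior("barriers")
        seq = parse_seqobs("1111112311")
        model = hmmlearn.CategoricalHMM(n_components=3, init_params="")
        model.startprob_ = spec.initial
        model.transmat_ = spec.transition
        model.emissionprob_ = spec.emission
        score = model.score(np.array(seq).reshape(-1, 1) - 1)
        assert loglikelihood(spec, seq) == pytest.approx(score, abs=1e-9)

    def test_repeated_symbol_concentrates_self_loop(self):
        """Identity emission forces the hidden path; EM must learn the loop."""
        spec = HMMSpec(
            ("A", "B"), ("1", "2"),
            np.array([[0.6, 0.4], [0.4, 0.6]]),
            np.eye(2),
            np.array([0.5, 0.5]),
        )
        fit = baum_welch(spec, [1] * 8)
        assert fit.posterior.transition[0, 0] > 0.999

    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=25, deadline=None)
    def test_loglikelihood_nondecreasing(self, seed):
        rng = np.random.default_rng(seed)
        spec = _random_spec(rng, n=int(rng.integers(2, 5)), m=int(rng.integers(2, 5)))
        window = [int(s) for s in rng.integers(1, len(spec.observed_symbols) + 1, size=10)]
        fit = baum_welch(spec, window)
        ll = np.array(fit.log_likelihood)
        assert (np.diff(ll) >= -1e-9).all()
        assert np.allclose(fit.posterior.transition.sum(axis=1), 1.0)
        assert np.allclose(fit.posterior.emission.sum(axis=1), 1.0)

    def test_unseen_state_rows_stay_stochastic(self):
        spec = default_hmm_prior("barriers")
        fit = baum_welch(spec, [1] * 10)
        assert np.allclose(fit.posterior.transition.sum(axis=1), 1.0)
        assert (fit.posterior.transition >= 0).all()

    def test_symbol_outside_alphabet_rejected(self):
        with pytest.raises(ValueError, match="alphabet"):
            baum_welch(default_hmm_prior("barriers"), [1, 2, 7])

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            baum_welch(default_hmm_prior("barriers"), [])


class TestChainSummaries:
    def test_stationary_identity_follows_initial(self):
        pi = stationary(np.eye(3), initial=np.array([1.0, 0.0, 0.0]))
        assert pi.tolist() == [1.0, 0.0, 0.0]

    def test_stationary_two_state_closed_form(self):
        a, b = 0.3, 0.4
        P = np.array([[1 - a, a], [b, 1 - b]])
        np.testing.assert_allclose(stationary(P), [b / (a + b), a / (a + b)], atol=1e-12)

    def test_stationary_doubly_stochastic_uniform(self):
        P = np.array([[0.5, 0.3, 0.2], [0.2, 0.5, 0.3], [0.3, 0.2, 0.5]])
        np.testing.assert_allclose(stationary(P), np.ones(3) / 3, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_stationary_fixed_point_residual(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.dirichlet(np.ones(4), size=4)
        pi = stationary(P)
        assert np.abs(pi @ P - pi).max() < 1e-10
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_expected_visits_identity_and_uniform(self):
        np.testing.assert_allclose(
            expected_visits(np.eye(3), np.array([1.0, 0, 0]), horizon=10), [10, 0, 0]
        )
        np.testing.assert_allclose(
            expected_visits(np.full((2, 2), 0.5), np.array([1.0, 0]), horizon=10), [5, 5]
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_expected_visits_sum_to_horizon(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.dirichlet(np.ones(3), size=3)
        ev = expected_visits(P, rng.dirichlet(np.ones(3)), horizon=17)
        assert ev.sum() == pytest.approx(17.0)

    def test_first_passage_geometric_closed_form(self):
        a = 0.2
        P = np.array([[1 - a, a], [0.3, 0.7]])
        m = first_passage(P, target=1)
        assert m[0] == pytest.approx(1 / a)
        assert m[1] == 0.0

    def test_first_passage_absorbing_target_one_step(self):
        P = np.array([[0.0, 1.0, 0.0], [0.0, 1.0, 0.0], [0.0, 1.0, 0.0]])
        np.testing.assert_allclose(first_passage(P, 1), [1.0, 0.0, 1.0])

    def test_first_passage_unreachable_flagged(self):
        P = np.array([[1.0, 0.0], [0.5, 0.5]])
        m = first_passage(P, target=1)
        assert np.isnan(m[0])  # state 0 is absorbing away from the target
        assert m[1] == 0.0

    def test_first_passage_partial_reachability(self):
        """A state that may drift into an absorbing non-target trap has
        infinite expected passage time and must be flagged."""
        P = np.array([
            [0.5, 0.25, 0.25],
            [0.0, 1.0, 0.0],   # trap
            [0.0, 0.0, 1.0],   # target
        ])
        m = first_passage(P, target=2)
        assert np.isnan(m[0]) and np.isnan(m[1]) and m[2] == 0.0

    def test_summarize_chain_defaults_to_last_state(self):
        spec = default_hmm_prior("barriers")
        cs = summarize_chain(spec, horizon=10)
        assert cs.target == 2
        assert cs.expected_visits.sum() == pytest.approx(10.0)
        assert np.abs(cs.stationary @ spec.transition - cs.stationary).max() < 1e-10


class TestRecurrentUpdate:
    def test_posterior_becomes_prior_and_window_shifts(self):
        prior = default_hmm_prior("barriers")
        window = ObservationWindow(symbols=tuple(parse_seqobs("1111112311")))
        fit = baum_welch(prior, window)
        new_prior, new_window = recurrent_hmm_update(fit, 2)
        assert new_prior is fit.posterior
        assert "".join(map(str, new_window.symbols)) == "1111123112"
        refit = baum_welch(new_prior, new_window)
        assert refit.iterations >= 1

    def test_underfull_window_rejected(self):
        fit = baum_welch(default_hmm_prior("barriers"), [1, 1, 2])
        with pytest.raises(ValueError, match="capacity"):
            recurrent_hmm_update(fit, 2)

    def test_bad_symbol_rejected(self):
        fit = baum_welch(default_hmm_prior("barriers"),
                         ObservationWindow(symbols=tuple(parse_seqobs("1111112311"))))
        with pytest.raises(ValueError, match="alphabet"):
            recurrent_hmm_update(fit, 9)
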