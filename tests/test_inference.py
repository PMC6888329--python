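"""The five rate models: conjugate updates, log-posteriors, and their limits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from srckit.inference import (
    GammaPrior,
    NormalPrior,
    compare_posteriors,
    exponential_gamma_logpost,
    exponential_normal_logpost,
    poisson_gamma_update,
    poisson_normal_logpost,
    weibull_gamma_logpost,
)

WORKED_SERIES = [0, 0, 0, 1, 0, 0, 1, 1, 0, 0]


def _mode(logpost, bracket=(1e-6, 0.1, 50.0)):
    res = minimize_scalar(lambda lam: -logpost(lam), bracket=bracket)
    return res.x


class TestPoissonGamma:
    @pytest.mark.parametrize(
        "nt, mean, sd",
        [
            (1, 0.00, 0.032),
            (2, 0.00, 0.016),
            (3, 0.00, 0.011),
            (4, 0.25, 0.25),
            (5, 0.20, 0.20),
            (6, 0.17, 0.17),
            (7, 0.29, 0.20),
            (8, 0.38, 0.22),
            (9, 0.33, 0.19),
            (10, 0.30, 0.17),
        ],
    )
    def test_worked_case_interval_table(self, zero_target_prior, nt, mean, sd):
        """Cumulative posteriors over the ten-interval incidence series."""
        s = sum(WORKED_SERIES[:nt])
        est = poisson_gamma_update(zero_target_prior, s, nt)
        assert est.mean == pytest.approx(mean, abs=0.005)
        assert est.sd == pytest.approx(sd, abs=0.005)
        assert est.params == {"alpha": 0.001 + s, "beta": 0.001 + nt}

    @given(counts=st.lists(st.integers(0, 5), min_size=1, max_size=15),
           alpha=st.floats(0.001, 10), beta=st.floats(0.001, 10))
    @settings(max_examples=50, deadline=None)
    def test_sequential_equals_cumulative(self, counts, alpha, beta):
        """Interval-by-interval threading equals the single cumulative update."""
        prior = GammaPrior(alpha, beta)
        threaded = prior
        for i, y in enumerate(counts, start=1):
            est = poisson_gamma_update(threaded, y, 1)
            threaded = GammaPrior(est.params["alpha"], est.params["beta"])
        cumulative = poisson_gamma_update(prior, sum(counts), len(counts))
        assert threaded.alpha == pytest.approx(cumulative.params["alpha"])
        assert threaded.beta == pytest.approx(cumulative.params["beta"])

    def test_sd_strictly_decreasing_in_intervals(self, zero_target_prior):
        sds = [poisson_gamma_update(zero_target_prior, 2, nt).sd for nt in range(1, 30)]
        assert all(a > b for a, b in zip(sds, sds[1:]))

    def test_mean_vanishes_without_incidences(self):
        est = poisson_gamma_update(GammaPrior(0.5, 10), 0, 10**6)
        assert est.mean == pytest.approx(0.0, abs=1e-6)

    def test_preconditions(self, zero_target_prior):
        with pytest.raises(ValueError):
            poisson_gamma_update(zero_target_prior, -1, 4)
        with pytest.raises(ValueError):
            poisson_gamma_update(zero_target_prior, 1, 0)


class TestLogPosteriors:
    def test_exponential_gamma_closed_form(self):
        _, oracle = exponential_gamma_logpost(GammaPrior(0.5, 10), t=4.0)
        assert oracle.params == {"alpha": 1.5, "beta": 14.0}
        assert oracle.mean == pytest.approx(1.5 / 14)

    def test_exponential_gamma_boundary_and_errors(self):
        logpost, _ = exponential_gamma_logpost(GammaPrior(0.5, 10), t=4.0)
        assert logpost(0.0) == -np.inf
        with pytest.raises(ValueError):
            exponential_gamma_logpost(GammaPrior(0.5, 10), t=0.0)

    def test_weibull_reduces_to_exponential_at_c_one(self):
        """With c = 1 the fatigue model's log-posterior equals the
        exponential-gamma one up to an additive constant (here zero)."""
        prior, t = GammaPrior(0.7, 8.0), 3.0
        exp_lp, _ = exponential_gamma_logpost(prior, t)
        weib_lp = weibull_gamma_logpost(prior, t, c=1.0)
        lams = np.linspace(0.01, 2.0, 50)
        diff = weib_lp(lams) - exp_lp(lams)
        assert np.allclose(diff, diff[0], atol=1e-12)

    def test_weibull_mode_closed_form(self):
        """alpha=1, beta→0, c=2, t=1: d/dλ log-post = 2/λ − 2λ = 0 at λ = 1."""
        logpost = weibull_gamma_logpost(GammaPrior(1.0, 1e-9), t=1.0, c=2.0)
        assert _mode(logpost) == pytest.approx(1.0, rel=1e-4)

    def test_weibull_rejects_bad_fatigue(self):
        with pytest.raises(ValueError):
            weibull_gamma_logpost(GammaPrior(1, 1), t=1.0, c=0.0)

    def test_exponential_normal_flat_prior_mode(self):
        """With a vague prior the posterior mode approaches 1/t."""
        logpost = exponential_normal_logpost(NormalPrior(0.05, 1e6), t=2.0)
        assert _mode(logpost) == pytest.approx(0.5, rel=1e-3)
        assert logpost(-0.1) == -np.inf and logpost(0.0) == -np.inf

    def test_poisson_normal_flat_prior_mode(self):
        logpost = poisson_normal_logpost(NormalPrior(0.05, 1e6), events=1, exposure=4.0)
        assert _mode(logpost) == pytest.approx(0.25, rel=1e-3)

    def test_poisson_normal_zero_count_is_pure_prior(self):
        prior = NormalPrior(0.05, 0.1)
        logpost = poisson_normal_logpost(prior, events=0, exposure=4.0)
        lams = np.linspace(0.01, 0.5, 20)
        expected = -((prior.mu - lams) ** 2) / (2 * prior.sigma**2)
        assert np.allclose(logpost(lams), expected)

    def test_poisson_normal_literal_reading_swaps_roles(self):
        prior = NormalPrior(0.05, 0.1)
        default = poisson_normal_logpost(prior, events=2, exposure=5.0)
        literal = poisson_normal_logpost(prior, events=5, exposure=2.0, literal=True)
        lams = np.linspace(0.01, 1.0, 10)
        assert np.allclose(default(lams), literal(lams))

    @pytest.mark.parametrize(
        "make",
        [
            lambda: exponential_gamma_logpost(GammaPrior(0.5, 10), 4.0)[0],
            lambda: weibull_gamma_logpost(GammaPrior(0.5, 10), 4.0, c=1.5),
            lambda: exponential_normal_logpost(NormalPrior(0.05, 0.1), 4.0),
            lambda: poisson_normal_logpost(NormalPrior(0.05, 0.1), 1, 4.0),
        ],
        ids=["exp-gamma", "weibull-gamma", "exp-normal", "poisson-normal"],
    )
    def test_posterior_is_normalizable(self, make):
        """exp(log-posterior) integrates to a finite positive constant."""
        logpost = make()
        shift = logpost(_mode(logpost))
        val, _ = quad(lambda lam: np.exp(logpost(lam) - shift), 0, np.inf, limit=200)
        assert 0 < val < np.inf


class TestCompare:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(0.25, 0.25, 0.0), (0.20, 0.25, 25.0), (0.29, 0.33, 13.793)],
    )
    def test_relative_percent_difference(self, a, b, expected):
        from srckit.inference import PosteriorEstimate

        pa = PosteriorEstimate("gamma", a, 0.1, (0, 1))
        pb = PosteriorEstimate("gamma", b, 0.1, (0, 1))
        assert compare_posteriors(pa, pb) == pytest.approx(expected, abs=0.01)

    def test_zero_reference_rejected(self):
        from srckit.inference import PosteriorEstimate

        z = PosteriorEstimate("gamma", 0.0, 0.1, (0, 1))
        o = PosteriorEstimate("gamma", 0.1, 0.1, (0, 1))
        with pytest.raises(ValueError):
            compare_posteriors(z, o)
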