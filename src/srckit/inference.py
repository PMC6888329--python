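"""Bayesian models for the accident-rate parameter λ.

Five likelihood/prior pairs are supported for the per-interval event rate:

==================  ============  =========================================
likelihood          prior         posterior
==================  ============  =========================================
Poisson counts      gamma(α, β)   gamma(α + s, β + N_t)      (closed form)
exponential t       gamma(α, β)   gamma(α + 1, β + t)        (closed form)
Weibull t, shape c  gamma(α, β)   ∝ λ^(α−1+c) e^(−λβ−(λt)^c) (sampled)
exponential t       normal(x, σ)  ∝ λ e^(−λt) e^(−(x−λ)²/2σ²) (sampled)
Poisson counts      normal(x, σ)  ∝ Poisson(n | λ·y) e^(−(x−λ)²/2σ²) (sampled)
==================  ============  =========================================

Conjugate cases return a full :class:`PosteriorEstimate`; the others return
an unnormalized log-posterior over λ > 0 for the Metropolis–Hastings engine
in :mod:`srckit.sampler`.  Normal priors are truncated to λ > 0 (a rate is
nonnegative and every likelihood has positive support); truncation only
shifts the log-posterior by a constant, which the sampler ignores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

__all__ = [
    "GammaPrior",
    "NormalPrior",
    "PosteriorEstimate",
    "poisson_gamma_update",
    "exponential_gamma_logpost",
    "weibull_gamma_logpost",
    "exponential_normal_logpost",
    "poisson_normal_logpost",
    "compare_posteriors",
]

LogPost = Callable[[float], float]


@dataclass(frozen=True)
class GammaPrior:
    """Gamma prior on λ with shape ``alpha`` and rate ``beta``."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError(f"gamma prior needs alpha, beta > 0, got {self}")

    @property
    def mean(self) -> float:
        return self.alpha / self.beta

    @property
    def sd(self) -> float:
        return np.sqrt(self.alpha) / self.beta


@dataclass(frozen=True)
class NormalPrior:
    """Normal prior on λ centred at ``mu`` (the paper's evolving x) with spread ``sigma``."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"normal prior needs sigma > 0, got {self}")


@dataclass(frozen=True)
class PosteriorEstimate:
    """Posterior summary for λ: family, parameters, mean, sd and 5–95% CI."""

    family: str  # "gamma", "normal" or "sampled"
    mean: float
    sd: float
    ci: tuple[float, float]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mean < 0 or self.sd < 0:
            raise ValueError("posterior mean and sd must be nonnegative")
        if self.ci[0] > self.ci[1]:
            raise ValueError(f"credible interval {self.ci} is not ordered")


def _gamma_estimate(alpha: float, beta: float) -> PosteriorEstimate:
    lo, hi = stats.gamma.ppf([0.05, 0.95], alpha, scale=1.0 / beta)
    return PosteriorEstimate(
        family="gamma",
        mean=alpha / beta,
        sd=float(np.sqrt(alpha) / beta),
        ci=(float(lo), float(hi)),
        params={"alpha": alpha, "beta": beta},
    )


def poisson_gamma_update(prior: GammaPrior, s: int, nt: int) -> PosteriorEstimate:
    """Conjugate Poisson–gamma update: gamma(α + s, β + N_t).

    ``s`` is the total number of incidences observed over ``nt`` intervals.
    Posterior mean (α+s)/(β+N_t) and sd sqrt(α+s)/(β+N_t) are exact; the
    sequential interval-by-interval update and the single cumulative update
    produce identical parameters.
    """
    if s < 0 or int(s) != s:
        raise ValueError(f"total incidence count s must be a nonnegative integer, got {s}")
    if nt < 1:
        raise ValueError(f"number of intervals must be >= 1, got {nt}")
    return _gamma_estimate(prior.alpha + s, prior.beta + nt)


def exponential_gamma_logpost(
    prior: GammaPrior, t: float
) -> tuple[LogPost, PosteriorEstimate]:
    """Exponential likelihood with gamma prior: λ^α e^(−λ(β+t)).

    Returns the unnormalized log-posterior (for the sampler) together with
    its closed-form conjugate posterior gamma(α + 1, β + t), which serves as
    the independent oracle for sampler validation.
    """
    if t <= 0:
        raise ValueError(f"waiting time must be positive, got {t}")
    alpha, beta = prior.alpha, prior.beta

    def logpost(lam):
        lam = np.asarray(lam, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = np.where(lam > 0, alpha * np.log(lam) - lam * (beta + t), -np.inf)
        return lp if lp.ndim else float(lp)

    return logpost, _gamma_estimate(alpha + 1.0, beta + t)


def weibull_gamma_logpost(prior: GammaPrior, t: float, c: float = 1.5) -> LogPost:
    """Weibull likelihood with fatigue shape c and gamma prior.

    Unnormalized posterior λ^(α−1)·e^(−λβ)·λ^c·e^(−(λt)^c).  The shape c
    models operator fatigue: c > 1 gives an increasing failure-rate function,
    c = 1 recovers the exponential–gamma model exactly, 0 < c < 1 a
    decreasing one.  A conservative default of c = 1.5 is used throughout.
    """
    if t <= 0:
        raise ValueError(f"waiting time must be positive, got {t}")
    if c <= 0:
        raise ValueError(f"fatigue parameter must be positive, got {c}")
    alpha, beta = prior.alpha, prior.beta

    def logpost(lam):
        lam = np.asarray(lam, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = np.where(
                lam > 0,
                (alpha - 1.0 + c) * np.log(lam) - lam * beta - (lam * t) ** c,
                -np.inf,
            )
        return lp if lp.ndim else float(lp)

    return logpost


def exponential_normal_logpost(prior: NormalPrior, t: float) -> LogPost:
    """Exponential likelihood with a (truncated) normal prior on λ.

    Unnormalized posterior λ e^(−λt) · e^(−(x−λ)²/2σ²) on λ > 0.
    """
    if t <= 0:
        raise ValueError(f"waiting time must be positive, got {t}")
    x, sigma = prior.mu, prior.sigma
    inv2s2 = 0.5 / sigma**2

    def logpost(lam):
        lam = np.asarray(lam, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = np.where(
                lam > 0, np.log(lam) - lam * t - (x - lam) ** 2 * inv2s2, -np.inf
            )
        return lp if lp.ndim else float(lp)

    return logpost


def poisson_normal_logpost(
    prior: NormalPrior,
    events: int,
    exposure: float,
    literal: bool = False,
) -> LogPost:
    """Poisson likelihood with a (truncated) normal prior on λ.

    With ``literal=False`` (default) the likelihood is read with
    exposure-count semantics: ``events`` occurrences over ``exposure``
    observed intervals, i.e. (λ·y)^n e^(−λ·y) with n = events, y = exposure.
    ``literal=True`` keeps the printed-form role of the symbols (count and
    exposure swapped); the zero-count case degenerates to the pure prior in
    both readings.
    """
    if events < 0 or int(events) != events:
        raise ValueError(f"event count must be a nonnegative integer, got {events}")
    if exposure < 0:
        raise ValueError(f"exposure must be nonnegative, got {exposure}")
    x, sigma = prior.mu, prior.sigma
    inv2s2 = 0.5 / sigma**2
    n, y = (exposure, events) if literal else (events, exposure)

    def logpost(lam):
        lam = np.asarray(lam, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            prior_term = -((x - lam) ** 2) * inv2s2
            if n == 0 or y == 0:
                lp = np.where(lam > 0, prior_term, -np.inf)
            else:
                lp = np.where(
                    lam > 0,
                    n * np.log(lam * y) - lam * y + prior_term,
                    -np.inf,
                )
        return lp if lp.ndim else float(lp)

    return logpost


def compare_posteriors(a: PosteriorEstimate, b: PosteriorEstimate) -> float:
    """Relative percent difference of posterior means, 100·|a−b|/a."""
    if not (np.isfinite(a.mean) and np.isfinite(b.mean)):
        raise ValueError("posterior means must be finite")
    if a.mean == 0:
        raise ValueError("reference posterior mean is zero")
    return 100.0 * abs(a.mean - b.mean) / a.mean
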