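"""Random-walk Metropolis–Hastings engine for the non-conjugate rate models.

Protocol: each run consists of a number of independent replicate cycles
(default 10); each cycle draws 4500 values with a symmetric Gaussian
random-walk proposal reflected at zero, discards the first 500 as burn-in,
and the retained draws from all cycles are pooled.  The pooled mean, sd and
5–95% percentile interval summarize the posterior; the pooled acceptance
rate (AR) is a sampling-quality indicator with a target band of 48–68%.
An out-of-band AR is reported, and optionally warned about, but never an
error — it flags poor mixing, not an invalid result.

Reflection at zero keeps the proposal symmetric on the half-line (a move
λ → |λ + ε| has the same proposal density as its reverse), so the
acceptance ratio depends on the target alone and the AR band is meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .inference import LogPost, PosteriorEstimate

__all__ = ["SamplerConfig", "SamplerTrace", "metropolis_hastings", "tune_proposal"]


@dataclass(frozen=True)
class SamplerConfig:
    n_draws: int = 4500
    burn_in: int = 500
    cycles: int = 10
    proposal_scale: float = 0.05
    seed: int = 0
    auto_tune: bool = True
    ar_band: tuple[float, float] = (0.48, 0.68)

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_draws:
            raise ValueError(f"need 0 <= burn_in < n_draws, got {self}")
        if self.cycles < 1:
            raise ValueError(f"cycles must be >= 1, got {self.cycles}")


@dataclass(frozen=True)
class SamplerTrace:
    draws: np.ndarray  # shape (cycles, n_draws - burn_in)
    acceptance_rate: float
    cycle_means: np.ndarray
    summary: PosteriorEstimate
    proposal_scale: float


def _initial_point(logpost: LogPost) -> float:
    """Start from the log-posterior's argmax over a coarse log-grid.

    Cheap, deterministic, and guarantees a finite starting density for any
    target that is finite somewhere on (0, ∞).
    """
    grid = np.logspace(-6, 2, 200)
    vals = np.asarray(logpost(grid), dtype=float)
    if not np.isfinite(vals).any():
        raise ValueError("log-posterior is nowhere finite on (0, inf)")
    return float(grid[np.nanargmax(np.where(np.isfinite(vals), vals, -np.inf))])


def _run_chain(
    logpost: LogPost, n: int, scale: float, rng: np.random.Generator, x0: float
) -> tuple[np.ndarray, int]:
    draws = np.empty(n)
    steps = rng.normal(0.0, scale, size=n)
    logu = np.log(rng.random(size=n))
    x = x0
    lp = float(logpost(x))
    accepted = 0
    for k in range(n):
        xp = abs(x + steps[k])  # reflect at 0
        lpp = float(logpost(xp))
        if logu[k] < lpp - lp:
            x, lp = xp, lpp
            accepted += 1
        draws[k] = x
    return draws, accepted


def metropolis_hastings(logpost: LogPost, cfg: SamplerConfig) -> SamplerTrace:
    """Sample a 1-D log-posterior over λ > 0 under the replicate-cycle protocol.

    Runs ``cfg.cycles`` independent chains (per-cycle seeds derived
    deterministically from ``cfg.seed``), burns in each, pools the retained
    draws, and reports the pooled mean, sd, 5–95% interval and acceptance
    rate.  Fully reproducible from the master seed.
    """
    scale = cfg.proposal_scale
    if cfg.auto_tune:
        scale = tune_proposal(logpost, cfg)
    if scale <= 0:
        raise ValueError(f"proposal scale must be positive, got {scale}")

    x0 = _initial_point(logpost)
    kept = cfg.n_draws - cfg.burn_in
    draws = np.empty((cfg.cycles, kept))
    accepted = 0
    for c in range(cfg.cycles):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(c,)))
        chain, acc = _run_chain(logpost, cfg.n_draws, scale, rng, x0)
        if acc == 0:
            raise RuntimeError(
                f"all {cfg.n_draws} proposals rejected in cycle {c}; "
                "proposal scale is degenerate for this target"
            )
        draws[c] = chain[cfg.burn_in :]
        accepted += acc

    pooled = draws.ravel()
    lo, hi = np.percentile(pooled, [5.0, 95.0])
    ar = accepted / (cfg.cycles * cfg.n_draws)
    if not cfg.ar_band[0] <= ar <= cfg.ar_band[1]:
        warnings.warn(
            f"acceptance rate {ar:.2f} outside the quality band {cfg.ar_band}",
            stacklevel=2,
        )
    summary = PosteriorEstimate(
        family="sampled",
        mean=float(pooled.mean()),
        sd=float(pooled.std(ddof=1)),
        ci=(float(lo), float(hi)),
    )
    return SamplerTrace(
        draws=draws,
        acceptance_rate=ar,
        cycle_means=draws.mean(axis=1),
        summary=summary,
        proposal_scale=scale,
    )


def tune_proposal(logpost: LogPost, cfg: SamplerConfig, max_steps: int = 30) -> float:
    """Find a proposal scale whose acceptance rate falls in the quality band.

    Pilot chains of n_draws/4 draws are run while the scale is doubled
    (AR too low → proposal too wide) or halved (AR too high → too narrow)
    up to ``max_steps`` times.  If the band is never hit the nearest-achieved
    scale is returned with a warning — the band is a quality indicator, not
    a hard constraint.
    """
    lo, hi = cfg.ar_band
    n_pilot = max(cfg.n_draws // 4, 200)
    x0 = _initial_point(logpost)
    scale = cfg.proposal_scale
    if scale <= 0:
        raise ValueError(f"proposal scale must be positive, got {scale}")
    best_scale, best_dist = scale, np.inf
    for step in range(max_steps):
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=cfg.seed, spawn_key=(0xA5, step)))
        _, acc = _run_chain(logpost, n_pilot, scale, rng, x0)
        ar = acc / n_pilot
        if lo <= ar <= hi:
            return scale
        dist = lo - ar if ar < lo else ar - hi
        if dist < best_dist:
            best_scale, best_dist = scale, dist
        scale = scale * 2.0 if ar > hi else scale / 2.0
    warnings.warn(
        f"proposal tuner could not reach AR band {cfg.ar_band} in {max_steps} "
        f"steps; using nearest-achieved scale {best_scale:g}",
        stacklevel=2,
    )
    return best_scale
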