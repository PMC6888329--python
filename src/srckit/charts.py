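"""Control-chart engine for statistical risk surveillance.

Every interval carries a Bayesian posterior for the event rate λ; the chart
plots the event-based observed rate against a center line with control
limits at center ± k·σ_post.  Four updating modes exist:

* ``recurrent_mean_prior`` — each interval's posterior becomes the next
  interval's prior, but the center line is held at the stated target rate
  (0 for a zero-accident policy, 0.05 for one accident per 20 intervals).
* ``recurrent_mean_posterior`` — posterior threads forward and the center
  line follows the current posterior mean.
* ``direct_mean_prior`` / ``direct_mean_posterior`` — each interval
  recomputes the posterior from the initial prior and all data accumulated
  so far; center per the same rule.

Alarms are raised when a new incidence arrives: the observed rate (count
divided by intervals elapsed since the previous incidence) is compared with
the limits.  A point equal to a limit at display precision (2 dp) is marked
``at_limit``; beyond it, ``out_of_limits``.  Intervals without a new
observation carry the last observed value for plotting continuity but are
``in_control`` — an alarm needs an observation to trigger it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bowtie import ObservationSeries
from .inference import (
    GammaPrior,
    NormalPrior,
    PosteriorEstimate,
    poisson_gamma_update,
)
from .sampler import SamplerConfig, metropolis_hastings

__all__ = [
    "ChartMode",
    "Flag",
    "ChartConfig",
    "ChartPoint",
    "ControlChart",
    "ConfigurationError",
    "observed_rate",
    "build_chart",
    "export_chart",
    "read_chart",
]

#: Model/prior pairs with a supported posterior.
_SUPPORTED = {
    ("poisson", "gamma"),
    ("exponential", "gamma"),
    ("weibull", "gamma"),
    ("exponential", "normal"),
    ("poisson", "normal"),
}


class ConfigurationError(ValueError):
    """Raised for an unsupported model/prior combination or bad chart config."""


class ChartMode(str, Enum):
    direct_mean_prior = "direct_mean_prior"
    direct_mean_posterior = "direct_mean_posterior"
    recurrent_mean_prior = "recurrent_mean_prior"
    recurrent_mean_posterior = "recurrent_mean_posterior"

    @property
    def recurrent(self) -> bool:
        return self.value.startswith("recurrent")

    @property
    def mean_prior(self) -> bool:
        return self.value.endswith("mean_prior")


class Flag(str, Enum):
    in_control = "in_control"
    at_limit = "at_limit"
    out_of_limits = "out_of_limits"


@dataclass(frozen=True)
class ChartConfig:
    mode: ChartMode = ChartMode.recurrent_mean_prior
    k_sigma: float = 1.0
    target_mean: float = 0.05
    horizon: int | None = None  # default: the series horizon

    def __post_init__(self) -> None:
        if self.k_sigma <= 0:
            raise ConfigurationError(f"k_sigma must be positive, got {self.k_sigma}")


@dataclass(frozen=True)
class ChartPoint:
    interval: int
    posterior_mean: float
    posterior_sd: float
    observed_rate: float  # NaN before the first event
    center: float
    ucl: float
    lcl: float
    flag: Flag
    ci_lo: float = float("nan")
    ci_hi: float = float("nan")

    def __post_init__(self) -> None:
        if not self.lcl <= self.center <= self.ucl:
            raise ValueError(f"limits not ordered at interval {self.interval}")
        if self.lcl < 0:
            raise ValueError(f"negative LCL at interval {self.interval}")


@dataclass(frozen=True)
class ControlChart:
    config: ChartConfig
    model: str
    prior_family: str
    points: tuple[ChartPoint, ...]

    @property
    def flagged_intervals(self) -> list[int]:
        return [p.interval for p in self.points if p.flag is not Flag.in_control]

    _COLUMNS = (
        "interval", "posterior_mean", "posterior_sd", "observed_rate",
        "center", "ucl", "lcl", "ci_lo", "ci_hi", "flag",
    )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "interval": p.interval,
                    "posterior_mean": p.posterior_mean,
                    "posterior_sd": p.posterior_sd,
                    "observed_rate": p.observed_rate,
                    "center": p.center,
                    "ucl": p.ucl,
                    "lcl": p.lcl,
                    "ci_lo": p.ci_lo,
                    "ci_hi": p.ci_hi,
                    "flag": p.flag.value,
                }
                for p in self.points
            ],
            columns=list(self._COLUMNS),
        )


def observed_rate(y: Sequence[int], i: int) -> float | None:
    """Event-based rate at interval ``i`` (1-based) for counts ``y``.

    At an interval with y_i > 0 the rate is y_i divided by the number of
    intervals elapsed since the previous incidence (since interval 0 for the
    first).  At a quiet interval the previous observed value is carried for
    plotting continuity; ``None`` before any incidence has occurred.
    """
    if not 1 <= i <= len(y):
        raise ValueError(f"interval {i} outside horizon {len(y)}")
    event_intervals = [k + 1 for k in range(i) if y[k] > 0]
    if not event_intervals:
        return None
    last = event_intervals[-1]
    prev = event_intervals[-2] if len(event_intervals) > 1 else 0
    return y[last - 1] / (last - prev)


# ---------------------------------------------------------------------------
# composite log-posteriors over accumulated event blocks
#
# One "event block" is (k events, elapsed time t).  The inference-module ops
# are the single-block primitives; charts accumulate blocks for the direct
# modes and thread priors for the recurrent ones.


def _waiting_logpost(model, prior, blocks, c):
    """Log-posterior for exponential/Weibull waiting-time blocks."""
    ks = np.array([k for k, _ in blocks], dtype=float)
    ts = np.array([t for _, t in blocks], dtype=float)
    if isinstance(prior, GammaPrior):
        alpha, beta = prior.alpha, prior.beta
        if model == "exponential":
            shape = alpha - 1.0 + ks.sum()
            rate = beta + ts.sum()

            def logpost(lam):
                lam = np.asarray(lam, dtype=float)
                with np.errstate(divide="ignore", invalid="ignore"):
                    lp = np.where(lam > 0, shape * np.log(lam) - lam * rate, -np.inf)
                return lp if lp.ndim else float(lp)

        else:  # weibull
            shape = alpha - 1.0 + c * ks.sum()

            def logpost(lam):
                lam = np.asarray(lam, dtype=float)
                with np.errstate(divide="ignore", invalid="ignore"):
                    pen = sum(k * (lam * t) ** c for k, t in zip(ks, ts))
                    lp = np.where(
                        lam > 0, shape * np.log(lam) - lam * beta - pen, -np.inf
                    )
                return lp if lp.ndim else float(lp)

        return logpost
    # normal prior: only exponential waiting times are defined
    x, sigma = prior.mu, prior.sigma
    inv2s2 = 0.5 / sigma**2
    ktot, ttot = ks.sum(), ts.sum()

    def logpost(lam):
        lam = np.asarray(lam, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = np.where(
                lam > 0,
                ktot * np.log(lam) - lam * ttot - (x - lam) ** 2 * inv2s2,
                -np.inf,
            )
        return lp if lp.ndim else float(lp)

    return logpost


def _poisson_normal_blocks_logpost(prior, blocks):
    """Poisson likelihood over (events, exposure) blocks with a normal prior."""
    x, sigma = prior.mu, prior.sigma
    inv2s2 = 0.5 / sigma**2
    blocks = [(n, y) for n, y in blocks if n > 0 and y > 0]

    def logpost(lam):
        lam = np.asarray(lam, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            lik = sum(n * np.log(lam * y) - lam * y for n, y in blocks)
            lp = np.where(lam > 0, lik - (x - lam) ** 2 * inv2s2, -np.inf)
        return lp if lp.ndim else float(lp)

    return logpost


def _gamma_from_moments(mean: float, sd: float) -> GammaPrior:
    """Moment-matched gamma prior (used to thread non-conjugate posteriors)."""
    mean = max(mean, 1e-12)
    sd = max(sd, 1e-12)
    return GammaPrior(alpha=(mean / sd) ** 2, beta=mean / sd**2)


def _flag(observed: float, ucl: float, lcl: float) -> Flag:
    """Compare the monitored value with the limits at 2-dp display precision."""
    if round(observed, 2) == round(ucl, 2) or (lcl > 0 and round(observed, 2) == round(lcl, 2)):
        return Flag.at_limit
    if observed > ucl or observed < lcl:
        return Flag.out_of_limits
    return Flag.in_control


def _prior_estimate(prior) -> tuple[float, float]:
    if isinstance(prior, GammaPrior):
        return prior.mean, prior.sd
    return prior.mu, prior.sigma


def build_chart(
    series: ObservationSeries | Sequence[int],
    model: str,
    prior: GammaPrior | NormalPrior,
    chart: ChartConfig,
    sampler: SamplerConfig | None = None,
    fatigue_c: float = 1.5,
    literal_poisson: bool = False,
) -> ControlChart:
    """Run the full surveillance chart for one model/prior pair.

    ``series`` is an :class:`ObservationSeries` (or a raw per-interval count
    vector).  The Poisson–gamma pair uses the exact conjugate posterior;
    every other pair is sampled with Metropolis–Hastings using per-interval
    seeds derived from ``sampler.seed``, so a chart is reproducible from its
    configuration alone.
    """
    prior_family = "gamma" if isinstance(prior, GammaPrior) else "normal"
    if (model, prior_family) not in _SUPPORTED:
        raise ConfigurationError(f"unsupported model/prior pair ({model}, {prior_family})")
    if model == "weibull" and fatigue_c <= 0:
        raise ConfigurationError(f"fatigue parameter must be positive, got {fatigue_c}")

    if isinstance(series, ObservationSeries):
        y = np.zeros(series.horizon, dtype=int)
        for rec in series.records:
            y[rec.interval - 1] += len(rec.incidences)
    else:
        y = np.asarray(series, dtype=int)
    horizon = chart.horizon or len(y)
    if horizon > len(y):
        raise ConfigurationError(f"horizon {horizon} exceeds series length {len(y)}")

    if sampler is None:
        sampler = SamplerConfig()

    closed_form = model == "poisson" and prior_family == "gamma"
    points: list[ChartPoint] = []
    est: PosteriorEstimate | None = None
    cur_prior = prior
    blocks: list[tuple[int, float]] = []  # accumulated (events, elapsed) blocks
    last_event = 0
    s_cum = 0

    for i in range(1, horizon + 1):
        new_obs = y[i - 1] > 0
        if closed_form:
            # recurrent and direct coincide: the cumulative conjugate update
            s_cum += int(y[i - 1])
            est = poisson_gamma_update(prior, s_cum, i)
        elif new_obs:
            k, dt = int(y[i - 1]), float(i - last_event)
            block = (k, dt)
            use_blocks = blocks + [block] if not chart.mode.recurrent else [block]
            base_prior = prior if not chart.mode.recurrent else cur_prior
            if model == "poisson":
                logpost = _poisson_normal_blocks_logpost(base_prior, use_blocks)
                if literal_poisson:
                    from .inference import poisson_normal_logpost

                    logpost = poisson_normal_logpost(base_prior, k, dt, literal=True)
            else:
                logpost = _waiting_logpost(model, base_prior, use_blocks, fatigue_c)
            cfg = replace(sampler, seed=(sampler.seed * 1_000_003 + i) % 2**31)
            est = metropolis_hastings(logpost, cfg).summary
            blocks.append(block)
            last_event = i
            if chart.mode.recurrent:
                if prior_family == "gamma":
                    if model == "exponential":
                        cur_prior = GammaPrior(cur_prior.alpha + k, cur_prior.beta + dt)
                    else:
                        cur_prior = _gamma_from_moments(est.mean, est.sd)
                else:
                    center_mu = chart.target_mean if chart.mode.mean_prior else est.mean
                    cur_prior = NormalPrior(mu=center_mu, sigma=max(est.sd, 1e-9))

        if est is None:
            pm, ps = _prior_estimate(prior)
            ci = (math.nan, math.nan)
        else:
            pm, ps = est.mean, est.sd
            ci = est.ci

        center = chart.target_mean if chart.mode.mean_prior else pm
        ucl = center + chart.k_sigma * ps
        lcl = max(0.0, center - chart.k_sigma * ps)
        obs = observed_rate(y, i)
        flag = Flag.in_control
        if new_obs and obs is not None:
            flag = _flag(obs, ucl, lcl)
        points.append(
            ChartPoint(
                interval=i,
                posterior_mean=pm,
                posterior_sd=ps,
                observed_rate=math.nan if obs is None else obs,
                center=center,
                ucl=ucl,
                lcl=lcl,
                flag=flag,
                ci_lo=ci[0],
                ci_hi=ci[1],
            )
        )

    return ControlChart(config=chart, model=model, prior_family=prior_family, points=tuple(points))


def export_chart(
    chart: ControlChart, outdir: str | Path, basename: str = "chart", plot: bool = True
) -> dict[str, Path]:
    """Write the chart as a delimited table (and a plot) under ``outdir``.

    The table round-trips losslessly through :func:`read_chart`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    table = outdir / f"{basename}.csv"
    chart.to_frame().to_csv(table, index=False)
    paths["table"] = table
    if plot:
        paths["plot"] = _plot_chart(chart, outdir / f"{basename}.png")
    return paths


def read_chart(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def _plot_chart(chart: ControlChart, path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = chart.to_frame()
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(df["interval"], df["posterior_mean"], "o-", label=r"$\lambda_{post}$")
    ax.plot(df["interval"], df["observed_rate"], "s--", color="gray", label="observed")
    ax.plot(df["interval"], df["center"], color="green", lw=1, label="center")
    ax.plot(df["interval"], df["ucl"], color="red", lw=1, label="UCL")
    ax.plot(df["interval"], df["lcl"], color="red", lw=1, ls=":", label="LCL")
    out = df[df["flag"] != Flag.in_control.value]
    ax.scatter(out["interval"], out["observed_rate"], facecolor="none",
               edgecolor="blue", s=160, label="alarm")
    ax.set_xlabel("interval")
    ax.set_ylabel("rate per interval")
    ax.set_title(f"{chart.model}–{chart.prior_family} / {chart.config.mode.value}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
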