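"""Synthetic incident streams, HMM sequences, and the worked case fixture.

Everything the surveillance pipeline consumes can be generated here with a
known ground truth: per-interval incidence counts from Poisson, exponential
or Weibull renewal processes at a known rate, hidden-Markov observation
sequences from known transition/emission matrices, and the MDF-plant
first-level scenario with its ten-interval observation log (incidences at
intervals 4, 7 and 8) and the two ten-symbol observation strings used by
the hidden-Markov analyses.

All generators take explicit seeds; there is no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bowtie import (
    AnalysisLevel,
    BarrierRole,
    CauseClass,
    EndState,
    InitiationCause,
    ObservationRecord,
    ObservationSeries,
    SafetyBarrier,
    Scenario,
)
from .hmm import HMMSpec

__all__ = [
    "StreamSpec",
    "BarrierSimSpec",
    "simulate_incidences",
    "simulate_hmm",
    "worked_case_fixture",
]


@dataclass(frozen=True)
class StreamSpec:
    """An incident stream: renewal/count process with a known true rate.

    ``true_lambda`` is the expected number of events per observation
    interval for every process; the Weibull stream's scale is chosen so the
    fatigue shape changes waiting-time dispersion without changing the rate.
    """

    process: str = "poisson"  # poisson | exponential | weibull
    true_lambda: float = 0.05
    fatigue_c: float = 1.5
    horizon: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.process not in ("poisson", "exponential", "weibull"):
            raise ValueError(f"unknown process {self.process!r}")
        if self.true_lambda <= 0:
            raise ValueError("true_lambda must be positive")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.fatigue_c <= 0:
            raise ValueError("fatigue_c must be positive")


@dataclass(frozen=True)
class BarrierSimSpec:
    truth: HMMSpec
    length: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")


def simulate_incidences(spec: StreamSpec) -> ObservationSeries:
    """Draw a per-interval incidence series from the named process.

    Poisson streams draw interval counts directly; exponential and Weibull
    streams are renewal processes in continuous time whose event times are
    binned onto the unit interval grid.  Deterministic under the seed.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.process == "poisson":
        counts = rng.poisson(spec.true_lambda, size=spec.horizon)
    else:
        mean_wait = 1.0 / spec.true_lambda
        counts = np.zeros(spec.horizon, dtype=int)
        t = 0.0
        # draw in batches until the horizon is covered
        while t < spec.horizon:
            if spec.process == "exponential":
                waits = rng.exponential(mean_wait, size=64)
            else:
                from scipy.special import gamma as gamma_fn

                scale = mean_wait / gamma_fn(1.0 + 1.0 / spec.fatigue_c)
                waits = scale * rng.weibull(spec.fatigue_c, size=64)
            for w in waits:
                t += w
                if t >= spec.horizon:
                    break
                counts[int(t)] += 1
    return ObservationSeries.from_counts(counts.tolist())


def simulate_hmm(spec: BarrierSimSpec) -> tuple[list[int], list[int]]:
    """Generative sampling: (observed 1-based symbols, hidden 1-based path)."""
    rng = np.random.default_rng(spec.seed)
    A, B, pi = spec.truth.transition, spec.truth.emission, spec.truth.initial
    n = A.shape[0]
    hidden: list[int] = []
    observed: list[int] = []
    state = rng.choice(n, p=pi)
    for _ in range(spec.length):
        observed.append(int(rng.choice(B.shape[1], p=B[state])) + 1)
        hidden.append(int(state) + 1)
        state = rng.choice(n, p=A[state])
    return observed, hidden


def worked_case_fixture() -> tuple[Scenario, ObservationSeries, dict[str, str]]:
    """The MDF-plant first-level scenario and its observation log.

    Three mitigative barriers SF1 < SF2 < SF3 (general workplace
    protections, safety controls/alarms/shutdown, emergency power and
    rescue) bound four end states: no injury, minor, serious, fatal.
    Preventive barriers cover job/safety self-control and supervision plus
    the general automated barrier.  The ten-interval log records a sensor
    fault on SF1's first-level sub-function at interval 4, a job
    self-control failure at interval 7 and a failed rescue test on SF3's
    sub-function at interval 8, giving counts [0,0,0,1,0,0,1,1,0,0].

    Also returns the two ten-symbol observation strings for the
    hidden-Markov analyses: end states observed ("1111112311") and active
    barriers observed ("1111112211").
    """
    preventive = [
        SafetyBarrier(id=f"IS_{tag}", role=BarrierRole.preventive,
                      subfunctions=(f"SF_IS_{tag}1",))
        for tag in ("JSC", "JSU", "SSC", "SSU")
    ] + [SafetyBarrier(id="SF_ISg", role=BarrierRole.preventive, subfunctions=("SF_ISg1",))]
    mitigative = [
        SafetyBarrier(id="SF1", role=BarrierRole.mitigative, order=1, subfunctions=("SF11",)),
        SafetyBarrier(id="SF2", role=BarrierRole.mitigative, order=2, subfunctions=("SF21",)),
        SafetyBarrier(id="SF3", role=BarrierRole.mitigative, order=3, subfunctions=("SF31",)),
    ]
    causes = (
        InitiationCause(id="ic_sensor", cause_class=CauseClass.basic,
                        description="pressure-sensor fault in hot pressing",
                        attached_to="SF11"),
        InitiationCause(id="ic_jsc", cause_class=CauseClass.human,
                        description="job self-control failure", attached_to="IS_JSC"),
        InitiationCause(id="ic_rescue", cause_class=CauseClass.basic,
                        description="failed internal rescue test", attached_to="SF31"),
        InitiationCause(id="ic_fatigue", cause_class=CauseClass.potential,
                        description="operator fatigue near shift end",
                        attached_to="IS_SSU"),
    )
    end_states = (
        EndState(id="V1", severity_rank=1, label="no injury"),
        EndState(id="V2", severity_rank=2, label="minor injury"),
        EndState(id="V3", severity_rank=3, label="serious injury"),
        EndState(id="V4", severity_rank=4, label="fatality"),
    )
    scenario = Scenario(
        causes=causes,
        barriers=tuple(preventive + mitigative),
        end_states=end_states,
        analysis_level=AnalysisLevel.first_level,
    )
    records = (
        ObservationRecord(interval=4, incidences=("ic_sensor",)),
        ObservationRecord(interval=7, incidences=("ic_jsc",)),
        ObservationRecord(interval=8, incidences=("ic_rescue",)),
    )
    series = ObservationSeries(horizon=10, records=records)
    seqobs = {"end_states": "1111112311", "barriers": "1111112211"}
    return scenario, series, seqobs
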