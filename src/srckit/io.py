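"""Readers, writers and the end-to-end surveillance pipeline.

File formats are deliberately plain:

* scenario — a YAML tree (causes, barriers, end_states, analysis_level);
* observations — delimited text with header ``interval,item_id,item_kind``
  and an optional ``end_state`` column (one row per incidence; rows sharing
  an interval merge into one record);
* matrices — delimited text with labeled rows and columns;
* run configuration — a YAML tree with model/chart/sampler blocks.

Malformed input is rejected with the offending line named; nothing is
silently coerced.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

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
    counts_per_interval,
    validate_scenario,
)
from .charts import ChartConfig, ChartMode, ConfigurationError, Flag, build_chart, export_chart
from .hmm import HMMSpec, ObservationWindow, baum_welch, parse_seqobs, summarize_chain
from .inference import GammaPrior, NormalPrior
from .sampler import SamplerConfig

__all__ = [
    "read_scenario",
    "write_scenario",
    "read_observations",
    "write_observations",
    "read_matrix",
    "write_matrix",
    "default_hmm_prior",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger("srckit")

_ITEM_KINDS = {"cause", "subfunction", "barrier", "none"}


def read_scenario(path: str | Path) -> Scenario:
    """Load a scenario from its YAML description and validate it."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        scenario = Scenario(
            causes=tuple(
                InitiationCause(
                    id=c["id"],
                    cause_class=CauseClass(c["cause_class"]),
                    description=c.get("description", ""),
                    attached_to=c.get("attached_to", ""),
                )
                for c in doc.get("causes", [])
            ),
            barriers=tuple(
                SafetyBarrier(
                    id=b["id"],
                    role=BarrierRole(b["role"]),
                    order=b.get("order"),
                    subfunctions=tuple(b.get("subfunctions", [])),
                )
                for b in doc.get("barriers", [])
            ),
            end_states=tuple(
                EndState(
                    id=e["id"],
                    severity_rank=int(e["severity_rank"]),
                    label=e.get("label", ""),
                )
                for e in doc.get("end_states", [])
            ),
            analysis_level=AnalysisLevel(doc.get("analysis_level", "first_level")),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ValueError(f"malformed scenario file {path}: {exc}") from exc
    violations = validate_scenario(scenario)
    if violations:
        raise ValueError(f"invalid scenario {path}: " + "; ".join(violations))
    return scenario


def write_scenario(scenario: Scenario, path: str | Path) -> None:
    doc = {
        "analysis_level": scenario.analysis_level.value,
        "causes": [
            {
                "id": c.id,
                "cause_class": c.cause_class.value,
                "description": c.description,
                "attached_to": c.attached_to,
            }
            for c in scenario.causes
        ],
        "barriers": [
            {
                "id": b.id,
                "role": b.role.value,
                **({"order": b.order} if b.order is not None else {}),
                "subfunctions": list(b.subfunctions),
            }
            for b in scenario.barriers
        ],
        "end_states": [
            {"id": e.id, "severity_rank": e.severity_rank, "label": e.label}
            for e in scenario.end_states
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_observations(path: str | Path) -> list[ObservationRecord]:
    """Parse an observation log, reporting the line number of any bad row."""
    per_interval: dict[int, dict] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"interval", "item_id", "item_kind"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"{path}: header must contain {sorted(required)}, got {reader.fieldnames}"
            )
        for row in reader:
            line = reader.line_num
            try:
                interval = int(row["interval"])
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}, line {line}: interval {row['interval']!r} is not an integer"
                ) from None
            if interval < 1:
                raise ValueError(f"{path}, line {line}: interval must be >= 1")
            kind = (row["item_kind"] or "none").strip()
            if kind not in _ITEM_KINDS:
                raise ValueError(
                    f"{path}, line {line}: unknown item_kind {kind!r} "
                    f"(expected one of {sorted(_ITEM_KINDS)})"
                )
            slot = per_interval.setdefault(
                interval, {"incidences": [], "end_state": None}
            )
            item = (row["item_id"] or "").strip()
            if kind != "none" and item:
                slot["incidences"].append(item)
            end_state = (row.get("end_state") or "").strip()
            if end_state:
                slot["end_state"] = end_state
    records = [
        ObservationRecord(
            interval=i,
            incidences=tuple(slot["incidences"]),
            end_state_observed=slot["end_state"],
        )
        for i, slot in sorted(per_interval.items())
    ]
    return records


def write_observations(
    records: list[ObservationRecord],
    path: str | Path,
    scenario: Scenario | None = None,
) -> None:
    """Write records in the delimited observation-log format."""

    def kind_of(item: str) -> str:
        if scenario is None:
            return "cause"
        if item in {c.id for c in scenario.causes}:
            return "cause"
        if item in {b.id for b in scenario.barriers}:
            return "barrier"
        return "subfunction"

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["interval", "item_id", "item_kind", "end_state"])
        for rec in sorted(records, key=lambda r: r.interval):
            wrote = False
            for item in rec.incidences:
                writer.writerow(
                    [rec.interval, item, kind_of(item), rec.end_state_observed or ""]
                )
                wrote = True
            if not wrote:
                writer.writerow([rec.interval, "", "none", rec.end_state_observed or ""])


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Labeled matrix (rows = origin states, columns = destinations/symbols)."""
    return pd.read_csv(path, index_col=0)


def write_matrix(m: np.ndarray, rows, cols, path: str | Path) -> None:
    pd.DataFrame(np.asarray(m), index=list(rows), columns=list(cols)).to_csv(path)


def default_hmm_prior(mode: str) -> HMMSpec:
    """A mildly diagonal prior for either hidden-Markov analysis mode.

    ``barriers``: barriers SF1..SF3 hidden, end states V1..V4 observed —
    each barrier mostly emits its own end state; SF3 splits between serious
    and fatal.  ``endstates``: end states S1..S4 hidden, active barriers
    V1..V3 observed.  These priors are deliberately weak: the recurrent
    Baum–Welch procedure is what adapts them to the observations.
    """
    if mode == "barriers":
        hidden = ("SF1", "SF2", "SF3")
        symbols = ("V1", "V2", "V3", "V4")
        transition = np.array(
            [[0.80, 0.15, 0.05], [0.20, 0.60, 0.20], [0.20, 0.20, 0.60]]
        )
        emission = np.array(
            [
                [0.85, 0.05, 0.05, 0.05],
                [0.05, 0.85, 0.05, 0.05],
                [0.05, 0.05, 0.45, 0.45],
            ]
        )
        initial = np.array([0.8, 0.1, 0.1])
    elif mode == "endstates":
        hidden = ("S1", "S2", "S3", "S4")
        symbols = ("V1", "V2", "V3")
        transition = np.array(
            [
                [0.70, 0.15, 0.10, 0.05],
                [0.25, 0.55, 0.15, 0.05],
                [0.20, 0.20, 0.50, 0.10],
                [0.20, 0.15, 0.15, 0.50],
            ]
        )
        emission = np.array(
            [
                [0.90, 0.05, 0.05],
                [0.10, 0.80, 0.10],
                [0.05, 0.15, 0.80],
                [0.10, 0.10, 0.80],
            ]
        )
        initial = np.array([0.7, 0.1, 0.1, 0.1])
    else:
        raise ValueError(f"unknown hmm mode {mode!r} (expected barriers|endstates)")
    return HMMSpec(
        hidden_states=hidden,
        observed_symbols=symbols,
        transition=transition,
        emission=emission,
        initial=initial,
    )


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunConfig:
    scenario: Path
    observations: Path
    outdir: Path
    likelihood: str = "poisson"
    prior_family: str = "gamma"
    alpha: float = 0.001
    beta: float = 0.001
    mu: float = 0.05
    sigma: float = 0.1
    fatigue_c: float = 1.5
    chart: ChartConfig = field(default_factory=ChartConfig)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    hmm_mode: str | None = None  # barriers | endstates
    hmm_seq: str | None = None
    hmm_transition: Path | None = None
    hmm_emission: Path | None = None
    fail_on_alarm: bool = True
    horizon: int | None = None  # default: the last recorded interval

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        for block in ("scenario", "observations", "outdir", "model"):
            if block not in doc:
                raise ConfigurationError(f"run config missing {block!r} block")
        model = doc["model"]
        known = {"likelihood", "prior", "alpha", "beta", "mu", "sigma", "fatigue_c"}
        unknown = set(model) - known
        if unknown:
            raise ConfigurationError(f"unknown model keys {sorted(unknown)}")
        chart_doc = doc.get("chart", {})
        sampler_doc = doc.get("sampler", {})
        hmm_doc = doc.get("hmm", {})
        return cls(
            scenario=Path(doc["scenario"]),
            observations=Path(doc["observations"]),
            outdir=Path(doc["outdir"]),
            likelihood=model.get("likelihood", "poisson"),
            prior_family=model.get("prior", "gamma"),
            alpha=float(model.get("alpha", 0.001)),
            beta=float(model.get("beta", 0.001)),
            mu=float(model.get("mu", 0.05)),
            sigma=float(model.get("sigma", 0.1)),
            fatigue_c=float(model.get("fatigue_c", 1.5)),
            chart=ChartConfig(
                mode=ChartMode(chart_doc.get("mode", "recurrent_mean_prior")),
                k_sigma=float(chart_doc.get("k_sigma", 1.0)),
                target_mean=float(chart_doc.get("target_mean", 0.05)),
            ),
            sampler=SamplerConfig(
                n_draws=int(sampler_doc.get("n_draws", 4500)),
                burn_in=int(sampler_doc.get("burn_in", 500)),
                cycles=int(sampler_doc.get("cycles", 10)),
                proposal_scale=float(sampler_doc.get("proposal_scale", 0.05)),
                seed=int(sampler_doc.get("seed", 0)),
                auto_tune=bool(sampler_doc.get("auto_tune", True)),
            ),
            hmm_mode=hmm_doc.get("mode"),
            hmm_seq=hmm_doc.get("seq"),
            hmm_transition=Path(hmm_doc["transition"]) if "transition" in hmm_doc else None,
            hmm_emission=Path(hmm_doc["emission"]) if "emission" in hmm_doc else None,
            fail_on_alarm=bool(doc.get("fail_on_alarm", True)),
            horizon=int(doc["horizon"]) if "horizon" in doc else None,
        )

    def make_prior(self) -> GammaPrior | NormalPrior:
        if self.prior_family == "gamma":
            return GammaPrior(alpha=self.alpha, beta=self.beta)
        if self.prior_family == "normal":
            return NormalPrior(mu=self.mu, sigma=self.sigma)
        raise ConfigurationError(f"unknown prior family {self.prior_family!r}")


def run_pipeline(cfg: RunConfig) -> int:
    """Execute the surveillance pipeline; returns the process exit status.

    Reads the scenario and observation log, builds and exports the control
    chart, writes a flag summary, and — when an observation sequence is
    configured — fits the hidden-Markov model and writes its matrices and
    chain summaries.  Every artifact is regenerable byte-identically from
    (config, seed, inputs).  The exit status is 1 when any interval is out
    of limits and ``fail_on_alarm`` is set, else 0.
    """
    scenario = read_scenario(cfg.scenario)
    records = read_observations(cfg.observations)
    horizon = cfg.horizon or max((r.interval for r in records), default=1)
    y = counts_per_interval(scenario, records, horizon)
    series = ObservationSeries.from_counts(y.tolist())
    log.info("observed counts over %d intervals: %s", horizon, y.tolist())

    chart = build_chart(
        series,
        model=cfg.likelihood,
        prior=cfg.make_prior(),
        chart=cfg.chart,
        sampler=cfg.sampler,
        fatigue_c=cfg.fatigue_c,
    )
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    export_chart(chart, cfg.outdir)
    for p in chart.points:
        log.info(
            "interval %d: lambda_post=%.4g sd=%.4g flag=%s",
            p.interval, p.posterior_mean, p.posterior_sd, p.flag.value,
        )

    alarms = [p.interval for p in chart.points if p.flag is Flag.out_of_limits]
    summary = {
        "model": cfg.likelihood,
        "prior": cfg.prior_family,
        "mode": cfg.chart.mode.value,
        "flagged_intervals": chart.flagged_intervals,
        "out_of_limits_intervals": alarms,
    }

    if cfg.hmm_mode and cfg.hmm_seq:
        prior = default_hmm_prior(cfg.hmm_mode)
        if cfg.hmm_transition is not None and cfg.hmm_emission is not None:
            t = read_matrix(cfg.hmm_transition)
            e = read_matrix(cfg.hmm_emission)
            prior = HMMSpec(
                hidden_states=tuple(t.index),
                observed_symbols=tuple(e.columns),
                transition=t.to_numpy(),
                emission=e.to_numpy(),
                initial=prior.initial,
            )
        window = ObservationWindow(symbols=tuple(parse_seqobs(cfg.hmm_seq)))
        fit = baum_welch(prior, window)
        cs = summarize_chain(fit.posterior, horizon=window.capacity)
        write_matrix(fit.posterior.transition, prior.hidden_states,
                     prior.hidden_states, cfg.outdir / "transition_posterior.csv")
        write_matrix(fit.posterior.emission, prior.hidden_states,
                     prior.observed_symbols, cfg.outdir / "emission_posterior.csv")
        summary["hmm"] = {
            "mode": cfg.hmm_mode,
            "iterations": fit.iterations,
            "log_likelihood": fit.log_likelihood[-1],
            "stationary": cs.stationary.tolist(),
            "expected_visits": cs.expected_visits.tolist(),
            "first_passage": [None if np.isnan(v) else v for v in cs.first_passage],
        }
        log.info("hmm stationary occupations: %s", np.round(cs.stationary, 3).tolist())

    with open(cfg.outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return 1 if (alarms and cfg.fail_on_alarm) else 0
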