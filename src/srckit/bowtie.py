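"""Bow-tie risk scenarios and the barrier-cascade end-state logic.

A scenario is a bow-tie: initiation causes (basic equipment failures ``ba``,
human errors ``ha`` and hard-to-predict potential causes ``pot``) feed
preventive barriers on the left side; if the accident event fires, an ordered
cascade of mitigative barriers SF1 < SF2 < ... < SFn on the right side decides
the injury end state.  The first barrier that acts correctly stops the
cascade, so with n mitigative barriers there are exactly n + 1 end states:
no injury (SF1 held), one state per failing prefix, and the worst state when
every barrier fails.

This module holds the data model, its validation, the deterministic mapping
from barrier outcomes to end states, and the routing of observation records
into per-interval incidence counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CauseClass",
    "BarrierRole",
    "AnalysisLevel",
    "InitiationCause",
    "SafetyBarrier",
    "EndState",
    "Scenario",
    "ObservationRecord",
    "ObservationSeries",
    "validate_scenario",
    "end_state_from_outcomes",
    "counts_per_interval",
]


class CauseClass(str, Enum):
    """Class of an initiation cause: basic (ba), human (ha) or potential (pot)."""

    basic = "ba"
    human = "ha"
    potential = "pot"


class BarrierRole(str, Enum):
    preventive = "preventive"
    mitigative = "mitigative"


class AnalysisLevel(str, Enum):
    """Observation scope: the full bow-tie or only first-level items."""

    full = "full"
    first_level = "first_level"


@dataclass(frozen=True)
class InitiationCause:
    """A precursor event that can start an accident sequence."""

    id: str
    cause_class: CauseClass
    description: str = ""
    attached_to: str = ""


@dataclass(frozen=True)
class SafetyBarrier:
    """A preventive or mitigative barrier with its sub-functions.

    Mitigative barriers carry a strict order rank (1 = first to act after the
    accident event); preventive barriers carry none.  ``subfunctions`` is
    ordered by level, the first entry being the first-level sub-function.
    """

    id: str
    role: BarrierRole
    order: int | None = None
    subfunctions: tuple[str, ...] = ()


@dataclass(frozen=True)
class EndState:
    """An injury end state; severity_rank 1 is no injury, n+1 the worst."""

    id: str
    severity_rank: int
    label: str = ""


@dataclass(frozen=True)
class Scenario:
    causes: tuple[InitiationCause, ...]
    barriers: tuple[SafetyBarrier, ...]
    end_states: tuple[EndState, ...]
    analysis_level: AnalysisLevel = AnalysisLevel.first_level

    @property
    def mitigative_barriers(self) -> list[SafetyBarrier]:
        bs = [b for b in self.barriers if b.role is BarrierRole.mitigative]
        return sorted(bs, key=lambda b: (b.order is None, b.order))

    def known_ids(self) -> set[str]:
        ids: set[str] = {c.id for c in self.causes}
        for b in self.barriers:
            ids.add(b.id)
            ids.update(b.subfunctions)
        ids.update(e.id for e in self.end_states)
        return ids

    def first_level_ids(self) -> set[str]:
        """Ids observable at the first level of the bow-tie.

        First-level items are each barrier's first-level sub-function, the
        barriers themselves, and causes attached directly to a barrier or to
        a first-level sub-function.
        """
        level1: set[str] = set()
        for b in self.barriers:
            level1.add(b.id)
            if b.subfunctions:
                level1.add(b.subfunctions[0])
        for c in self.causes:
            if c.attached_to in level1:
                level1.add(c.id)
        return level1


@dataclass(frozen=True)
class ObservationRecord:
    """What was seen in one time interval.

    ``incidences`` lists ids of causes or barrier sub-functions that fired;
    the optional fields carry categorical observations for the hidden-Markov
    analyses (an end state, or the barrier seen active).
    """

    interval: int
    incidences: tuple[str, ...] = ()
    end_state_observed: str | None = None
    active_barrier_observed: str | None = None


@dataclass(frozen=True)
class ObservationSeries:
    """An observation log over a fixed horizon of 1-based intervals."""

    horizon: int
    records: tuple[ObservationRecord, ...] = ()

    @classmethod
    def from_counts(cls, counts: Sequence[int], item_id: str = "ic") -> "ObservationSeries":
        recs = []
        for i, c in enumerate(counts, start=1):
            if c:
                recs.append(ObservationRecord(interval=i, incidences=(item_id,) * int(c)))
        return cls(horizon=len(counts), records=tuple(recs))


def validate_scenario(s: Scenario) -> list[str]:
    """Check every scenario invariant; return human-readable violations.

    Returns an empty list iff the scenario is well formed.  Violations name
    the offending element so they can be surfaced directly to the user.
    """
    violations: list[str] = []

    all_ids = [c.id for c in s.causes] + [b.id for b in s.barriers] + [e.id for e in s.end_states]
    for b in s.barriers:
        all_ids.extend(b.subfunctions)
    for dup, n in Counter(all_ids).items():
        if n > 1:
            violations.append(f"duplicate id {dup!r} declared {n} times")

    mit = [b for b in s.barriers if b.role is BarrierRole.mitigative]
    orders = sorted(b.order for b in mit if b.order is not None)
    if any(b.order is None for b in mit):
        violations.append("mitigative barrier without an order rank")
    elif orders != list(range(1, len(mit) + 1)):
        violations.append(
            f"mitigative order ranks {orders} are not consecutive 1..{len(mit)}"
        )
    for b in s.barriers:
        if b.role is BarrierRole.preventive and b.order is not None:
            violations.append(f"preventive barrier {b.id!r} carries an order rank")

    n = len(mit)
    if len(s.end_states) != n + 1:
        violations.append(
            f"end-state count {len(s.end_states)} != n+1 = {n + 1} for {n} mitigative barriers"
        )
    ranks = sorted(e.severity_rank for e in s.end_states)
    if ranks != list(range(1, len(s.end_states) + 1)):
        violations.append(f"severity ranks {ranks} are not a permutation of 1..{len(s.end_states)}")

    attachable = {b.id for b in s.barriers}
    for b in s.barriers:
        attachable.update(b.subfunctions)
    for c in s.causes:
        if c.attached_to and c.attached_to not in attachable:
            violations.append(
                f"cause {c.id!r} attached to undeclared barrier/sub-function {c.attached_to!r}"
            )

    return violations


def end_state_from_outcomes(s: Scenario, outcomes: Sequence[int]) -> EndState:
    """Map an ordered barrier outcome vector to its end state.

    ``outcomes`` has one bit per mitigative barrier in cascade order;
    0 = the barrier acted correctly, 1 = it failed.  Severity is one plus
    the number of leading failures before the first success — the cascade
    stops at the first working barrier, so bits after the first 0 are
    ignored — and reaches rank n+1 when every barrier fails.
    """
    mit = s.mitigative_barriers
    n = len(mit)
    if len(outcomes) != n:
        raise ValueError(
            f"outcome vector of length {len(outcomes)} for {n} mitigative barriers"
        )
    if any(o not in (0, 1) for o in outcomes):
        raise ValueError(f"outcome bits must be 0/1, got {list(outcomes)}")
    leading_failures = 0
    for o in outcomes:
        if o == 1:
            leading_failures += 1
        else:
            break
    severity = leading_failures + 1
    for e in s.end_states:
        if e.severity_rank == severity:
            return e
    raise ValueError(f"no end state with severity rank {severity}")  # pragma: no cover


def counts_per_interval(
    s: Scenario,
    records: Iterable[ObservationRecord],
    horizon: int,
) -> np.ndarray:
    """Aggregate observation records into the incidence count vector y.

    ``y[i-1]`` is the number of incidences (initiation causes plus barrier
    sub-function fails) recorded in interval ``i``; intervals without records
    are zero.  When the scenario's analysis level is ``first_level``, only
    first-level items are counted.
    """
    known = s.known_ids()
    keep = s.first_level_ids() if s.analysis_level is AnalysisLevel.first_level else known
    y = np.zeros(horizon, dtype=int)
    for rec in records:
        if not 1 <= rec.interval <= horizon:
            raise ValueError(f"record interval {rec.interval} outside horizon {horizon}")
        for item in rec.incidences:
            if item not in known:
                raise ValueError(f"record references unknown id {item!r}")
            if item in keep:
                y[rec.interval - 1] += 1
    return y
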