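"""Hidden-Markov analysis of mitigative safety barriers and injury end states.

Two complementary views share one engine (only the label bindings differ):

* mode A — the barriers SF1..SFn are the hidden states and the injury end
  states V1..V(n+1) are the observed symbols;
* mode B — the end states S1..S(n+1) are hidden and the active barriers are
  observed.

Observations are kept in a rolling FIFO window (capacity 10 by default);
each window is fitted with the Baum–Welch EM algorithm, and the fitted
transition matrix is summarized by its steady-state occupations, the
expected number of visits to each state over the window horizon, and the
mean first-passage time from each state to the most critical one.  The
fitted matrices can be threaded forward as the next window's prior
(recurrent updating).

Symbols are 1-based integers, matching observation strings such as
"1111112311" (six no-injury observations, one minor, one serious, two
no-injury).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "HMMSpec",
    "ObservationWindow",
    "HMMFit",
    "ChainSummary",
    "parse_seqobs",
    "baum_welch",
    "stationary",
    "expected_visits",
    "first_passage",
    "recurrent_hmm_update",
    "summarize_chain",
]

_ROW_TOL = 1e-8
_ZERO_ROW_EPS = 1e-8


def _check_stochastic(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2:
        raise ValueError(f"{name} must be a matrix")
    if (m < -_ROW_TOL).any() or (m > 1 + _ROW_TOL).any():
        raise ValueError(f"{name} entries must lie in [0, 1]")
    if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError(f"{name} rows must sum to 1")
    return m


@dataclass(frozen=True)
class HMMSpec:
    """Transition/emission/initial parameters with state and symbol labels."""

    hidden_states: tuple[str, ...]
    observed_symbols: tuple[str, ...]
    transition: np.ndarray
    emission: np.ndarray
    initial: np.ndarray

    def __post_init__(self) -> None:
        t = _check_stochastic(self.transition, "transition")
        e = _check_stochastic(self.emission, "emission")
        pi = np.asarray(self.initial, dtype=float)
        n, m = len(self.hidden_states), len(self.observed_symbols)
        if t.shape != (n, n):
            raise ValueError(f"transition shape {t.shape} inconsistent with {n} states")
        if e.shape != (n, m):
            raise ValueError(f"emission shape {e.shape} inconsistent with {n}x{m}")
        if pi.shape != (n,) or not np.isclose(pi.sum(), 1.0, atol=1e-6):
            raise ValueError("initial must be a probability vector over the hidden states")
        object.__setattr__(self, "transition", t)
        object.__setattr__(self, "emission", e)
        object.__setattr__(self, "initial", pi)


@dataclass(frozen=True)
class ObservationWindow:
    """FIFO window of 1-based observation symbols (newest in, oldest out)."""

    symbols: tuple[int, ...]
    capacity: int = 10

    def __post_init__(self) -> None:
        if len(self.symbols) > self.capacity:
            raise ValueError(f"window holds {len(self.symbols)} > capacity {self.capacity}")

    def push(self, symbol: int) -> "ObservationWindow":
        syms = self.symbols + (int(symbol),)
        if len(syms) > self.capacity:
            syms = syms[1:]
        return ObservationWindow(symbols=syms, capacity=self.capacity)


@dataclass(frozen=True)
class HMMFit:
    posterior: HMMSpec
    log_likelihood: tuple[float, ...]  # per EM iteration
    iterations: int
    window: ObservationWindow


@dataclass(frozen=True)
class ChainSummary:
    stationary: np.ndarray
    expected_visits: np.ndarray
    first_passage: np.ndarray  # NaN where the target is not hit almost surely
    target: int


def parse_seqobs(s: str) -> list[int]:
    """Parse an observation string like "1111112311" into 1-based symbols."""
    if not s or not s.isdigit():
        raise ValueError(f"observation string must be nonempty digits, got {s!r}")
    return [int(ch) for ch in s]


# ---------------------------------------------------------------------------
# Baum–Welch with scaled forward-backward recursions


def _forward_backward(A, B, pi, obs):
    T, n = len(obs), A.shape[0]
    alpha = np.empty((T, n))
    beta = np.empty((T, n))
    scale = np.empty(T)
    alpha[0] = pi * B[:, obs[0]]
    scale[0] = alpha[0].sum()
    if scale[0] <= 0:
        raise ValueError("observation sequence has zero likelihood under the prior")
    alpha[0] /= scale[0]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ A) * B[:, obs[t]]
        scale[t] = alpha[t].sum()
        if scale[t] <= 0:
            raise ValueError("observation sequence has zero likelihood under the prior")
        alpha[t] /= scale[t]
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[:, obs[t + 1]] * beta[t + 1])) / scale[t + 1]
    loglik = float(np.log(scale).sum())
    return alpha, beta, scale, loglik


def _regularize_rows(m: np.ndarray) -> np.ndarray:
    """Re-normalize rows, lifting all-zero rows with a small epsilon.

    Zero rows can arise in EM re-estimation when a state is never visited;
    the epsilon keeps the matrices row-stochastic so that a fitted model can
    serve as the next recurrent prior.
    """
    m = np.where(m.sum(axis=1, keepdims=True) > 0, m, _ZERO_ROW_EPS)
    return m / m.sum(axis=1, keepdims=True)


def loglikelihood(spec: HMMSpec, symbols: Sequence[int]) -> float:
    """Forward log-likelihood of a 1-based symbol sequence under ``spec``."""
    obs = _to_indices(spec, symbols)
    return _forward_backward(spec.transition, spec.emission, spec.initial, obs)[3]


def _to_indices(spec: HMMSpec, symbols: Sequence[int]) -> np.ndarray:
    obs = np.asarray(symbols, dtype=int) - 1
    if len(obs) == 0:
        raise ValueError("empty observation window")
    if (obs < 0).any() or (obs >= len(spec.observed_symbols)).any():
        bad = sorted(set(int(s) for s in np.asarray(symbols)[
            (obs < 0) | (obs >= len(spec.observed_symbols))]))
        raise ValueError(f"symbols {bad} outside the alphabet of {len(spec.observed_symbols)}")
    return obs


def baum_welch(
    prior: HMMSpec,
    seq: ObservationWindow | Sequence[int],
    tol: float = 1e-6,
    max_iter: int = 500,
) -> HMMFit:
    """Fit transition/emission/initial parameters to the window by EM.

    Standard Baum–Welch re-estimation from forward-backward statistics,
    stopping when the log-likelihood improves by less than ``tol`` or after
    ``max_iter`` iterations.  The log-likelihood trace is nondecreasing (up
    to the zero-row regularization epsilon).
    """
    symbols = seq.symbols if isinstance(seq, ObservationWindow) else seq
    obs = _to_indices(prior, symbols)
    A = prior.transition.copy()
    B = prior.emission.copy()
    pi = prior.initial.copy()
    T, n, m = len(obs), A.shape[0], B.shape[1]

    trace: list[float] = []
    for it in range(1, max_iter + 1):
        alpha, beta, scale, ll = _forward_backward(A, B, pi, obs)
        trace.append(ll)
        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        if T > 1:
            # xi_sum[i,j] = sum_t alpha[t,i] * A[i,j] * B[j,o_{t+1}] * beta[t+1,j] / c_{t+1}
            w = B[:, obs[1:]].T * beta[1:] / scale[1:, None]
            A = _regularize_rows((alpha[:-1].T @ w) * A)
        B_new = np.zeros((n, m))
        for s in range(m):
            B_new[:, s] = gamma[obs == s].sum(axis=0)
        B = _regularize_rows(B_new)
        pi = gamma[0]
        if it > 1 and trace[-1] - trace[-2] < tol:
            break

    posterior = HMMSpec(
        hidden_states=prior.hidden_states,
        observed_symbols=prior.observed_symbols,
        transition=A,
        emission=B,
        initial=pi,
    )
    if isinstance(seq, ObservationWindow):
        window = seq
    else:
        syms = tuple(int(s) for s in symbols)
        window = ObservationWindow(symbols=syms, capacity=max(10, len(syms)))
    return HMMFit(
        posterior=posterior,
        log_likelihood=tuple(trace),
        iterations=len(trace),
        window=window,
    )


# ---------------------------------------------------------------------------
# chain summaries


def stationary(transition: np.ndarray, initial: np.ndarray | None = None) -> np.ndarray:
    """Steady-state occupations π with πP = π and Σπ = 1.

    For a reducible chain the fixed point of the recurrent class reachable
    from ``initial`` (uniform when omitted) is returned, with zeros
    elsewhere; if several recurrent classes are reachable the first in
    state order is used.
    """
    P = _check_stochastic(np.asarray(transition, dtype=float), "transition")
    n = P.shape[0]
    if initial is None:
        initial = np.full(n, 1.0 / n)
    initial = np.asarray(initial, dtype=float)

    adj = csr_matrix((P > 1e-15).astype(int))
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    # a recurrent class has no edge leaving its component
    recurrent = []
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        outside = np.setdiff1d(np.arange(n), members)
        if len(outside) == 0 or P[np.ix_(members, outside)].sum() <= 1e-15:
            recurrent.append(members)

    reach = _reachable_sets(P)
    support = np.flatnonzero(initial > 0)
    chosen = None
    for members in sorted(recurrent, key=lambda ms: ms[0]):
        if any(reach[s][members].any() for s in support):
            chosen = members
            break
    if chosen is None:  # pragma: no cover - every finite chain has one
        chosen = recurrent[0]

    sub = P[np.ix_(chosen, chosen)]
    k = len(chosen)
    A = np.vstack([sub.T - np.eye(k), np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi_sub, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.zeros(n)
    pi[chosen] = np.clip(pi_sub, 0.0, None)
    pi /= pi.sum()
    return pi


def _reachable_sets(P: np.ndarray) -> list[np.ndarray]:
    """Boolean reachability (including self) for each state."""
    n = P.shape[0]
    adj = P > 1e-15
    reach = []
    for s in range(n):
        seen = np.zeros(n, dtype=bool)
        stack = [s]
        seen[s] = True
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(adj[u]):
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        reach.append(seen)
    return reach


def expected_visits(
    transition: np.ndarray, initial: np.ndarray, horizon: int = 10
) -> np.ndarray:
    """Expected occupancy of each state over steps 1..horizon.

    The initial distribution is propagated through the transition matrix and
    the per-step state distributions are summed, so the entries always sum
    to the horizon.
    """
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    P = _check_stochastic(np.asarray(transition, dtype=float), "transition")
    d = np.asarray(initial, dtype=float)
    total = np.zeros_like(d)
    for _ in range(horizon):
        d = d @ P
        total += d
    return total


def first_passage(transition: np.ndarray, target: int) -> np.ndarray:
    """Mean first-passage steps m_i from every state to ``target`` (0-based).

    Solves m_i = 1 + Σ_{k≠j} p_ik·m_k.  States from which the target is not
    reached almost surely (hitting probability < 1) are flagged with NaN
    instead of a number; the target itself has m = 0.
    """
    P = _check_stochastic(np.asarray(transition, dtype=float), "transition")
    n = P.shape[0]
    if not 0 <= target < n:
        raise ValueError(f"target {target} outside 0..{n - 1}")

    # hitting probabilities: h_j = 1, h = 0 on states that cannot reach j,
    # linear system elsewhere
    reach = _reachable_sets(P)
    can_reach = np.array([reach[i][target] for i in range(n)])
    h = np.zeros(n)
    h[target] = 1.0
    solve_states = np.flatnonzero(can_reach & (np.arange(n) != target))
    if len(solve_states):
        Q = P[np.ix_(solve_states, solve_states)]
        rhs = P[solve_states, target]
        h[solve_states] = np.linalg.solve(np.eye(len(solve_states)) - Q, rhs)

    m = np.full(n, np.nan)
    m[target] = 0.0
    sure = np.flatnonzero((h > 1 - 1e-9) & (np.arange(n) != target))
    if len(sure):
        Q = P[np.ix_(sure, sure)]
        m[sure] = np.linalg.solve(np.eye(len(sure)) - Q, np.ones(len(sure)))
    return m


def recurrent_hmm_update(
    fit: HMMFit, new_symbol: int
) -> tuple[HMMSpec, ObservationWindow]:
    """Thread a fit forward: posterior becomes the next prior, window shifts.

    Requires the window the fit was computed on at full capacity so that the
    FIFO shift is well defined; returns the new prior spec and the shifted
    window (oldest symbol dropped, ``new_symbol`` appended).
    """
    if len(fit.window.symbols) < fit.window.capacity:
        raise ValueError(
            f"window holds {len(fit.window.symbols)} symbols; "
            f"recurrent updating needs it at capacity {fit.window.capacity}"
        )
    sym = int(new_symbol)
    if not 1 <= sym <= len(fit.posterior.observed_symbols):
        raise ValueError(
            f"symbol {sym} outside the alphabet of {len(fit.posterior.observed_symbols)}"
        )
    return fit.posterior, fit.window.push(sym)


def summarize_chain(
    spec: HMMSpec, horizon: int = 10, target: int | None = None
) -> ChainSummary:
    """Stationary occupations, expected visits and first passage to ``target``.

    ``target`` defaults to the last (most critical) hidden state.
    """
    if target is None:
        target = len(spec.hidden_states) - 1
    return ChainSummary(
        stationary=stationary(spec.transition, spec.initial),
        expected_visits=expected_visits(spec.transition, spec.initial, horizon),
        first_passage=first_passage(spec.transition, target),
        target=target,
    )
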