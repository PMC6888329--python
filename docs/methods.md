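# Methods

## Scope and model

`srckit` monitors an occupational-accident *rate* λ (events per observation
interval) from precursor observations, under the assumption that precursors
arrive as a memoryless or renewal stream: Poisson counts per interval,
exponential waiting times between events, or Weibull waiting times when an
increasing failure-rate ("fatigue") effect is plausible.  The prior on λ is
either a gamma distribution (conjugate to the Poisson and exponential
likelihoods) or a normal distribution truncated to λ > 0 — λ is a rate, and
truncation only changes the normalizing constant, which neither the sampler
nor the chart uses.

The bow-tie layer is deliberately non-probabilistic: it is an
observation-routing structure.  Causes and barrier sub-functions are
catalogued, observations referencing them are counted per interval
(optionally restricted to the first level of the bow-tie), and the ordered
mitigative barriers define the injury end states through a first-success
cascade: severity = 1 + number of leading barrier failures, so outcome bits
after the first success are ignored, and the preimage sizes of severities
1..n+1 over all 2^n outcome vectors are 2^(n−1), …, 2, 1, 1.

## Inference and threading

The Poisson–gamma chart uses the exact cumulative conjugate posterior
gamma(α + Σy, β + N_t) at every interval; the sequential (posterior → next
prior) and cumulative forms coincide exactly, which is also a property
test.  Waiting-time models update at event intervals, with waiting times
measured in whole intervals since the previous event (since interval 0 for
the first).  If an interval carries k > 1 incidences they enter the
likelihood as one block of k events over the elapsed time.

Recurrent modes thread the posterior into the next event's prior:
conjugately for gamma/exponential, by gamma moment-matching for the Weibull
posterior, and as normal(center, σ_post) for normal priors.  In the
mean-prior modes the prior/center stays at the stated target rate and only
the spread threads; in the mean-posterior modes the center follows the
posterior mean.  Direct modes recompute each interval from the initial
prior and all accumulated blocks.  Whether the first interval's σ comes
from a data-based estimate or the prior is an open choice; the prior is
used here, documented as the default.

## The alarm rule

The monitored value is the event-based observed rate y_i/(i − j) (j = the
previous event interval, 0 if none), compared against center ± k·σ_post at
the interval where the incidence arrives; quiet intervals carry the last
observed value for plotting but raise no alarm.  Equality with a limit at
2-dp display precision is a distinct `at_limit` flag.  This is the only
rule under which the worked case behaves as published: with a zero target
the first observation (0.25) sits exactly on the UCL (σ_post = 0.25), the
later ones (0.33, 1) are out of limits, and *every* model — including the
sampled ones, whose posterior means at the first event are near 0.10 and
therefore inside their own ±1σ band — alarms at exactly the event intervals
{4, 7, 8}.  Monitoring the posterior mean instead would break that pattern
for the non-conjugate models; the posterior mean, sd and 5–95% interval are
still computed, plotted and exported per interval.

## Sampler

Non-conjugate posteriors use a random-walk Metropolis–Hastings sampler on
λ with a Gaussian step reflected at zero; reflection keeps the proposal
symmetric on the half-line so the acceptance ratio involves the target
only.  The protocol is 10 independent replicate cycles of 4500 draws with
the first 500 of each burned; retained draws are pooled for the mean, sd
and 5–95% interval.  Per-cycle seeds derive deterministically from one
master seed.  The proposal scale is tuned by doubling/halving against pilot
chains of 1125 draws until the acceptance rate lands in the 48–68% quality
band; the band is advisory — out-of-band rates warn, never fail.  The
exponential–gamma pair doubles as the sampler's oracle: its closed-form
posterior must be matched within 2% (mean) and 5% (sd) under the default
protocol, which the acceptance suite checks.

Chains start at the target's argmax over a coarse log-grid — deterministic,
and finite for any target that is finite somewhere on (0, ∞).

## Hidden-Markov layer

Both analysis modes (barriers hidden / end states observed, and the
reverse) use one discrete-emission engine: scaled forward–backward
recursions, Baum–Welch re-estimation with a stopping rule of < 1e−6
log-likelihood gain or 500 iterations, and zero-row regularization (1e−8,
renormalized) so a fitted model always remains a valid recurrent prior.
Chain summaries from the fitted transition matrix:

* **stationary** — left fixed point πP = π solved by least squares on the
  recurrent class reachable from the initial distribution (first such class
  in state order if several are reachable, a documented tie-break);
  residual below 1e−10.
* **expected visits** — the initial distribution propagated 1..H steps and
  summed (H = 10, the window capacity), so entries always sum to H.
* **first passage** — m_i = 1 + Σ_{k≠j} p_ik·m_k solved linearly; states
  whose hitting probability of the target is below 1 (checked via the
  hitting-probability system) are flagged NaN rather than given a number.

The FIFO window holds the ten most recent symbols; ten observations is the
point at which re-estimated matrices become representative, and the
recurrent update (posterior → prior, window shifted by one) keeps the
analysis current.  Short windows can legitimately produce absorbing fitted
chains — a single new severe observation can collapse the steady state onto
one state; this is a property of EM on ten symbols, not an error.

Published occupations for the worked sequence (≈ 80/10/10% for SF1–SF3 with
a first passage of 8 intervals from SF1 to SF3) are reproduced only
qualitatively: they depend on prior matrices available solely as figures,
so tests assert the engine's guarantees (monotone EM, fixed-point residual,
oracle-matched passage times, parameter recovery) rather than those exact
numbers.  The forward log-likelihood is cross-checked exactly against
`hmmlearn` as an independent oracle; all estimation code here is
self-contained.

## Synthetic data

`simulate_incidences` draws Poisson counts directly, or runs
exponential/Weibull renewal processes in continuous time and bins event
times onto the unit interval grid.  `true_lambda` is always the event rate:
the Weibull scale is set to 1/(λ·Γ(1+1/c)) so the fatigue shape c changes
waiting-time dispersion, not the rate.  Default conditions mirror the study
setting — target rate 0.05 (one accident per 20 intervals), fatigue
c = 1.5, ten-interval observation horizon for the worked case; long-run
checks use horizons of 10^4–10^5 where the empirical rate converges within
2%.  The generator emulates a stationary precursor stream with independent
intervals; real plants have shift structure, reporting delays and
non-stationary exposure, so passing tests demonstrate correctness of the
machinery, not calibration to any particular plant.

`worked_case_fixture` encodes the MDF-plant first-level scenario: the
barrier and end-state structure and the incidence intervals are as
published; the concrete cause identifiers are invented since no catalogue
of first-level cause ids is published.

## Numerical choices and limitations

* Posterior summaries are computed at full precision; displays round to
  2 dp (3 dp below 0.1).
* The normal-prior spread defaults to σ = 0.1 — the same order as the 0.05
  target, which places the sampled posterior means at the worked case's
  first event near 0.10, consistent with the published cross-model
  comparison.  It is a configuration knob (`sigma`).
* The Poisson–normal likelihood defaults to exposure-count semantics
  (n events over y observed intervals); a `literal` flag preserves the
  alternative reading in which the two symbols swap roles.  No supported
  chart behavior differs between the readings.
* Monte-Carlo cross-checks (first passage, expected visits) use 10^5
  seeded runs on chains with transition entries bounded away from zero so
  the 1% comparison tolerance is well inside simulation error.
* The chart assumes at most one alarm evaluation per interval and does not
  implement runs rules (Western-Electric, CUSUM, EWMA); those are natural
  extensions, not part of this methodology.
* Direct modes carry no published reference values; they are covered by
  property tests (agreement with recurrent threading in the conjugate
  case, flag monotonicity in k).
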