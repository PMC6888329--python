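# srckit — statistical risk control for occupational-accident surveillance

`srckit` implements a dynamic risk-surveillance methodology for workplaces
(its worked case is a highly automated medium-density fiberboard plant): a
bow-tie description of the risk scenario routes observed accident
*precursors* — initiation causes and safety-barrier failures — into a
Bayesian update of the event rate λ, plots the result on a control chart
whose limits tighten as evidence accumulates, and follows the mitigative
safety barriers with a hidden-Markov model so that a drifting barrier is
noticed *before* an accident happens.  It is aimed at safety engineers and
methodologists who want a rate-surveillance pipeline that is reproducible
from a seed and testable against closed forms.

## The model

Precursor observations at discrete intervals update the rate λ via Bayes'
rule, `f(λ|data) ∝ g(data|λ)·f(λ)`, under five likelihood/prior pairs:

| likelihood | prior | posterior |
|---|---|---|
| Poisson counts y_i (s = Σy_i over N_t intervals) | gamma(α, β) | gamma(α+s, β+N_t), closed form |
| exponential waiting time t | gamma(α, β) | gamma(α+1, β+t), closed form |
| Weibull waiting time, fatigue shape c (default 1.5) | gamma(α, β) | ∝ λ^(α−1+c) e^(−λβ−(λt)^c), sampled |
| exponential waiting time t | normal(x, σ), truncated to λ>0 | sampled |
| Poisson counts | normal(x, σ), truncated to λ>0 | sampled |

Non-conjugate posteriors are sampled with a random-walk Metropolis–Hastings
scheme (10 independent cycles of 4500 draws, 500 burned each, pooled; the
proposal scale is auto-tuned to a 48–68% acceptance-rate band).

The control chart holds a center line (a target rate such as 0 or 0.05, or
the running posterior mean, depending on the mode) with limits at
center ± k·σ_post.  When a new incidence arrives, the event-based observed
rate — count divided by intervals since the previous incidence — is compared
with the limits: equal at display precision is *at the limit*, beyond is
*out of limits*, and either condition calls for corrective review.

The mitigative barriers SF1 < SF2 < ... < SFn bound n+1 injury end states
(no injury … fatality) through a first-success cascade.  A rolling FIFO
window of the last ten categorical observations (end states, or active
barriers) is fitted with Baum–Welch; the fitted chain yields steady-state
barrier occupations, expected visits over the window horizon, and mean
first-passage times to the most critical state.

## Worked example

```python
from srckit import (GammaPrior, ChartConfig, build_chart,
                    counts_per_interval, worked_case_fixture)

scenario, series, seqobs = worked_case_fixture()
y = counts_per_interval(scenario, series.records, series.horizon)
print(y.tolist())

chart = build_chart(y.tolist(), "poisson", GammaPrior(0.001, 0.001),
                    ChartConfig(k_sigma=1.0, target_mean=0.0))
for p in chart.points:
    print(p.interval, round(p.posterior_mean, 2), round(p.posterior_sd, 3),
          p.flag.value)
```

prints

```
[0, 0, 0, 1, 0, 0, 1, 1, 0, 0]
1 0.0 0.032 in_control
2 0.0 0.016 in_control
3 0.0 0.011 in_control
4 0.25 0.25 at_limit
5 0.2 0.2 in_control
6 0.17 0.167 in_control
7 0.29 0.202 out_of_limits
8 0.38 0.217 out_of_limits
9 0.33 0.192 in_control
10 0.3 0.173 in_control
```

Three precursors (a sensor fault at interval 4, a job self-control failure
at 7, a failed rescue test at 8) drive the posterior rate from 0 to 0.38
events per interval.  The first observation, 1 incidence in 4 intervals
(rate 0.25), lands exactly on the upper control limit of a zero-accident
target; the next two (rates 0.33 and 1) are out of limits, so each triggers
a review well before any injury occurs.  The hidden-Markov side of the same
case (`srckit hmm --mode barriers --seq 1111112311 --out out/`) reports
steady-state occupations ≈ (0.78, 0.11, 0.11): the first barrier absorbs
almost all the activity, and the mean first passage from SF1 to the
last-resort barrier SF3 is about 8 observation intervals.

The same pipeline is scriptable from the shell:

```sh
srckit chart --scenario scenario.yaml --observations obs.csv \
       --model poisson --prior gamma --target 0 --out out/
srckit simulate --process weibull --rate 0.05 --horizon 100 --seed 7 --out obs.csv
```

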