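# stagehmm

Stage-structured hidden Markov models for juvenile mark–recapture data with
imperfect detection and dead recovery.

## The problem

Juvenile insects are hard to study in the field: caterpillars molt (so they
cannot be physically marked), eggs and pupae are nearly invisible, corpses
vanish within days, and every survey misses some of the animals that are
present. `stagehmm` estimates stage-specific survival and growth for such
cohorts — egg, five instars (I1–I5), pupa — from repeated surveys in which
individuals are relocated by position, by separating the demographic process
from the observation process in a hidden Markov model.

It was built for a leafwing-butterfly (*Anaea*) caterpillar system — 14 host
plots resurveyed every 3 days on a staggered rotation over one spring
recruitment pulse — but the model applies to any multi-state mark–recapture
design with unobservable stages and transient dead recoveries.

## The model

Each individual occupies one of 15 states: 7 live stages, 7 "newly dead"
stages (a corpse still findable for one survey interval), and an absorbing
dead state. Two parallel categorical chains drive the data, with
column-stochastic kernels:

    X_t | X_{t-1} ~ Categorical(PX x_{t-1})     (demography)
    Y_t | X_t     ~ Categorical(PO x_t)         (observation)

`PX` is the block matrix [[J, Z], [M, U]]: `J[j,i] = phi_i * psi_{ji}`
(survive with stage-specific probability `phi_i`, then grow from stage *i*
to *j* with probability `psi_{ji}`), `M` routes the dying mass `1 - phi_i`
into the newly dead stages, `Z = 0` (no resurrection), and `U` sends every
newly dead state to the absorbing state. `PO` puts `p_s` on "seen as one's
true stage" and `1 - p_s` on "not seen" — no misclassification.

Survival uses a logit link (constant, or linear in survey date or in
size-scaled caterpillar density — the summed lengths of caterpillars on a
plant); growth uses a multinomial logit over allowed destinations (stasis,
one or two stages up; constant, or linear in date or 3-day mean air
temperature). Egg survival, egg hatching, and pupation are nearly invisible
to field data and carry informative beta priors instead. The per-individual
likelihood marginalizes the hidden state path with the forward algorithm,
conditioned on the state at first detection, and is checked in the test
suite against brute-force enumeration of all hidden paths.

Fitting is Bayesian: adaptive random-walk Metropolis (numba-compiled,
single-site sweeps) with normal(0, 100) priors on coefficients and
uniform(0, 1) on detection probabilities; convergence is assessed with
Gelman–Rubin psrf (univariate and multivariate) and multivariate effective
sample size. Candidate structures — 3 survival forms x 2 stage groupings x
3 growth forms = 18 models — are ranked by AICc computed from the mean
posterior deviance, `AICc = D̄ + 2K + 2K(K+1)/(n−K−1)`.

Because the original field data are not public, the package includes a
first-class synthetic-cohort generator (`generate_cohort`) that emulates the
study design — staggered surveys, an early oviposition pulse, a warming
temperature series, and a log-linear rise in per-capita predation (11% per
day by default) — and retains the full latent truth for parameter-recovery
testing.

## Worked example

```python
import stagehmm as sh

cfg = sh.CohortConfig(seed=7)                      # default study design
histories, tables, truth = sh.generate_cohort(cfg)

tally = tables["survey"].sort_values(["plot_id", "occasion"]).copy()
tally["exposure"] = tally.groupby("plot_id")["live_instars"].shift(1)
tally = tally.dropna(subset=["exposure"])
trend = sh.fit_corpse_trend(tally["corpses"], tally["exposure"], tally["day"])
print(f"{trend.percent_per_day:+.1f}% per day")
```

prints

```
+13.2% per day
```

the estimated daily percent change in the per-capita corpse-encounter rate
for this one replicate (generator truth: +11.0%; single-cohort estimates
scatter by a couple of points, and the 50-replicate average in the
acceptance run below lands on the truth). The `examples/` directory holds
one short script per capability — `simulate_cohort.py`,
`fit_constant_model.py` (posterior summaries next to the generating truth,
psrf/mESS diagnostics), `rank_models.py` (AICc ranking of a candidate
grid), `corpse_trend.py` — each printing what it computes and what the
numbers mean. A thin CLI wraps the same library calls:
`stagehmm simulate|fit|select|diagnose|summarize`.

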