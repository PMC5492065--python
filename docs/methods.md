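# Methods

## State space and kernels

The demographic unit is an individual in one of 15 states: live {egg, I1,
I2, I3, I4, I5, pupa}, newly dead (same seven stages), and an absorbing
dead state. One time step spans one survey interval (3 days). The
transition kernel `PX` is column stochastic — every column lists all
possible fates of its state and sums to one — with blocks

- `J` (live to live): `J[j,i] = phi_i * psi[j,i]`, survival times growth;
- `M` (live to dead space): the dying mass `1 - phi_i`;
- `Z = 0`: the dead do not return;
- `U`: every newly dead state moves to absorbing with probability one, so a
  corpse is discoverable for exactly one interval.

Allowed growth transitions: eggs hatch to I1; I1–I3 may hold, advance one
stage, or advance two (a fast molt cycle can fit inside 3 days for small
instars); I4 holds or advances to I5; I5 holds or pupates; the pupa is
terminal within the model because pupae leave the plant and adult
recruitment is never observed — pupal survival and maturation are not
estimable from these data and are deliberately out of scope.

Two conventions exist for where the dying mass lands. The default keeps it
in the current stage (`M` diagonal): most field deaths are predation, which
leaves a corpse of the stage that died. The alternative, available as
`partition_dying_by_growth=True`, partitions it by the growth kernel
(`M[j,i] = (1-phi_i) psi[j,i]`), which treats deaths during molting as
deaths in the new stage. The partitioned form is not the default for a
concrete reason: it converts part of egg mortality into *observable*
first-instar corpses and part of fifth-instar mortality into *unobservable*
pupal corpses, which distorts the per-capita corpse-encounter trend that
the corpse tally is meant to measure (and that the generator emulates).

The observation kernel `PO` is also column stochastic: a live or newly dead
individual of stage *s* is seen as exactly stage *s* with probability `p_s`
and missed otherwise; there is no misclassification mass. Newly dead eggs
and pupae exist as states (to keep columns stochastic) but have detection
fixed at zero — only instar corpses are ever recovered — and live pupal
detection defaults to zero for the same reason.

## Vital-rate models and covariates

Instar survival uses a logit link: `phi = logistic(b0_g + b1_g x)`, with
one intercept (and, under a covariate form, one slope) per survival group.
Grouping is either `full_stage` (I1..I5 separate) or `early_grouped`
(I1–I4 pooled, I5 separate). The survival covariate `x` is either the
survey date (a stand-in for everything that changes as spring progresses)
or caterpillar density on the individual's plant. Density is computed from
*observed* co-occupants — the summed body lengths (mm) of live instars
detected there, a biomass proxy; a plain count metric is also provided —
because that is what a field worker could actually tally; unobserved
individuals contribute nothing.

Growth uses a multinomial logit with stasis as the reference category:
`psi_j = exp(a0_j + a1 x) / (1 + sum_k exp(a0_k + a1 x))`, one intercept
per destination and one slope per stage shared across destinations (a
parsimony choice; destination-specific slopes would double the growth
parameters a 9-occasion study cannot support). The growth covariate is
either date or the mean hourly air temperature over the 3-day interval the
transition spans. Temperature intervals tolerate up to 10% missing hourly
records (mean over available hours); beyond that the covariate build fails
loudly rather than guess.

All covariates are z-standardized with stored means and sds, so priors act
on a common scale and fitted slopes can be back-transformed to natural
units (`posterior_summary(..., covariates=...)`).

Egg survival, egg hatching, and pupation are treated separately: eggs and
pupae are nearly unobservable, so these three probabilities are sampled on
the probability scale under informative beta priors, emulating rates
measured on lab-reared larvae. They are deliberately *not* given
logit-linear covariate forms — with of order ten egg detections per cohort
a diffuse logit-scale coefficient is unidentified (its posterior develops a
one-sided plateau that no finite chain explores), which is precisely why
informative priors are the right tool here. `matched_priors(truth,
strength)` builds beta priors centered on the generator's truth with
effective pseudo-count `strength` (default 30, a plausible lab sample).

## Likelihood

Each individual enters the analysis at first live detection; the forward
recursion starts from a unit mass on that state and alternates `PX`
multiplication with the observation row of the observed category,
rescaling every step and accumulating the log scale, so 9-occasion
histories with path probabilities at 1e-300 stay finite. `-inf` is a legal
return for impossible histories. Conditioning on first capture (rather
than modeling time of entry) is standard mark–recapture practice; the
oviposition process lives only in the generator. Transition kernels for
the step [t-1, t) are built from covariates measured at t-1.

`brute_force_loglik` re-derives the same quantity by summing the product
of transition and observation probabilities over every hidden-state path
(15^L terms); the suite checks agreement with the forward pass to 1e-12
across random kernels and histories. The production evaluator packs the
whole dataset into flat arrays, deduplicates (individual, occasion)
covariate pairs into classes, builds one kernel per class, and runs the
forward pass in numba exploiting the kernel's structural sparsity; it is
itself tested against the plain per-history forward pass.

## Priors, sampler, diagnostics

Coefficients get normal(0, 100) priors; detection probabilities uniform(0,
1); the three informative probabilities their beta priors. Sampling works
on the unconstrained scale (logit for probabilities) with the
change-of-variable Jacobian included.

The sampler is adaptive random-walk Metropolis updating one parameter at a
time; per-coordinate proposal scales combine a running posterior variance
with a Robbins–Monro correction toward 0.44 acceptance, with diminishing
adaptation frozen at the end of burn-in (so retained draws come from a
fixed Markov kernel). Single-site sweeps were chosen over larger joint
blocks after the latter showed psrf values of 2–4 on detection parameters
at test-scale chain lengths; with single-site updates all parameters reach
psrf ≤ 1.01 at 2,000 + 2,000 iterations on a 300-individual cohort.
Default settings mirror the full-scale protocol (3 chains, 120,000
burn-in, 10,000 retained, no thinning); tests and examples scale down to
hundreds or thousands of iterations, which the acceptance checks show is
sufficient at these data sizes. Chains start from overdispersed but
numerically sane points: coefficients from N(0, 2.5), probabilities from
logit(U(0.05, 0.95)). Raw draws from the sd-100 prior would start on the
logistic plateaus (|logit| > 100) where the posterior is numerically flat
and short burn-ins cannot escape.

Convergence: univariate Gelman–Rubin `psrf = sqrt(((n-1)/n W + B/n)/W)`,
the Brooks–Gelman multivariate psrf from the largest eigenvalue of
`W^{-1}B/n`, and multivariate effective sample size
`mESS = n (det Λ / det Σ)^{1/p}` with Λ the sample covariance and Σ a
batch-means long-run covariance (batch size floor(sqrt(n)); summed over
chains). Exact batch-size and psrf variants are conventions of this
package; an independent cross-check against arviz's rank-normalized rhat
on stationary chains is in the tests.

## Model selection

Candidate structures are scored by `AICc = D̄ + 2K + 2K(K+1)/(n-K-1)` with
D̄ the mean posterior deviance (DIC is deliberately not offered; its
effective-parameter count can go negative for models like these). `K`
counts all sampled parameters, including the three informative-prior
probabilities (excludable via a switch), and `n` is the number of
encounter histories — individuals, not observations; the choice is
configurable and documented rather than asserted, since the correction is
a convention at these sample sizes. Ties break toward smaller `K`, then
lexicographic structure order, making rankings order-invariant.

## Synthetic cohorts

The generator reproduces the study design: 14 plots surveyed 9 times each
on a staggered 3-day rotation (offsets 0/1/2 days; 27 calendar days), 500
egg arrivals by default. Arrivals follow a Beta(1.5, 4)-shaped pulse over
the season — oviposition peaks in the first week — so the cohort matures
to late-instar predominance within the survey window, matching the
observed field pattern. States propagate through the same kernels the
model fits (by construction there is no model misspecification when the
predation trend is switched off); observations are drawn from `PO`;
recorded lengths are stage mean + N(0, 0.5 mm) with stage means 4.1, 6.4,
9.4, 13.3, 19.9 mm.

Two emulated field signals:

- **Temperature**: an hourly series with a linear warming trend (default
  +20 degrees over 30 days, the seasonal rise the generator emulates; units
  follow the series, read as Fahrenheit), a diurnal sinusoid (amplitude 8),
  and N(0, 2) noise; 3-day means per plot-occasion form the covariate
  table.
- **Predation**: the per-step death probability is multiplied by
  `exp(slope (day - 13))`, slope ln(1.11), an 11%-per-day rise
  in the per-capita corpse-encounter rate, anchored mid-season so death
  probabilities stay within [0, 1] without clipping at the defaults.

Rates the field study never printed are package conventions, chosen once
for realism: instar survival 0.9 per 3-day step (uniform across instars),
egg survival 0.88, hatch 0.7, pupation 0.35; growth simplexes slowing with
stage (e.g. I1: 0.25/0.55/0.20 for stasis/+1/+2; I4: 0.45 stasis/0.55
advance); live detection 0.75 for instars and 0.05 for eggs; corpse
detection 0.6 for all instars; 8 plants per plot. Stage-homogeneous instar
mortality and detection make the expected per-capita corpse-encounter rate
exactly log-linear in day — the generator's defining contract, since that
trend is the quantity the corpse regression estimates. The marked subset
(encounter histories) contains only individuals first seen alive; the
generator additionally returns a per-survey field tally that includes
corpses of never-marked individuals, because a field crew counts every
corpse it finds and the trend regression consumes that tally.

What the generator does **not** emulate — and hence what passing recovery
tests do not establish about real data: movement between plants or plots
(dispersing late instars violate the closed-plot assumption), stage
misidentification, temperature- or density-dependence in the default truth
(available via config but off by default), overdispersed or clustered
predation (predators emptying a whole plant), tag loss (relocation by
position can fail), and developmental time-delays (the chain is memoryless
within stage, a real limitation for late instars whose stage duration
exceeds the 3-day step).

## Descriptive summaries

The per-capita predation trend is a Poisson GLM (statsmodels IRLS) of
per-survey corpse counts on survey day with `log(exposure)` offset, where
exposure is the previous survey's live-instar count on that plot; the
offset form is the standard equivalent of regressing corpses per capita,
and a no-offset variant is available. Day indices are each plot's own
survey days, respecting the stagger. Reported as
`100 (exp(slope) - 1)` percent per day. Abundance series and stage mean
lengths are straight tallies of detected individuals.

## Numerical conventions

- Column-stochasticity and simplex checks use 1e-12 absolute tolerance
  (double-precision headroom at these magnitudes).
- Multinomial logits subtract the max linear predictor before
  exponentiating.
- Occasions are 1-based in files, 0-based internally; day indices are
  0-based integers from season start; transitions cover the half-open
  interval [t, t+3).
- CSV dialect: UTF-8, comma, "." decimal; categories NS, E, L1–L5, P,
  D1–D5.
- All randomness flows from explicit integer seeds; fits and simulations
  are bit-reproducible given the seed.

## Problem sizes in the test suite

Replicated studies run at sizes chosen to make their statistical targets
decisive at desk scale: 50 replicate cohorts of 500 arrivals for the
corpse-trend recovery (the mean's Monte Carlo SE is ~0.3 points of
percent); 20 replicate fits of 300-arrival cohorts at 3 chains x (2,000 +
2,000) iterations for credible-interval coverage and psrf; 20 replicate
4-model grid fits of 250-arrival cohorts at 1 chain x (600 + 600) for
AICc self-selection; exhaustive-enumeration likelihood checks at up to 5
occasions, where 15^4 paths are still exact and fast.
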