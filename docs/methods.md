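# Methods

This note documents the models and procedures implemented in `pirabias`, the
numerical and design choices that were genuinely open, and what the
synthetic-data generator does and does not emulate.

## Event detection

Time is integer days since randomisation; calendar dates are out of scope.
All windows are **closed intervals in days**: the 12-week confirmation gap is
≥84 days, the confirmation-visit exclusion after a relapse is the closed
window `[onset, onset + 30]` (a visit on the relapse day itself is excluded),
and the RAW window is `[onset, onset + 90]` before the event onset. Closed
intervals make every off-by-one case testable exactly.

A worsening candidate at visit *v* needs `edss(v) − reference ≥ 1.0` when the
reference EDSS is ≤5.5, else ≥0.5. The threshold from a reference of 0 is
1.0; the alternative clinical convention of 1.5 from EDSS 0 is deliberately
not applied (the two-level rule is the one this package operationalises, and
the simulator never starts patients at 0). Improvements use the same
magnitude rule mirrored; they exist only to drive the roving baseline, which
is the least-surprising symmetric choice given that the baseline must reset
at "every improvement or worsening event".

Confirmation requires that **all** visits strictly between onset and the
confirmation visit, and the confirmation visit itself, sustain the change
relative to the reference — the standard confirmed-worsening reading.
Relapse-tainted visits are barred only from the *confirmation role*; they
still count toward the sustained-change check. After a confirmed event the
reference moves to the confirmation visit **and its value** (not the onset
value: a transiently inflated onset would otherwise poison later
comparisons), and scanning resumes there, so events never overlap.

The relapse-based re-baseline scheme (reset at the first visit ≥30 days
after a relapse with EDSS not below the original day-0 baseline) is applied
*on top of* event-driven resets. When an event confirmation overtakes a
pending relapse reset at a skipped visit, the event reset supersedes it; the
two mechanisms target the same reference state and the confirmation is the
later, more informed anchor. Relapse re-baseline resets may lower the
reference below the current roving reference (the rule compares against the
original baseline only). In the simulation study only the roving scheme is
used, matching the principle of re-baselining only after confirmed events
rather than after any relapse.

## PIRA classification

Relapse-free intervals per definition (all closed):

| definition | intervals |
|---|---|
| standard1 | `[reference, confirmation]` |
| standard2 | `[reference, event+30]`, `[confirmation−30, confirmation+30]` |
| standard3 | `[event−90, event+30]`, `[confirmation−90, confirmation+30]` |
| non_raw   | `[event−90, event]` |

A relapse exactly 30 days after the event violates standard2 (endpoint
included). `non_raw`'s interval is identical to the RAW predicate's window,
making PIRA and RAW set-complementary by construction: every confirmed
worsening is exactly one of the two. Under the other definitions an event
can be *undefined* (interval violated by a relapse that does not precede the
onset). RAW events are *transient* when any later visit returns to (or
below) the event's reference value, else *sustained*; with no later visit no
recovery is observable and the event counts as sustained.

## RIC decomposition

For each relapse, in onset order and on the already-adjusted values: the
acute increment Δ is the excess over the last pre-onset visit of the maximum
EDSS in the closed influence window `[onset, onset+90]` (the window length is
deliberately `raw_window_days`, coupling the decomposition to the RAW
definition); the sustained residual ρ is the excess of the **minimum** EDSS
after the window, capped at Δ — the minimum avoids attributing later
relapse-independent progression to the relapse. Window visits after the
onset lose `min(Δ, excess)`; post-window visits lose ρ. An assessment on the
onset day itself is treated as pre-relapse (the generator mirrors this).
Adjusted values may leave the half-point grid and are **not re-rounded**;
re-rounding would reintroduce relapse artefacts. Detection on the residual
applies thresholds to the raw adjusted values and still honours the
relapse-based confirmation exclusion. Overlapping influence windows are
handled sequentially; this is a documented, testable variant of the
decomposition idea, not a reimplementation of any published algorithm — its
exactness is guaranteed (and tested) when no progression step falls inside a
relapse influence span and rounding is disabled.

## Principal-stratum risk ratio

Monotonicity (treatment never causes relapses) splits patients into immune /
preventable / doomed strata; observables are arm, any-relapse and any-CDA
indicators. Priors: Dirichlet(1,1,1) on prevalences, Beta(1,1) on each CDA
risk θ[s,z]. The sampler is a collapsed data-augmented Gibbs over sufficient
counts (latent Binomial splits for treated non-relapsers and control
relapsers), O(1) per iteration in the number of patients and invariant to
patient order by construction. Defaults: 5000 draws after 1000 burn-in;
validation runs use 4 chains and require split-R-hat < 1.01 on log RR.

The treated-arm mixture identifies only the weighted mean of θ[immune,1] and
θ[preventable,1], so an identification assumption is required (`constraint`
flag): the default `"equal"` sets θ[preventable,1] = θ[immune,1] — treated
non-relapsers experience no relapses irrespective of stratum, so if relapse
proneness affects disability only through relapse-associated worsening their
CDA risk is stratum-independent — which point-identifies the estimand and is
exactly the condition under which the never-relapser risk ratio equals the
relapse-free treatment effect in the simulator's world. The one-sided
`"ordered"` variant (θ[preventable,1] ≥ θ[immune,1]) and `"none"` are kept
for sensitivity analysis: under them the posterior spreads over the feasible
ridge, the credible interval widens drastically and the posterior median is
pulled low, which is why the constraint choice is surfaced as a single
switchable argument rather than buried in the sampler.

## Effect estimation

Hazard ratios come from a Cox fit with arm as the sole covariate (lifelines,
Efron ties — integer-day event times are heavily tied, Newton precision
1e-9); a diverging coefficient (|log HR| > 10, monotone likelihood) raises an
estimation error and the replicate is dropped with a logged warning. Risk
ratios are plain proportion ratios (log-binomial regression would only be
needed for covariate adjustment, which the simulation design excludes).
Across replicates, ratio measures are aggregated as the **geometric mean**
(ratio scales are multiplicative; an arithmetic-mean mode exists behind
`scale="natural"` for sensitivity) with percentile-bootstrap CIs. Bias is
the difference of the aggregated estimated and true effects with a **paired**
bootstrap — the same replicate resample enters both aggregates, so shared
Monte-Carlo noise cancels and the bias CI is narrower than the two effect
CIs combined.

## The trial simulator

The generator emulates a two-arm randomised trial in which relapse-
independent and relapse-associated worsening are *separate additive
components*, so the true effect on PIRA is known by construction. Defaults
(one frozen block, `GeneratorConstants` / `ScenarioSpec`):

| parameter | default | rationale |
|---|---|---|
| n per arm | 800 | study condition |
| follow-up | 672 d (96 wk), visits every 84 d | typical phase-3 schedule; spacing ≤ the 90-day RAW window guarantees a visit in every relapse influence window |
| baseline EDSS | uniform on {1.0,…,4.0} | relapsing-population entry range |
| progression | +1.0 permanent steps, Poisson rate λ_p (control), λ_p·HR (treated) | +1.0 is the worsening threshold at these baselines; linear/stepwise PIRA course |
| λ_p | calibrated, ≈1.16e−3/d | see below |
| control relapse rate | mean 0.5/yr, Gamma frailty shape 1 | study condition; exponential inter-patient heterogeneity |
| acute relapse bump | {0.5,1.0,1.5,2.0} w.p. {0.3,0.4,0.2,0.1} | typical relapse-severity spread |
| recovery | linear over 60 d to the residual | acute-phase duration |
| sustained fraction | 0.3 of relapses leave the full bump permanently | incomplete-recovery rates in relapsing MS |

The frailty shape is the one generator constant calibrated against the
package's own full-scale bias runs (the acute-bump and recovery constants
barely move the interval-definition bias, which is driven by relapse timing;
the frailty shape controls how relapses concentrate across patients).
Visit EDSS is baseline + components, rounded to the half-point grid and
clipped to [0,10]; `rounding=False` exposes the exact superposition
(combined − independent = relapse component) for the decomposition tests.

**Calibration.** Under an exponential first-step model, the probability of a
confirmed relapse-independent worsening over follow-up is
`q = 1 − exp(−λ_p·D)` with `D = 588` the last arrival day whose onset visit
still has a confirmation visit; the treated/control risk ratio at hazard
ratio 0.75 is `(1 − (1−q)^0.75)/q`. `calibrate_lambda_p` solves this for the
target true risk ratio 0.81 by root bracketing, giving `λ_p·D ≈ 0.68` and a
control-arm confirmed-progression risk near 0.49. The same λ_p is used in
the null scenario (the progression rate is a disease property, not a
scenario knob).

**Seeding.** Hierarchical: `SeedSequence((master_seed, replicate,
patient_index))`, one stream per patient with a fixed draw order (baseline,
progression, relapse process). Progression draws precede and are unaffected
by the relapse-reduction level, so the relapse-independent component is
bit-identical across reduction levels — common random numbers that keep the
bias curves smooth in the reduction grid.

**What the generator does not emulate:** dropout and missed visits, EDSS
measurement noise, non-linear progression courses, baseline covariates,
MRI/lesion activity, and relapse effects on future relapse risk. Passing
tests therefore demonstrate the estimator-bias mechanism — differential
discarding of true PIRA events by relapse-dependent windows — not the
magnitude of bias in any particular real trial.

## Problem sizes

The acceptance runs and the end-to-end tests use the full study conditions
(800/arm, 200 replicates per cell; about 50–90 s per cell on one CPU).
Structural property tests run at reduced sizes chosen for coverage, not
precision: 150–300 patients/arm, 8–60 replicates, 1500 MCMC draws inside the
zero-bias grid, 4000/arm for principal-stratum recovery.

## Known limitations

* The decomposition's sequential handling of overlapping relapse windows is
  a pragmatic rule; exactness is only guaranteed for non-interacting
  windows.
* The principal-stratum estimand is point-identified only under the `equal`
  assumption; real populations in which relapse-prone patients carry higher
  relapse-independent CDA risk under treatment violate it, and the `ordered`
  sensitivity mode then shows how wide the feasible range is.
* The estimated-bias magnitudes (as opposed to the ground-truth effects and
  the ordering of definitions) depend on the generator constants above.
* Only one disability score is modelled; composite endpoints (timed walk,
  peg test) and covariate-adjusted or stratified effect models are out of
  scope.
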