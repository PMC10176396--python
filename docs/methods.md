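# Methods

## Overview

`breathecon` chains three models that together evaluate breathlessness
support services for older people with advanced disease (COPD, interstitial
lung disease, lung cancer):

1. a **conditional logit** preference model estimated from discrete-choice
   data, yielding utility weights for service attributes;
2. an **uptake** mapping from any configured service to an acceptance
   probability against the "neither" alternative;
3. a **Markov cohort model** of costs and QALYs over five years, comparing
   usual care with a breathlessness service whose effect lasts one or two
   12-week cycles, with delta-method intervals, probabilistic sensitivity
   analysis (PSA) and cost-effectiveness acceptability curves (CEAC).

Because the underlying patient-level trial data and the full estimated
coefficient vector of the original study are not published, the package
ships a first-class synthetic-data module that generates every input with
known ground truth, at the study's geometry, so all stages can be tested
for recovery.

## Choice model

Each choice task offers two service configurations and an opt-out.  An
alternative's utility is linear in its design row,

    U_j = x_j' beta,      P(choose j) = exp(U_j) / sum_k exp(U_k),

with the opt-out normalised to U = 0 (an all-zero row) and an
alternative-specific constant (ASC) equal to 1 for any service.  Dummy
coding contributes one column per non-reference level; waiting time can be
switched to a single linear column (weeks) for willingness-to-wait style
analyses.

*Estimation.*  The log-likelihood is globally concave, so we use a damped
Newton iteration with analytic gradient and observed information, starting
from the zero vector, stopping when the gradient infinity-norm falls below
1e-6 (at most 200 iterations).  The covariance is the inverse observed
information; the default reported covariance is the cluster-robust sandwich
grouped by respondent, since each respondent answers several tasks.  A
mixed (random-parameters) logit is deliberately out of scope: the target
output is a single coefficient vector per respondent group.

*Degenerate inputs.*  Columns that never vary within any task are rejected
by name before fitting (their coefficients are not identified).  Perfect
separation is flagged — not silently returned — when coefficients diverge
during iteration (|beta| > 30) or sit beyond 15 utility units at numerical
convergence (odds of about 3 x 10^6 : 1, far outside anything plausible for
stated preferences).  Tasks without a recorded choice are dropped task-wise,
never respondent-wise; two chosen flags in one task are rejected at load.

*Subgroup comparison.*  `lr_test` compares nested fits by the likelihood
ratio against a chi-square tail; `lr_test_split` builds the standard
heterogeneity test (group-specific vs pooled coefficients), with
(G-1) x K degrees of freedom.

*Bootstrap.*  `cluster_bootstrap` resamples respondents with replacement,
refits, and returns percentile intervals.  Non-converging refits are
discarded and counted; more than 10% discards raises a warning.

## Coefficient parameterisations

Published preference tables sometimes print a weight for *every* level of
an attribute, which is not an identifiable dummy parameterisation.  The
package accepts such full vectors: `configuration_utility` simply sums the
level keys present (missing keys contribute zero), and `reexpress` converts
a full vector into the dummy parameterisation against any chosen reference
levels, absorbing the reference weights into the ASC.  Every configuration's
utility — and hence its uptake probability — is invariant to this
re-expression, which is also verified by test.

## Uptake

Acceptance is modelled as a binary offer against the opt-out:
p(uptake) = expit(U).  This matches its downstream use as a one-time
decision node in the Markov model rather than a three-way share within a
task.  Intervals come from the delta method on U (then mapped through the
inverse logit, keeping the interval inside (0,1)) or from the cluster
bootstrap when raw data are supplied.  Two "expectation" attributes are held
fixed across all presented services; being common to every service
alternative, their weight is absorbed by the ASC and they are not part of
the varying design.

## Markov cohort model

Five mutually exclusive states: `usual_care`, `bs_effect`,
`bs_extended_effect`, `no_change`, and absorbing `dead`.  Defaults: 20
cycles of 0.25 years (5-year horizon), 3.5%/year discount compounded per
cycle, factor (1.035)^(-0.25 t).

Design choices where the structure was genuinely open:

- **Entry split.** Intervention strategies split the cohort once at entry:
  the uptake fraction starts in the effect state, the remainder receives
  usual care within the same strategy (no decliner penalty).  Uptake is not
  re-offered per cycle.
- **Effect duration.** Effect-state occupants move to `no_change` after
  `effect_cycles` cycles (1 for the base service, 2 for the lasting-effects
  scenario); `no_change` defaults to usual-care payoffs.
- **Mortality switching.** Cycle 1 applies all-cause mortality, cycles 2-20
  respiratory mortality, both age- and sex-indexed with age advanced every
  four cycles; annual probabilities convert by p_cycle = 1-(1-p_annual)^0.25
  (constant hazard within the year).
- **Accrual.** Costs and QALYs accrue on cycle-start occupancy with no
  half-cycle correction by default (a flag enables the midpoint rule).
- **Bookkeeping.** Occupancy conservation is enforced to 1e-9 (the engine
  aborts on drift); in practice rows sum to one within 1e-12.

ICER = dCost/dQALY with explicit dominance labels; a zero QALY difference
with a non-zero cost difference is reported as *undefined*, never printed
as +/- infinity.

## Uncertainty

The discounted totals are linear in the per-state payoffs, so the
delta-method variance is exact given payoff variances: each payoff's
gradient is its accumulated discounted occupancy weight.  Payoff objects
shared between arms (the usual-care payoff) contribute through their *net*
weight across the incremental contrast, so common uncertainty largely
cancels — exactly as it does in the Monte Carlo, where a cloned scenario
preserves the payoff aliasing and one draw feeds both arms.  This is what
makes delta and PSA intervals agree (verified to within 10% relative
half-width at 1000 draws).

PSA families follow standard health-economics practice for each parameter's
support: gamma (method of moments) for costs, beta on (-0.6, 1) for EQ-5D
utilities, normal for unbounded coefficients, logit-normal available for
probabilities.  Zero-variance distributions return the mean exactly, so a
degenerate PSA reproduces the deterministic result bit-for-bit.  Draws
outside a declared support are resampled and counted.  The CEAC counts
strict inequalities (NMB > 0); ties count as non-acceptance.  Default
willingness-to-pay grid: £0-£50,000 in £1,000 steps.

## Synthetic data: what it emulates, and what it does not

`simulate_choice_data` draws choices from the softmax over true utilities
(equivalently, Gumbel errors added to each alternative), over randomly
paired distinct configurations with uniform level sampling — approximately
level-balanced, seedable, bit-reproducible.  The original survey's blocked
fractional-factorial design is not reproduced (it is not public); an
explicit design can be loaded from file instead.  Respondent-level taste
heterogeneity, attribute non-attendance and ordering effects are *not*
simulated, so passing recovery tests demonstrates correctness of the
estimator under the model's own assumptions, not robustness to real-world
misspecification.

The default preference truth uses the published point estimates
(any-service constant 1.52; GP surgery -0.30; outpatient clinic 0.16; home
visit 0.15; comprehensive review 0.15; holistic support 0.19; no support
-0.23; social worker alone -0.15) plus clearly-labelled synthetic
waiting-time placeholders (2 weeks +0.15, 4 weeks +0.05, 8 weeks -0.20),
chosen so that shorter waits are preferred and the standard 7-step
configuration ladder is monotone.

`synth_trial_payoffs` draws per-patient costs from a gamma distribution and
EQ-5D utilities from a bounded normal (resampling outside [-0.6, 1],
counted).  Defaults are anchored to the published incremental results for a
75-year-old male cohort at 0.85 uptake: usual-care cost £2,000 per 12-week
cycle, a saving of £780/cycle while the effect lasts, an EQ-5D gain of
0.06, per-patient sd £1,750 (costs) and 0.155 (utilities) at 100 patients
per arm — reproducing incremental totals near -£660 and +0.013 QALYs with
comparable interval widths.  These are stand-ins for an unpublished trial
dataset, not estimates of it.

`synth_life_table` grows annual all-cause mortality log-linearly
(Gompertz-like) from a base rate at the youngest age (default 0.04 at 65,
slope ln(1.1)/year), with respiratory mortality a constant fraction
(default 0.35) of all-cause, clamped to [0,1] with a warning.  It is
labelled synthetic; it is not a national life table.

## Problem sizes used in the test suite

Parameter recovery runs 200 replicates of 300 respondents x 6 tasks; null
calibration of the subgroup test runs 1000 simulations of 300 respondents
split into two 150-respondent groups (adequate for the chi-square
asymptotics at 8 degrees of freedom); PSA checks use 1000 draws; bootstrap
coverage uses 25 replicates of 199 resamples.  The complete-acceptance CEAC
check runs under the lasting-effects scenario, whose cost saving is many
standard errors from zero, so an identically-one empirical curve is the
expected outcome rather than a coin flip.

## Known limitations

- No mixed logit, nested logit or latent-class models; no willingness-to-pay
  monetisation of waiting time.
- The Markov engine is a cohort model; no patient-level microsimulation,
  and no informal-care or productivity costs.
- Beta/gamma method-of-moments PSA families fail for very large variances
  (beta shape parameters must stay positive); the error message says so.
- The delta method is exact here only because the accumulators are linear
  in the payoffs; uncertainty in uptake or mortality, if added, would make
  it first-order approximate.
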