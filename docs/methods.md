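# Methods

`regionsim` implements a system dynamics (stock-and-flow) model of regional
mental health service provision and suicidal behaviour, and the scenario
machinery used to study regional versus centralised suicide prevention
planning: exhaustive intervention-portfolio search, state-level
aggregation, derivative-free calibration and Latin-hypercube sensitivity
analysis. This note records the model equations, the reasoning behind the
open design choices, and what the synthetic test bed does and does not
establish.

## Simulation frame

Simulations run from 1 January 2011 for 20 model years with explicit Euler
integration at `dt` = 1/8 week (0.875 days). One model year is defined as
exactly 52 weeks; calendar drift of about 1.25 days per year against the
Gregorian calendar is accepted, and forecast-window boundaries (2021 to
the start of 2031) are converted to model weeks on that convention.
Explicit Euler was chosen as the standard fixed-step scheme in system
dynamics practice; higher-order or adaptive schemes are out of scope. The
first-order error of Euler on an exponential process with rate *r* per
week accumulates to roughly `exp(T·r²·dt/2) − 1`; at the model's typical
rate magnitudes (≤ 0.05/week) this is well under 0.5 % over the full
horizon, and halving `dt` changes cumulative outputs by < 10⁻⁴ relative
(tested). Stocks are clamped at zero with a warning if a flow overdraws
one; the default parameterisation never triggers the clamp (tested).

## Stock set

Eleven living-person stocks partition the catchment population:

| stock | meaning |
|---|---|
| `low_distress` | Kessler-10 10–15 |
| `distressed_not_in_care` | K10 ≥ 16, not seeking/receiving care |
| `waiting_gp`, `waiting_specialist` | queued for an intake |
| `in_gp_care`, `in_specialist_care`, `in_cmhc`, `in_inpatient`, `in_online` | in care |
| `post_discharge` | recently discharged from inpatient care (elevated risk) |
| `disengaged` | dropped out of the service pathway |

plus cumulative event stocks (suicides, self-harm hospitalisations, ED
presentations, GP/specialist/CMHC contacts, inpatient admissions,
disengagements) and four capacity stocks (GP and specialist intake slots
per week, CMHC places per week, inpatient beds). The exact stock list of
the original regional models is not published in machine-readable form;
this set is a minimal reconstruction faithful to the four described
sectors, and every flow equation below is the package's own.

## Sector equations (rates per week)

**Population.** Births enter `low_distress` at `birth_rate ×` total living
population; net migration and background mortality act proportionally on
every person stock. Suicide deaths are removed from their stock of origin,
so the person stocks always sum to the demographically implied population
(closure tested to 10⁻⁶ relative at every step; in practice it holds to
machine precision).

**Psychological distress.** Onset moves `low_distress →
distressed_not_in_care` at `distress_onset_rate`; untreated recovery
returns people at `distress_recovery_untreated`; in-care stocks recover
faster (`distress_recovery_in_care`). Two deliberate asymmetries drive the
congestion mechanics: people stuck in a queue recover at only
`waiting_recovery_factor` (default 0.2) of the untreated rate (waiting is
not care, and active help-seekers are not on a natural-remission
trajectory), and the disengaged recover at `disengaged_recovery_factor`
(default 0.5) of it (a discouraged group). The attempt hazard of queued
and disengaged people is the same as the untreated hazard; harm from
congestion therefore comes from *lost recovery time*, not from an assumed
extra risk premium.

**Services.** Help seeking moves `distressed_not_in_care` into the GP
queue at `help_seeking_rate`, with `direct_online_fraction` going straight
to online care; the disengaged re-seek at a reduced rate
(`reengagement_factor`). GP and specialist intakes are
`min(queue / min_intake_wait, capacity)`. Completed GP episodes (mean
`gp_care_duration`) split by `referral_fractions` into the specialist
queue, CMHC, inpatient, online care, or discharge back to
`distressed_not_in_care`. CMHC and inpatient admissions are capacity
limited (beds / length-of-stay defines inpatient throughput); refused
referrals return to `distressed_not_in_care`. Inpatient discharges enter
`post_discharge`, a first-order stock with mean residence
`postdischarge_window` (26 weeks) from which a fraction recovers.
Expected waiting time is `queue / capacity`, capped at
`max_waiting_time` (52 weeks) so an idle service cannot produce an
infinity. Disengagement from queues rises with waiting time through a
saturating law `disengagement_max_rate · w/(w + waiting_tolerance)`;
in-care patients disengage at `dissatisfaction_rate`. Capacities grow
continuously (exponentially) at their configured yearly rates — the
"business as usual" assumption — rather than stepwise.

**Suicidal behaviour.** Each risk group generates attempts at its hazard:
untreated/queued/disengaged share `attempt_rate_distressed_untreated`,
in-care stocks use the lower `attempt_rate_in_care`, and `post_discharge`
the elevated `attempt_rate_postdischarge`. `case_fatality` of attempts are
suicides (removed from the population);
`hospitalisation_fraction_of_attempts` are counted as self-harm
hospitalisations, and surviving hospitalised attempters are routed into
inpatient care — closing the loop that makes post-attempt aftercare a
meaningful intervention. Mental-health-related ED presentations accrue at
`ed_presentation_rate` per distressed person.

## Interventions

Thirteen interventions are modelled by their *direct* parameter effects
only (multiply / add / replace on dotted parameter paths), switched on at
1 January 2021 with a 13-week linear ramp (one quarter; roll-out dynamics
are not published, so a single default is used). Each effect ramps
individually (`1 + (m−1)·r(t)` for a multiplier `m`) and effects compose
commutatively; all indirect consequences — queue relief, congestion,
altered case mix — emerge from the model structure, which is why combined
effects need not be additive (tested: some pairs deviate from additivity
by more than 1 % of baseline suicides).

Safety planning deserves a note: its direct effect is an attempt-hazard
reduction among ED-presenting distressed people, so its effective reach
scales with the catchment's per-capita ED presentation rate
(`reach = min(1, ed_presentation_rate × safety_planning_reach_scale)`).
This single mechanism reproduces the qualitative finding that the same
intervention is markedly more effective in remote, high-ED-presentation
catchments.

The published material names ten interventions; three catalogue entries
(`gp_capacity`, `online_services`, `ed_aftercare_outreach`) are
reconstructions completing the catalogue to thirteen and are flagged as
such. Default magnitudes are calibrated-to-figure choices: they place
single-intervention reductions on the synthetic state in plausible
published ranges (post-attempt care ≈ 6 %, social connectedness ≈ 4.4 %,
safety planning ≈ 3.7–8.4 % across catchments, awareness campaigns
between +2.8 % and −4.7 %). They are configuration, not estimates, and are
the quantities sampled by the sensitivity analysis.

## Scenario analysis

A scenario's effect in a catchment is the *reduction*: cumulative suicides
over 2021–2031 under business as usual minus the same under the scenario
(negative when harmful). State-level effects are exact sums of
per-catchment reductions. The optimal state combination is found by
exhaustive enumeration of all C(13,4) = 715 and C(13,5) = 1287 subsets,
applied identically in every catchment; the regional planning benefit of a
catchment is its own best subset's reduction minus its reduction under
the state-optimal subset (non-negative by construction), and the
suboptimality count is the number of subsets preventing strictly fewer
suicides than the state-optimal one. Reductions are compared after
rounding to 10⁻⁶ persons, with lexicographic tie-breaking, so optima are
independent of float summation order; "fewer" is strict.

Because no intervention starts before the forecast window, the 2011–2021
segment is shared by all scenarios of a catchment: it is integrated once,
and the window itself is integrated as a single batched state with one
column per subset. Batched and scalar runs agree to machine precision
(tested), and results are independent of execution order.

## Calibration

Free parameters are fitted by minimising the mean absolute per cent error
(MAPE) across all observed (metric, year) points — all points weighted
equally — using Powell's derivative-free direction-set method. Powell's
method is unconstrained, so box bounds are enforced by the smooth
reparameterisation `x = lo + (hi−lo)(sin z + 1)/2`; fitted values can
therefore never leave their bounds. Convergence uses relative
tolerances of 10⁻⁴ (objective and parameters) with a 200-iteration cap;
non-convergence returns the best-so-far point flagged, not an exception.
Catchments are calibrated independently. Parameter recovery is verified
end-to-end: on noise-free synthetic series with three free parameters the
truth is recovered to well under 1 % relative with final MAPE < 0.5 %, and
under 5 % multiplicative observation noise to within 10 %.

## Sensitivity analysis

Uncertainty in intervention direct-effect magnitudes is propagated with a
Latin hypercube design: 100 joint draws, each parameter uniform over
±20 % of its default, exactly one draw per equal-probability stratum per
parameter (scipy's LHS engine, seeded and logged). Only intervention
magnitudes are sampled, so the baseline is computed once per catchment.
Distributions of reductions are summarised by the mean, the 50 % interval
(25th–75th percentile) and the 95 % interval (2.5th–97.5th percentile),
using linear interpolation between order statistics. These intervals
measure sensitivity to the assumed effect sizes; they are **not**
confidence intervals.

## Synthetic state

The regional parameter tables and historical series behind the original
analysis are not available in machine-readable form, so the package
generates a synthetic ten-catchment state spanning the published
heterogeneity: populations in [243 000, 1 570 000]; density classes metro
/ regional / remote with remote catchments given 1.5–2× ED presentation
multipliers, capacity slack 0.70–0.88 and near-zero capacity growth, and
metro catchments slack 1.15–1.40 with faster growth; target mean yearly
suicide rates in [7.61, 12.18] per 10⁵. Service capacities are set to
slack × an analytic steady-demand approximation, so slack < 1 produces a
genuinely congested network. Suicide-risk parameters are calibrated per
catchment by bisection on a joint attempt-rate multiplier until the
baseline run hits the target rate (2 % relative tolerance). Synthetic
"observed" series are model runs under known true parameters with
mean-one multiplicative lognormal noise (keeps values positive, as MAPE
requires). Everything is deterministic given the seed.

What the synthetic state does *not* emulate: age/sex structure, real PHN
geographies or disadvantage distributions, between-catchment interaction,
COVID-era shocks, and the actual calibrated parameter values of any real
region. Consequently the pipeline's headline outputs on synthetic data
(state baseline ≈ 8 700 suicides over 2021–2031; best-4 ≈ 20 %, best-5
≈ 24 % reductions) are scale-compatible with published figures but are
properties of the generator's study conditions, not estimates for New
South Wales. Passing tests establish the mechanics and the qualitative
mechanisms (reach scaling, congestion harm, regional heterogeneity), not
quantitative real-world predictions.

## Problem sizes and runtimes

The default test and acceptance runs use: ten catchments × 20 years at
dt = 1/8 week; full 715 + 1287 subset sweeps per catchment (batched, a
few seconds per catchment); calibration recovery with three free
parameters over a 10-year grid; a 100-draw LHS for one catchment and the
best-4 scenario. A handful of unit tests use 4 steps/week or two-catchment
toys, chosen as the smallest sizes that exercise the relevant mechanism.

## Known limitations

- All functional forms (queue service, disengagement response, recovery
  asymmetries) are reconstructions; alternatives (e.g. different
  disengagement shapes) are configurable but only the defaults are tested.
- Capacity interventions act through growth rates; in this
  parameterisation the binding constraint is usually GP intake, so
  specialist-capacity interventions have small effects everywhere —
  real systems may bind elsewhere.
- MAPE calibration with equal weights can trade off metrics of very
  different magnitude; identifiability beyond the recovery tests is not
  analysed.
- The state optimum assumes one subset applied in all catchments;
  budget-constrained or heuristic portfolio search is out of scope.
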