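# Methods

## The derivation model

The pipeline treats HEMS dispatch as a two-layer sampling process.
Whole-system EMS taskings arrive per AMPDS code as a Poisson stream;
each tasking with code *j* triggers a HEMS dispatch with probability
*p_j* (the code's HEMS-dispatch fraction). A HEMS dispatch with code
*j* achieves patient contact with probability *c_j*, and a contact
produces an HLIDD (HEMS-level intervention/drug/diagnostic, including
helicopter conveyance by default) with probability *h_j*. The
derivation estimates *c_j* and *h_j* from the HEMS stream, *p_j* from
the EMS reference stream, and applies three criteria:

1. **Screen significance.** Codes with ≥ 50 dispatches are compared
   with the pooled remainder in one logistic model per outcome, with
   the code as a categorical predictor. This is equivalent, code by
   code, to the 2×2 cross-product odds ratio against the pool; a code
   is flagged when the two-sided Wald p < 0.05 *and* OR > 1 (the
   question is whether rates are *high*, so significantly low codes
   are never flagged). No multiplicity correction is applied across
   codes; exports carry the raw p-values.
2. **System utility.** A code passes when strictly more than 10% of
   its EMS reference taskings led to a HEMS dispatch. A code's share
   of the HEMS workload is additionally reported as a descriptive
   metric but plays no part in the filter.
3. **Rate thresholds.** At a grid cell (θ_c, θ_h) a flagged,
   utility-passing code is selected when contact rate ≥ θ_c and/or
   HLIDD rate ≥ θ_h (inclusive ≥, strict > for utility — exactly the
   printed conventions). A code with zero contacts has an undefined
   HLIDD rate and fails any θ_h > 0.

Each cell projects the load of dispatching immediately to its codes.
The default basis counts the selected codes' taskings in the EMS
reference stream per day; this is a *projected immediate-dispatch
load*, deliberately larger than the historical HEMS volume on the same
codes, because the policy being evaluated is "send HEMS whenever this
code appears". The historical basis (HEMS dispatches / study days) is
also implemented and selectable. The golden set is the selection of
the highest-threshold cell (largest θ_c + θ_h, ties toward θ_c) whose
projection lands inside the 10–20 taskings/24 h operating target;
when no cell qualifies the derivation raises a structured error rather
than silently choosing a nearest cell.

### Separation and degenerate tables

When a code has a zero cell (all or no successes) the GLM parameter is
unidentified, so the code's estimate falls back to the
Haldane–Anscombe +0.5-corrected 2×2 odds ratio with Woolf CI, and the
significance flag is decided by a one-sided Fisher exact test. A
2×2 table with an empty margin has no defined odds ratio and raises an
error. The screening GLM is fitted with a deviance tolerance of 1e-12
so the saturated model's estimates agree with the closed form to
better than 1e-6 relative error.

## Covariate models

For the busiest AMPDS categories, two logistic models per category
estimate adjusted odds ratios: contact ~ shift + platform + desk
composition, and HLIDD (contact taskings only) ~ the same plus sex and
age bin (<16, 16–55 reference, >55). Reference levels are day,
helicopter, no-CCP desk, female, 16–55. Stand-down taskings have no
patient, so age and sex cannot enter the contact models. Taskings
treating more than one patient are excluded from the age/sex analysis
(their other covariates remain available, but complete-case deletion
removes them from models that include age/sex); missingness is treated
as missing-at-random with listwise deletion, and every exclusion is
counted in the dataset's log.

Model building: an optional univariate pre-screen (on by default)
keeps terms significant alone; backward elimination then removes the
least significant term (whole-term p ≥ 0.05; the age bin is judged by
a 2-df likelihood-ratio test, binary terms by Wald p) and refits until
all retained terms are significant, which terminates in at most one
refit per starting term. Configured pairwise interactions (default:
shift × platform, a plausible operational coupling) are tested among
retained terms by 1-df likelihood-ratio tests and kept when p < 0.05.

Diagnostics on the final model: Cook's distance with the conventional
4/n cutoff for influence, variance inflation factors with a cutoff of
5 for collinearity, and a logit-linearity check that reports "not
applicable" while every covariate is categorical (it would apply only
if a continuous covariate were configured).

## The synthetic generator

The generator exists so every stage can be validated against known
truth without any data access. It emulates:

* **Heavy-tailed code frequencies.** Per-code HEMS rates are lognormal
  weights scaled to an annual budget. The default dispersion σ = 2.0
  comes from a closed-form calibration: for lognormal weights the top
  fraction q of codes carries 1 − Φ(Φ⁻¹(1−q) − σ) of the mass, and
  matching "the top ~12.4% of codes carry ~79% of dispatches" gives
  σ ≈ 1.96.
* **Code-level probabilities.** Background codes draw
  dispatch/contact/HLIDD probabilities from beta laws centred near the
  system-wide marginals (dispatch fraction ~0.06, clipped to
  [0.02, 0.9] so the implied EMS stream stays bounded and estimable;
  contact ~0.58; HLIDD | contact ~0.6). Planted profiles pass through
  exactly as specified.
* **Covariate effects on the log-odds scale** — the same functional
  form the downstream models assume, so planted effects are directly
  recoverable. Default effects are representative of the adjusted ORs
  the per-category models report (night ~0.7 and RRV ~0.75 on contact;
  RRV ~0.5, male ~1.3, age <16 ~0.4, age >55 ~1.2 on HLIDD; desk
  composition null); recovery tests pass explicit effect
  configurations instead.
* **Covariate marginals** from the descriptive table of the source
  system: day share 0.717, helicopter 0.641, desk CCP 0.908, dispatch
  type 0.54/0.24/0.21, male share 0.661, ~7.7% children, adult ages
  approximately normal(49, 21) truncated to [16, 99] to mimic the
  attended-patient age distribution.
* **Imperfections**: ~9.7% of dispatches lose their code (masked
  completely at random, matching the ~90.3% coded fraction), ~0.5–0.6%
  missing age/sex, ~6% of contact taskings treat two patients, and a
  small transgender share (recorded descriptively, missing in models).
  Intervention sets are decorated onto the planted HLIDD flag with the
  source system's frequency weights, never assigning helicopter
  conveyance on RRV taskings, so the derived classification always
  reproduces the planted flag.

Platform is independent of shift by default; an optional
helicopter-share-by-shift conditional is exposed because real systems
shift to road vehicles at night, but no default coupling is assumed.

The nine default planted golden profiles use a HEMS-dispatch fraction
of 0.25 (clear of the 0.10 bar) and baseline contact/HLIDD
probabilities of 0.90. The default covariate effects pull the marginal
rates down to ≈ 0.88, which still clears the 0.8 grid cell — the cell
the highest-within-target policy typically makes operative — with
margin; at ~640 EMS taskings/year each, the planted set's projected
load sits mid-target at ≈ 16/day.

### What passing tests do and do not show

The generator's outcomes really are conditionally independent
Bernoulli draws on the logistic scale, frequencies really are
lognormal, and missingness really is completely at random. Real
dispatch data violate all three in unknown ways (code drift over
years, informative missingness, within-incident correlation,
platform–shift coupling). Recovery results therefore demonstrate that
the pipeline is correct and well-calibrated *under its own model*, not
that the model is true of any particular EMS system.

## Problem sizes and numerical choices

The test suite exercises the derivation at a 200-code / ~6,000
dispatches-per-year / four-year scale (about a quarter of the full
universe's codes, full per-code depth for the planted profiles), with
100-seed loops for the end-to-end and covariate recovery properties;
the acceptance script runs the full 678-code scale once plus 20
lighter replicates. These sizes give per-code counts comparable to the
real study's eligible codes while keeping a complete run in the low
minutes on one core.

Ties and edge rules, fixed once and used everywhere: the day shift is
the half-open window [07:00, 19:00); eligibility is inclusive
(≥ 50 dispatches); rate thresholds are inclusive, the utility
threshold strict; percentages round half-up to one decimal; grid
policy ties break toward the higher contact threshold; suffixed AMPDS
codes are distinct codes; records without a parseable code are
excluded from analysis but retained and counted in the attrition log.

## Known limitations

* Under-triage is unobservable by construction: the data only contain
  taskings HEMS was dispatched to, so the pipeline can bound
  over-triage (the contact-branch threshold caps the pooled stand-down
  rate at 1 − θ_c plus sampling noise) but can say nothing about
  HEMS-appropriate calls that never received a dispatch.
* The screens are unadjusted by design; covariate effects live in the
  per-category models and do not feed back into code selection.
* Backward elimination inherits the usual instability of stepwise
  selection at small n; the per-category minimum row count (default
  50) refuses clearly under-powered fits but is no cure.
* Very rare but operationally critical codes (mass-casualty, automatic
  crash notification) fall below the 50-dispatch eligibility bar and
  are out of scope of this derivation by design.
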