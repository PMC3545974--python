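# Methods

This note records the modelling assumptions, parameter conventions, and
numerical choices behind `osteosim`, including the points where the model
structure was genuinely open and a choice had to be made.

## Model structure

The model is an individual-level (first-order Monte Carlo) state-transition
simulation with a 6-month cycle. Each patient carries age, gender, a fixed
measured BMD T-score, disease class (PMO or GIOP), treatment arm and
persistence status, and a time-stamped fracture history. Three fracture
sites are modelled — hip, clinical vertebral, wrist — because they
dominate osteoporosis burden and have usable efficacy, cost, and utility
data; other sites are ignored.

Within a cycle, events resolve in a fixed order: (1) fracture-excess death,
(2) fracture draws per site in hip/vertebral/wrist order, (3) natural
death, (4) discontinuation update at the cycle boundary, (5) accrual.
Only the timing convention is externally fixed (excess deaths at the cycle
start, natural deaths at mid-cycle); the rest of the order is this
package's choice and is what the scripted-draw audit tests pin down.

Accrual fractions follow the death timing: 1 for a survived cycle, 0.5 for
a natural death, 0 for an excess death. The fraction applies uniformly to
drug, monitoring, and continuing fracture costs and to utility; the acute
cost of a fracture in a death cycle accrues in full, because the fracture
draw precedes the natural-death draw in event order. Undiscounted life
years accrue as 0.5 x fraction per cycle.

## Fracture hazards

Baseline annual first-fracture probabilities are tabulated for women at
age-band midpoints (the 50–54 value belongs to age 52) and interpolated
linearly in age, clamped to the end values outside the table. Male rates
are imputed by multiplying the female rates by male:female incidence
ratios, capped at 1.

Annual probabilities convert to 6-month probabilities by the
complement-power rule p6 = 1 − (1 − p)^(1/2), which is exact under a
constant hazard and keeps probabilities in [0, 1]; simple halving is
available via `hazard_composition="rate"`. Multipliers then compose on the
6-month probability scale with a hard cap at 1. Composing on the rate
scale instead would change results only where the product approaches 1.

The BMD multiplier is g^(T_mean(age) − T_measured), with g the relative
risk per SD of bone density and T_mean the age- and gender-specific
population mean T-score. The exponential-in-SD form is the standard
gradient-of-risk parameterisation; the per-site gradients in the default
bundle (hip 2.6, vertebral 1.8, wrist 1.4) are placeholder values at
field-typical magnitudes.

Fracture history raises risk for 5 years after each event (configurable
window; the boundary cycle is included, so a fracture exactly 5 years old
still counts in the cycle where its age reaches the window). One in-window
fracture of a site with relative risk r contributes r; a second in-window
fracture of the same site contributes 1 + (1+s)(r−1), with the
second-fracture increase s = 1.0 for PMO and 0.5 for GIOP; third and later
same-site fractures reuse the second-fracture multiplier (a choice — the
sources are silent beyond the second). Across sites the largest multiplier
applies, not the product.

## Treatment

Both active arms treat for 18 months (3 cycles). Efficacy is a relative
risk on the fracture hazard: constant while on drug; after cessation a
sustained phase (teriparatide: vertebral RR 0.43 for 18 months,
non-vertebral RR 0.73 for 30 months) followed by a linear return to 1 over
18 months. Bisphosphonate efficacy ramps linearly from its on-treatment
value to 1 over 18 months with no sustained plateau, which makes the
mid-ramp RR (1 + RR_on)/2. After early discontinuation the same
post-treatment timeline is anchored at the cessation cycle, with no
proportional scaling by time on drug — the defensible alternative
(scaling the sustained period by exposure) is not implemented.

Persistence curves give the probability of still being on drug at each
treated-cycle boundary; the engine draws the conditional
continue-probability curve[k]/curve[k−1] at the end of each treated cycle.
A patient who discontinues at the boundary of cycle k pays drug and
monitoring for cycles before k only. The untreated arm accrues no visit or
monitoring costs (a choice; monitoring of untreated patients is not
modelled).

Drug cost per treated cycle is the daily price times 182.625 days
(365.25/2, configurable as `days_per_cycle`); results are insensitive to
the exact day count at below the 0.3% level for the teriparatide arm.
Monitoring visits charge the BMD-inclusive price (201 EUR) in odd treated
cycles and the basic price (194 EUR) otherwise, giving the published
201/194/201 pattern over an adherent course.

## Mortality

Natural mortality is q(age, gender) x (1 − p_fx(age, gender)), the
life-table probability with the fracture-attributable proportion of deaths
removed to avoid double counting. Excess mortality applies only after hip
and vertebral fractures: the base fracture-death probability for the
patient's age and gender times (m − 1), where m is read from a
year-since-fracture schedule (2.5 in year 1, linear to 1.0 at year 7 for
hip and year 6 for vertebral) and the larger of the hip/vertebral
multipliers wins. Elapsed time maps to schedule years as
year = ceil(cycles/2), so the two cycles after an event are year 1. The
base fracture-mortality series is a separate table (0.007 for a 65-year-old
man to 0.0375 for a 90+ woman at its anchors) rather than a multiplier on
all-cause mortality — the source wiring is terse, and this reading keeps
excess mortality additive and bounded.

Ages advance 0.5 years per cycle; all lookups use the age at cycle start.
The horizon is a lifetime proxy capped at age 100 (configurable).

## Costs

Fracture costs split into an acute 6-month cost and a continuing per-cycle
cost that persists for life. Wrist fractures have no continuing cost.
Repeat fractures of a site pay their acute cost and then the *maximum* of
the old and new continuing cost (supersession): long-term care is never
double-counted, dearer old entitlements are never lost. Continuing costs
of fractures that predate the model start (the cohort's historical and
incident vertebral fractures) are seeded into the continuing-cost map at
the cost level of the age at which they occurred. Vertebral continuing
costs (analgesics) run through the same map as hip (nursing-home) costs.

Discounting is 3%/year on both costs and effects, applied per cycle as
(1.03)^(−k/2) at the cycle start; no mid-cycle discounting refinement.

## Utilities

Cycle utility is base(age) times one multiplier per fractured site. The
"first year" of a fracture is its event cycle plus the next cycle; the
subsequent multiplier then applies for life (fracture disutilities do not
expire with the 5-year risk window). Pre-start fractures enter at their
subsequent multiplier, except that the incident fracture 6 months before
start is still in the second cycle of its first year at model start.

For a repeat fracture of the same site the first-year multiplier combines
with a proportion q = 0.25 of the previous fracture's subsequent
disutility. The printed rule is ambiguous; the default reading multiplies
factors, m_first x (1 − q(1 − m_sub)), and a literal additive reading,
1 − [(1 − m_first) + q(1 − m_sub)], is available as
`repeat_rule="literal"`. The two differ by under 1% for the default
multipliers.

## Engine and random numbers

Arms are compared under common random numbers: each patient's uniforms
(six per cycle — excess death, three fracture sites, natural death,
discontinuation — drawn for every cycle regardless of which are consumed)
are replayed identically across arms, so arm differences flow only through
treatment-dependent quantities. Patients are drawn in fixed blocks of
4,096 from generators seeded by (seed, replication, block), making runs
bit-identical for a seed and independent of the requested cohort size.
Gender is a Bernoulli draw per patient from the cohort's female fraction
(80% for GIOP, 100% for PMO); exact stratification is not implemented.

Replication-level means feed normal-approximation 95% confidence
intervals; ICER intervals come from percentiles of per-replication
incremental ratios.

## Sensitivity analyses

One-way analyses rerun the paired comparison with a single parameter at a
low and a high value under the same seeds and report both ICERs, sorted by
range. Parameters are addressed by dotted paths into the bundle
(e.g. `efficacy.teriparatide.vertebral.sustained_months`).

The PSA samples fracture costs as mean-1 lognormal scale factors per site
(sigma = ln 4 / (2 x 1.96), so the central 95% of mass spans 0.5x–2x;
rejection-truncated to that support, which biases the mean by well under
1%), and disutilities and teriparatide efficacy RRs as beta variables
rescaled to their stated ranges with mean at baseline and SD set to a
quarter of the range (shrunk near the edges to keep the distribution
proper). Sampled first-year utility multipliers are clamped to stay at or
below the subsequent multiplier. Each simulation runs both arms once under
common random numbers — a variance-reduction choice; the sources do not
say whether the original analysis did this.

The acceptability curve's primary definition is the share of simulations
whose cost per QALY is below the threshold, counting dominant draws as
acceptable and dominated draws as not — this matches the published curve
construction even though it treats the (rare) cheaper-and-worse quadrant
unconventionally; the textbook net-monetary-benefit rule is available via
`method="nmb"`.

## Synthetic default tables

The packaged bundle's age-resolved tables are placeholders built by a
monotone interpolator (PCHIP through coarse anchors, optional seeded
jitter, anchor values reproduced exactly) because the original appendix
tables are not available in the body text. Anchors were chosen once at
field-plausible levels: hip incidence rising steeply with age to ~3%/year
at 90+, a Gompertz life table calibrated to modern Swedish levels,
nursing-home-driven hip continuing costs rising with age, persistence
around 83% (teriparatide) and 55% (bisphosphonate) at the last treated
cycle. They emulate the *structure* of the real inputs (monotone age
trends, right orders of magnitude, correct zero patterns) but not their
values; passing tests therefore demonstrate correct model mechanics,
invariance properties, and exact reproduction of the printed unit costs
and worked examples — not reproduction of published cohort-level results,
which requires a complete user-supplied bundle.

## Problem sizes

The published base case used 200 replications of 100,000 patients and a
PSA of 1,000 simulations of 1,000 patients. The package defaults and the
acceptance script use scaled-down sizes chosen as a practical desk scale:
10 x 10,000 for the base case (Monte Carlo standard errors on mean costs
and QALYs of order 0.3%) and 200 x 500 for the PSA. Full-scale runs are a
matter of raising the arguments.

## Known limitations

- Placeholder tables, as above; all flagged in `ParameterSet.provenance`.
- No side-effect costs or disutilities, no societal costs, no CPI
  machinery (inputs are taken as already inflated).
- No FRAX-style risk integration; no fracture sites beyond
  hip/vertebral/wrist; no cause-of-death attribution beyond the
  natural/excess split.
- Gender is sampled, not stratified, so small-cohort GIOP runs carry
  binomial noise in the gender mix.
- The engine is single-threaded; large runs scale linearly in
  patients x replications x arms (roughly 80 microseconds per
  patient-arm-lifetime on commodity hardware).
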