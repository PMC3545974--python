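# osteosim

Patient-level Monte Carlo microsimulation of osteoporosis treatment
cost-effectiveness in Sweden: teriparatide versus oral bisphosphonate versus
no treatment, for severe postmenopausal osteoporosis (PMO) and
glucocorticoid-induced osteoporosis (GIOP) cohorts.

The package is written for health economists and modellers who need a
transparent, fully parameterised re-implementation of this class of model:
every input (fracture risks, treatment efficacy timelines, persistence
curves, mortality, costs, utilities) is an auditable table or scalar in a
`ParameterSet`, and every simulated patient can be dumped as a
cycle-by-cycle ledger.

## The model

Patients advance in 6-month cycles from a cohort start age (69 years) until
death or age 100. In each cycle a patient faces, in order: a
fracture-excess death risk (deaths at the cycle start), fracture risks for
hip, clinical vertebral, and wrist sites, a natural death risk (deaths at
mid-cycle), and a treatment-discontinuation draw at the cycle boundary.

The per-cycle fracture probability for site *f* is

> p = p6(age, gender, f) x g_f^(T_mean(age) - T) x RR_hist x RR_GIOP x RR_rx

where p6 is the 6-month baseline first-fracture probability
(1 - (1 - p_annual)^(1/2)), g_f is the relative risk per SD of bone
density below the age mean, RR_hist is the fracture-history multiplier
(largest across sites; a second in-window fracture of the same site
contributes 1 + (1+s)(r-1) with s = 1.0 for PMO and 0.5 for GIOP), RR_GIOP
the glucocorticoid loading, and RR_rx the arm's efficacy timeline value
(constant on treatment, sustained after cessation, then a linear return to
1). The product is capped at 1.

Natural mortality is the life-table probability with the
fracture-attributable share of deaths removed; hip and vertebral fractures
add excess mortality through year-indexed multipliers (2.5 in year 1,
phasing out to 1 over 7 and 6 years respectively; the larger applies).

Utility in a cycle is the age-interpolated base utility times one
multiplicative multiplier per fractured site (first-year multiplier for two
cycles, subsequent multiplier for life; repeat fractures fold in 25% of the
prior subsequent disutility). Costs cover drug acquisition, monitoring
visits (BMD-inclusive in treated cycles 1 and 3, basic in cycle 2), acute
fracture costs, and lifelong continuing costs with a supersession rule that
prevents double-counting of long-term care. Costs and QALYs are discounted
at 3% per year; arms are compared under common random numbers.

Incremental results are reported as ICERs (with dominance labels),
fractures avoided per 1,000 patients, and incremental life years;
uncertainty via one-way sensitivity analyses (tornado tables) and
probabilistic sensitivity analysis (lognormal fracture costs, beta
disutilities and efficacy relative risks) with cost-effectiveness
acceptability curves.

## Parameter provenance

The packaged default bundle reproduces every unit cost and scalar printed
in the source cost study (teriparatide 14.74 EUR/day from 3,728.50 SEK per
28 injections at 9.0335 SEK/EUR, alendronate 0.42 EUR/day, monitoring
visits 201 and 194 EUR, 3% discounting, 18-month treatment). Age-resolved
tables published only in that study's supplementary appendix (baseline
risks, male/female ratios, GIOP relative risks, mean T-score by age,
age-banded fracture costs, persistence curves, bisphosphonate efficacy) are
shipped as clearly flagged, structurally faithful **placeholders**; any
result computed from them carries `uses_placeholder_tables: true` in its
metadata, and published cohort-level numbers are not expected to be
reproduced until a complete bundle is supplied via `--params`.

## Worked example

```python
from osteosim import (COHORTS, default_parameter_set, run_cohort, icer,
                      fractures_avoided_per_1000)

params = default_parameter_set()
res = run_cohort(COHORTS["pmo_2fx"], params, n_patients=10_000,
                 n_replications=4, seed=1)
for arm, s in res.arms.items():
    print(f"{arm:15s} cost €{s.mean_cost:8.0f}  QALY {s.mean_qaly:.3f}  "
          f"LY {s.mean_life_years:.2f}")
ce = icer(res.arms["teriparatide"], res.arms["bisphosphonate"])
print("ICER:", round(ce.icer), "€/QALY")
```

prints (placeholder bundle, seed 1):

```
teriparatide    cost €   23676  QALY 7.584  LY 17.29
bisphosphonate  cost €   17956  QALY 7.517  LY 17.22
none            cost €   18542  QALY 7.488  LY 17.20
ICER: 85682 €/QALY
```

Teriparatide costs more (18 months at 14.74 EUR/day plus monitoring) but
avoids fractures — 39 hip, 76 vertebral, and 32 wrist fractures per 1,000
patients against no treatment in this run — which buys QALYs and life years
(94 per 1,000 patients); the ICER divides the discounted incremental cost
by the discounted incremental QALYs.

The same run from the shell:

```bash
osteosim run --cohort pmo_2fx -n 10000 -r 4 -s 1 --out out/
osteosim psa --cohort pmo_2fx --sims 1000 -n 1000 --out psa/
osteosim sa  --cohort pmo_2fx --variations variations.csv --out sa/
osteosim export-params --out my_bundle/   # edit, then pass --params my_bundle
```

## Layout

- `src/osteosim/parameters.py` — domain types, validation, bundle I/O,
  placeholder generation; `data/default/` is the packaged bundle
- `src/osteosim/fracture_model.py` — per-cycle fracture hazards
- `src/osteosim/survival_model.py` — natural and excess mortality, timing
- `src/osteosim/economics.py` — cost accrual and discounting
- `src/osteosim/utility_model.py` — utilities and QALYs
- `src/osteosim/engine.py` — the Monte Carlo engine
- `src/osteosim/analysis.py` — ICERs, sensitivity analyses, acceptability
- `src/osteosim/cli.py` — the `osteosim` command
- `docs/methods.md` — modelling assumptions and numerical choices
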