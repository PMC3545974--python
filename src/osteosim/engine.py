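"""Patient-level Monte Carlo simulation.

Each simulated patient advances in 6-month cycles from the cohort start age
until death or age 100.  Within a cycle, events resolve in a fixed order:

1. fracture-excess death draw (deaths at the cycle start, nothing accrues);
2. fracture draws per site (hip, vertebral, wrist);
3. natural death draw (deaths at mid-cycle, half the cycle accrues);
4. treatment-discontinuation update at the cycle boundary;
5. cost and utility accrual at the cycle's accrual fraction (acute fracture
   costs accrue in full — the fracture precedes any mid-cycle death).

Arms are compared under common random numbers: every arm of a patient
replays the same uniform draws, so arms differ only through
treatment-dependent quantities.  Draw streams are deterministic for a given
seed, replication and patient block, independent of the number of patients
requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .economics import CycleLedger
from .fracture_model import FractureEvent, treatment_rr
from .parameters import (
    ARMS,
    FRACTURE_TYPES,
    CohortSpec,
    FractureType,
    ParameterSet,
)
from .utility_model import repeat_first_year_multiplier

_HIP, _VERT, _WRIST = 0, 1, 2
_DRAWS_PER_CYCLE = 6  # excess death, 3 fracture sites, natural death, discontinuation
_PATIENT_BLOCK = 4096  # patients per RNG block; fixed so streams are size-independent


@dataclass
class PatientState:
    """Evolving state of one simulated patient (reference/audit API)."""

    age: float
    gender: str
    t_score: float
    disease: str
    arm: str
    alive: bool = True
    on_treatment: bool = True
    cycles_treated: int = 0
    cessation_cycle: int | None = None
    history: list[FractureEvent] = field(default_factory=list)
    continuing_costs: dict[FractureType, float] = field(default_factory=dict)


@dataclass
class PatientRun:
    """Output of one simulated patient life."""

    ledgers: list[CycleLedger]
    fracture_counts: dict[FractureType, int]
    events: list[FractureEvent]
    gender: str
    cessation_cycle: int


@dataclass
class ArmSummary:
    """Per-arm cohort means with replication-level detail."""

    arm: str
    n_patients: int
    n_replications: int
    mean_cost: float
    mean_qaly: float
    mean_life_years: float
    mean_fractures: dict[FractureType, float]
    rep_cost: np.ndarray
    rep_qaly: np.ndarray
    rep_life_years: np.ndarray
    rep_fractures: np.ndarray  # (replications, 3) in hip/vertebral/wrist order

    def ci_halfwidth(self, which: str = "cost") -> float:
        """Normal-approximation 95% CI half-width from the replication means."""
        series = {"cost": self.rep_cost, "qaly": self.rep_qaly, "life_years": self.rep_life_years}[
            which
        ]
        if len(series) < 2:
            return float("nan")
        return 1.96 * float(np.std(series, ddof=1)) / math.sqrt(len(series))


@dataclass
class CohortResult:
    """All arm summaries for one cohort run, plus run metadata."""

    cohort: str
    arms: dict[str, ArmSummary]
    metadata: dict


# ---------------------------------------------------------------------------
# compiled model context
# ---------------------------------------------------------------------------


class ModelContext:
    """Cycle-indexed lookup tables compiled from (CohortSpec, ParameterSet).

    All age-dependent quantities are pre-evaluated on the cycle grid
    (age = start_age + 0.5 k) so the inner simulation loop does no
    interpolation.
    """

    def __init__(self, spec: CohortSpec, params: ParameterSet):
        spec.validate()
        self.spec = spec
        self.params = params
        C = int(round((spec.age_cap - spec.start_age) * 2))
        self.n_cycles = C
        ages = spec.start_age + 0.5 * np.arange(C)
        self.treat_cycles = params.treatment_cycles
        window = params.history_window_cycles
        self.window = window

        genders = ("female", "male")
        self.static_hazard = []  # [gender][site][cycle]
        self.q_nat = []
        self.fxmort = []
        self.base_util = []
        for g in genders:
            per_site = []
            t_mean = params.mean_t_score[g].at(ages)
            for ft in FRACTURE_TYPES:
                p_ann = np.clip(params.risk_table.get(g, ft).at(ages), 0.0, 1.0)
                if params.hazard_composition == "rate":
                    p6 = p_ann / 2.0
                else:
                    p6 = 1.0 - np.sqrt(1.0 - p_ann)
                m_bmd = params.bmd_gradient[ft] ** (t_mean - spec.t_score)
                m_giop = params.giop_rr[ft].at(ages) if spec.disease == "GIOP" else 1.0
                per_site.append((p6 * m_bmd * m_giop).tolist())
            self.static_hazard.append(per_site)
            q = params.mortality.life_q6[g].at(ages)
            pfx = params.mortality.fracture_death_proportion[g].at(ages)
            self.q_nat.append((q * (1.0 - pfx)).tolist())
            self.fxmort.append(params.mortality.fracture_mortality[g].at(ages).tolist())
            self.base_util.append(params.utility.base_series(g).at(ages).tolist())

        self.acute = [params.cost_table.acute[ft].at(ages).tolist() for ft in FRACTURE_TYPES]
        self.cont = [params.cost_table.continuing[ft].at(ages).tolist() for ft in FRACTURE_TYPES]

        # excess-mortality multiplier by elapsed cycles since a fracture
        self.excess_by_elapsed = []
        for ft in (FractureType.HIP, FractureType.VERTEBRAL):
            sched = params.mortality.excess_schedule[ft]
            by_d = [1.0]  # d = 0 unused (event this cycle has no effect yet)
            for d in range(1, 2 * len(sched) + 1):
                year = (d + 1) // 2
                by_d.append(float(sched[year - 1]) if year <= len(sched) else 1.0)
            self.excess_by_elapsed.append(by_d)

        # treatment RR by (arm, cessation cycle, site, cycle)
        cl = params.cycle_length_months
        self.rr = {}
        for arm in ("teriparatide", "bisphosphonate"):
            profile = params.efficacy[arm]
            per_cess = [None]
            for cess in range(1, self.treat_cycles + 1):
                per_site = []
                for ft in FRACTURE_TYPES:
                    per_site.append(
                        [treatment_rr(arm, ft, k * cl, cess * cl, profile) for k in range(C)]
                    )
                per_cess.append(per_site)
            self.rr[arm] = per_cess
        self.rr["none"] = None

        # conditional probability of continuing into treated cycle j (0-based)
        self.disc_cond = {}
        for arm in ("teriparatide", "bisphosphonate"):
            curve = np.asarray(params.discontinuation.remaining[arm], dtype=float)
            cond = [1.0]
            for j in range(1, self.treat_cycles):
                cond.append(float(curve[j] / curve[j - 1]) if curve[j - 1] > 0 else 0.0)
            self.disc_cond[arm] = cond
        self.disc_cond["none"] = [1.0] * self.treat_cycles

        self.drug_per_cycle = {
            arm: params.cost_table.drug_daily[arm] * params.cost_table.days_per_cycle
            for arm in ARMS
        }
        self.visit_bmd = params.cost_table.visit_bmd_eur
        self.visit_basic = params.cost_table.visit_basic_eur

        self.df_cost = [(1.0 + params.discount_rate_costs) ** (-0.5 * k) for k in range(C)]
        self.df_eff = [(1.0 + params.discount_rate_effects) ** (-0.5 * k) for k in range(C)]

        self.faf_rr = [params.fracture_after_fracture_rr[ft] for ft in FRACTURE_TYPES]
        self.s_second = params.second_fracture_increase[spec.disease]
        ut = params.utility
        self.m_first = [ut.first_year[ft] for ft in FRACTURE_TYPES]
        self.m_sub = [ut.subsequent[ft] for ft in FRACTURE_TYPES]
        self.m_first_repeat = [
            repeat_first_year_multiplier(self.m_first[i], self.m_sub[i], ut.repeat_q, ut.repeat_rule)
            for i in range(3)
        ]

        # pre-start fracture history: (site index, cycle index <= -1)
        self.init_events: list[tuple[int, int]] = []
        ft_index = {ft: i for i, ft in enumerate(FRACTURE_TYPES)}
        for ftype, months in spec.history:
            cyc = -max(1, int(round(months / cl)))
            self.init_events.append((ft_index[ftype], cyc))
        self.init_events.sort(key=lambda e: e[1])
        # continuing costs of pre-start fractures persist into the model
        self.init_cont: dict[int, float] = {}
        for t, cyc in self.init_events:
            age_at = spec.start_age + 0.5 * cyc
            c = float(params.cost_table.continuing[FRACTURE_TYPES[t]].at(age_at))
            if c > 0.0:
                self.init_cont[t] = max(self.init_cont.get(t, 0.0), c)


# ---------------------------------------------------------------------------
# single-patient simulation
# ---------------------------------------------------------------------------


def _simulate(
    ctx: ModelContext,
    arm: str,
    gender_idx: int,
    uniforms,
    collect_ledger: bool = False,
):
    """Simulate one patient life for one arm from a (cycles, 6) draw matrix.

    Returns (discounted cost, discounted QALYs, undiscounted life years,
    fracture counts per site, ledgers or None, events, cessation cycle).
    """
    C = ctx.n_cycles
    hazards = ctx.static_hazard[gender_idx]
    q_nat = ctx.q_nat[gender_idx]
    fxmort = ctx.fxmort[gender_idx]
    base_util = ctx.base_util[gender_idx]
    rr_arm = ctx.rr[arm]
    disc_cond = ctx.disc_cond[arm]
    drug_cycle = ctx.drug_per_cycle[arm]
    treat_cycles = ctx.treat_cycles
    window = ctx.window
    excess = ctx.excess_by_elapsed
    faf = ctx.faf_rr
    s2 = ctx.s_second
    m_first, m_sub, m_first_rep = ctx.m_first, ctx.m_sub, ctx.m_first_repeat

    # per-site event cycle lists (pre-start history included)
    ev_cycles: list[list[int]] = [[], [], []]
    for t, cyc in ctx.init_events:
        ev_cycles[t].append(cyc)
    cont_map: dict[int, float] = dict(ctx.init_cont)

    cessation = treat_cycles  # first untreated cycle; may shrink on discontinuation
    cost = 0.0
    qaly = 0.0
    life_years = 0.0
    counts = [0, 0, 0]
    ledgers: list[CycleLedger] | None = [] if collect_ledger else None

    for k in range(C):
        u = uniforms[k]

        # 1. excess fracture mortality at cycle start
        mult = 1.0
        for t in (0, 1):
            by_d = excess[t]
            n_by_d = len(by_d)
            for e in ev_cycles[t]:
                d = k - e
                if 1 <= d < n_by_d:
                    m = by_d[d]
                    if m > mult:
                        mult = m
        if mult > 1.0 and u[0] < fxmort[k] * (mult - 1.0):
            if collect_ledger:
                ledgers.append(CycleLedger(cycle_index=k, accrual_fraction=0.0))
            break

        # 2. fracture draws
        hist_mult = 1.0
        for t in (0, 1, 2):
            n_in = 0
            for e in ev_cycles[t]:
                if 1 <= k - e <= window:
                    n_in += 1
            if n_in:
                r = faf[t]
                m = r if n_in == 1 else 1.0 + (1.0 + s2) * (r - 1.0)
                if m > hist_mult:
                    hist_mult = m
        on_treat = k < cessation
        new_types = []
        acute_cost = 0.0
        for t in (0, 1, 2):
            p = hazards[t][k] * hist_mult
            if rr_arm is not None:
                p *= rr_arm[cessation][t][k]
            if p > 1.0:
                p = 1.0
            if u[1 + t] < p:
                ev_cycles[t].append(k)
                counts[t] += 1
                new_types.append(t)
                acute_cost += ctx.acute[t][k]
                c = ctx.cont[t][k]
                if c > 0.0:
                    prev = cont_map.get(t, 0.0)
                    if c > prev:
                        cont_map[t] = c

        # 3. natural mortality at mid-cycle
        died = u[4] < q_nat[k]
        af = 0.5 if died else 1.0

        # 4. discontinuation at the cycle boundary (affects next cycle)
        if not died and on_treat and k + 1 < cessation:
            if u[5] >= disc_cond[k + 1]:
                cessation = k + 1

        # 5. accrual
        drug = drug_cycle if on_treat else 0.0
        if on_treat:
            monitoring = ctx.visit_bmd if (k + 1) % 2 == 1 else ctx.visit_basic
        else:
            monitoring = 0.0
        cont_cost = 0.0
        for t, c in cont_map.items():
            if t not in new_types:
                cont_cost += c
        u_val = base_util[k]
        for t in (0, 1, 2):
            evs = ev_cycles[t]
            if not evs:
                continue
            last = evs[-1]
            if k - last <= 1:
                u_val *= m_first_rep[t] if len(evs) >= 2 else m_first[t]
            else:
                u_val *= m_sub[t]

        cycle_cost = (drug + monitoring + cont_cost) * af + acute_cost
        cost += cycle_cost * ctx.df_cost[k]
        qaly += u_val * 0.5 * af * ctx.df_eff[k]
        life_years += 0.5 * af
        if collect_ledger:
            ledgers.append(
                CycleLedger(
                    cycle_index=k,
                    cost_drug=drug * af,
                    cost_monitoring=monitoring * af,
                    cost_fracture_acute=acute_cost,
                    cost_fracture_continuing=cont_cost * af,
                    utility=u_val,
                    accrual_fraction=af,
                )
            )
        if died:
            break

    events = [
        FractureEvent(FRACTURE_TYPES[t], c) for t in (0, 1, 2) for c in ev_cycles[t]
    ]
    events.sort(key=lambda e: e.cycle_index)
    return cost, qaly, life_years, counts, ledgers, events, cessation


def simulate_patient(
    spec: CohortSpec,
    arm: str,
    params: ParameterSet,
    rng,
    gender: str | None = None,
    context: ModelContext | None = None,
) -> PatientRun:
    """Simulate one patient and return the full cycle ledger.

    ``rng`` must provide ``random(size)``; a scripted sequence of uniforms
    can be injected for draw-by-draw audits.  When ``gender`` is None it is
    drawn from the cohort's female fraction (consuming one uniform first, so
    arms sharing a stream agree on gender).
    """
    ctx = context or ModelContext(spec, params)
    if gender is None:
        gender = "female" if float(rng.random()) < spec.female_fraction else "male"
    g_idx = 0 if gender == "female" else 1
    U = np.asarray(rng.random((ctx.n_cycles, _DRAWS_PER_CYCLE)))
    cost, qaly, ly, counts, ledgers, events, cess = _simulate(
        ctx, arm, g_idx, U, collect_ledger=True
    )
    return PatientRun(
        ledgers=ledgers,
        fracture_counts={ft: counts[i] for i, ft in enumerate(FRACTURE_TYPES)},
        events=events,
        gender=gender,
        cessation_cycle=cess,
    )


# ---------------------------------------------------------------------------
# cohort runs
# ---------------------------------------------------------------------------


def run_cohort(
    spec: CohortSpec,
    params: ParameterSet,
    n_patients: int,
    n_replications: int,
    seed: int,
    arms: Sequence[str] | None = None,
) -> CohortResult:
    """Run the cohort for every arm under common random numbers.

    Patients are drawn in fixed-size blocks seeded by (seed, replication,
    block), so results are bit-identical for a fixed seed and every arm of a
    given patient replays the same uniforms.
    """
    if n_patients < 1 or n_replications < 1:
        raise ValueError("n_patients and n_replications must be >= 1")
    arms = tuple(arms) if arms is not None else spec.arms
    ctx = ModelContext(spec, params)
    C = ctx.n_cycles
    n_arms = len(arms)

    rep_cost = np.zeros((n_replications, n_arms))
    rep_qaly = np.zeros((n_replications, n_arms))
    rep_ly = np.zeros((n_replications, n_arms))
    rep_fx = np.zeros((n_replications, n_arms, 3))

    for r in range(n_replications):
        done = 0
        block = 0
        while done < n_patients:
            n_block = min(_PATIENT_BLOCK, n_patients - done)
            rng = np.random.default_rng([seed, r, block])
            genders = (rng.random(n_block) >= spec.female_fraction).astype(np.int64)
            U_all = rng.random((n_block, C, _DRAWS_PER_CYCLE))
            for i in range(n_block):
                U = U_all[i]
                g = int(genders[i])
                for a, arm in enumerate(arms):
                    cost, qaly, ly, counts, _, _, _ = _simulate(ctx, arm, g, U)
                    rep_cost[r, a] += cost
                    rep_qaly[r, a] += qaly
                    rep_ly[r, a] += ly
                    rep_fx[r, a, 0] += counts[0]
                    rep_fx[r, a, 1] += counts[1]
                    rep_fx[r, a, 2] += counts[2]
            done += n_block
            block += 1
    rep_cost /= n_patients
    rep_qaly /= n_patients
    rep_ly /= n_patients
    rep_fx /= n_patients

    summaries = {}
    for a, arm in enumerate(arms):
        summaries[arm] = ArmSummary(
            arm=arm,
            n_patients=n_patients * n_replications,
            n_replications=n_replications,
            mean_cost=float(rep_cost[:, a].mean()),
            mean_qaly=float(rep_qaly[:, a].mean()),
            mean_life_years=float(rep_ly[:, a].mean()),
            mean_fractures={
                ft: float(rep_fx[:, a, i].mean()) for i, ft in enumerate(FRACTURE_TYPES)
            },
            rep_cost=rep_cost[:, a].copy(),
            rep_qaly=rep_qaly[:, a].copy(),
            rep_life_years=rep_ly[:, a].copy(),
            rep_fractures=rep_fx[:, a, :].copy(),
        )
    metadata = {
        "cohort": spec.name,
        "seed": seed,
        "n_patients": n_patients,
        "n_replications": n_replications,
        "arms": list(arms),
        "uses_placeholder_tables": params.has_placeholders(),
        "placeholder_tables": params.placeholder_tables(),
    }
    return CohortResult(cohort=spec.name, arms=summaries, metadata=metadata)
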