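"""Monte Carlo engine: scripted-draw audits, common random numbers,
determinism, and consistency with the reference hazard functions."""

import copy

import numpy as np
import pytest

from osteosim.engine import ModelContext, run_cohort, simulate_patient
from osteosim.fracture_model import FractureEvent, cycle_fracture_probability
from osteosim.parameters import CohortSpec, EfficacyTimeline, FractureType
from osteosim.survival_model import life_table_expected_years

from conftest import ScriptedRNG, make_toy_params

HIP, VERT, WRIST = FractureType.HIP, FractureType.VERTEBRAL, FractureType.WRIST
SAFE = 0.999


def _neutral_efficacy(params):
    for arm in ("teriparatide", "bisphosphonate"):
        params.efficacy[arm] = {
            ft: EfficacyTimeline(1.0, 1.0, 0.0, 0.0) for ft in (HIP, VERT, WRIST)
        }
    return params


class TestDegenerateInputs:
    def test_no_risk_no_mortality_runs_to_age_cap(self, pmo_cohort):
        params = make_toy_params(annual_risk=0.0, q6=0.0)
        spec = CohortSpec("short", "PMO", 69.0, 1.0, 0.0, age_cap=70.5)
        run = simulate_patient(spec, "none", params, np.random.default_rng(0))
        assert len(run.ledgers) == 3
        assert all(l.accrual_fraction == 1.0 for l in run.ledgers)
        assert sum(run.fracture_counts.values()) == 0

    def test_female_fraction_zero_gives_male(self, toy_params):
        spec = CohortSpec("males", "PMO", 69.0, 0.0, 0.0, age_cap=71.0)
        run = simulate_patient(spec, "none", toy_params, np.random.default_rng(0))
        assert run.gender == "male"


class TestScriptedTrajectory:
    """Single-patient oracle: a scripted draw sequence produces a ledger that
    matches an independent cycle-by-cycle recomputation to 1e-12."""

    def _run(self):
        params = make_toy_params(disc_curve=(1.0, 0.8, 0.8))
        spec = CohortSpec("scripted", "PMO", 69.0, 1.0, 0.0)
        draws = (
            [SAFE, SAFE, SAFE, SAFE, SAFE, 0.0]  # cycle 0: survive, stay on drug
            + [SAFE, SAFE, SAFE, SAFE, SAFE, 0.0]  # cycle 1: survive, stay on drug
            + [SAFE, SAFE, 0.001, SAFE, SAFE, SAFE]  # cycle 2: vertebral fracture
            + [SAFE, SAFE, SAFE, SAFE, 0.001, SAFE]  # cycle 3: natural death
        )
        rng = ScriptedRNG(draws, fill=SAFE)
        return simulate_patient(spec, "teriparatide", params, rng, gender="female")

    def test_event_stream(self):
        run = self._run()
        assert run.fracture_counts == {HIP: 0, VERT: 1, WRIST: 0}
        assert run.events == [FractureEvent(VERT, 2)]
        assert run.cessation_cycle == 3  # completed the full 18-month course
        assert len(run.ledgers) == 4

    def test_ledger_matches_hand_computation(self):
        run = self._run()
        drug = 14.74 * 182.625
        # independent spreadsheet-style recomputation, cycle by cycle:
        # (drug, monitoring, acute, continuing, utility, accrual)
        expected = [
            (drug, 201.0, 0.0, 0.0, 0.8, 1.0),
            (drug, 194.0, 0.0, 0.0, 0.8, 1.0),
            (drug, 201.0, 400.0, 0.0, 0.8 * 0.626, 1.0),  # fracture cycle: acute only
            (0.0, 0.0, 0.0, 10.0 * 0.5, 0.8 * 0.626, 0.5),  # death cycle: half accrual
        ]
        for ledger, (d, m, a, c, u, af) in zip(run.ledgers, expected):
            assert ledger.cost_drug == pytest.approx(d * af, abs=1e-12)
            assert ledger.cost_monitoring == pytest.approx(m * af, abs=1e-12)
            assert ledger.cost_fracture_acute == pytest.approx(a, abs=1e-12)
            assert ledger.cost_fracture_continuing == pytest.approx(c, abs=1e-12)
            assert ledger.utility == pytest.approx(u, abs=1e-12)
            assert ledger.accrual_fraction == af

    def test_totals_match_hand_discounting(self):
        from osteosim.economics import discounted_total_cost
        from osteosim.utility_model import accumulate_qalys

        run = self._run()
        df = [1.03 ** (-0.5 * k) for k in range(4)]
        drug = 14.74 * 182.625
        exp_cost = (
            (drug + 201.0) * df[0]
            + (drug + 194.0) * df[1]
            + (drug + 201.0 + 400.0) * df[2]
            + 5.0 * df[3]
        )
        exp_qaly = (
            0.8 * 0.5 * (df[0] + df[1])
            + 0.8 * 0.626 * 0.5 * df[2]
            + 0.8 * 0.626 * 0.5 * 0.5 * df[3]
        )
        assert discounted_total_cost(run.ledgers, 0.03) == pytest.approx(exp_cost, abs=1e-12)
        qaly, years = accumulate_qalys(run.ledgers, 0.03)
        assert qaly == pytest.approx(exp_qaly, abs=1e-12)
        assert years == pytest.approx(1.75, abs=1e-12)

    def test_early_discontinuation_stops_drug_and_anchors_efficacy(self):
        params = make_toy_params(disc_curve=(1.0, 0.8, 0.8))
        spec = CohortSpec("dropout", "PMO", 69.0, 1.0, 0.0)
        draws = [SAFE, SAFE, SAFE, SAFE, SAFE, 0.9]  # u >= 0.8: discontinue after cycle 0
        run = simulate_patient(
            spec, "teriparatide", params, ScriptedRNG(draws, fill=SAFE), gender="female"
        )
        assert run.cessation_cycle == 1
        assert run.ledgers[0].cost_drug > 0
        assert all(l.cost_drug == 0.0 and l.cost_monitoring == 0.0 for l in run.ledgers[1:])


class TestCommonRandomNumbers:
    def test_neutral_efficacy_gives_identical_fracture_streams(self, pmo_cohort):
        params = _neutral_efficacy(make_toy_params(annual_risk=0.10))
        runs = {}
        for arm in ("none", "teriparatide"):
            runs[arm] = simulate_patient(
                pmo_cohort, arm, params, np.random.default_rng(1234)
            )
        assert runs["none"].events == runs["teriparatide"].events
        assert runs["none"].fracture_counts == runs["teriparatide"].fracture_counts

    def test_neutral_effects_and_costs_make_all_arm_summaries_identical(self, pmo_cohort):
        params = _neutral_efficacy(make_toy_params(annual_risk=0.10))
        params.cost_table.drug_daily = {a: 0.0 for a in params.cost_table.drug_daily}
        params.cost_table.visit_basic_eur = 0.0
        params.cost_table.visit_bmd_eur = 0.0
        res = run_cohort(pmo_cohort, params, n_patients=400, n_replications=2, seed=7)
        ref = res.arms["none"]
        for arm in ("teriparatide", "bisphosphonate"):
            s = res.arms[arm]
            assert np.array_equal(s.rep_cost, ref.rep_cost)
            assert np.array_equal(s.rep_qaly, ref.rep_qaly)
            assert np.array_equal(s.rep_fractures, ref.rep_fractures)


class TestDeterminismAndAggregation:
    def test_fixed_seed_bit_identical(self, pmo_cohort, toy_params):
        a = run_cohort(pmo_cohort, toy_params, 300, 2, seed=11)
        b = run_cohort(pmo_cohort, toy_params, 300, 2, seed=11)
        for arm in a.arms:
            assert np.array_equal(a.arms[arm].rep_cost, b.arms[arm].rep_cost)
            assert np.array_equal(a.arms[arm].rep_qaly, b.arms[arm].rep_qaly)
            assert a.arms[arm].mean_cost == b.arms[arm].mean_cost

    def test_placeholder_usage_reported_in_metadata(self, pmo_cohort, default_params):
        res = run_cohort(pmo_cohort, default_params, 50, 1, seed=1, arms=("none",))
        assert res.metadata["uses_placeholder_tables"] is True
        assert "baseline_risks" in res.metadata["placeholder_tables"]

    def test_toy_bundle_reports_no_placeholders(self, pmo_cohort, toy_params):
        res = run_cohort(pmo_cohort, toy_params, 50, 1, seed=1, arms=("none",))
        assert res.metadata["uses_placeholder_tables"] is False

    def test_qaly_bounded_by_life_years_times_max_utility(self, pmo_cohort, toy_params):
        res = run_cohort(pmo_cohort, toy_params, 500, 1, seed=3)
        for s in res.arms.values():
            assert s.mean_qaly <= s.mean_life_years * 0.8 + 1e-12

    def test_higher_efficacy_weakly_reduces_fractures(self, pmo_cohort):
        params_strong = make_toy_params(annual_risk=0.10)
        params_null = _neutral_efficacy(make_toy_params(annual_risk=0.10))
        strong = run_cohort(pmo_cohort, params_strong, 2000, 1, seed=5, arms=("teriparatide",))
        null = run_cohort(pmo_cohort, params_null, 2000, 1, seed=5, arms=("teriparatide",))
        for ft in (HIP, VERT, WRIST):
            assert (
                strong.arms["teriparatide"].mean_fractures[ft]
                <= null.arms["teriparatide"].mean_fractures[ft]
            )


class TestLifeTableAgreement:
    def test_fracture_free_life_years_match_closed_form(self, pmo_cohort):
        params = make_toy_params(annual_risk=0.0)
        oracle = life_table_expected_years(69.0, "female", params.mortality, age_cap=100.0)
        res = run_cohort(pmo_cohort, params, 5000, 4, seed=9, arms=("none",))
        s = res.arms["none"]
        se = float(np.std(s.rep_life_years, ddof=1)) / np.sqrt(s.n_replications)
        assert abs(s.mean_life_years - oracle) < 5 * se


class TestHazardConsistency:
    """The engine's compiled hazard path agrees with the reference per-cycle
    fracture probability function."""

    def test_static_hazard_times_rr_matches_reference(self):
        params = make_toy_params()
        spec = CohortSpec(
            "giop_check", "GIOP", 69.0, 1.0, -1.0,
            history=((VERT, 6.0),),
        )
        ctx = ModelContext(spec, params)

        class _P:
            gender = "female"
            t_score = -1.0
            disease = "GIOP"
            arm = "teriparatide"
            history = [FractureEvent(VERT, -1)]
            cessation_cycle = None

        for k in (0, 1, 2, 5, 9, 30):
            p = _P()
            p.age = 69.0 + 0.5 * k
            for i, ft in enumerate((HIP, VERT, WRIST)):
                ref = cycle_fracture_probability(p, ft, k, params).final
                hist = 1.0
                n_in = 1 if 1 <= k - (-1) <= params.history_window_cycles else 0
                if n_in:
                    hist = params.fracture_after_fracture_rr[ft]
                # largest across sites: only vertebral history exists
                hist = max(
                    1.0,
                    params.fracture_after_fracture_rr[VERT]
                    if 1 <= k + 1 <= params.history_window_cycles
                    else 1.0,
                )
                got = min(
                    1.0, ctx.static_hazard[0][i][k] * hist * ctx.rr["teriparatide"][3][i][k]
                )
                assert got == pytest.approx(ref, abs=1e-12)
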