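"""Outcome statistics: ICER and dominance, fractures avoided, sensitivity
analyses, PSA sampling distributions, acceptability curves."""

import math

import numpy as np
import pytest

from osteosim.analysis import (
    BetaSpec,
    CostScaleSpec,
    PSAConfig,
    PSADraw,
    _sample_scaled_beta,
    _sample_truncated_lognormal,
    acceptability_at,
    acceptability_curve,
    classify_incremental,
    fractures_avoided_per_1000,
    get_by_path,
    icer,
    incremental_life_years_per_1000,
    one_way_sa,
    resolve_path,
    run_psa,
    sample_psa_draw,
    set_by_path,
)
from osteosim.engine import ArmSummary, run_cohort
from osteosim.parameters import CohortSpec, FractureType

from conftest import make_toy_params

HIP, VERT, WRIST = FractureType.HIP, FractureType.VERTEBRAL, FractureType.WRIST


def _summary(arm, cost, qaly, ly=15.0, fx=(0.1, 0.2, 0.05), n=1000, reps=4):
    return ArmSummary(
        arm=arm,
        n_patients=n,
        n_replications=reps,
        mean_cost=cost,
        mean_qaly=qaly,
        mean_life_years=ly,
        mean_fractures={HIP: fx[0], VERT: fx[1], WRIST: fx[2]},
        rep_cost=np.full(reps, cost),
        rep_qaly=np.full(reps, qaly),
        rep_life_years=np.full(reps, ly),
        rep_fractures=np.tile(fx, (reps, 1)),
    )


class TestIcer:
    def test_trade_off_ratio(self):
        ce = icer(_summary("a", 11000.0, 10.05), _summary("b", 10000.0, 10.0))
        assert ce.label == "icer"
        assert ce.icer == pytest.approx(1000.0 / 0.05)

    def test_dominant_when_cheaper_and_better(self):
        ce = icer(_summary("a", 9990.0, 10.01), _summary("b", 10000.0, 10.0))
        assert ce.label == "dominant" and ce.icer is None

    def test_dominated_when_dearer_and_worse(self):
        ce = icer(_summary("a", 10500.0, 9.9), _summary("b", 10000.0, 10.0))
        assert ce.label == "dominated"

    def test_undefined_when_qalys_equal(self):
        ce = icer(_summary("a", 10500.0, 10.0), _summary("b", 10000.0, 10.0))
        assert ce.label == "undefined" and ce.icer is None

    def test_south_west_flagged(self):
        ce = icer(_summary("a", 9000.0, 9.9), _summary("b", 10000.0, 10.0))
        assert ce.label == "icer" and ce.south_west

    def test_mismatched_runs_rejected(self):
        with pytest.raises(ValueError):
            icer(_summary("a", 1.0, 1.0, n=1000), _summary("b", 1.0, 2.0, n=2000))

    def test_quadrant_classification_matches_brute_force(self):
        # independent sign-table classifier over 10,000 random pairs
        rng = np.random.default_rng(0)
        dc = rng.normal(0, 1000, 10_000)
        dq = rng.normal(0, 0.05, 10_000)
        for c, q in zip(dc, dq):
            got = classify_incremental(c, q)
            if q > 0 and c > 0:
                expected = "icer"
            elif q > 0:
                expected = "dominant"
            elif q < 0 and c >= 0:
                expected = "dominated"
            elif q < 0:
                expected = "icer"
            else:
                expected = "undefined"
            assert got == expected


class TestClinicalDeltas:
    def test_identical_arms_avoid_nothing(self):
        a = _summary("a", 1.0, 1.0)
        assert all(v == 0.0 for v in fractures_avoided_per_1000(a, a).values())

    def test_avoided_arithmetic(self):
        a = _summary("a", 1.0, 1.0, fx=(0.25, 0.25, 0.25))
        b = _summary("b", 1.0, 1.0, fx=(0.30, 0.30, 0.30))
        avoided = fractures_avoided_per_1000(a, b)
        assert avoided[HIP] == pytest.approx(50.0)

    def test_incremental_life_years_scaling(self):
        a = _summary("a", 1.0, 1.0, ly=15.1)
        b = _summary("b", 1.0, 1.0, ly=15.0)
        assert incremental_life_years_per_1000(a, b) == pytest.approx(100.0)


class TestParameterPaths:
    def test_scalar_attribute(self, toy_params):
        assert get_by_path(toy_params, "discount_rate_costs") == 0.03
        set_by_path(toy_params, "discount_rate_costs", 0.05)
        assert toy_params.discount_rate_costs == 0.05

    def test_dict_with_enum_keys(self, toy_params):
        assert get_by_path(toy_params, "cost_table.drug_daily.teriparatide") == 14.74
        assert get_by_path(toy_params, "efficacy.teriparatide.vertebral.on_treatment_rr") == 0.17
        set_by_path(toy_params, "utility.first_year.hip", 0.7)
        assert toy_params.utility.first_year[HIP] == 0.7

    def test_unresolvable_path_raises(self, toy_params):
        with pytest.raises(KeyError, match="nonsense"):
            resolve_path(toy_params, "cost_table.nonsense")


class TestOneWaySA:
    def test_empty_variation_list(self, toy_params, pmo_cohort):
        assert one_way_sa(pmo_cohort, toy_params, [], n_patients=10, n_replications=1) == []

    def test_inert_parameter_leaves_icer_unchanged(self, pmo_cohort):
        # the untreated arm's (zero) drug price touches neither compared arm
        params = make_toy_params(annual_risk=0.10)
        rows = one_way_sa(
            pmo_cohort,
            params,
            [("cost_table.drug_daily.none", 0.0, 50.0)],
            n_patients=400,
            n_replications=1,
            seed=3,
        )
        assert rows[0].icer_low == rows[0].icer_high

    def test_faster_efficacy_offset_raises_icer(self, pmo_cohort):
        # removing the teriparatide post-treatment plateau (sustained period
        # to zero) must make teriparatide look worse vs bisphosphonate
        params = make_toy_params(annual_risk=0.10)
        rows = one_way_sa(
            pmo_cohort,
            params,
            [("efficacy.teriparatide.vertebral.sustained_months", 0.0, 18.0)],
            n_patients=1500,
            n_replications=1,
            seed=3,
        )
        r = rows[0]
        assert r.label_low == r.label_high == "icer"
        assert r.icer_low > r.icer_high


class TestPsaSampling:
    def test_truncated_lognormal_moments_and_support(self):
        rng = np.random.default_rng(1)
        draws = np.array([_sample_truncated_lognormal(rng, 0.5, 2.0) for _ in range(10_000)])
        assert np.all((draws >= 0.5) & (draws <= 2.0))
        assert abs(draws.mean() - 1.0) < 0.02

    def test_scaled_beta_mean_and_support(self):
        rng = np.random.default_rng(2)
        draws = np.array([_sample_scaled_beta(rng, 0.17, 0.06, 0.42) for _ in range(10_000)])
        assert np.all((draws >= 0.06) & (draws <= 0.42))
        assert abs(draws.mean() - 0.17) < 0.01

    def test_degenerate_supports_return_baseline(self, toy_params):
        cfg = PSAConfig(
            cost_scales=[CostScaleSpec(ft, 1.0, 1.0) for ft in (HIP, VERT, WRIST)],
            betas=[BetaSpec("efficacy.teriparatide.vertebral.on_treatment_rr", 0.17, 0.17, 0.17)],
        )
        p, sampled = sample_psa_draw(toy_params, cfg, np.random.default_rng(0))
        assert p == toy_params
        assert sampled["efficacy.teriparatide.vertebral.on_treatment_rr"] == 0.17

    def test_sampled_rr_perturbs_only_target(self, toy_params):
        cfg = PSAConfig(
            betas=[BetaSpec("efficacy.teriparatide.vertebral.on_treatment_rr", 0.17, 0.06, 0.42)]
        )
        p, sampled = sample_psa_draw(toy_params, cfg, np.random.default_rng(3))
        assert p.efficacy["teriparatide"][VERT].on_treatment_rr == sampled[
            "efficacy.teriparatide.vertebral.on_treatment_rr"
        ]
        assert p.efficacy["teriparatide"][HIP] == toy_params.efficacy["teriparatide"][HIP]
        assert p.cost_table.acute[HIP] == toy_params.cost_table.acute[HIP]


class TestRunPsa:
    def _spec(self):
        return CohortSpec("psa_toy", "PMO", 69.0, 1.0, 0.0)

    def test_quadrant_counts_partition_sims(self):
        params = make_toy_params(annual_risk=0.10)
        res = run_psa(self._spec(), params, n_sims=20, n_patients=100, seed=4)
        assert sum(res.quadrant_counts.values()) == 20

    def test_degenerate_distributions_reproduce_base_case(self):
        params = make_toy_params(annual_risk=0.10)
        cfg = PSAConfig(
            cost_scales=[CostScaleSpec(ft, 1.0, 1.0) for ft in (HIP, VERT, WRIST)],
            betas=[],
        )
        res = run_psa(self._spec(), params, cfg, n_sims=1, n_patients=300, seed=8)
        # the same run, replayed directly with the seed the PSA derived
        rng = np.random.default_rng([8, 104729, 0])
        run_seed = int(rng.integers(0, 2**31 - 1))
        base = run_cohort(
            self._spec(), params, 300, 1, run_seed, arms=("teriparatide", "bisphosphonate")
        )
        dc = base.arms["teriparatide"].mean_cost - base.arms["bisphosphonate"].mean_cost
        dq = base.arms["teriparatide"].mean_qaly - base.arms["bisphosphonate"].mean_qaly
        assert res.draws[0].delta_cost == dc
        assert res.draws[0].delta_qaly == dq


class TestAcceptability:
    def test_all_dominant_is_one_everywhere(self):
        draws = [PSADraw(i, -100.0, 0.01, {}) for i in range(5)]
        for wtp in (0.0, 1e4, 1e6):
            assert acceptability_at(draws, wtp) == 1.0

    def test_wtp_zero_counts_only_dominant(self):
        draws = [
            PSADraw(0, -100.0, 0.01, {}),  # dominant
            PSADraw(1, 100.0, 0.01, {}),  # trade-off
            PSADraw(2, 100.0, -0.01, {}),  # dominated
        ]
        assert acceptability_at(draws, 0.0) == pytest.approx(1 / 3)

    def test_synthetic_icers_counted_below_threshold(self):
        draws = [
            PSADraw(0, 100.0, 0.01, {}),  # 10,000 per QALY
            PSADraw(1, 300.0, 0.01, {}),  # 30,000 per QALY
            PSADraw(2, 700.0, 0.01, {}),  # 70,000 per QALY
        ]
        assert acceptability_at(draws, 50_000.0) == pytest.approx(2 / 3)

    def test_curve_monotone_non_decreasing(self):
        rng = np.random.default_rng(5)
        draws = [
            PSADraw(i, float(rng.normal(0, 500)), float(rng.normal(0.01, 0.02)), {})
            for i in range(200)
        ]
        grid = np.linspace(0, 120_000, 25)
        curve = acceptability_curve(draws, grid)
        assert np.all(np.diff(curve["fraction_acceptable"]) >= 0)

    def test_nmb_variant_differs_only_in_south_west(self):
        sw = PSADraw(0, -700.0, -0.01, {})  # saves 70,000 per QALY forgone
        assert acceptability_at([sw], 50_000.0) == 0.0  # 70k not < 50k
        assert acceptability_at([sw], 50_000.0, method="nmb") == 1.0  # saves more than WTP

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            acceptability_at([], 1000.0)
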