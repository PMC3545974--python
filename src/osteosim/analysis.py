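"""Cost-effectiveness outcome statistics and sensitivity analyses.

Turns per-arm cohort summaries into incremental comparisons (ICER with
dominance labelling, fractures avoided per 1,000 patients, incremental life
years), runs one-way sensitivity analyses (tornado tables under paired
seeds) and probabilistic sensitivity analyses (fracture costs lognormal,
disutilities and treatment relative risks beta, means fixed at baseline),
and builds cost-effectiveness acceptability curves.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import ArmSummary, CohortResult, ModelContext, run_cohort
from .parameters import FRACTURE_TYPES, CohortSpec, FractureType, ParameterSet

DEFAULT_WTP_EUR = 50_000.0


# ---------------------------------------------------------------------------
# incremental comparisons
# ---------------------------------------------------------------------------


@dataclass
class CEResult:
    """Incremental comparison of an intervention against a comparator.

    ``label`` is "icer" in the trade-off quadrants (ICER defined), "dominant"
    (cheaper and more effective), "dominated" (dearer and less effective), or
    "undefined" when the QALY difference is exactly zero.  A negative-
    negative pair (cheaper, less effective) carries label "icer" with
    ``south_west=True``: the ratio is savings per QALY forgone.
    """

    intervention: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    label: str
    icer: float | None
    south_west: bool = False
    icer_ci: tuple[float, float] | None = None
    delta_cost_ci: tuple[float, float] | None = None
    delta_qaly_ci: tuple[float, float] | None = None


def classify_incremental(delta_cost: float, delta_qaly: float) -> str:
    """Quadrant classification of an incremental (cost, QALY) pair."""
    if delta_qaly == 0.0:
        return "undefined"
    if delta_qaly > 0.0:
        return "icer" if delta_cost > 0.0 else "dominant"
    return "dominated" if delta_cost >= 0.0 else "icer"


def icer(intervention: ArmSummary, comparator: ArmSummary) -> CEResult:
    """Incremental cost-effectiveness of ``intervention`` vs ``comparator``."""
    if intervention.n_patients != comparator.n_patients:
        raise ValueError(
            "arm summaries come from different runs: "
            f"{intervention.n_patients} vs {comparator.n_patients} patients"
        )
    dc = intervention.mean_cost - comparator.mean_cost
    dq = intervention.mean_qaly - comparator.mean_qaly
    label = classify_incremental(dc, dq)
    ratio = dc / dq if label == "icer" else None
    ci = None
    dc_ci = dq_ci = None
    if intervention.n_replications >= 2 and label == "icer":
        d_cost = intervention.rep_cost - comparator.rep_cost
        d_qaly = intervention.rep_qaly - comparator.rep_qaly
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = d_cost / d_qaly
        ratios = ratios[np.isfinite(ratios)]
        if len(ratios) >= 2:
            ci = (float(np.percentile(ratios, 2.5)), float(np.percentile(ratios, 97.5)))
        n = len(d_cost)
        hw_c = 1.96 * float(np.std(d_cost, ddof=1)) / math.sqrt(n)
        hw_q = 1.96 * float(np.std(d_qaly, ddof=1)) / math.sqrt(n)
        dc_ci = (dc - hw_c, dc + hw_c)
        dq_ci = (dq - hw_q, dq + hw_q)
    return CEResult(
        intervention=intervention.arm,
        comparator=comparator.arm,
        delta_cost=dc,
        delta_qaly=dq,
        label=label,
        icer=ratio,
        south_west=(dq < 0 and dc < 0),
        icer_ci=ci,
        delta_cost_ci=dc_ci,
        delta_qaly_ci=dq_ci,
    )


def fractures_avoided_per_1000(
    intervention: ArmSummary, comparator: ArmSummary
) -> dict[FractureType, float]:
    """Fractures avoided per 1,000 patients, per site (comparator minus
    intervention); round for table-style reporting."""
    return {
        ft: (comparator.mean_fractures[ft] - intervention.mean_fractures[ft]) * 1000.0
        for ft in FRACTURE_TYPES
    }


def incremental_life_years_per_1000(
    intervention: ArmSummary, comparator: ArmSummary
) -> float:
    """Undiscounted incremental life years per 1,000 patients."""
    return (intervention.mean_life_years - comparator.mean_life_years) * 1000.0


# ---------------------------------------------------------------------------
# one-way sensitivity analysis
# ---------------------------------------------------------------------------


def resolve_path(params: ParameterSet, path: str):
    """Resolve a dotted parameter path to (owner, key) for get/set.

    Segments traverse dataclass attributes and dict keys; dict keys that are
    fracture types or disease labels are matched by string value, e.g.
    ``"cost_table.drug_daily.teriparatide"`` or
    ``"efficacy.teriparatide.hip.on_treatment_rr"``.
    """
    obj = params
    parts = path.split(".")
    for i, part in enumerate(parts):
        last = i == len(parts) - 1
        if isinstance(obj, dict):
            key = part
            if part not in obj:
                matches = [k for k in obj if getattr(k, "value", str(k)) == part]
                if not matches:
                    raise KeyError(f"cannot resolve segment {part!r} in path {path!r}")
                key = matches[0]
            if last:
                return obj, key
            obj = obj[key]
        else:
            if not hasattr(obj, part):
                raise KeyError(f"cannot resolve segment {part!r} in path {path!r}")
            if last:
                return obj, part
            obj = getattr(obj, part)
    raise KeyError(f"empty path {path!r}")  # pragma: no cover


def get_by_path(params: ParameterSet, path: str):
    owner, key = resolve_path(params, path)
    return owner[key] if isinstance(owner, dict) else getattr(owner, key)


def set_by_path(params: ParameterSet, path: str, value) -> None:
    owner, key = resolve_path(params, path)
    if isinstance(owner, dict):
        owner[key] = value
    else:
        setattr(owner, key, value)


@dataclass
class TornadoRow:
    path: str
    low: float
    high: float
    icer_low: float | None
    icer_high: float | None
    label_low: str
    label_high: str

    @property
    def icer_range(self) -> float:
        vals = [v for v in (self.icer_low, self.icer_high) if v is not None]
        return max(vals) - min(vals) if len(vals) == 2 else float("inf")


def one_way_sa(
    spec: CohortSpec,
    params: ParameterSet,
    variations: Sequence[tuple[str, float, float]],
    arm_pair: tuple[str, str] = ("teriparatide", "bisphosphonate"),
    n_patients: int = 2000,
    n_replications: int = 2,
    seed: int = 0,
) -> list[TornadoRow]:
    """One-way sensitivity analysis: rerun the paired comparison with one
    parameter at its low and high value (same seeds) and report both ICERs,
    sorted by ICER range (widest bar first)."""
    rows = []
    for path, low, high in variations:
        get_by_path(params, path)  # fail fast on unresolvable paths
        results = {}
        for bound, value in (("low", low), ("high", high)):
            p = copy.deepcopy(params)
            set_by_path(p, path, value)
            p.validate()
            res = run_cohort(spec, p, n_patients, n_replications, seed, arms=arm_pair)
            ce = icer(res.arms[arm_pair[0]], res.arms[arm_pair[1]])
            results[bound] = ce
        rows.append(
            TornadoRow(
                path=path,
                low=low,
                high=high,
                icer_low=results["low"].icer,
                icer_high=results["high"].icer,
                label_low=results["low"].label,
                label_high=results["high"].label,
            )
        )
    rows.sort(key=lambda r: r.icer_range, reverse=True)
    return rows


def tornado_frame(rows: Sequence[TornadoRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": r.path,
                "low": r.low,
                "high": r.high,
                "icer_low": r.icer_low,
                "icer_high": r.icer_high,
                "label_low": r.label_low,
                "label_high": r.label_high,
                "icer_range": r.icer_range,
            }
            for r in rows
        ]
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

#: lognormal sigma so the central 95% of mass spans a factor of 4 (0.5x-2x)
_LN_SIGMA = math.log(4.0) / (2.0 * 1.96)


@dataclass
class BetaSpec:
    """A beta-distributed parameter rescaled to [low, high] with mean at
    baseline; the path points at the scalar to perturb."""

    path: str
    baseline: float
    low: float
    high: float


@dataclass
class CostScaleSpec:
    """A lognormal multiplicative scale (mean 1) applied to one site's acute
    and continuing fracture costs, truncated to [low, high]."""

    ftype: FractureType
    low: float = 0.5
    high: float = 2.0


@dataclass
class PSAConfig:
    """Which parameters the PSA perturbs and over what supports."""

    cost_scales: list[CostScaleSpec] = field(default_factory=list)
    betas: list[BetaSpec] = field(default_factory=list)

    @staticmethod
    def default(params: ParameterSet) -> "PSAConfig":
        """Fracture costs 50-200% of baseline per site; teriparatide
        on-treatment RRs within trial-style 95% CIs; first-year fracture
        utility multipliers within plausible published spreads.  CI and
        spread endpoints are placeholders pending a complete bundle."""
        cost_scales = [CostScaleSpec(ft) for ft in FRACTURE_TYPES]
        eff = params.efficacy["teriparatide"]
        ut = params.utility
        rr_ci = {
            FractureType.VERTEBRAL: (0.06, 0.42),
            FractureType.HIP: (0.25, 0.88),
            FractureType.WRIST: (0.25, 0.88),
        }
        betas = []
        for ft in FRACTURE_TYPES:
            lo, hi = rr_ci[ft]
            betas.append(
                BetaSpec(
                    f"efficacy.teriparatide.{ft.value}.on_treatment_rr",
                    eff[ft].on_treatment_rr,
                    lo,
                    hi,
                )
            )
        util_range = {
            FractureType.HIP: (0.55, 0.85),
            FractureType.VERTEBRAL: (0.50, 0.80),
            FractureType.WRIST: (0.90, 1.00),
        }
        for ft in FRACTURE_TYPES:
            lo, hi = util_range[ft]
            betas.append(
                BetaSpec(f"utility.first_year.{ft.value}", ut.first_year[ft], lo, hi)
            )
        return PSAConfig(cost_scales=cost_scales, betas=betas)


def _sample_truncated_lognormal(rng, low: float, high: float) -> float:
    """Mean-1 lognormal scale truncated (by rejection) to [low, high]."""
    mu = -0.5 * _LN_SIGMA**2
    for _ in range(1000):
        x = float(np.exp(rng.normal(mu, _LN_SIGMA)))
        if low <= x <= high:
            return x
    return 1.0  # pragma: no cover - rejection cannot realistically exhaust


def _sample_scaled_beta(rng, baseline: float, low: float, high: float) -> float:
    """Beta on [low, high] with mean at baseline; spread set so +/-2 SD spans
    the range, shrunk near the edges to keep the distribution proper."""
    if high <= low:
        return baseline
    m = (baseline - low) / (high - low)
    m = min(max(m, 1e-9), 1.0 - 1e-9)
    sd = min(0.25, 0.5 * math.sqrt(m * (1.0 - m)))
    nu = m * (1.0 - m) / sd**2 - 1.0
    a, b = m * nu, (1.0 - m) * nu
    return low + (high - low) * float(rng.beta(a, b))


def sample_psa_draw(
    params: ParameterSet, dist_config: PSAConfig, rng
) -> tuple[ParameterSet, dict[str, float]]:
    """One perturbed ParameterSet plus the sampled values by name.

    Degenerate supports (low == high == baseline) return the baseline
    untouched; all other parameters are left at their base values.
    """
    p = copy.deepcopy(params)
    sampled: dict[str, float] = {}
    for cs in dist_config.cost_scales:
        if cs.low == cs.high == 1.0:
            scale = 1.0
        else:
            scale = _sample_truncated_lognormal(rng, cs.low, cs.high)
        sampled[f"cost_scale.{cs.ftype.value}"] = scale
        if scale != 1.0:
            p.cost_table.acute[cs.ftype] = p.cost_table.acute[cs.ftype].scaled(scale)
            p.cost_table.continuing[cs.ftype] = p.cost_table.continuing[cs.ftype].scaled(scale)
    for bs in dist_config.betas:
        if bs.low == bs.high:
            value = bs.baseline
        else:
            value = _sample_scaled_beta(rng, bs.baseline, bs.low, bs.high)
        if bs.path.startswith("utility.first_year."):
            # keep the first-year multiplier at or below the subsequent one
            site = FractureType(bs.path.rsplit(".", 1)[1])
            value = min(value, p.utility.subsequent[site])
        sampled[bs.path] = value
        set_by_path(p, bs.path, value)
    return p, sampled


@dataclass
class PSADraw:
    index: int
    delta_cost: float
    delta_qaly: float
    sampled: dict[str, float]

    @property
    def label(self) -> str:
        return classify_incremental(self.delta_cost, self.delta_qaly)


@dataclass
class PSAResult:
    draws: list[PSADraw]
    quadrant_counts: dict[str, int]
    intervention: str
    comparator: str

    def fraction_acceptable(self, wtp: float) -> float:
        return acceptability_at(self.draws, wtp)


def run_psa(
    spec: CohortSpec,
    params: ParameterSet,
    dist_config: PSAConfig | None = None,
    n_sims: int = 1000,
    n_patients: int = 1000,
    seed: int = 0,
    arm_pair: tuple[str, str] = ("teriparatide", "bisphosphonate"),
) -> PSAResult:
    """Probabilistic sensitivity analysis.

    Per simulation: sample one parameter set, run both arms once under
    common random numbers, record the incremental (cost, QALY) pair.
    Quadrant counts partition the simulations: trade-off (both deltas
    positive), dominant (more QALYs, lower cost), dominated (fewer QALYs,
    higher cost), south-west (both negative), undefined (zero QALY delta).
    """
    if n_sims < 1 or n_patients < 1:
        raise ValueError("n_sims and n_patients must be >= 1")
    if dist_config is None:
        dist_config = PSAConfig.default(params)
    draws: list[PSADraw] = []
    counts = {"trade_off": 0, "dominant": 0, "dominated": 0, "south_west": 0, "undefined": 0}
    for s in range(n_sims):
        rng = np.random.default_rng([seed, 104729, s])
        p, sampled = sample_psa_draw(params, dist_config, rng)
        res = run_cohort(spec, p, n_patients, 1, seed=int(rng.integers(0, 2**31 - 1)), arms=arm_pair)
        a, b = res.arms[arm_pair[0]], res.arms[arm_pair[1]]
        dc = a.mean_cost - b.mean_cost
        dq = a.mean_qaly - b.mean_qaly
        draws.append(PSADraw(index=s, delta_cost=dc, delta_qaly=dq, sampled=sampled))
        label = classify_incremental(dc, dq)
        if label == "icer":
            counts["trade_off" if dq > 0 else "south_west"] += 1
        else:
            counts[label] += 1
    return PSAResult(
        draws=draws,
        quadrant_counts=counts,
        intervention=arm_pair[0],
        comparator=arm_pair[1],
    )


# ---------------------------------------------------------------------------
# acceptability curves
# ---------------------------------------------------------------------------


def acceptability_at(
    draws: Sequence[PSADraw], wtp: float, method: str = "cost_per_qaly"
) -> float:
    """Fraction of PSA draws acceptable at a willingness-to-pay threshold.

    ``cost_per_qaly`` (primary): a draw is acceptable when its cost per QALY
    is below the threshold, counting dominant draws as acceptable and
    dominated draws as not.  ``nmb``: acceptable when the incremental net
    monetary benefit ``wtp * dQ - dC`` is non-negative (the textbook rule;
    differs from the primary one only in the south-west quadrant).
    """
    if not draws:
        raise ValueError("acceptability requires at least one draw")
    acc = 0
    for d in draws:
        if method == "nmb":
            ok = wtp * d.delta_qaly - d.delta_cost >= 0.0
        else:
            label = d.label
            if label == "dominant":
                ok = True
            elif label in ("dominated", "undefined"):
                ok = False
            else:
                ok = (d.delta_cost / d.delta_qaly) < wtp
        acc += ok
    return acc / len(draws)


def acceptability_curve(
    draws: Sequence[PSADraw],
    wtp_grid: Sequence[float],
    method: str = "cost_per_qaly",
) -> pd.DataFrame:
    """Acceptability at each willingness-to-pay value on a grid."""
    return pd.DataFrame(
        {
            "wtp": list(wtp_grid),
            "fraction_acceptable": [acceptability_at(draws, w, method) for w in wtp_grid],
        }
    )
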