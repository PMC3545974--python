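"""Per-cycle fracture probabilities.

Each patient's 6-month fracture probability for a site is the baseline
annual first-fracture probability (age/gender interpolated), converted to a
6-month probability, multiplied by a bone-density multiplier (risk gradient
per SD below the age-specific mean T-score), a fracture-history multiplier
(largest across sites, with an extra loading for a second in-window fracture
of the same site), a glucocorticoid multiplier for GIOP patients, and the
treatment relative risk from the arm's efficacy timeline; the product is
capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .parameters import (
    AgeSeries,
    EfficacyTimeline,
    FractureType,
    ParameterSet,
    RiskTable,
)


@dataclass(frozen=True)
class FractureEvent:
    """A fracture of one site in one 6-month cycle.

    ``cycle_index`` counts cycles since model start; negative indices encode
    fractures before the start (e.g. -1 is an incident fracture 6 months
    before, -10 a historical fracture 5 years before).
    """

    ftype: FractureType
    cycle_index: int


@dataclass(frozen=True)
class HazardBreakdown:
    """The factors composing one cycle's fracture probability."""

    baseline_annual: float
    baseline_6mo: float
    bmd_multiplier: float
    history_multiplier: float
    giop_multiplier: float
    treatment_rr: float
    final: float


def interpolate_baseline_risk(
    age: float, gender: str, ftype: FractureType, table: RiskTable
) -> float:
    """Annual first-fracture probability at ``age``, linear between band
    midpoints and clamped to the end values outside the tabulated range."""
    return float(table.get(gender, ftype).at(age))


def male_risk_from_female(female_risk: float, ratio: float) -> float:
    """Impute a male risk as female risk times the male:female ratio, capped at 1."""
    if ratio <= 0:
        raise ValueError(f"male:female ratio must be positive, got {ratio}")
    return min(female_risk * ratio, 1.0)


def bmd_multiplier(
    t_measured: float, t_mean_at_age: float, gradient: float
) -> float:
    """Risk multiplier for measured bone density relative to the age mean.

    ``gradient`` is the relative risk per SD of BMD below the mean; the
    multiplier is ``gradient ** (t_mean - t_measured)`` and equals 1 when the
    measured T-score sits at the age-specific mean.
    """
    if gradient <= 1:
        raise ValueError(f"BMD gradient must exceed 1, got {gradient}")
    return float(gradient ** (t_mean_at_age - t_measured))


def history_multiplier(
    history: Sequence[FractureEvent],
    now: int,
    disease: str,
    params: ParameterSet,
) -> float:
    """Fracture-history risk multiplier at cycle ``now``.

    Only events within the post-fracture impact window (default 5 years,
    inclusive at the boundary) contribute.  One in-window fracture of a site
    with relative risk r contributes r; a second in-window fracture of the
    same site contributes ``1 + (1+s)*(r-1)`` where s is the second-fracture
    increase (0.5 for GIOP, 1.0 for PMO); third and later same-site fractures
    reuse the second-fracture multiplier.  Across sites the largest
    multiplier applies.
    """
    window = params.history_window_cycles
    s = params.second_fracture_increase[disease]
    best = 1.0
    for ftype in params.fracture_after_fracture_rr:
        n_in_window = sum(
            1 for ev in history if ev.ftype == ftype and 1 <= now - ev.cycle_index <= window
        )
        if n_in_window == 0:
            continue
        r = params.fracture_after_fracture_rr[ftype]
        mult = r if n_in_window == 1 else 1.0 + (1.0 + s) * (r - 1.0)
        best = max(best, mult)
    return best


def treatment_rr(
    arm: str,
    ftype: FractureType,
    months_since_treatment_start: float,
    months_treated: float,
    profile: dict[FractureType, EfficacyTimeline] | None,
) -> float:
    """Treatment relative risk at a point on the efficacy timeline.

    On treatment the timeline's on-treatment RR applies.  After cessation
    (time measured from the cessation point, whether scheduled completion or
    early discontinuation) the sustained RR holds for ``sustained_months``,
    then fades linearly to 1 over ``offset_months``.
    """
    if arm == "none" or profile is None:
        return 1.0
    if months_since_treatment_start < 0:
        raise ValueError("months_since_treatment_start must be >= 0")
    tl = profile[ftype]
    if months_since_treatment_start < months_treated:
        return tl.on_treatment_rr
    t = months_since_treatment_start - months_treated
    if t <= tl.sustained_months:
        return tl.sustained_rr
    t -= tl.sustained_months
    if t <= tl.offset_months and tl.offset_months > 0:
        return tl.sustained_rr + (1.0 - tl.sustained_rr) * (t / tl.offset_months)
    return 1.0


def annual_to_cycle_probability(p_annual: float, mode: str = "probability") -> float:
    """Convert an annual probability to a 6-month one.

    The default complement-power conversion ``1 - (1-p)**0.5`` is exact under
    a constant hazard; ``mode="rate"`` divides by two (simple halving).
    """
    if mode == "rate":
        return p_annual / 2.0
    return 1.0 - (1.0 - p_annual) ** 0.5


def cycle_fracture_probability(
    patient,
    ftype: FractureType,
    cycle: int,
    params: ParameterSet,
) -> HazardBreakdown:
    """Full per-cycle fracture probability for one site, with its breakdown.

    ``patient`` needs attributes ``age`` (at cycle start), ``gender``,
    ``t_score``, ``disease``, ``arm``, ``history`` (FractureEvent sequence),
    and ``cessation_cycle`` (first untreated cycle, or None while the
    scheduled course is still possible).
    """
    age = patient.age
    p_annual = interpolate_baseline_risk(age, patient.gender, ftype, params.risk_table)
    p6 = annual_to_cycle_probability(p_annual, params.hazard_composition)
    t_mean = float(params.mean_t_score[patient.gender].at(age))
    m_bmd = bmd_multiplier(patient.t_score, t_mean, params.bmd_gradient[ftype])
    m_hist = history_multiplier(patient.history, cycle, patient.disease, params)
    m_giop = float(params.giop_rr[ftype].at(age)) if patient.disease == "GIOP" else 1.0
    cessation = getattr(patient, "cessation_cycle", None)
    if cessation is None:
        cessation = params.treatment_cycles
    months = cycle * params.cycle_length_months
    rr = treatment_rr(
        patient.arm,
        ftype,
        months,
        cessation * params.cycle_length_months,
        params.efficacy.get(patient.arm),
    )
    final = min(1.0, p6 * m_bmd * m_hist * m_giop * rr)
    return HazardBreakdown(p_annual, p6, m_bmd, m_hist, m_giop, rr, final)
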