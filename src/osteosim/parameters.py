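"""Parameter bundle: domain types, validation, loading and saving.

Every quantity the simulation consumes lives in a :class:`ParameterSet`:
baseline fracture-risk tables, relative-risk multipliers (fracture history,
glucocorticoid use, bone-density gradient), treatment efficacy timelines,
persistence (discontinuation) curves, life tables with the fracture-attributable
share of deaths removed, excess-mortality multiplier schedules, fracture and
drug costs, base utilities and fracture utility multipliers, and the scalar
settings (discount rate, exchange rate, cycle length, treatment duration).

Tables carry a provenance flag.  Values printed in the source cost study are
tagged ``packaged-default``; age-resolved tables whose exact contents were
published only in that study's supplementary appendix are regenerated here from
coarse anchors and tagged ``placeholder`` — they are structurally faithful
(monotone in age, right order of magnitude) but not the original numbers, and
any engine result computed from them says so in its metadata.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import PchipInterpolator


class FractureType(str, enum.Enum):
    """The three fracture sites carried by the model."""

    HIP = "hip"
    VERTEBRAL = "vertebral"
    WRIST = "wrist"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


FRACTURE_TYPES: tuple[FractureType, ...] = (
    FractureType.HIP,
    FractureType.VERTEBRAL,
    FractureType.WRIST,
)

ARMS: tuple[str, ...] = ("teriparatide", "bisphosphonate", "none")
GENDERS: tuple[str, ...] = ("female", "male")


class ValidationError(ValueError):
    """Raised when a parameter bundle violates a structural invariant.

    The message lists every offending field so an incomplete bundle is
    rejected with a named-field report rather than failing mid-simulation.
    """


# ---------------------------------------------------------------------------
# age-indexed series
# ---------------------------------------------------------------------------


@dataclass
class AgeSeries:
    """A quantity tabulated at age-band midpoints.

    ``at(age)`` interpolates linearly between midpoints and clamps to the end
    values outside the tabulated range, which is the convention used for the
    risk tables (band values are assigned to the band midpoint, e.g. the 50-54
    value belongs to age 52).
    """

    ages: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)

    def at(self, age: float | np.ndarray) -> float | np.ndarray:
        out = np.interp(age, self.ages, self.values)
        return float(out) if np.isscalar(age) else out

    def scaled(self, factor: float) -> "AgeSeries":
        return AgeSeries(self.ages.copy(), self.values * factor)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, AgeSeries)
            and np.array_equal(self.ages, other.ages)
            and np.array_equal(self.values, other.values)
        )


@dataclass
class StepSeries:
    """A quantity constant within age bands (left-closed steps).

    Used for fracture costs, which the sources report per age band rather
    than per age; ``at(age)`` returns the value of the band containing
    ``age``, clamping below the first band.
    """

    lower_bounds: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.values = np.asarray(self.values, dtype=float)

    def at(self, age: float | np.ndarray) -> float | np.ndarray:
        idx = np.clip(np.searchsorted(self.lower_bounds, age, side="right") - 1, 0, None)
        out = self.values[idx]
        return float(out) if np.isscalar(age) else out

    def scaled(self, factor: float) -> "StepSeries":
        return StepSeries(self.lower_bounds.copy(), self.values * factor)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, StepSeries)
            and np.array_equal(self.lower_bounds, other.lower_bounds)
            and np.array_equal(self.values, other.values)
        )


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Definition of a simulated cohort.

    ``history`` lists pre-existing fractures as (type, months before model
    start); the canonical severe-osteoporosis cohorts carry an incident
    vertebral fracture 6 months before start and, in the two-fracture
    variants, a historical vertebral fracture 5 years before start.
    """

    name: str
    disease: str  # "PMO" | "GIOP"
    start_age: float
    female_fraction: float
    t_score: float
    history: tuple[tuple[FractureType, float], ...] = ()
    arms: tuple[str, ...] = ARMS
    age_cap: float = 100.0

    def validate(self) -> None:
        errs = []
        if self.disease not in ("PMO", "GIOP"):
            errs.append(f"disease must be PMO or GIOP, got {self.disease!r}")
        if self.start_age < 50:
            errs.append(f"start_age must be >= 50, got {self.start_age}")
        if self.t_score > 0:
            errs.append(f"t_score must be <= 0, got {self.t_score}")
        if not 0.0 <= self.female_fraction <= 1.0:
            errs.append(f"female_fraction outside [0,1]: {self.female_fraction}")
        for ftype, months in self.history:
            if months < 0:
                errs.append(f"history entry {ftype} has negative months: {months}")
        for arm in self.arms:
            if arm not in ARMS:
                errs.append(f"unknown arm {arm!r}")
        if errs:
            raise ValidationError("; ".join(errs))


@dataclass
class EfficacyTimeline:
    """Relative fracture risk under and after treatment, for one site.

    While on drug the relative risk is ``on_treatment_rr``.  After cessation
    it holds at ``sustained_rr`` for ``sustained_months``, then returns
    linearly to 1 over ``offset_months``.
    """

    on_treatment_rr: float
    sustained_rr: float
    sustained_months: float
    offset_months: float

    def validate(self, label: str) -> list[str]:
        errs = []
        for name in ("on_treatment_rr", "sustained_rr"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                errs.append(f"{label}.{name} outside (0,1]: {v}")
        for name in ("sustained_months", "offset_months"):
            if getattr(self, name) < 0:
                errs.append(f"{label}.{name} negative")
        return errs


# per arm, per fracture type
EfficacyProfile = dict[FractureType, EfficacyTimeline]


@dataclass
class RiskTable:
    """Annual first-fracture probabilities at population-mean BMD.

    Keyed by gender and fracture type; each series is tabulated at age-band
    midpoints.  Male series are imputed from the female ones via the
    male:female ratio table when a bundle ships only female rows.
    """

    series: dict[tuple[str, FractureType], AgeSeries]

    def get(self, gender: str, ftype: FractureType) -> AgeSeries:
        try:
            return self.series[(gender, ftype)]
        except KeyError:
            raise KeyError(f"risk table has no series for ({gender}, {ftype.value})")

    def validate(self) -> list[str]:
        errs = []
        for gender in GENDERS:
            for ftype in FRACTURE_TYPES:
                key = (gender, ftype)
                if key not in self.series:
                    errs.append(f"risk table missing ({gender}, {ftype.value})")
                    continue
                s = self.series[key]
                if np.any((s.values < 0) | (s.values > 1)):
                    errs.append(f"risk table ({gender},{ftype.value}) has probability outside [0,1]")
                if np.any(np.diff(s.ages) <= 0):
                    errs.append(f"risk table ({gender},{ftype.value}) ages not strictly increasing")
        return errs


@dataclass
class CostTable:
    """Fracture, drug, and monitoring costs in euros.

    Acute costs cover the six months after a fracture; continuing costs
    recur every six months for the rest of life (zero for wrist).  Drug costs
    are per day; visits are charged per treated cycle, with the BMD-inclusive
    price in alternating cycles starting at the first.
    """

    acute: dict[FractureType, StepSeries]
    continuing: dict[FractureType, StepSeries]
    drug_daily: dict[str, float]
    visit_basic_eur: float
    visit_bmd_eur: float
    days_per_cycle: float = 182.625

    def validate(self) -> list[str]:
        errs = []
        for group_name, group in (("acute", self.acute), ("continuing", self.continuing)):
            for ftype in FRACTURE_TYPES:
                if ftype not in group:
                    errs.append(f"cost table missing {group_name} series for {ftype.value}")
                    continue
                if np.any(group[ftype].values < 0):
                    errs.append(f"cost table {group_name}[{ftype.value}] has negative cost")
        if FractureType.WRIST in self.continuing and np.any(
            self.continuing[FractureType.WRIST].values != 0
        ):
            errs.append("wrist continuing costs must be zero")
        for arm in ARMS:
            if arm not in self.drug_daily:
                errs.append(f"cost table missing drug_daily[{arm}]")
            elif self.drug_daily[arm] < 0:
                errs.append(f"drug_daily[{arm}] negative")
        for name in ("visit_basic_eur", "visit_bmd_eur"):
            if getattr(self, name) < 0:
                errs.append(f"{name} negative")
        if self.days_per_cycle <= 0:
            errs.append("days_per_cycle must be positive")
        return errs


@dataclass
class MortalityTables:
    """Life-table and fracture-mortality inputs.

    ``life_q6`` is the all-cause 6-month death probability by age and gender;
    ``fracture_death_proportion`` is the share of those deaths attributable
    to fracture (removed to obtain natural mortality); ``fracture_mortality``
    is the base 6-month fracture-death probability that excess multipliers
    scale; ``excess_schedule`` maps each site to year-indexed multipliers
    (year 1 first), phasing out to 1.
    """

    life_q6: dict[str, AgeSeries]
    fracture_death_proportion: dict[str, AgeSeries]
    fracture_mortality: dict[str, AgeSeries]
    excess_schedule: dict[FractureType, np.ndarray]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, MortalityTables)
            and self.life_q6 == other.life_q6
            and self.fracture_death_proportion == other.fracture_death_proportion
            and self.fracture_mortality == other.fracture_mortality
            and set(self.excess_schedule) == set(other.excess_schedule)
            and all(
                np.array_equal(self.excess_schedule[k], other.excess_schedule[k])
                for k in self.excess_schedule
            )
        )

    def validate(self) -> list[str]:
        errs = []
        for name, group in (
            ("life_q6", self.life_q6),
            ("fracture_death_proportion", self.fracture_death_proportion),
            ("fracture_mortality", self.fracture_mortality),
        ):
            for gender in GENDERS:
                if gender not in group:
                    errs.append(f"mortality table {name} missing gender {gender}")
                    continue
                v = group[gender].values
                if np.any((v < 0) | (v > 1)):
                    errs.append(f"mortality table {name}[{gender}] outside [0,1]")
        for gender in GENDERS:
            if gender in self.fracture_death_proportion and np.any(
                self.fracture_death_proportion[gender].values >= 1
            ):
                errs.append(f"fracture_death_proportion[{gender}] must be < 1")
        for ftype in (FractureType.HIP, FractureType.VERTEBRAL):
            sched = self.excess_schedule.get(ftype)
            if sched is None or len(sched) == 0:
                errs.append(f"excess_schedule missing for {ftype.value}")
                continue
            sched = np.asarray(sched, dtype=float)
            if np.any(sched < 1):
                errs.append(f"excess_schedule[{ftype.value}] has multiplier < 1")
            if np.any(np.diff(sched) > 0):
                errs.append(f"excess_schedule[{ftype.value}] not non-increasing")
            if sched[-1] != 1.0:
                errs.append(f"excess_schedule[{ftype.value}] must reach 1 at phase-out")
        return errs


@dataclass
class UtilityTable:
    """Base utilities by age and multiplicative fracture utility multipliers.

    ``first_year`` applies for the two cycles from the fracture event,
    ``subsequent`` thereafter for life.  A repeat fracture of the same type
    re-applies the first-year multiplier combined with a proportion
    ``repeat_q`` of the subsequent disutility of the earlier fracture.
    """

    base: dict[str, AgeSeries]  # keyed by gender, or "all" as fallback
    first_year: dict[FractureType, float]
    subsequent: dict[FractureType, float]
    repeat_q: float = 0.25
    repeat_rule: str = "multiplicative"  # or "literal"

    def base_series(self, gender: str) -> AgeSeries:
        return self.base.get(gender, self.base["all"]) if "all" in self.base or gender in self.base \
            else self.base[next(iter(self.base))]

    def validate(self) -> list[str]:
        errs = []
        if not self.base:
            errs.append("utility table has no base series")
        for key, s in self.base.items():
            if np.any((s.values <= 0) | (s.values > 1)):
                errs.append(f"base utility[{key}] outside (0,1]")
        for ftype in FRACTURE_TYPES:
            if ftype not in self.first_year or ftype not in self.subsequent:
                errs.append(f"utility multipliers missing for {ftype.value}")
                continue
            fy, sub = self.first_year[ftype], self.subsequent[ftype]
            for name, v in (("first_year", fy), ("subsequent", sub)):
                if not 0 < v <= 1:
                    errs.append(f"utility {name}[{ftype.value}] outside (0,1]: {v}")
            if fy > sub:
                errs.append(f"utility first_year[{ftype.value}] > subsequent[{ftype.value}]")
        if not 0 <= self.repeat_q <= 1:
            errs.append(f"repeat_q outside [0,1]: {self.repeat_q}")
        if self.repeat_rule not in ("multiplicative", "literal"):
            errs.append(f"unknown repeat_rule {self.repeat_rule!r}")
        return errs


@dataclass
class DiscontinuationCurve:
    """Per-arm probability of remaining on treatment at cycle boundaries.

    ``remaining[arm][k]`` is the probability of still being on treatment
    during treated cycle ``k+1`` (index 0 is 1.0: everyone starts).
    """

    remaining: dict[str, np.ndarray]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, DiscontinuationCurve)
            and set(self.remaining) == set(other.remaining)
            and all(
                np.array_equal(self.remaining[k], other.remaining[k]) for k in self.remaining
            )
        )

    def validate(self, treat_cycles: int) -> list[str]:
        errs = []
        for arm in ("teriparatide", "bisphosphonate"):
            if arm not in self.remaining:
                errs.append(f"discontinuation curve missing arm {arm}")
                continue
            curve = np.asarray(self.remaining[arm], dtype=float)
            if len(curve) < treat_cycles:
                errs.append(
                    f"discontinuation curve[{arm}] shorter than treatment duration "
                    f"({len(curve)} < {treat_cycles})"
                )
            if len(curve) and curve[0] != 1.0:
                errs.append(f"discontinuation curve[{arm}] must start at 1.0")
            if np.any((curve < 0) | (curve > 1)):
                errs.append(f"discontinuation curve[{arm}] outside [0,1]")
            if np.any(np.diff(curve) > 0):
                errs.append(f"discontinuation curve[{arm}] not non-increasing")
        return errs


@dataclass
class ParameterSet:
    """The full calibrated bundle driving one model configuration."""

    risk_table: RiskTable
    male_female_ratio: dict[FractureType, AgeSeries]
    bmd_gradient: dict[FractureType, float]  # RR per SD of BMD below age mean
    mean_t_score: dict[str, AgeSeries]
    giop_rr: dict[FractureType, AgeSeries]
    fracture_after_fracture_rr: dict[FractureType, float]
    second_fracture_increase: dict[str, float] = field(
        default_factory=lambda: {"GIOP": 0.5, "PMO": 1.0}
    )
    history_window_years: float = 5.0
    efficacy: dict[str, EfficacyProfile] = field(default_factory=dict)
    cost_table: CostTable = None  # type: ignore[assignment]
    mortality: MortalityTables = None  # type: ignore[assignment]
    utility: UtilityTable = None  # type: ignore[assignment]
    discontinuation: DiscontinuationCurve = None  # type: ignore[assignment]
    discount_rate_costs: float = 0.03
    discount_rate_effects: float = 0.03
    sek_per_eur: float = 9.0335
    cycle_length_months: float = 6.0
    treatment_duration_months: float = 18.0
    hazard_composition: str = "probability"  # or "rate"
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def treatment_cycles(self) -> int:
        return int(round(self.treatment_duration_months / self.cycle_length_months))

    @property
    def history_window_cycles(self) -> int:
        return int(round(self.history_window_years * 12 / self.cycle_length_months))

    def has_placeholders(self) -> bool:
        return any(v == "placeholder" for v in self.provenance.values())

    def placeholder_tables(self) -> list[str]:
        return sorted(k for k, v in self.provenance.items() if v == "placeholder")

    def validate(self) -> None:
        errs: list[str] = []
        errs += self.risk_table.validate()
        for ftype in FRACTURE_TYPES:
            if ftype not in self.male_female_ratio:
                errs.append(f"male_female_ratio missing {ftype.value}")
            elif np.any(self.male_female_ratio[ftype].values <= 0):
                errs.append(f"male_female_ratio[{ftype.value}] must be positive")
            g = self.bmd_gradient.get(ftype)
            if g is None or not np.isfinite(g) or g <= 1:
                errs.append(f"bmd_gradient[{ftype.value}] must be > 1, got {g}")
            if ftype not in self.giop_rr:
                errs.append(f"giop_rr missing {ftype.value}")
            elif np.any(self.giop_rr[ftype].values <= 0):
                errs.append(f"giop_rr[{ftype.value}] must be positive")
            r = self.fracture_after_fracture_rr.get(ftype)
            if r is None or r <= 0:
                errs.append(f"fracture_after_fracture_rr[{ftype.value}] must be positive")
        for gender in GENDERS:
            if gender not in self.mean_t_score:
                errs.append(f"mean_t_score missing gender {gender}")
        for disease in ("PMO", "GIOP"):
            s = self.second_fracture_increase.get(disease)
            if s is None or s < 0:
                errs.append(f"second_fracture_increase[{disease}] must be >= 0")
        for arm in ("teriparatide", "bisphosphonate"):
            profile = self.efficacy.get(arm)
            if not profile:
                errs.append(f"efficacy profile missing for arm {arm}")
                continue
            for ftype in FRACTURE_TYPES:
                if ftype not in profile:
                    errs.append(f"efficacy[{arm}] missing {ftype.value}")
                else:
                    errs += profile[ftype].validate(f"efficacy[{arm}][{ftype.value}]")
        if self.cost_table is None:
            errs.append("cost_table missing")
        else:
            errs += self.cost_table.validate()
        if self.mortality is None:
            errs.append("mortality tables missing")
        else:
            errs += self.mortality.validate()
        if self.utility is None:
            errs.append("utility table missing")
        else:
            errs += self.utility.validate()
        if self.discontinuation is None:
            errs.append("discontinuation curve missing")
        else:
            errs += self.discontinuation.validate(self.treatment_cycles)
        for name in ("discount_rate_costs", "discount_rate_effects"):
            if getattr(self, name) < 0:
                errs.append(f"{name} negative")
        if self.sek_per_eur <= 0:
            errs.append("sek_per_eur must be positive")
        if self.cycle_length_months <= 0:
            errs.append("cycle_length_months must be positive")
        if self.hazard_composition not in ("probability", "rate"):
            errs.append(f"unknown hazard_composition {self.hazard_composition!r}")
        if errs:
            raise ValidationError("parameter bundle invalid:\n  " + "\n  ".join(errs))


# ---------------------------------------------------------------------------
# currency conversion
# ---------------------------------------------------------------------------


def convert_sek_to_eur(
    amount_sek: float, rate: float = 9.0335, round_to: str | None = "cents"
) -> float:
    """Convert Swedish kronor to euros at ``rate`` SEK per euro.

    ``round_to`` controls the rounding policy: ``"cents"`` (default, used for
    daily drug costs), ``"euros"`` (whole euros, used for visit prices) or
    ``None`` for no rounding.
    """
    if rate <= 0:
        raise ValueError(f"exchange rate must be positive, got {rate}")
    eur = amount_sek / rate
    if round_to == "cents":
        return round(eur, 2)
    if round_to == "euros":
        return float(round(eur))
    if round_to is None:
        return eur
    raise ValueError(f"unknown rounding policy {round_to!r}")


# ---------------------------------------------------------------------------
# placeholder table generation
# ---------------------------------------------------------------------------


def generate_placeholder_series(
    anchors: Mapping[float, float],
    grid: Sequence[float],
    seed: int = 0,
    jitter: float = 0.0,
    increasing: bool | None = None,
) -> AgeSeries:
    """Interpolate coarse anchors onto an age grid, monotone-preserving.

    Stands in for age-resolved tables whose exact published values are not
    available in the body text.  Anchors must already follow the declared
    trend (``increasing=True/False``; ``None`` skips the check).  Values at
    anchor ages are reproduced exactly.  ``jitter`` adds a seeded relative
    perturbation to non-anchor grid points, clipped so the anchor trend is
    preserved; the output is bit-identical for identical inputs and seed.
    """
    ages = np.asarray(sorted(anchors), dtype=float)
    vals = np.asarray([anchors[a] for a in ages], dtype=float)
    if increasing is True and np.any(np.diff(vals) < 0):
        raise ValueError("anchors violate declared increasing trend")
    if increasing is False and np.any(np.diff(vals) > 0):
        raise ValueError("anchors violate declared decreasing trend")
    grid = np.asarray(grid, dtype=float)
    if len(ages) == 1:
        out = np.full_like(grid, vals[0])
    else:
        interp = PchipInterpolator(ages, vals, extrapolate=False)
        out = interp(np.clip(grid, ages[0], ages[-1]))
    if jitter > 0:
        rng = np.random.default_rng(seed)
        noise = 1.0 + jitter * (rng.random(len(grid)) - 0.5)
        is_anchor = np.isin(grid, ages)
        perturbed = np.where(is_anchor, out, out * noise)
        if increasing is True:
            perturbed = np.maximum.accumulate(perturbed)
        elif increasing is False:
            perturbed = np.minimum.accumulate(perturbed)
        out = np.where(is_anchor, out, perturbed)
    return AgeSeries(grid, out)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

SCHEMA_VERSION = 1

_TABLE_FILES = {
    "baseline_risks": "baseline_risks.csv",
    "male_female_ratio": "male_female_ratio.csv",
    "mean_t_score": "mean_t_score.csv",
    "giop_rr": "giop_rr.csv",
    "life_table": "life_table.csv",
    "fracture_death_proportion": "fracture_death_proportion.csv",
    "fracture_mortality": "fracture_mortality.csv",
    "fracture_costs": "fracture_costs.csv",
    "base_utilities": "base_utilities.csv",
}


def save_parameter_set(params: ParameterSet, path: str | Path) -> None:
    """Write a ParameterSet to a directory as a YAML config plus CSV tables."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    def _series_frame(rows: Iterable[tuple]) -> pd.DataFrame:
        return pd.DataFrame(rows)

    rows = []
    for (gender, ftype), s in sorted(
        params.risk_table.series.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        for age, v in zip(s.ages, s.values):
            rows.append({"gender": gender, "fracture_type": ftype.value, "age": age, "annual_risk": v})
    pd.DataFrame(rows).to_csv(path / _TABLE_FILES["baseline_risks"], index=False, float_format="%.17g")

    rows = []
    for ftype in FRACTURE_TYPES:
        s = params.male_female_ratio[ftype]
        for age, v in zip(s.ages, s.values):
            rows.append({"fracture_type": ftype.value, "age": age, "ratio": v})
    pd.DataFrame(rows).to_csv(path / _TABLE_FILES["male_female_ratio"], index=False, float_format="%.17g")

    rows = []
    for gender in GENDERS:
        s = params.mean_t_score[gender]
        for age, v in zip(s.ages, s.values):
            rows.append({"gender": gender, "age": age, "mean_t_score": v})
    pd.DataFrame(rows).to_csv(path / _TABLE_FILES["mean_t_score"], index=False, float_format="%.17g")

    rows = []
    for ftype in FRACTURE_TYPES:
        s = params.giop_rr[ftype]
        for age, v in zip(s.ages, s.values):
            rows.append({"fracture_type": ftype.value, "age": age, "rr": v})
    pd.DataFrame(rows).to_csv(path / _TABLE_FILES["giop_rr"], index=False, float_format="%.17g")

    for name, group in (
        ("life_table", params.mortality.life_q6),
        ("fracture_death_proportion", params.mortality.fracture_death_proportion),
        ("fracture_mortality", params.mortality.fracture_mortality),
    ):
        rows = []
        for gender in GENDERS:
            s = group[gender]
            for age, v in zip(s.ages, s.values):
                rows.append({"gender": gender, "age": age, "q6": v})
        pd.DataFrame(rows).to_csv(path / _TABLE_FILES[name], index=False, float_format="%.17g")

    rows = []
    for ftype in FRACTURE_TYPES:
        a, c = params.cost_table.acute[ftype], params.cost_table.continuing[ftype]
        for lo, v in zip(a.lower_bounds, a.values):
            rows.append({"fracture_type": ftype.value, "age_band_lower": lo, "kind": "acute", "cost_eur": v})
        for lo, v in zip(c.lower_bounds, c.values):
            rows.append({"fracture_type": ftype.value, "age_band_lower": lo, "kind": "continuing", "cost_eur": v})
    pd.DataFrame(rows).to_csv(path / _TABLE_FILES["fracture_costs"], index=False, float_format="%.17g")

    rows = []
    for key, s in params.utility.base.items():
        for age, v in zip(s.ages, s.values):
            rows.append({"gender": key, "age": age, "utility": v})
    pd.DataFrame(rows).to_csv(path / _TABLE_FILES["base_utilities"], index=False, float_format="%.17g")

    cfg = {
        "schema_version": SCHEMA_VERSION,
        "scalars": {
            "discount_rate_costs": params.discount_rate_costs,
            "discount_rate_effects": params.discount_rate_effects,
            "sek_per_eur": params.sek_per_eur,
            "cycle_length_months": params.cycle_length_months,
            "treatment_duration_months": params.treatment_duration_months,
            "history_window_years": params.history_window_years,
            "hazard_composition": params.hazard_composition,
            "days_per_cycle": params.cost_table.days_per_cycle,
        },
        "second_fracture_increase": dict(params.second_fracture_increase),
        "bmd_gradient": {ft.value: params.bmd_gradient[ft] for ft in FRACTURE_TYPES},
        "fracture_after_fracture_rr": {
            ft.value: params.fracture_after_fracture_rr[ft] for ft in FRACTURE_TYPES
        },
        "efficacy": {
            arm: {
                ft.value: dataclasses.asdict(tl) for ft, tl in profile.items()
            }
            for arm, profile in params.efficacy.items()
        },
        "drug_daily_eur": dict(params.cost_table.drug_daily),
        "visit_basic_eur": params.cost_table.visit_basic_eur,
        "visit_bmd_eur": params.cost_table.visit_bmd_eur,
        "excess_schedule": {
            ft.value: [float(x) for x in params.mortality.excess_schedule[ft]]
            for ft in params.mortality.excess_schedule
        },
        "discontinuation": {
            arm: [float(x) for x in curve] for arm, curve in params.discontinuation.remaining.items()
        },
        "utility_multipliers": {
            "first_year": {ft.value: params.utility.first_year[ft] for ft in FRACTURE_TYPES},
            "subsequent": {ft.value: params.utility.subsequent[ft] for ft in FRACTURE_TYPES},
            "repeat_q": params.utility.repeat_q,
            "repeat_rule": params.utility.repeat_rule,
        },
        "provenance": dict(params.provenance),
    }
    with open(path / "params.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def load_parameter_set(path: str | Path) -> ParameterSet:
    """Load and validate a parameter bundle from a directory.

    Raises :class:`FileNotFoundError` naming any missing table and
    :class:`ValidationError` with a named-field report on invariant
    violations.
    """
    path = Path(path)
    cfg_path = path / "params.yaml"
    if not cfg_path.exists():
        raise FileNotFoundError(f"missing config file: {cfg_path}")
    with open(cfg_path) as fh:
        cfg = yaml.safe_load(fh)
    for name, fname in _TABLE_FILES.items():
        if not (path / fname).exists():
            raise FileNotFoundError(f"missing table {name!r}: expected file {path / fname}")

    def read(name: str) -> pd.DataFrame:
        return pd.read_csv(path / _TABLE_FILES[name], float_precision="round_trip")

    df = read("baseline_risks")
    series: dict[tuple[str, FractureType], AgeSeries] = {}
    for (gender, ft), grp in df.groupby(["gender", "fracture_type"]):
        grp = grp.sort_values("age")
        series[(gender, FractureType(ft))] = AgeSeries(
            grp["age"].to_numpy(), grp["annual_risk"].to_numpy()
        )
    risk_table = RiskTable(series)

    df = read("male_female_ratio")
    ratio = {
        FractureType(ft): AgeSeries(g.sort_values("age")["age"].to_numpy(), g.sort_values("age")["ratio"].to_numpy())
        for ft, g in df.groupby("fracture_type")
    }

    # impute male risk series from female where a bundle ships only female rows
    for ftype in FRACTURE_TYPES:
        if ("male", ftype) not in risk_table.series and ("female", ftype) in risk_table.series:
            fem = risk_table.series[("female", ftype)]
            r = ratio[ftype].at(fem.ages)
            risk_table.series[("male", ftype)] = AgeSeries(
                fem.ages.copy(), np.minimum(fem.values * r, 1.0)
            )

    df = read("mean_t_score")
    mean_t = {
        g: AgeSeries(grp.sort_values("age")["age"].to_numpy(), grp.sort_values("age")["mean_t_score"].to_numpy())
        for g, grp in df.groupby("gender")
    }

    df = read("giop_rr")
    giop = {
        FractureType(ft): AgeSeries(g.sort_values("age")["age"].to_numpy(), g.sort_values("age")["rr"].to_numpy())
        for ft, g in df.groupby("fracture_type")
    }

    def read_mort(name: str) -> dict[str, AgeSeries]:
        df = read(name)
        return {
            g: AgeSeries(grp.sort_values("age")["age"].to_numpy(), grp.sort_values("age")["q6"].to_numpy())
            for g, grp in df.groupby("gender")
        }

    mortality = MortalityTables(
        life_q6=read_mort("life_table"),
        fracture_death_proportion=read_mort("fracture_death_proportion"),
        fracture_mortality=read_mort("fracture_mortality"),
        excess_schedule={
            FractureType(ft): np.asarray(v, dtype=float)
            for ft, v in cfg["excess_schedule"].items()
        },
    )

    df = read("fracture_costs")
    acute, continuing = {}, {}
    for (ft, kind), grp in df.groupby(["fracture_type", "kind"]):
        grp = grp.sort_values("age_band_lower")
        s = StepSeries(grp["age_band_lower"].to_numpy(), grp["cost_eur"].to_numpy())
        (acute if kind == "acute" else continuing)[FractureType(ft)] = s
    cost_table = CostTable(
        acute=acute,
        continuing=continuing,
        drug_daily={k: float(v) for k, v in cfg["drug_daily_eur"].items()},
        visit_basic_eur=float(cfg["visit_basic_eur"]),
        visit_bmd_eur=float(cfg["visit_bmd_eur"]),
        days_per_cycle=float(cfg["scalars"].get("days_per_cycle", 182.625)),
    )

    df = read("base_utilities")
    base = {
        g: AgeSeries(grp.sort_values("age")["age"].to_numpy(), grp.sort_values("age")["utility"].to_numpy())
        for g, grp in df.groupby("gender")
    }
    um = cfg["utility_multipliers"]
    utility = UtilityTable(
        base=base,
        first_year={FractureType(k): float(v) for k, v in um["first_year"].items()},
        subsequent={FractureType(k): float(v) for k, v in um["subsequent"].items()},
        repeat_q=float(um.get("repeat_q", 0.25)),
        repeat_rule=um.get("repeat_rule", "multiplicative"),
    )

    efficacy = {
        arm: {
            FractureType(ft): EfficacyTimeline(**tl) for ft, tl in profile.items()
        }
        for arm, profile in cfg["efficacy"].items()
    }

    sc = cfg["scalars"]
    params = ParameterSet(
        risk_table=risk_table,
        male_female_ratio=ratio,
        bmd_gradient={FractureType(k): float(v) for k, v in cfg["bmd_gradient"].items()},
        mean_t_score=mean_t,
        giop_rr=giop,
        fracture_after_fracture_rr={
            FractureType(k): float(v) for k, v in cfg["fracture_after_fracture_rr"].items()
        },
        second_fracture_increase={k: float(v) for k, v in cfg["second_fracture_increase"].items()},
        history_window_years=float(sc["history_window_years"]),
        efficacy=efficacy,
        cost_table=cost_table,
        mortality=mortality,
        utility=utility,
        discontinuation=DiscontinuationCurve(
            {arm: np.asarray(v, dtype=float) for arm, v in cfg["discontinuation"].items()}
        ),
        discount_rate_costs=float(sc["discount_rate_costs"]),
        discount_rate_effects=float(sc["discount_rate_effects"]),
        sek_per_eur=float(sc["sek_per_eur"]),
        cycle_length_months=float(sc["cycle_length_months"]),
        treatment_duration_months=float(sc["treatment_duration_months"]),
        hazard_composition=sc.get("hazard_composition", "probability"),
        provenance={str(k): str(v) for k, v in cfg.get("provenance", {}).items()},
    )
    params.validate()
    return params


def default_parameter_set() -> ParameterSet:
    """The packaged default bundle (printed values + flagged placeholders)."""
    from importlib.resources import files

    return load_parameter_set(Path(str(files("osteosim") / "data" / "default")))


# ---------------------------------------------------------------------------
# canonical cohorts
# ---------------------------------------------------------------------------


def _history_2fx() -> tuple[tuple[FractureType, float], ...]:
    return ((FractureType.VERTEBRAL, 60.0), (FractureType.VERTEBRAL, 6.0))


def _history_1fx() -> tuple[tuple[FractureType, float], ...]:
    return ((FractureType.VERTEBRAL, 6.0),)


COHORTS: dict[str, CohortSpec] = {
    "pmo_2fx": CohortSpec("pmo_2fx", "PMO", 69.0, 1.0, -3.0, _history_2fx()),
    "pmo_1fx": CohortSpec("pmo_1fx", "PMO", 69.0, 1.0, -3.0, _history_1fx()),
    "giop_2fx": CohortSpec("giop_2fx", "GIOP", 69.0, 0.8, -2.5, _history_2fx()),
    "giop_1fx": CohortSpec("giop_1fx", "GIOP", 69.0, 0.8, -2.5, _history_1fx()),
}
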