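"""Shared fixtures: the packaged default bundle and a hand-computable toy
bundle with flat tables so every expected value can be derived by pencil."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from osteosim._defaults import build_default_parameter_set

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from osteosim.parameters import (
    AgeSeries,
    CohortSpec,
    CostTable,
    DiscontinuationCurve,
    EfficacyTimeline,
    FractureType,
    MortalityTables,
    ParameterSet,
    RiskTable,
    StepSeries,
    UtilityTable,
)

HIP, VERT, WRIST = FractureType.HIP, FractureType.VERTEBRAL, FractureType.WRIST
FTYPES = (HIP, VERT, WRIST)


@pytest.fixture(scope="session")
def default_params() -> ParameterSet:
    return build_default_parameter_set()


def make_toy_params(
    annual_risk: float = 0.04,
    q6: float = 0.02,
    pfx: float = 0.1,
    fxmort: float = 0.01,
    acute=(1000.0, 400.0, 200.0),
    continuing=(100.0, 10.0, 0.0),
    base_utility: float = 0.8,
    disc_curve=(1.0, 1.0, 1.0),
    giop_rr: float = 2.0,
    faf_rr=(2.0, 2.0, 1.5),
) -> ParameterSet:
    """A flat-table bundle: every age-dependent quantity is constant, so
    per-cycle probabilities and accruals can be recomputed by hand."""
    ages = np.array([50.0, 105.0])
    flat = lambda v: AgeSeries(ages.copy(), np.array([v, v], dtype=float))
    step = lambda v: StepSeries(np.array([50.0]), np.array([float(v)]))

    risk = RiskTable(
        {(g, ft): flat(annual_risk) for g in ("female", "male") for ft in FTYPES}
    )
    params = ParameterSet(
        risk_table=risk,
        male_female_ratio={ft: flat(1.0) for ft in FTYPES},
        bmd_gradient={HIP: 2.6, VERT: 1.8, WRIST: 1.4},
        mean_t_score={"female": flat(0.0), "male": flat(0.0)},
        giop_rr={ft: flat(giop_rr) for ft in FTYPES},
        fracture_after_fracture_rr=dict(zip(FTYPES, faf_rr)),
        efficacy={
            "teriparatide": {
                VERT: EfficacyTimeline(0.17, 0.43, 18.0, 18.0),
                HIP: EfficacyTimeline(0.47, 0.73, 30.0, 18.0),
                WRIST: EfficacyTimeline(0.47, 0.73, 30.0, 18.0),
            },
            "bisphosphonate": {
                ft: EfficacyTimeline(0.6, 0.6, 0.0, 18.0) for ft in FTYPES
            },
        },
        cost_table=CostTable(
            acute=dict(zip(FTYPES, map(step, acute))),
            continuing=dict(zip(FTYPES, map(step, continuing))),
            drug_daily={"teriparatide": 14.74, "bisphosphonate": 0.42, "none": 0.0},
            visit_basic_eur=194.0,
            visit_bmd_eur=201.0,
        ),
        mortality=MortalityTables(
            life_q6={g: flat(q6) for g in ("female", "male")},
            fracture_death_proportion={g: flat(pfx) for g in ("female", "male")},
            fracture_mortality={g: flat(fxmort) for g in ("female", "male")},
            excess_schedule={
                HIP: np.linspace(2.5, 1.0, 7),
                VERT: np.linspace(2.5, 1.0, 6),
            },
        ),
        utility=UtilityTable(
            base={"all": flat(base_utility)},
            first_year={HIP: 0.697, VERT: 0.626, WRIST: 0.977},
            subsequent={HIP: 0.813, VERT: 0.909, WRIST: 0.999},
        ),
        discontinuation=DiscontinuationCurve(
            {
                "teriparatide": np.asarray(disc_curve, dtype=float),
                "bisphosphonate": np.asarray(disc_curve, dtype=float),
            }
        ),
    )
    params.validate()
    return params


@pytest.fixture
def toy_params() -> ParameterSet:
    return make_toy_params()


@pytest.fixture
def pmo_cohort() -> CohortSpec:
    return CohortSpec("toy_pmo", "PMO", 69.0, 1.0, 0.0)


class ScriptedRNG:
    """Replays a fixed sequence of uniforms; pads with a safe filler."""

    def __init__(self, values, fill: float = 0.999):
        self.values = list(values)
        self.fill = fill
        self.pos = 0

    def random(self, size=None):
        if size is None:
            return self._next()
        shape = (size,) if isinstance(size, int) else tuple(size)
        n = int(np.prod(shape))
        out = np.array([self._next() for _ in range(n)]).reshape(shape)
        return out

    def _next(self) -> float:
        if self.pos < len(self.values):
            v = self.values[self.pos]
            self.pos += 1
            return v
        return self.fill
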