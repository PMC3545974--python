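"""Per-cycle death probabilities and within-cycle death timing.

Natural mortality is the all-cause life-table probability with the
fracture-attributable share of deaths removed (avoiding double counting).
Excess fracture mortality applies after hip and clinical vertebral fractures
only, as the base fracture-death probability scaled by (multiplier - 1),
where the multiplier is read off a years-since-fracture schedule that phases
out to 1 (7 years for hip, 6 for vertebral); with both sites in history the
larger multiplier wins.  Natural deaths fall at mid-cycle (half-cycle
accrual of costs and utility), excess deaths at the cycle start (none).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .fracture_model import FractureEvent
from .parameters import FractureType, MortalityTables


def natural_death_probability(age: float, gender: str, tables: MortalityTables) -> float:
    """6-month natural (non-fracture) death probability at ``age``."""
    if gender not in tables.life_q6:
        raise KeyError(f"life table has no series for gender {gender!r}")
    q = float(tables.life_q6[gender].at(age))
    p_fx = float(tables.fracture_death_proportion[gender].at(age))
    return q * (1.0 - p_fx)


def excess_mortality_multiplier(
    history: Sequence[FractureEvent], now: int, tables: MortalityTables
) -> float:
    """Largest applicable excess-mortality multiplier at cycle ``now`` (>= 1)."""
    best = 1.0
    for ev in history:
        sched = tables.excess_schedule.get(ev.ftype)
        if sched is None:
            continue  # wrist and other sites carry no excess mortality
        d = now - ev.cycle_index
        if d < 1:
            continue
        year = (d + 1) // 2  # cycles 1-2 after the event are year 1, etc.
        if year <= len(sched):
            best = max(best, float(sched[year - 1]))
    return best


def excess_death_probability(
    history: Sequence[FractureEvent],
    age: float,
    gender: str,
    now: int,
    tables: MortalityTables,
) -> float:
    """6-month fracture-excess death probability at cycle ``now``.

    Zero for wrist-only histories and beyond the phase-out horizon; otherwise
    the base fracture-death probability for (age, gender) times
    (multiplier - 1).
    """
    mult = excess_mortality_multiplier(history, now, tables)
    if mult <= 1.0:
        return 0.0
    base = float(tables.fracture_mortality[gender].at(age))
    return min(1.0, base * (mult - 1.0))


def death_timing(kind: str) -> float:
    """Within-cycle accrual fraction for a death of the given kind.

    Natural deaths occur mid-cycle (0.5), fracture-excess deaths at the
    cycle start (0.0); a survivor accrues the full cycle (1.0).
    """
    if kind == "natural":
        return 0.5
    if kind == "fracture_excess":
        return 0.0
    if kind in ("none", "survivor"):
        return 1.0
    raise ValueError(f"unknown death kind {kind!r}")


def life_table_expected_years(
    start_age: float,
    gender: str,
    tables: MortalityTables,
    age_cap: float = 100.0,
    natural_only: bool = True,
) -> float:
    """Closed-form expected life years under the cycle conventions.

    Sums, over 6-month cycles until the age cap, the survival probability at
    cycle start times the expected within-cycle accrual (0.5 years if the
    patient survives the cycle, 0.25 if a mid-cycle natural death occurs).
    Serves as the analytic oracle for fracture-free simulation runs.
    """
    n_cycles = int(round((age_cap - start_age) * 2))
    alive = 1.0
    total = 0.0
    for k in range(n_cycles):
        age = start_age + 0.5 * k
        q = natural_death_probability(age, gender, tables) if natural_only else float(
            tables.life_q6[gender].at(age)
        )
        total += alive * ((1.0 - q) * 0.5 + q * 0.25)
        alive *= 1.0 - q
    return total
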