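"""Cost accrual and discounting.

Costs fall into drug acquisition (daily price times days in a treated
cycle), monitoring (one physician visit per treated cycle, at the
BMD-inclusive price in treated cycles 1, 3, 5, ... and the basic price
otherwise), acute fracture costs (first cycle after an event, accrued in
full even in a death cycle since the fracture precedes death in event
order), and continuing fracture costs (every later cycle for life, with a
supersession rule so repeat fractures of a site never double-count
long-term care: the site's continuing entry is the maximum of old and new).
Discounting is per cycle at 3%/year on both costs and effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .fracture_model import FractureEvent
from .parameters import CostTable, FractureType, ParameterSet


@dataclass
class CycleLedger:
    """Undiscounted accruals for one patient in one cycle.

    ``accrual_fraction`` is 1 for a survived cycle, 0.5 for a mid-cycle
    natural death, 0 for a start-of-cycle excess death; ``life_years`` is
    always ``0.5 * accrual_fraction``.
    """

    cycle_index: int
    cost_drug: float = 0.0
    cost_monitoring: float = 0.0
    cost_fracture_acute: float = 0.0
    cost_fracture_continuing: float = 0.0
    utility: float = 0.0
    accrual_fraction: float = 1.0

    @property
    def life_years(self) -> float:
        return 0.5 * self.accrual_fraction

    @property
    def total_cost(self) -> float:
        return (
            self.cost_drug
            + self.cost_monitoring
            + self.cost_fracture_acute
            + self.cost_fracture_continuing
        )


def discount_factor(cycle_index: int, annual_rate: float) -> float:
    """Discount factor at the start of a 6-month cycle (cycle 0 -> 1.0)."""
    if annual_rate < 0:
        raise ValueError("discount rate must be >= 0")
    return float((1.0 + annual_rate) ** (-0.5 * cycle_index))


def treatment_cycle_costs(
    arm: str,
    cycle_on_treatment: int,
    on_treatment: bool,
    params: ParameterSet,
) -> tuple[float, float]:
    """(drug, monitoring) euros for one cycle.

    ``cycle_on_treatment`` is 1-based.  Adherent patients over an 18-month
    course accrue three visits: BMD-inclusive in treated cycles 1 and 3,
    basic in cycle 2.  Discontinued or untreated patients accrue nothing.
    """
    if not on_treatment or arm == "none":
        return 0.0, 0.0
    if cycle_on_treatment < 1:
        raise ValueError("cycle_on_treatment must be >= 1 while on treatment")
    ct = params.cost_table
    drug = ct.drug_daily[arm] * ct.days_per_cycle
    monitoring = ct.visit_bmd_eur if cycle_on_treatment % 2 == 1 else ct.visit_basic_eur
    return drug, monitoring


def fracture_cycle_costs(
    new_events: Sequence[FractureEvent],
    active_continuing: Mapping[FractureType, float],
    age: float,
    table: CostTable,
) -> tuple[float, float, dict[FractureType, float]]:
    """(acute, continuing, updated continuing map) for one cycle.

    New events pay their acute cost and, for sites with long-term costs,
    update the continuing map to ``max(existing, new)``; wrist never enters
    the map.  Continuing costs accrue for every mapped site without a new
    event this cycle (a new event pays acute only in its first cycle).
    """
    updated = dict(active_continuing)
    new_types = {ev.ftype for ev in new_events}
    acute = 0.0
    for ev in new_events:
        acute += float(table.acute[ev.ftype].at(age))
        cont = float(table.continuing[ev.ftype].at(age))
        if cont > 0.0:
            updated[ev.ftype] = max(updated.get(ev.ftype, 0.0), cont)
    continuing = sum(v for ft, v in updated.items() if ft not in new_types)
    return acute, continuing, updated


def discounted_total_cost(ledgers: Iterable[CycleLedger], annual_rate: float) -> float:
    """Sum of per-cycle total costs discounted at the cycle start."""
    return sum(l.total_cost * discount_factor(l.cycle_index, annual_rate) for l in ledgers)
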