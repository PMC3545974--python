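"""Health utilities and QALY accumulation.

Utility in a cycle is the age-interpolated base utility times one
multiplicative factor per fracture site in the patient's history.  A site
contributes its first-year multiplier for the two cycles from its most
recent event and its subsequent multiplier for life thereafter.  A repeat
fracture of the same site combines the first-year multiplier with a
proportion (default 25%) of the subsequent disutility carried over from the
earlier fracture; two readings of that combination are provided (the
default multiplies the factors, the "literal" variant adds the disutilities).
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .economics import CycleLedger, discount_factor
from .fracture_model import FractureEvent
from .parameters import FractureType, ParameterSet, UtilityTable


def repeat_first_year_multiplier(
    m_first: float, m_subsequent: float, q: float, rule: str = "multiplicative"
) -> float:
    """First-year multiplier for a repeat fracture of the same site.

    ``multiplicative``: ``m_first * (1 - q*(1 - m_subsequent))`` — the
    carried-over share of the old subsequent disutility compounds with the
    new first-year loss.  ``literal``: disutilities add,
    ``1 - [(1 - m_first) + q*(1 - m_subsequent)]`` (floored just above 0).
    """
    if rule == "multiplicative":
        return m_first * (1.0 - q * (1.0 - m_subsequent))
    if rule == "literal":
        return max(1e-9, 1.0 - ((1.0 - m_first) + q * (1.0 - m_subsequent)))
    raise ValueError(f"unknown repeat rule {rule!r}")


def fracture_utility_multiplier(
    events: Sequence[FractureEvent],
    ftype: FractureType,
    cycle: int,
    table: UtilityTable,
) -> float:
    """Current utility multiplier contributed by one fracture site.

    ``events`` may contain any sites and times; only this site's events at or
    before ``cycle`` count.  The first year spans the event cycle and the
    next one.
    """
    cycles = sorted(ev.cycle_index for ev in events if ev.ftype == ftype and ev.cycle_index <= cycle)
    if not cycles:
        return 1.0
    last = cycles[-1]
    m_first = table.first_year[ftype]
    m_sub = table.subsequent[ftype]
    if cycle - last <= 1:
        if len(cycles) >= 2:
            return repeat_first_year_multiplier(m_first, m_sub, table.repeat_q, table.repeat_rule)
        return m_first
    return m_sub


def cycle_utility(
    age: float,
    gender: str,
    new_events: Sequence[FractureEvent],
    history: Sequence[FractureEvent],
    params: ParameterSet | UtilityTable,
    cycle: int = 0,
) -> float:
    """Utility for one cycle: base(age) times the product of site multipliers.

    ``history`` holds events before this cycle (including pre-start events at
    negative cycle indices); ``new_events`` this cycle's fractures.  Fracture
    disutilities persist for life — a prior fracture contributes its
    subsequent multiplier indefinitely.
    """
    table = params.utility if isinstance(params, ParameterSet) else params
    base = float(table.base_series(gender).at(age))
    events = list(history) + list(new_events)
    u = base
    for ftype in table.first_year:
        u *= fracture_utility_multiplier(events, ftype, cycle, table)
    return u


def accumulate_qalys(
    ledgers: Iterable[CycleLedger], rate: float
) -> tuple[float, float]:
    """(discounted QALYs, undiscounted life years) from a cycle ledger.

    Each cycle contributes ``utility * 0.5 * accrual_fraction`` QALYs
    (discounted at the cycle start) and ``0.5 * accrual_fraction``
    undiscounted life years.
    """
    qaly = 0.0
    years = 0.0
    for l in ledgers:
        qaly += l.utility * 0.5 * l.accrual_fraction * discount_factor(l.cycle_index, rate)
        years += 0.5 * l.accrual_fraction
    return qaly, years
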