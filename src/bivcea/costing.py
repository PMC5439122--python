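"""Event-level costing from a healthcare payer perspective.

Each clinical event is valued as inpatient (hospital) cost plus
physician fee, looked up in a :class:`UnitCostTable` (one fee schedule
per table; alternative physician-fee schedules support sensitivity
analysis).  Per-patient costs are accumulated by clinical category —
delivery, maternal complications, neonatal complications — and summed to
a total.  Arithmetic is carried in integer cents so category additivity
is exact; results are reported in dollars.

Protocol-driven research costs are excluded by construction: they have
no event codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CATEGORIES",
    "UnitCost",
    "UnitCostTable",
    "EventList",
    "CostBreakdown",
    "assign_costs",
    "cost_patients",
    "intervention_cost_per_patient",
    "load_unit_cost_tables",
    "write_unit_cost_tables",
]

CATEGORIES = ("delivery", "maternal", "neonatal", "intervention")


def _to_cents(dollars: float, what: str) -> int:
    if dollars < 0:
        raise ValueError(f"{what} must be non-negative, got {dollars}")
    return int(round(dollars * 100))


@dataclass(frozen=True)
class UnitCost:
    category: str
    inpatient_cents: int
    physician_cents: int

    @property
    def total_cents(self) -> int:
        return self.inpatient_cents + self.physician_cents


@dataclass
class UnitCostTable:
    """event_code -> (category, inpatient cost, physician fee) for one schedule."""

    schedule_id: str
    entries: dict = field(default_factory=dict)
    currency_year: str = "2013 CAD"

    def add(
        self,
        event_code: str,
        category: str,
        inpatient_cost: float,
        physician_fee: float,
    ) -> None:
        if category not in CATEGORIES:
            raise ValueError(
                f"unknown category {category!r}; expected one of {CATEGORIES}"
            )
        if event_code in self.entries:
            raise ValueError(
                f"duplicate event code {event_code!r} in schedule {self.schedule_id!r}"
            )
        self.entries[event_code] = UnitCost(
            category,
            _to_cents(inpatient_cost, f"inpatient cost of {event_code!r}"),
            _to_cents(physician_fee, f"physician fee of {event_code!r}"),
        )

    def lookup(self, event_code: str) -> UnitCost:
        try:
            return self.entries[event_code]
        except KeyError:
            raise KeyError(
                f"unknown event code {event_code!r} in schedule {self.schedule_id!r}"
            ) from None


@dataclass
class EventList:
    """Clinical events for one patient: exactly one delivery event plus
    zero or more complication events."""

    patient_id: str
    events: Sequence[str]


@dataclass(frozen=True)
class CostBreakdown:
    delivery_cost: float
    maternal_cost: float
    neonatal_cost: float
    total_cost: float


def assign_costs(events: EventList, table: UnitCostTable) -> CostBreakdown:
    """Value a patient's events under one fee schedule.

    Each category cost is the sum over its events of inpatient cost plus
    physician fee; the total is the sum of the three categories.  Raises
    ``KeyError`` for an unknown event code and ``ValueError`` unless the
    patient has exactly one delivery-category event.
    """
    cents = {"delivery": 0, "maternal": 0, "neonatal": 0}
    n_delivery = 0
    for code in events.events:
        uc = table.lookup(code)
        if uc.category == "intervention":
            raise ValueError(
                f"intervention-delivery costs are amortized per arm, not per "
                f"event (code {code!r})"
            )
        if uc.category == "delivery":
            n_delivery += 1
        cents[uc.category] += uc.total_cents
    if n_delivery != 1:
        raise ValueError(
            f"patient {events.patient_id!r} has {n_delivery} delivery events; "
            "exactly one is required"
        )
    total = sum(cents.values())
    return CostBreakdown(
        cents["delivery"] / 100.0,
        cents["maternal"] / 100.0,
        cents["neonatal"] / 100.0,
        total / 100.0,
    )


def cost_patients(
    event_lists: Iterable[EventList], table: UnitCostTable
) -> pd.DataFrame:
    """Vectorized convenience: one :func:`assign_costs` row per patient."""
    rows = []
    for ev in event_lists:
        b = assign_costs(ev, table)
        rows.append(
            {
                "patient_id": ev.patient_id,
                "delivery_cost": b.delivery_cost,
                "maternal_cost": b.maternal_cost,
                "neonatal_cost": b.neonatal_cost,
                "total_cost": b.total_cost,
            }
        )
    return pd.DataFrame(rows)


def intervention_cost_per_patient(
    total_program_cost: float, n_intervention_patients: int
) -> float:
    """Amortize the program's delivery cost uniformly over the
    intervention-arm post-period patients."""
    if n_intervention_patients <= 0:
        raise ValueError("n_intervention_patients must be > 0")
    if total_program_cost < 0:
        raise ValueError("total_program_cost must be >= 0")
    return total_program_cost / n_intervention_patients


def load_unit_cost_tables(path) -> Mapping[str, UnitCostTable]:
    """Read schedules from delimited text with columns
    schedule_id, event_code, category, inpatient_cost, physician_fee."""
    df = pd.read_csv(path)
    required = {"schedule_id", "event_code", "category", "inpatient_cost", "physician_fee"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"unit-cost table missing columns: {sorted(missing)}")
    tables: dict[str, UnitCostTable] = {}
    for row in df.itertuples(index=False):
        tab = tables.setdefault(str(row.schedule_id), UnitCostTable(str(row.schedule_id)))
        tab.add(str(row.event_code), str(row.category), float(row.inpatient_cost), float(row.physician_fee))
    return tables


def write_unit_cost_tables(tables: Mapping[str, UnitCostTable], path) -> None:
    rows = []
    for tab in tables.values():
        for code, uc in tab.entries.items():
            rows.append(
                {
                    "schedule_id": tab.schedule_id,
                    "event_code": code,
                    "category": uc.category,
                    "inpatient_cost": uc.inpatient_cents / 100.0,
                    "physician_fee": uc.physician_cents / 100.0,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
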