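"""Health-system treatment costs and household formula affordability.

Attributable cases flow through the care-seeking cascade (taken to a
facility → inpatient vs outpatient → facility-level mix) and are priced with
facility-level unit costs per outpatient visit and inpatient bed day.
Type II diabetes treatment is priced per diagnosed case-year.  The cascade
conserves cases: outpatient + inpatient = cases x pct_taken_to_facility.
"""

from __future__ import annotations

from dataclasses import dataclass

from .burden import PathwayBurden
from .domain import CareSeeking, CountryProfile, UnitCosts


@dataclass
class TreatmentCost:
    pathway: str
    outpatient_cases: float
    inpatient_cases: float
    outpatient_cost: float
    inpatient_cost: float

    @property
    def total_cost(self) -> float:
        return self.outpatient_cost + self.inpatient_cost


def inflate_unit_cost(cost: float, cpi_multiplier: float) -> float:
    """Adjust a unit cost by a cumulative country CPI multiplier."""
    if cpi_multiplier <= 0:
        raise ValueError(f"CPI multiplier must be > 0, got {cpi_multiplier!r}")
    return cost * cpi_multiplier


def child_treatment_cost(
    burden: PathwayBurden,
    cascade: CareSeeking,
    costs: UnitCosts,
    cpi_multiplier: float = 1.0,
) -> TreatmentCost | None:
    """Treatment cost of one child pathway's attributable cases.

    Unit costs are CPI-inflated before use.  Returns ``None`` when a facility
    level carries nonzero mix weight but has no unit cost, or when the burden
    itself was not computed.
    """
    if burden.attributable_cases is None:
        return None
    cases_at_facility = burden.attributable_cases * cascade.pct_taken_to_facility
    inpatient_cases = cases_at_facility * cascade.pct_inpatient_given_care
    outpatient_cases = cases_at_facility - inpatient_cases

    def _mix_price(mix: dict[str, float], unit: dict[str, float]) -> float | None:
        price = 0.0
        for level, weight in mix.items():
            if weight == 0.0:
                continue
            if level not in unit:
                return None
            price += weight * inflate_unit_cost(unit[level], cpi_multiplier)
        return price

    visit_price = _mix_price(cascade.facility_mix_outpatient, costs.outpatient_visit_cost)
    day_price = _mix_price(cascade.facility_mix_inpatient, costs.inpatient_day_cost)
    if visit_price is None or day_price is None:
        return None

    outpatient_cost = outpatient_cases * cascade.visits_per_outpatient_case * visit_price
    inpatient_cost = inpatient_cases * cascade.bed_days_per_inpatient_case * day_price
    return TreatmentCost(
        burden.pathway, outpatient_cases, inpatient_cases, outpatient_cost, inpatient_cost
    )


def t2dm_treatment_cost(burden: PathwayBurden, costs: UnitCosts) -> float | None:
    """Annual treatment cost of attributable type II diabetes in women:
    cases x share diagnosed x health expenditure per diagnosed case."""
    if (
        burden.attributable_cases is None
        or costs.pct_t2dm_diagnosed is None
        or costs.t2dm_expenditure_per_case is None
    ):
        return None
    return (
        burden.attributable_cases
        * costs.pct_t2dm_diagnosed
        * costs.t2dm_expenditure_per_case
    )


def formula_cost_share(
    costs: UnitCosts,
    profile: CountryProfile,
    fallback_price: float | None = None,
) -> float | None:
    """Formula feeding birth-to-two as a share of household earnings.

    The advised quantity of formula (in 900-g containers) times the unit
    price, divided by 24 months of mean earnings.  Countries without a
    formula price use ``fallback_price`` (the global mean) when given.
    Returns ``None`` when the wage is zero or missing (never infinity).
    """
    price = costs.formula_price_per_900g
    if price is None:
        price = fallback_price
    if price is None:
        return None
    wage = profile.mean_monthly_wage
    if wage is None or wage <= 0:
        return None
    return (costs.formula_containers_birth_to_24m * price) / (wage * 24.0)
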