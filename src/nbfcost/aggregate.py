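"""No-extrapolation aggregation and the scenario sensitivity grid.

Group totals (region, income group, global) are cumulative sums over the
member countries for which each field was actually computed; countries with
a missing field are excluded from that field's sum rather than contributing
zero, and no total is scaled up to the group's full population.  The percent
of GNI divides the summed total loss by the summed GNI of the same included
country set.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Callable, Iterable, Literal

from .domain import (
    DEFAULT_SCENARIOS,
    AggregateResult,
    CountryProfile,
    CountryResult,
    EconomicAssumptions,
    Scenario,
)

Grouping = Literal["region", "income", "global"]

_SCALAR_FIELDS = (
    "health_cost_total",
    "loss_child_mortality",
    "loss_maternal_mortality",
    "loss_cognitive",
    "loss_total",
)


def _group_key(grouping: Grouping) -> Callable[[CountryResult], str]:
    if grouping == "region":
        return lambda r: r.region.value
    if grouping == "income":
        return lambda r: r.income_group.value
    if grouping == "global":
        return lambda r: "Total"
    raise ValueError(f"unknown grouping {grouping!r}")


def _aggregate_one(label: str, members: list[CountryResult]) -> AggregateResult:
    agg = AggregateResult(label=label, n_countries=len(members))
    sums: dict[str, list[float]] = {}

    for r in members:
        for pw, v in r.attributable_cases.items():
            if v is not None:
                sums.setdefault(f"cases.{pw}", []).append(v)
        for pw, v in r.attributable_deaths.items():
            if v is not None:
                sums.setdefault(f"deaths.{pw}", []).append(v)
        for comp, v in r.health_cost.items():
            if v is not None:
                sums.setdefault(f"health_cost.{comp}", []).append(v)
        for name in _SCALAR_FIELDS:
            v = getattr(r, name)
            if v is not None:
                sums.setdefault(name, []).append(v)
        if r.loss_total is not None and r.gni_total is not None:
            sums.setdefault("gni_included", []).append(r.gni_total)

    for key, values in sums.items():
        total = math.fsum(values)
        agg.field_counts[key] = len(values)
        if key.startswith("cases."):
            agg.attributable_cases[key.removeprefix("cases.")] = total
        elif key.startswith("deaths."):
            agg.attributable_deaths[key.removeprefix("deaths.")] = total
        elif key.startswith("health_cost."):
            agg.health_cost[key.removeprefix("health_cost.")] = total
        else:
            setattr(agg, key, total)

    if agg.gni_included > 0 and "loss_total" in sums:
        agg.pct_gni = agg.loss_total / agg.gni_included
    return agg


def aggregate(
    results: Iterable[CountryResult], grouping: Grouping = "global"
) -> dict[str, AggregateResult]:
    """Aggregate country results into labelled group totals.

    Returns label → :class:`AggregateResult`; an empty input produces an
    empty mapping, and an empty group would carry zero totals and count 0.
    """
    key = _group_key(grouping)
    groups: dict[str, list[CountryResult]] = {}
    for r in results:
        groups.setdefault(key(r), []).append(r)
    return {label: _aggregate_one(label, members) for label, members in groups.items()}


def run_sensitivity(
    profiles: list[CountryProfile],
    scenarios: Iterable[Scenario] | None = None,
    assumptions: EconomicAssumptions | None = None,
    grouping: Grouping = "global",
) -> dict[str, dict[str, AggregateResult]]:
    """Re-estimate all countries under each (discount, growth) scenario.

    Burden and health costs do not depend on the discount or growth rates
    and are identical across scenarios; only the discounted-loss components
    move.  Returns scenario label → group label → aggregate.
    """
    from .pipeline import estimate_countries  # local import to avoid a cycle

    if scenarios is None:
        scenarios = list(DEFAULT_SCENARIOS.values())
    if assumptions is None:
        assumptions = EconomicAssumptions()
    out: dict[str, dict[str, AggregateResult]] = {}
    for sc in scenarios:
        scen_assumptions = replace(
            assumptions, discount_rate=sc.discount_rate, gdp_growth=sc.gdp_growth
        )
        results = estimate_countries(profiles, scen_assumptions)
        out[sc.label] = aggregate(results, grouping)
    return out
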