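"""Per-country orchestration: burden → health costs → discounted losses."""

from __future__ import annotations

from .burden import (
    PathwayBurden,
    child_pathway_burden,
    maternal_pathway_burden,
    obesity_burden,
)
from .domain import (
    CHILD_INFECTIOUS_PATHWAYS,
    MATERNAL_PATHWAYS,
    OBESITY_PATHWAY,
    CountryProfile,
    CountryResult,
    EconomicAssumptions,
)
from .economic_losses import (
    child_mortality_loss,
    cognitive_loss,
    maternal_mortality_loss,
    n_not_breastfed,
    total_loss,
)
from .health_costs import (
    child_treatment_cost,
    formula_cost_share,
    t2dm_treatment_cost,
)

# Health-cost component keys in reporting order.
HEALTH_COST_COMPONENTS = ("diarrhoea", "pneumonia", "t2dm")


def estimate_country(
    profile: CountryProfile,
    assumptions: EconomicAssumptions | None = None,
    global_mean_formula_price: float | None = None,
) -> CountryResult:
    """Run every estimation stage for one country.

    Any component whose inputs are unavailable is left ``None`` and listed in
    ``missing_components``; the remaining components are still computed.
    """
    if assumptions is None:
        assumptions = EconomicAssumptions()
    result = CountryResult(
        country_code=profile.country_code,
        region=profile.region,
        income_group=profile.income_group,
        gni_total=profile.gni_total,
    )

    burdens: dict[str, PathwayBurden | None] = {}
    for pathway in CHILD_INFECTIOUS_PATHWAYS:
        burdens[pathway] = child_pathway_burden(profile, pathway)
    burdens[OBESITY_PATHWAY] = obesity_burden(profile)
    for pathway in MATERNAL_PATHWAYS:
        burdens[pathway] = maternal_pathway_burden(profile, pathway)

    for pathway, burden in burdens.items():
        result.attributable_cases[pathway] = (
            burden.attributable_cases if burden is not None else None
        )
        result.attributable_deaths[pathway] = (
            burden.attributable_deaths if burden is not None else None
        )
        if burden is None:
            result.missing_components.append(f"burden.{pathway}")

    # Health-system costs
    cost_components: dict[str, float | None] = {}
    for pathway, key in zip(CHILD_INFECTIOUS_PATHWAYS, ("diarrhoea", "pneumonia")):
        burden = burdens[pathway]
        cascade = profile.cascade.get(pathway) if profile.cascade else None
        if burden is None or cascade is None or profile.unit_costs is None:
            cost_components[key] = None
        else:
            tc = child_treatment_cost(
                burden, cascade, profile.unit_costs, profile.cpi_cumulative_2008_2017
            )
            cost_components[key] = tc.total_cost if tc is not None else None
    t2dm_burden = burdens["t2dm_f"]
    if t2dm_burden is None or profile.unit_costs is None:
        cost_components["t2dm"] = None
    else:
        cost_components["t2dm"] = t2dm_treatment_cost(t2dm_burden, profile.unit_costs)
    result.health_cost = cost_components
    available_costs = [v for v in cost_components.values() if v is not None]
    result.health_cost_total = sum(available_costs) if available_costs else None
    for key, value in cost_components.items():
        if value is None:
            result.missing_components.append(f"health_cost.{key}")

    if profile.unit_costs is not None:
        result.formula_cost_share_of_wages = formula_cost_share(
            profile.unit_costs, profile, fallback_price=global_mean_formula_price
        )

    # Discounted future losses
    child_deaths = [
        burdens[p].attributable_deaths
        for p in CHILD_INFECTIOUS_PATHWAYS
        if burdens[p] is not None and burdens[p].attributable_deaths is not None
    ]
    if child_deaths:
        result.loss_child_mortality = child_mortality_loss(
            sum(child_deaths), profile, assumptions
        )
    result.loss_maternal_mortality = maternal_mortality_loss(burdens, profile, assumptions)
    n_exposed = n_not_breastfed(profile, assumptions)
    if n_exposed is not None:
        result.loss_cognitive = cognitive_loss(n_exposed, profile, assumptions)

    return total_loss(result)


def estimate_countries(
    profiles: list[CountryProfile],
    assumptions: EconomicAssumptions | None = None,
) -> list[CountryResult]:
    """Estimate every country, using the mean of available formula prices as
    the fallback for countries without a price — the stated proxy rule."""
    prices = [
        p.unit_costs.formula_price_per_900g
        for p in profiles
        if p.unit_costs is not None and p.unit_costs.formula_price_per_900g is not None
    ]
    mean_price = sum(prices) / len(prices) if prices else None
    return [
        estimate_country(p, assumptions, global_mean_formula_price=mean_price)
        for p in profiles
    ]
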