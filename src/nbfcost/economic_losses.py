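"""Discounted future earnings lost to mortality and cognitive deficit.

The human-capital approach values a death (or an IQ deficit) as the present
value of foregone earnings over the productive years.  Earnings are proxied
by GNI per capita at the base year, projected with a constant long-term GDP
growth rate g and discounted at rate r, both compounded annually with an
end-of-year convention, to the person's birth year:

    PV = sum over age years a in [start, end) of
         base x scale x ((1 + g) / (1 + r))^a,

with a fractional terminal (or initial) year pro-rated.  With g = r the
factors cancel and PV = base x scale x (end - start) exactly.

Child mortality streams run from the working start age (default 18) to the
earlier of retirement (default 65) and life expectancy; maternal mortality
streams run from the mean age at cause-specific death to the same endpoint;
cognitive losses scale the working-age stream by the IQ deficit (2.62
points) times the earnings elasticity per IQ point (1.067%).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .burden import PathwayBurden
from .domain import (
    MATERNAL_PATHWAYS,
    CountryProfile,
    CountryResult,
    EconomicAssumptions,
)


@dataclass
class EarningsStreamSpec:
    """One person's projected earnings stream.

    ``start_age``/``end_age`` bound the productive years (end exclusive;
    a fractional end pro-rates the last year).  ``scale_factors`` is the
    product of the optional wage-share and labour-force-participation
    multipliers.
    """

    base_income: float
    start_age: float
    end_age: float
    growth: float = 0.03
    discount: float = 0.03
    scale_factors: float = 1.0


def present_value(spec: EarningsStreamSpec) -> float:
    """Present value (US$ per person) of an earnings stream, discounted to
    the cohort's birth year.  Returns 0 with a warning when the stream is
    empty (start >= end)."""
    if spec.start_age >= spec.end_age:
        warnings.warn(
            f"empty earnings stream: start_age {spec.start_age} >= end_age {spec.end_age}",
            stacklevel=2,
        )
        return 0.0
    ratio = (1.0 + spec.growth) / (1.0 + spec.discount)
    pv = 0.0
    a = spec.start_age
    while a < spec.end_age:
        step = min(a + 1.0, spec.end_age) - a
        pv += step * ratio**a
        a += 1.0
    return spec.base_income * spec.scale_factors * pv


def _stream_scale(profile: CountryProfile, assumptions: EconomicAssumptions, maternal: bool) -> float:
    scale = 1.0
    if assumptions.apply_wage_share and profile.wage_share is not None:
        scale *= profile.wage_share
    # Only the female participation rate is carried in the profile, so the
    # LFPR multiplier is applied to maternal (all-female) streams only.
    if maternal and assumptions.apply_lfpr and profile.lfpr_female is not None:
        scale *= profile.lfpr_female
    return scale


def _working_stream(
    profile: CountryProfile, assumptions: EconomicAssumptions, maternal: bool = False
) -> EarningsStreamSpec | None:
    if profile.gni_per_capita is None or profile.life_expectancy is None:
        return None
    end = min(assumptions.retirement_age, profile.life_expectancy)
    return EarningsStreamSpec(
        base_income=profile.gni_per_capita,
        start_age=assumptions.work_start_age,
        end_age=end,
        growth=assumptions.gdp_growth,
        discount=assumptions.discount_rate,
        scale_factors=_stream_scale(profile, assumptions, maternal),
    )


def child_mortality_loss(
    deaths: float, profile: CountryProfile, assumptions: EconomicAssumptions
) -> float | None:
    """Future earnings lost to attributable child deaths in the one-year
    cohort: deaths x per-person PV over the working ages."""
    if deaths < 0:
        raise ValueError("deaths must be >= 0")
    spec = _working_stream(profile, assumptions)
    if spec is None:
        return None
    if spec.end_age <= spec.start_age:
        warnings.warn(
            f"{profile.country_code}: life expectancy {profile.life_expectancy} "
            f"below working start age; child-mortality loss is 0",
            stacklevel=2,
        )
        return 0.0
    return deaths * present_value(spec)


def maternal_mortality_loss(
    burdens: dict[str, PathwayBurden | None],
    profile: CountryProfile,
    assumptions: EconomicAssumptions,
) -> float | None:
    """Future earnings lost to attributable maternal deaths.

    Each pathway's deaths are valued over the years from the mean age at
    cause-specific death to the earlier of retirement and life expectancy
    (zero when the mean age already exceeds that endpoint).  Returns ``None``
    when no maternal pathway could be valued.
    """
    if profile.gni_per_capita is None or profile.life_expectancy is None:
        return None
    end = min(assumptions.retirement_age, profile.life_expectancy)
    scale = _stream_scale(profile, assumptions, maternal=True)
    total = 0.0
    any_computed = False
    for pathway in MATERNAL_PATHWAYS:
        burden = burdens.get(pathway)
        if burden is None or burden.attributable_deaths is None:
            continue
        epi = profile.epidemiology.get(pathway) if profile.epidemiology else None
        if epi is None or epi.mean_age_at_death_f is None:
            continue
        any_computed = True
        if epi.mean_age_at_death_f >= end:
            continue  # no productive years remain
        spec = EarningsStreamSpec(
            base_income=profile.gni_per_capita,
            start_age=epi.mean_age_at_death_f,
            end_age=end,
            growth=assumptions.gdp_growth,
            discount=assumptions.discount_rate,
            scale_factors=scale,
        )
        total += burden.attributable_deaths * present_value(spec)
    return total if any_computed else None


def n_not_breastfed(profile: CountryProfile, assumptions: EconomicAssumptions) -> float | None:
    """Size of the one-year birth cohort exposed to cognitive deficit.

    Default mode counts children not exclusively breastfed below 6 months;
    the alternative mode counts children not breastfed at 6 months.
    """
    prev = profile.prevalence
    if prev is None:
        return None
    if assumptions.cognitive_exposure_mode == "exclusive_lt6m":
        frac = 1.0 - prev.band_0_5m["exclusive"]
    elif assumptions.cognitive_exposure_mode == "bf_at_6m":
        frac = 1.0 - prev.bf_at_6m
    else:
        raise ValueError(
            f"unknown cognitive_exposure_mode {assumptions.cognitive_exposure_mode!r}"
        )
    return profile.births_annual * frac


def cognitive_loss(
    n_exposed: float, profile: CountryProfile, assumptions: EconomicAssumptions
) -> float | None:
    """Earnings lost to the breastfeeding-associated IQ deficit:
    children exposed x per-person working-age PV x IQ points x earnings
    elasticity per point."""
    if n_exposed < 0:
        raise ValueError("n_exposed must be >= 0")
    spec = _working_stream(profile, assumptions)
    if spec is None:
        return None
    if spec.end_age <= spec.start_age:
        return 0.0
    return n_exposed * present_value(spec) * assumptions.iq_gain * assumptions.earnings_per_iq


def total_loss(result: CountryResult) -> CountryResult:
    """Sum available loss components into ``loss_total`` and ``pct_gni``.

    Components that were not computed are recorded in
    ``missing_components`` and excluded from the sum (never treated as 0
    unless every component is missing, in which case the total is ``None``).
    """
    components = {
        "health_cost_total": result.health_cost_total,
        "loss_child_mortality": result.loss_child_mortality,
        "loss_maternal_mortality": result.loss_maternal_mortality,
        "loss_cognitive": result.loss_cognitive,
    }
    available = {k: v for k, v in components.items() if v is not None}
    for k in components:
        if components[k] is None and k not in result.missing_components:
            result.missing_components.append(k)
    if not available:
        result.loss_total = None
        result.loss_total_pct_gni = None
        return result
    result.loss_total = math.fsum(available.values())
    if result.gni_total and result.gni_total > 0:
        result.loss_total_pct_gni = result.loss_total / result.gni_total
    else:
        result.loss_total_pct_gni = None
    return result
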