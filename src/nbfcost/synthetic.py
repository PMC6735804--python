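"""Synthetic country-dataset generator.

Produces complete, internally consistent country input records whose shapes
and ranges emulate the open-access sources a real run would draw on:
population by age band (UN WPP-like), breastfeeding-practice prevalence
(UNICEF IYCF / DHS / MICS-like), disease incidence and deaths (GBD-like),
care-seeking percentages (MICS-like), facility unit costs (WHO-CHOICE-like)
and macro-economic indicators (WDI / ILOSTAT-like).  Relative-risk defaults
are placeholders drawn within literature-plausible ranges supplied as
configuration; no specific published RR is hard-coded.

The same seed always yields the identical dataset, and every generated
profile passes :func:`nbfcost.domain.validate_profile` with zero violations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .domain import (
    CATEGORIES_0_5M,
    FACILITY_LEVELS,
    BreastfeedingPrevalence,
    CareSeeking,
    CareSeekingCascade,
    CountryProfile,
    DiseaseEpidemiology,
    IncomeGroup,
    PathwayEpi,
    Region,
    RelativeRiskTable,
    UnitCosts,
)

# Literature-plausible placeholder ranges for relative risks of each
# non-reference exposure category (min, max).  Within the 0-5-month band the
# draws are sorted so predominant <= partial <= none.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "rr_diarrhoea_0_5m": (1.3, 4.5),
    "rr_diarrhoea_6_23m": (1.3, 2.5),
    "rr_pneumonia_0_5m": (1.2, 3.5),
    "rr_pneumonia_6_23m": (1.2, 2.2),
    "rr_obesity_never": (1.1, 1.4),
    "rr_breast_cancer": (1.1, 1.35),
    "rr_ovarian_cancer": (1.15, 1.45),
    "rr_t2dm": (1.2, 1.55),
    "ebf_prevalence": (0.10, 0.60),
    "gni_per_capita": (500.0, 60000.0),
    "life_expectancy": (50.0, 85.0),
    "births_annual": (2e4, 3e6),
    "formula_price_per_900g": (8.0, 32.0),
}


@dataclass
class FixtureSpec:
    """Configuration for one synthetic dataset.

    ``range_overrides`` replaces any entry of :data:`DEFAULT_RANGES`;
    ``universal_breastfeeding`` forces every practice indicator to the
    recommended level (the counterfactual in which all attributable burden
    is zero).  ``missing_formula_price_prob`` leaves that share of countries
    without a formula price, exercising the global-mean fallback.
    """

    n_countries: int = 130
    seed: int = 42
    range_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    universal_breastfeeding: bool = False
    missing_formula_price_prob: float = 0.2

    def ranges(self) -> dict[str, tuple[float, float]]:
        out = dict(DEFAULT_RANGES)
        out.update(self.range_overrides)
        return out


def _code(i: int) -> str:
    a = i // 676
    b = (i // 26) % 26
    c = i % 26
    return "".join(chr(ord("A") + x) for x in (a % 26, b, c))


def _income_group(gni_pc: float) -> IncomeGroup:
    # World Bank-style operational thresholds (US$ GNI per capita).
    if gni_pc < 1085:
        return IncomeGroup.LOW
    if gni_pc < 4255:
        return IncomeGroup.LOWER_MIDDLE
    if gni_pc < 13205:
        return IncomeGroup.UPPER_MIDDLE
    return IncomeGroup.HIGH


def _uniform(rng: np.random.Generator, rg: tuple[float, float]) -> float:
    return float(rng.uniform(rg[0], rg[1]))


def _band_0_5m(rng: np.random.Generator, ebf: float) -> dict[str, float]:
    rest = rng.dirichlet((2.0, 3.0, 1.5)) * (1.0 - ebf)
    vec = {
        "exclusive": ebf,
        "predominant": float(rest[0]),
        "partial": float(rest[1]),
        "none": float(rest[2]),
    }
    # renormalise away float error so the simplex invariant holds exactly
    total = sum(vec.values())
    return {k: v / total for k, v in vec.items()}


def generate_country(rng: np.random.Generator, index: int, spec: FixtureSpec) -> CountryProfile:
    rg = spec.ranges()
    region = Region(list(Region)[int(rng.integers(len(Region)))].value)
    log_lo, log_hi = np.log(rg["gni_per_capita"][0]), np.log(rg["gni_per_capita"][1])
    gni_pc = float(np.exp(rng.uniform(log_lo, log_hi)))
    income = _income_group(gni_pc)
    # richer countries live longer: interpolate the LE range on log-income
    le_lo, le_hi = rg["life_expectancy"]
    rel = (np.log(gni_pc) - log_lo) / (log_hi - log_lo)
    life_expectancy = float(
        np.clip(le_lo + rel * (le_hi - le_lo) + rng.normal(0, 3.0), le_lo, le_hi)
    )
    births = _uniform(rng, rg["births_annual"])
    children = births * 2.0 * float(rng.uniform(0.93, 0.99))
    population = births * float(rng.uniform(25.0, 45.0))
    gni_total = gni_pc * population
    wage_share = float(rng.uniform(0.35, 0.65))
    lfpr_female = float(rng.uniform(0.30, 0.80))
    wage = gni_pc / 12.0 * float(rng.uniform(0.6, 1.2))
    cpi = float(rng.uniform(1.05, 1.9))

    if spec.universal_breastfeeding:
        prevalence = BreastfeedingPrevalence(
            band_0_5m={"exclusive": 1.0, "predominant": 0.0, "partial": 0.0, "none": 0.0},
            band_6_23m={"any": 1.0, "none": 0.0},
            ever_breastfed=1.0,
            bf_at_6m=1.0,
            lifetime_duration_level=1.0,
        )
    else:
        ebf = _uniform(rng, rg["ebf_prevalence"])
        any_623 = float(rng.uniform(0.30, 0.90))
        prevalence = BreastfeedingPrevalence(
            band_0_5m=_band_0_5m(rng, ebf),
            band_6_23m={"any": any_623, "none": 1.0 - any_623},
            ever_breastfed=float(rng.uniform(0.70, 0.99)),
            bf_at_6m=float(rng.uniform(0.40, 0.90)),
            lifetime_duration_level=float(rng.uniform(0.20, 0.70)),
        )

    # epidemiology: poorer countries carry higher infectious burden and
    # case fatality; maternal chronic-disease burden scales with women 15+
    women = population * 0.36
    poverty = 1.0 - rel
    diarrhoea_inc = children * float(rng.uniform(0.5, 1.5) + 2.0 * poverty * rng.uniform(0.5, 1.0))
    pneumonia_inc = children * float(rng.uniform(0.02, 0.10) + 0.2 * poverty * rng.uniform(0.5, 1.0))
    diarrhoea_cfr = float(10 ** rng.uniform(-4.5, -3.0)) * (0.2 + poverty)
    pneumonia_cfr = float(10 ** rng.uniform(-3.5, -2.0)) * (0.2 + poverty)
    epi = DiseaseEpidemiology(
        pathways={
            "diarrhoea_0_23m": PathwayEpi(
                incidence_annual=diarrhoea_inc,
                deaths_annual=diarrhoea_inc * diarrhoea_cfr,
                share_cases_0_5m=float(rng.uniform(0.2, 0.45)),
                share_deaths_0_5m=float(rng.uniform(0.3, 0.6)),
            ),
            "pneumonia_0_23m": PathwayEpi(
                incidence_annual=pneumonia_inc,
                deaths_annual=pneumonia_inc * pneumonia_cfr,
                share_cases_0_5m=float(rng.uniform(0.2, 0.45)),
                share_deaths_0_5m=float(rng.uniform(0.3, 0.6)),
            ),
            "obesity_child": PathwayEpi(
                incidence_annual=children * float(rng.uniform(0.005, 0.05) * (0.3 + rel)),
            ),
            "breast_cancer_f": PathwayEpi(
                incidence_annual=women * float(10 ** rng.uniform(-3.8, -3.0)),
                deaths_annual=women * float(10 ** rng.uniform(-4.5, -3.7)),
                mean_age_at_death_f=float(rng.uniform(55.0, 70.0)),
            ),
            "ovarian_cancer_f": PathwayEpi(
                incidence_annual=women * float(10 ** rng.uniform(-4.5, -3.7)),
                deaths_annual=women * float(10 ** rng.uniform(-5.0, -4.2)),
                mean_age_at_death_f=float(rng.uniform(58.0, 72.0)),
            ),
            "t2dm_f": PathwayEpi(
                incidence_annual=women * float(10 ** rng.uniform(-3.0, -2.0)),
                deaths_annual=women * float(10 ** rng.uniform(-4.3, -3.5)),
                mean_age_at_death_f=float(rng.uniform(58.0, 74.0)),
            ),
        }
    )

    def _band_rrs(key: str) -> dict[str, float]:
        lo, hi = rg[key]
        draws = sorted(float(rng.uniform(lo, hi)) for _ in range(3))
        return {
            "exclusive": 1.0,
            "predominant": draws[0],
            "partial": draws[1],
            "none": draws[2],
        }

    rr = RelativeRiskTable(
        tables={
            "diarrhoea_0_5m": _band_rrs("rr_diarrhoea_0_5m"),
            "diarrhoea_6_23m": {"any": 1.0, "none": _uniform(rng, rg["rr_diarrhoea_6_23m"])},
            "pneumonia_0_5m": _band_rrs("rr_pneumonia_0_5m"),
            "pneumonia_6_23m": {"any": 1.0, "none": _uniform(rng, rg["rr_pneumonia_6_23m"])},
            "obesity_child": {"ever": 1.0, "never": _uniform(rng, rg["rr_obesity_never"])},
            "breast_cancer_f": {
                "recommended": 1.0,
                "not_recommended": _uniform(rng, rg["rr_breast_cancer"]),
            },
            "ovarian_cancer_f": {
                "recommended": 1.0,
                "not_recommended": _uniform(rng, rg["rr_ovarian_cancer"]),
            },
            "t2dm_f": {"recommended": 1.0, "not_recommended": _uniform(rng, rg["rr_t2dm"])},
        }
    )

    def _mix(alpha: tuple[float, ...]) -> dict[str, float]:
        draw = rng.dirichlet(alpha)
        vec = {lvl: float(w) for lvl, w in zip(FACILITY_LEVELS, draw)}
        total = sum(vec.values())
        return {k: v / total for k, v in vec.items()}

    def _care() -> CareSeeking:
        return CareSeeking(
            pct_taken_to_facility=float(rng.uniform(0.30, 0.90)),
            pct_inpatient_given_care=float(rng.uniform(0.05, 0.25)),
            facility_mix_outpatient=_mix((4.0, 3.0, 2.0, 1.0)),
            facility_mix_inpatient=_mix((1.0, 3.0, 3.0, 2.0)),
            visits_per_outpatient_case=1.0,
            bed_days_per_inpatient_case=float(rng.uniform(2.0, 5.0)),
        )

    cascade = CareSeekingCascade(
        pathways={"diarrhoea_0_23m": _care(), "pneumonia_0_23m": _care()}
    )

    # WHO-CHOICE-style unit costs rising with facility level and income
    visit_base = gni_pc * float(rng.uniform(5e-4, 2e-3))
    day_base = visit_base * float(rng.uniform(2.0, 4.0))
    level_mult = {"health_centre": 1.0, "primary_hospital": 1.5,
                  "secondary_hospital": 2.5, "tertiary_hospital": 4.0}
    price = (
        None
        if rng.uniform() < spec.missing_formula_price_prob
        else _uniform(rng, rg["formula_price_per_900g"])
    )
    unit_costs = UnitCosts(
        outpatient_visit_cost={lvl: visit_base * m for lvl, m in level_mult.items()},
        inpatient_day_cost={lvl: day_base * m for lvl, m in level_mult.items()},
        t2dm_expenditure_per_case=gni_pc * float(rng.uniform(0.01, 0.10)),
        pct_t2dm_diagnosed=float(rng.uniform(0.30, 0.80)),
        formula_price_per_900g=price,
        formula_containers_birth_to_24m=50.0,
    )

    return CountryProfile(
        country_code=_code(index),
        region=region,
        income_group=income,
        births_annual=births,
        children_0_23m=children,
        gni_total=gni_total,
        gni_per_capita=gni_pc,
        life_expectancy=life_expectancy,
        retirement_age=65.0,
        wage_share=wage_share,
        lfpr_female=lfpr_female,
        mean_monthly_wage=wage,
        cpi_cumulative_2008_2017=cpi,
        prevalence=prevalence,
        epidemiology=epi,
        relative_risks=rr,
        cascade=cascade,
        unit_costs=unit_costs,
        data_flags={"formula_price_per_900g": price is not None},
    )


def generate_countries(spec: FixtureSpec) -> list[CountryProfile]:
    """Generate ``spec.n_countries`` internally consistent country profiles.

    Deterministic in ``spec.seed``: the same spec always yields the same
    dataset, field for field.
    """
    if spec.n_countries < 1:
        raise ValueError("n_countries must be >= 1")
    rng = np.random.default_rng(spec.seed)
    return [generate_country(rng, i, spec) for i in range(spec.n_countries)]
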