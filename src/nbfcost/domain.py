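"""Core domain types for the cost-of-not-breastfeeding estimation engine.

Every quantity used by a downstream equation — breastfeeding-exposure
prevalences, relative risks, disease incidence and deaths, care-seeking
fractions, unit costs, and the macro-economic assumptions — lives in exactly
one of the types below.  A :class:`CountryProfile` bundles one country's full
input record; missing indicators are represented explicitly (``None`` plus a
data flag) and propagate downstream as "component not computed", never as a
silent zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping


class Region(str, Enum):
    """The seven World Bank geographic regions used for reporting."""

    EAST_ASIA_PACIFIC = "East Asia and Pacific"
    EUROPE_CENTRAL_ASIA = "Europe and Central Asia"
    MIDDLE_EAST_NORTH_AFRICA = "Middle East and North Africa"
    LATIN_AMERICA_CARIBBEAN = "Latin America and Caribbean"
    NORTH_AMERICA = "North America"
    SOUTH_ASIA = "South Asia"
    SUB_SAHARAN_AFRICA = "Sub-Saharan Africa"


class IncomeGroup(str, Enum):
    HIGH = "High income"
    UPPER_MIDDLE = "Upper-middle-income"
    LOWER_MIDDLE = "Lower-middle-income"
    LOW = "Low income"


# Disease pathways.  Child infectious pathways act on ages 0-23 months;
# maternal pathways act on women over their lifetime breastfeeding history.
CHILD_INFECTIOUS_PATHWAYS = ("diarrhoea_0_23m", "pneumonia_0_23m")
OBESITY_PATHWAY = "obesity_child"
MATERNAL_PATHWAYS = ("breast_cancer_f", "ovarian_cancer_f", "t2dm_f")
ALL_PATHWAYS = CHILD_INFECTIOUS_PATHWAYS + (OBESITY_PATHWAY,) + MATERNAL_PATHWAYS

# Exposure categories.  The recommended practice is the PAF reference
# category (relative risk 1) in every table.
CATEGORIES_0_5M = ("exclusive", "predominant", "partial", "none")
CATEGORIES_6_23M = ("any", "none")
CATEGORIES_EVER = ("ever", "never")
CATEGORIES_MATERNAL = ("recommended", "not_recommended")
REFERENCE_CATEGORY = {
    "0_5m": "exclusive",
    "6_23m": "any",
    "ever": "ever",
    "maternal": "recommended",
}

FACILITY_LEVELS = (
    "health_centre",
    "primary_hospital",
    "secondary_hospital",
    "tertiary_hospital",
)

_SUM_TOL = 1e-9


@dataclass
class BreastfeedingPrevalence:
    """Population distribution over breastfeeding-practice categories.

    ``band_0_5m`` and ``band_6_23m`` are category → fraction maps that each
    sum to one.  ``lifetime_duration_level`` is the population mean attainment
    of the recommended lifetime breastfeeding duration, used by the maternal
    pathways (1.0 means the universal-breastfeeding counterfactual is met).
    """

    band_0_5m: dict[str, float]
    band_6_23m: dict[str, float]
    ever_breastfed: float
    bf_at_6m: float
    lifetime_duration_level: float


@dataclass
class PathwayEpi:
    """Annual incidence and deaths for one disease pathway.

    For chronic maternal pathways, incident cases and deaths belong to
    different cohorts, so deaths may legitimately exceed incidence in odd
    years; no cross-bound is enforced.  ``share_cases_0_5m`` /
    ``share_deaths_0_5m`` give the 0-5-month band's share of the 0-23-month
    burden (child infectious pathways only) and default to an even split when
    the surveillance source does not stratify.
    """

    incidence_annual: float | None = None
    deaths_annual: float | None = None
    mean_age_at_death_f: float | None = None
    share_cases_0_5m: float | None = None
    share_deaths_0_5m: float | None = None


@dataclass
class DiseaseEpidemiology:
    pathways: dict[str, PathwayEpi] = field(default_factory=dict)

    def get(self, pathway: str) -> PathwayEpi | None:
        return self.pathways.get(pathway)


@dataclass
class RelativeRiskTable:
    """Relative risk by exposure category, per pathway (and age band).

    Keys are ``diarrhoea_0_5m``, ``diarrhoea_6_23m``, ``pneumonia_0_5m``,
    ``pneumonia_6_23m``, ``obesity_child``, ``breast_cancer_f``,
    ``ovarian_cancer_f`` and ``t2dm_f``; each maps category → RR with the
    recommended-practice reference category at exactly 1.
    """

    tables: dict[str, dict[str, float]] = field(default_factory=dict)

    def get(self, key: str) -> dict[str, float] | None:
        return self.tables.get(key)


@dataclass
class CareSeeking:
    """Treatment cascade for one child pathway: sought care → inpatient vs
    outpatient → facility-level mix → service units per case."""

    pct_taken_to_facility: float
    pct_inpatient_given_care: float
    facility_mix_outpatient: dict[str, float]
    facility_mix_inpatient: dict[str, float]
    visits_per_outpatient_case: float = 1.0
    bed_days_per_inpatient_case: float = 3.0


@dataclass
class CareSeekingCascade:
    pathways: dict[str, CareSeeking] = field(default_factory=dict)

    def get(self, pathway: str) -> CareSeeking | None:
        return self.pathways.get(pathway)


@dataclass
class UnitCosts:
    """Service unit costs (US$) plus formula-feeding price inputs."""

    outpatient_visit_cost: dict[str, float] = field(default_factory=dict)
    inpatient_day_cost: dict[str, float] = field(default_factory=dict)
    t2dm_expenditure_per_case: float | None = None
    pct_t2dm_diagnosed: float | None = None
    formula_price_per_900g: float | None = None
    formula_containers_birth_to_24m: float = 50.0


@dataclass
class EconomicAssumptions:
    """Macro-economic assumptions shared by every discounted-loss equation.

    Defaults: 3% discount, 3% long-term GDP growth, productive years 18-65,
    a 2.62-IQ-point cognitive deficit per child not breastfed per
    recommendation and a 1.067% earnings loss per IQ point.  The wage-share
    and labour-force-participation multipliers are off by default so the
    plain GNI-per-capita earnings stream is used.
    """

    discount_rate: float = 0.03
    gdp_growth: float = 0.03
    work_start_age: float = 18.0
    retirement_age: float = 65.0
    iq_gain: float = 2.62
    earnings_per_iq: float = 0.01067
    cognitive_exposure_mode: str = "exclusive_lt6m"  # or "bf_at_6m"
    apply_wage_share: bool = False
    apply_lfpr: bool = False


@dataclass
class Scenario:
    """A (discount rate, GDP growth) pair for the sensitivity grid."""

    label: str
    discount_rate: float
    gdp_growth: float


DEFAULT_SCENARIOS = {
    "default": Scenario("default", 0.03, 0.03),
    "conservative": Scenario("conservative", 0.05, 0.015),
    "optimistic": Scenario("optimistic", 0.015, 0.05),
}


@dataclass
class CountryProfile:
    """One country's full input record, subrecords included.

    ``data_flags`` records per-indicator availability; a missing indicator is
    flagged and its dependent components are skipped, never zeroed.
    """

    country_code: str
    region: Region
    income_group: IncomeGroup
    births_annual: float
    children_0_23m: float
    gni_total: float | None = None
    gni_per_capita: float | None = None
    life_expectancy: float | None = None
    retirement_age: float = 65.0
    wage_share: float | None = None
    lfpr_female: float | None = None
    mean_monthly_wage: float | None = None
    cpi_cumulative_2008_2017: float = 1.0
    prevalence: BreastfeedingPrevalence | None = None
    epidemiology: DiseaseEpidemiology | None = None
    relative_risks: RelativeRiskTable | None = None
    cascade: CareSeekingCascade | None = None
    unit_costs: UnitCosts | None = None
    data_flags: dict[str, bool] = field(default_factory=dict)

    def has(self, indicator: str) -> bool:
        """Availability of ``indicator``; defaults to the recorded flag,
        falling back to non-None-ness of the attribute of the same name."""
        if indicator in self.data_flags:
            return self.data_flags[indicator]
        return getattr(self, indicator, None) is not None


@dataclass
class CountryResult:
    """Per-country attributable burden, health costs and discounted losses.

    Component values are ``None`` when their inputs were unavailable;
    ``missing_components`` lists them.  ``loss_total`` is the sum of the
    available components among health-system cost, mortality losses and
    cognitive losses.
    """

    country_code: str
    region: Region
    income_group: IncomeGroup
    gni_total: float | None = None
    attributable_cases: dict[str, float | None] = field(default_factory=dict)
    attributable_deaths: dict[str, float | None] = field(default_factory=dict)
    health_cost: dict[str, float | None] = field(default_factory=dict)
    health_cost_total: float | None = None
    formula_cost_share_of_wages: float | None = None
    loss_child_mortality: float | None = None
    loss_maternal_mortality: float | None = None
    loss_cognitive: float | None = None
    loss_total: float | None = None
    loss_total_pct_gni: float | None = None
    missing_components: list[str] = field(default_factory=list)


@dataclass
class AggregateResult:
    """Cumulative totals over a country set, with per-field inclusion counts.

    Group totals are sums over member records where each field was computed —
    never extrapolated to the group's full population.  ``pct_gni`` divides
    the summed total loss by the summed GNI of the same included set.
    """

    label: str
    n_countries: int = 0
    attributable_cases: dict[str, float] = field(default_factory=dict)
    attributable_deaths: dict[str, float] = field(default_factory=dict)
    health_cost: dict[str, float] = field(default_factory=dict)
    health_cost_total: float = 0.0
    loss_child_mortality: float = 0.0
    loss_maternal_mortality: float = 0.0
    loss_cognitive: float = 0.0
    loss_total: float = 0.0
    gni_included: float = 0.0
    pct_gni: float | None = None
    field_counts: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Validation


def _check_fraction(violations: list[str], path: str, value: float | None) -> None:
    if value is None:
        return
    if not (0.0 <= value <= 1.0) or math.isnan(value):
        violations.append(f"{path}: fraction {value!r} outside [0, 1]")


def _check_nonneg(violations: list[str], path: str, value: float | None) -> None:
    if value is None:
        return
    if value < 0 or math.isnan(value):
        violations.append(f"{path}: value {value!r} must be >= 0")


def _check_simplex(
    violations: list[str], path: str, vec: Mapping[str, float], categories: tuple[str, ...]
) -> None:
    for cat in categories:
        if cat not in vec:
            violations.append(f"{path}: missing category {cat!r}")
    for cat, v in vec.items():
        _check_fraction(violations, f"{path}[{cat}]", v)
    total = sum(vec.values())
    if abs(total - 1.0) > _SUM_TOL:
        violations.append(f"{path}: category fractions sum to {total!r}, expected 1")


def validate_profile(profile: CountryProfile) -> list[str]:
    """Collect every invariant violation in ``profile``.

    Returns a list of ``"field.path: message"`` strings; the empty list means
    the profile is valid.  Validation never raises — callers decide what to
    do with the violations.
    """
    v: list[str] = []

    _check_nonneg(v, "births_annual", profile.births_annual)
    _check_nonneg(v, "children_0_23m", profile.children_0_23m)
    _check_nonneg(v, "gni_total", profile.gni_total)
    _check_nonneg(v, "gni_per_capita", profile.gni_per_capita)
    if profile.life_expectancy is not None and profile.life_expectancy <= 0:
        v.append(f"life_expectancy: {profile.life_expectancy!r} must be > 0")
    _check_nonneg(v, "retirement_age", profile.retirement_age)
    _check_fraction(v, "wage_share", profile.wage_share)
    _check_fraction(v, "lfpr_female", profile.lfpr_female)
    _check_nonneg(v, "mean_monthly_wage", profile.mean_monthly_wage)
    _check_nonneg(v, "cpi_cumulative_2008_2017", profile.cpi_cumulative_2008_2017)

    if profile.prevalence is not None:
        prev = profile.prevalence
        _check_simplex(v, "prevalence.band_0_5m", prev.band_0_5m, CATEGORIES_0_5M)
        _check_simplex(v, "prevalence.band_6_23m", prev.band_6_23m, CATEGORIES_6_23M)
        _check_fraction(v, "prevalence.ever_breastfed", prev.ever_breastfed)
        _check_fraction(v, "prevalence.bf_at_6m", prev.bf_at_6m)
        _check_fraction(v, "prevalence.lifetime_duration_level", prev.lifetime_duration_level)

    if profile.epidemiology is not None:
        for pw, epi in profile.epidemiology.pathways.items():
            _check_nonneg(v, f"epidemiology.{pw}.incidence_annual", epi.incidence_annual)
            _check_nonneg(v, f"epidemiology.{pw}.deaths_annual", epi.deaths_annual)
            _check_nonneg(v, f"epidemiology.{pw}.mean_age_at_death_f", epi.mean_age_at_death_f)
            _check_fraction(v, f"epidemiology.{pw}.share_cases_0_5m", epi.share_cases_0_5m)
            _check_fraction(v, f"epidemiology.{pw}.share_deaths_0_5m", epi.share_deaths_0_5m)

    if profile.relative_risks is not None:
        for key, table in profile.relative_risks.tables.items():
            if key.endswith("_0_5m"):
                ref = REFERENCE_CATEGORY["0_5m"]
            elif key.endswith("_6_23m"):
                ref = REFERENCE_CATEGORY["6_23m"]
            elif key == OBESITY_PATHWAY:
                ref = REFERENCE_CATEGORY["ever"]
            else:
                ref = REFERENCE_CATEGORY["maternal"]
            if ref not in table:
                v.append(f"relative_risks.{key}: missing reference category {ref!r}")
            elif table[ref] != 1.0:
                v.append(
                    f"relative_risks.{key}[{ref}]: reference RR is {table[ref]!r}, must be 1"
                )
            for cat, rr in table.items():
                if rr <= 0 or math.isnan(rr):
                    v.append(f"relative_risks.{key}[{cat}]: RR {rr!r} must be > 0")

    if profile.cascade is not None:
        for pw, cs in profile.cascade.pathways.items():
            _check_fraction(v, f"cascade.{pw}.pct_taken_to_facility", cs.pct_taken_to_facility)
            _check_fraction(
                v, f"cascade.{pw}.pct_inpatient_given_care", cs.pct_inpatient_given_care
            )
            _check_simplex(
                v, f"cascade.{pw}.facility_mix_outpatient", cs.facility_mix_outpatient,
                FACILITY_LEVELS,
            )
            _check_simplex(
                v, f"cascade.{pw}.facility_mix_inpatient", cs.facility_mix_inpatient,
                FACILITY_LEVELS,
            )
            _check_nonneg(v, f"cascade.{pw}.visits_per_outpatient_case", cs.visits_per_outpatient_case)
            _check_nonneg(v, f"cascade.{pw}.bed_days_per_inpatient_case", cs.bed_days_per_inpatient_case)

    if profile.unit_costs is not None:
        uc = profile.unit_costs
        for level, cost in uc.outpatient_visit_cost.items():
            _check_nonneg(v, f"unit_costs.outpatient_visit_cost[{level}]", cost)
        for level, cost in uc.inpatient_day_cost.items():
            _check_nonneg(v, f"unit_costs.inpatient_day_cost[{level}]", cost)
        _check_nonneg(v, "unit_costs.t2dm_expenditure_per_case", uc.t2dm_expenditure_per_case)
        _check_fraction(v, "unit_costs.pct_t2dm_diagnosed", uc.pct_t2dm_diagnosed)
        _check_nonneg(v, "unit_costs.formula_price_per_900g", uc.formula_price_per_900g)
        _check_nonneg(v, "unit_costs.formula_containers_birth_to_24m", uc.formula_containers_birth_to_24m)

    return v


def assumptions_violations(assumptions: EconomicAssumptions) -> list[str]:
    """Invariant check for an assumption set (same never-raise convention)."""
    v: list[str] = []
    for name in ("discount_rate", "gdp_growth"):
        rate = getattr(assumptions, name)
        if not (0.0 <= rate < 1.0):
            v.append(f"{name}: rate {rate!r} outside [0, 1)")
    if assumptions.work_start_age >= assumptions.retirement_age:
        v.append("work_start_age: must be < retirement_age")
    if assumptions.iq_gain < 0:
        v.append(f"iq_gain: {assumptions.iq_gain!r} must be >= 0")
    if assumptions.cognitive_exposure_mode not in ("exclusive_lt6m", "bf_at_6m"):
        v.append(
            f"cognitive_exposure_mode: unknown mode {assumptions.cognitive_exposure_mode!r}"
        )
    return v
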