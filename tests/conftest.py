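import pytest

from nbfcost.domain import (
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
from nbfcost.synthetic import FixtureSpec, generate_countries


@pytest.fixture
def profile() -> CountryProfile:
    """A hand-built, fully populated, internally consistent country."""
    return CountryProfile(
        country_code="TST",
        region=Region.SOUTH_ASIA,
        income_group=IncomeGroup.LOWER_MIDDLE,
        births_annual=100_000,
        children_0_23m=195_000,
        gni_total=5.0e10,
        gni_per_capita=2_000.0,
        life_expectancy=70.0,
        retirement_age=65.0,
        wage_share=0.5,
        lfpr_female=0.5,
        mean_monthly_wage=640.0,
        cpi_cumulative_2008_2017=1.35,
        prevalence=BreastfeedingPrevalence(
            band_0_5m={"exclusive": 0.4, "predominant": 0.3, "partial": 0.2, "none": 0.1},
            band_6_23m={"any": 0.7, "none": 0.3},
            ever_breastfed=0.8,
            bf_at_6m=0.6,
            lifetime_duration_level=0.4,
        ),
        epidemiology=DiseaseEpidemiology(
            pathways={
                "diarrhoea_0_23m": PathwayEpi(100_000.0, 1_000.0, None, 0.5, 0.5),
                "pneumonia_0_23m": PathwayEpi(50_000.0, 2_000.0, None, 0.4, 0.6),
                "obesity_child": PathwayEpi(incidence_annual=10_000.0),
                "breast_cancer_f": PathwayEpi(3_000.0, 2_000.0, 55.0),
                "ovarian_cancer_f": PathwayEpi(800.0, 500.0, 60.0),
                "t2dm_f": PathwayEpi(1_000.0, 300.0, 58.0),
            }
        ),
        relative_risks=RelativeRiskTable(
            tables={
                "diarrhoea_0_5m": {"exclusive": 1.0, "predominant": 1.5, "partial": 2.0, "none": 3.0},
                "diarrhoea_6_23m": {"any": 1.0, "none": 2.0},
                "pneumonia_0_5m": {"exclusive": 1.0, "predominant": 1.3, "partial": 1.7, "none": 2.5},
                "pneumonia_6_23m": {"any": 1.0, "none": 1.8},
                "obesity_child": {"ever": 1.0, "never": 1.4},
                "breast_cancer_f": {"recommended": 1.0, "not_recommended": 1.26},
                "ovarian_cancer_f": {"recommended": 1.0, "not_recommended": 1.3},
                "t2dm_f": {"recommended": 1.0, "not_recommended": 1.32},
            }
        ),
        cascade=CareSeekingCascade(
            pathways={
                "diarrhoea_0_23m": CareSeeking(
                    pct_taken_to_facility=0.6,
                    pct_inpatient_given_care=0.1,
                    facility_mix_outpatient={
                        "health_centre": 0.7, "primary_hospital": 0.3,
                        "secondary_hospital": 0.0, "tertiary_hospital": 0.0,
                    },
                    facility_mix_inpatient={
                        "health_centre": 0.0, "primary_hospital": 0.0,
                        "secondary_hospital": 1.0, "tertiary_hospital": 0.0,
                    },
                    visits_per_outpatient_case=1.0,
                    bed_days_per_inpatient_case=2.0,
                ),
                "pneumonia_0_23m": CareSeeking(
                    pct_taken_to_facility=0.5,
                    pct_inpatient_given_care=0.2,
                    facility_mix_outpatient={
                        "health_centre": 0.5, "primary_hospital": 0.3,
                        "secondary_hospital": 0.2, "tertiary_hospital": 0.0,
                    },
                    facility_mix_inpatient={
                        "health_centre": 0.0, "primary_hospital": 0.4,
                        "secondary_hospital": 0.4, "tertiary_hospital": 0.2,
                    },
                    visits_per_outpatient_case=1.0,
                    bed_days_per_inpatient_case=4.0,
                ),
            }
        ),
        unit_costs=UnitCosts(
            outpatient_visit_cost={
                "health_centre": 5.0, "primary_hospital": 10.0,
                "secondary_hospital": 20.0, "tertiary_hospital": 40.0,
            },
            inpatient_day_cost={
                "health_centre": 10.0, "primary_hospital": 15.0,
                "secondary_hospital": 20.0, "tertiary_hospital": 30.0,
            },
            t2dm_expenditure_per_case=200.0,
            pct_t2dm_diagnosed=0.5,
            formula_price_per_900g=18.74,
            formula_containers_birth_to_24m=50.0,
        ),
    )


@pytest.fixture(scope="session")
def synthetic_profiles():
    """130 seed-controlled synthetic country profiles (default conditions)."""
    return generate_countries(FixtureSpec(n_countries=130, seed=42))
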