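"""Present-value streams and the mortality / cognitive loss components."""

import math

import numpy as np
import pytest

from nbfcost.burden import maternal_pathway_burden
from nbfcost.domain import CountryResult, EconomicAssumptions, IncomeGroup, Region
from nbfcost.economic_losses import (
    EarningsStreamSpec,
    child_mortality_loss,
    cognitive_loss,
    maternal_mortality_loss,
    n_not_breastfed,
    present_value,
    total_loss,
)


def pv_loop_oracle(spec: EarningsStreamSpec) -> float:
    """Independent year-by-year summation with per-year powers."""
    total = 0.0
    a = spec.start_age
    while a < spec.end_age:
        step = min(a + 1.0, spec.end_age) - a
        total += step * (1.0 + spec.growth) ** a / (1.0 + spec.discount) ** a
        a += 1.0
    return spec.base_income * spec.scale_factors * total


class TestPresentValue:
    def test_growth_and_discount_cancel(self):
        spec = EarningsStreamSpec(1_000.0, 18.0, 20.0, growth=0.03, discount=0.03)
        assert present_value(spec) == 2_000.0

    def test_two_year_discounted_stream(self):
        spec = EarningsStreamSpec(1_000.0, 1.0, 3.0, growth=0.0, discount=0.05)
        expected = 1_000.0 / 1.05 + 1_000.0 / 1.05**2
        assert present_value(spec) == pytest.approx(expected)
        assert expected == pytest.approx(1_859.41, abs=0.005)

    def test_zero_base_income(self):
        assert present_value(EarningsStreamSpec(0.0, 18.0, 65.0)) == 0.0

    def test_empty_stream_returns_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert present_value(EarningsStreamSpec(1_000.0, 65.0, 60.0)) == 0.0

    def test_fractional_terminal_year_pro_rated(self):
        full = present_value(EarningsStreamSpec(1_000.0, 18.0, 20.0, 0.03, 0.03))
        frac = present_value(EarningsStreamSpec(1_000.0, 18.0, 19.5, 0.03, 0.03))
        assert frac == pytest.approx(0.75 * full)

    def test_agrees_with_loop_oracle_on_random_specs(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            start = float(rng.uniform(0, 70))
            spec = EarningsStreamSpec(
                base_income=float(rng.uniform(100, 80_000)),
                start_age=start,
                end_age=start + float(rng.uniform(0.1, 60)),
                growth=float(rng.uniform(0.0, 0.08)),
                discount=float(rng.uniform(0.0, 0.08)),
                scale_factors=float(rng.uniform(0.2, 1.0)),
            )
            assert present_value(spec) == pytest.approx(pv_loop_oracle(spec), rel=1e-9)

    def test_monotone_in_discount_growth_and_span(self):
        base = EarningsStreamSpec(1_000.0, 18.0, 65.0, 0.03, 0.03)
        assert present_value(EarningsStreamSpec(1_000.0, 18.0, 65.0, 0.03, 0.05)) < present_value(base)
        assert present_value(EarningsStreamSpec(1_000.0, 18.0, 65.0, 0.05, 0.03)) > present_value(base)
        assert present_value(EarningsStreamSpec(1_000.0, 18.0, 60.0, 0.03, 0.03)) < present_value(base)

    def test_g_equals_r_closed_form_exact(self):
        for start, end in [(18.0, 65.0), (55.0, 65.0), (18.0, 62.5)]:
            spec = EarningsStreamSpec(2_000.0, start, end, 0.04, 0.04, scale_factors=0.5)
            assert present_value(spec) == pytest.approx(2_000.0 * 0.5 * (end - start), rel=1e-15)


class TestChildMortalityLoss:
    def test_zero_deaths(self, profile):
        assert child_mortality_loss(0.0, profile, EconomicAssumptions()) == 0.0

    def test_linear_in_deaths(self, profile):
        a = EconomicAssumptions()
        assert child_mortality_loss(100.0, profile, a) == pytest.approx(
            100.0 * child_mortality_loss(1.0, profile, a)
        )

    def test_cancellation_closed_form(self, profile):
        # g = r, GNI pc 2000, working ages 18-65 capped by retirement: 47 years
        a = EconomicAssumptions(discount_rate=0.03, gdp_growth=0.03)
        assert child_mortality_loss(10.0, profile, a) == pytest.approx(10.0 * 2_000.0 * 47.0)

    def test_life_expectancy_below_working_age_gives_zero(self, profile):
        profile.life_expectancy = 15.0
        with pytest.warns(UserWarning):
            assert child_mortality_loss(10.0, profile, EconomicAssumptions()) == 0.0

    def test_missing_gni_not_computed(self, profile):
        profile.gni_per_capita = None
        assert child_mortality_loss(10.0, profile, EconomicAssumptions()) is None


class TestMaternalMortalityLoss:
    def _burdens(self, profile, assumptions=None):
        return {pw: maternal_pathway_burden(profile, pw) for pw in
                ("breast_cancer_f", "ovarian_cancer_f", "t2dm_f")}

    def test_death_after_retirement_contributes_nothing(self, profile):
        for pw, epi in profile.epidemiology.pathways.items():
            if epi.mean_age_at_death_f is not None:
                epi.mean_age_at_death_f = 70.0
        loss = maternal_mortality_loss(self._burdens(profile), profile, EconomicAssumptions())
        assert loss == 0.0

    def test_cancellation_closed_form(self, profile):
        # 10 deaths at mean age 55, base 1000, g = r, end 65 -> 10 x 1000 x 10
        profile.gni_per_capita = 1_000.0
        epi = profile.epidemiology.pathways
        epi["breast_cancer_f"].mean_age_at_death_f = 55.0
        epi["ovarian_cancer_f"].deaths_annual = 0.0
        epi["t2dm_f"].deaths_annual = 0.0
        burdens = self._burdens(profile)
        deaths = burdens["breast_cancer_f"].attributable_deaths
        loss = maternal_mortality_loss(burdens, profile, EconomicAssumptions())
        assert loss == pytest.approx(deaths * 1_000.0 * 10.0)

    def test_zero_deaths(self, profile):
        for epi in profile.epidemiology.pathways.values():
            if epi.deaths_annual is not None:
                epi.deaths_annual = 0.0
        loss = maternal_mortality_loss(self._burdens(profile), profile, EconomicAssumptions())
        assert loss == 0.0

    def test_missing_mean_age_not_computed(self, profile):
        for epi in profile.epidemiology.pathways.values():
            epi.mean_age_at_death_f = None
        loss = maternal_mortality_loss(self._burdens(profile), profile, EconomicAssumptions())
        assert loss is None


class TestCognitiveLoss:
    def test_arithmetic_from_stream_inputs(self, profile):
        # 1 child, base 10 000, g = r, two working years before life
        # expectancy cuts the stream off at age 20
        profile.gni_per_capita = 10_000.0
        profile.life_expectancy = 20.0
        a = EconomicAssumptions()
        loss = cognitive_loss(1.0, profile, a)
        assert loss == pytest.approx(10_000.0 * 2.0 * 2.62 * 0.01067)
        assert loss == pytest.approx(559.11, abs=0.005)

    def test_zero_iq_gain(self, profile):
        a = EconomicAssumptions(iq_gain=0.0)
        assert cognitive_loss(1_000.0, profile, a) == 0.0

    def test_exposure_modes(self, profile):
        default = n_not_breastfed(profile, EconomicAssumptions())
        alt = n_not_breastfed(profile, EconomicAssumptions(cognitive_exposure_mode="bf_at_6m"))
        assert default == pytest.approx(profile.births_annual * 0.6)  # 1 - EBF 0.4
        assert alt == pytest.approx(profile.births_annual * 0.4)  # 1 - bf_at_6m 0.6

    def test_universal_exclusive_breastfeeding_zero_exposure(self, profile):
        profile.prevalence.band_0_5m = {
            "exclusive": 1.0, "predominant": 0.0, "partial": 0.0, "none": 0.0,
        }
        n = n_not_breastfed(profile, EconomicAssumptions())
        assert n == 0.0
        assert cognitive_loss(n, profile, EconomicAssumptions()) == 0.0

    def test_wage_share_toggle_scales_stream(self, profile):
        plain = cognitive_loss(100.0, profile, EconomicAssumptions())
        scaled = cognitive_loss(100.0, profile, EconomicAssumptions(apply_wage_share=True))
        assert scaled == pytest.approx(plain * profile.wage_share)


class TestTotalLoss:
    def _result(self, **kwargs) -> CountryResult:
        return CountryResult(
            "TST", Region.SOUTH_ASIA, IncomeGroup.LOWER_MIDDLE, gni_total=1.0e12, **kwargs
        )

    def test_sums_components(self):
        r = total_loss(
            self._result(
                health_cost_total=1.0,
                loss_child_mortality=2.0,
                loss_maternal_mortality=3.0,
                loss_cognitive=4.0,
            )
        )
        assert r.loss_total == 10.0
        assert r.loss_total_pct_gni == pytest.approx(10.0 / 1.0e12)

    def test_all_missing_flagged_not_zero(self):
        r = total_loss(self._result())
        assert r.loss_total is None
        assert set(r.missing_components) == {
            "health_cost_total",
            "loss_child_mortality",
            "loss_maternal_mortality",
            "loss_cognitive",
        }

    def test_component_magnitudes_add(self):
        r = total_loss(
            self._result(
                health_cost_total=0.196e9,
                loss_child_mortality=6.3e9,
                loss_maternal_mortality=0.0,
                loss_cognitive=59.0e9,
            )
        )
        assert r.loss_total == pytest.approx(65.496e9)

    def test_partial_missing_recorded_and_excluded(self):
        r = total_loss(
            self._result(health_cost_total=1.5, loss_child_mortality=None,
                         loss_maternal_mortality=2.5, loss_cognitive=None)
        )
        assert r.loss_total == 4.0
        assert "loss_child_mortality" in r.missing_components
        assert "loss_cognitive" in r.missing_components
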