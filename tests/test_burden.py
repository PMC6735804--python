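"""Attributable-fraction combining formula and per-pathway burden."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbfcost.burden import (
    child_pathway_burden,
    maternal_pathway_burden,
    obesity_burden,
    paf,
)


def expected_risk_paf(prevalence, rr):
    """Independent oracle: excess of the population's expected risk over the
    all-reference counterfactual, as a share of the expected risk."""
    expected = math.fsum(p * rr[c] for c, p in prevalence.items())
    counterfactual = math.fsum(prevalence.values())  # everyone at RR = 1
    return 1.0 - counterfactual / expected


class TestPaf:
    @pytest.mark.parametrize(
        "prevalence, rr, expected",
        [
            # all mass on the reference category: no excess risk
            ({"ref": 1.0, "exposed": 0.0}, {"ref": 1.0, "exposed": 3.0}, 0.0),
            # everyone exposed at RR 2 halves the burden if removed
            ({"exposed": 1.0, "ref": 0.0}, {"exposed": 2.0, "ref": 1.0}, 0.5),
            # three categories, expected risk 1.9 -> 0.9/1.9
            (
                {"a": 0.2, "b": 0.3, "c": 0.5},
                {"a": 1.0, "b": 1.5, "c": 2.5},
                0.9 / 1.9,
            ),
        ],
    )
    def test_known_values(self, prevalence, rr, expected):
        assert paf(prevalence, rr) == pytest.approx(expected, abs=1e-12)

    def test_category_mismatch_is_structural_error(self):
        with pytest.raises(KeyError):
            paf({"a": 1.0}, {"b": 1.0})

    def test_prevalence_must_sum_to_one(self):
        with pytest.raises(ValueError):
            paf({"a": 0.5, "b": 0.4}, {"a": 1.0, "b": 2.0})

    def test_reference_category_required(self):
        with pytest.raises(ValueError):
            paf({"a": 0.5, "b": 0.5}, {"a": 1.2, "b": 2.0})

    def test_agrees_with_expected_risk_oracle_on_random_draws(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            k = int(rng.integers(2, 6))
            cats = [f"c{i}" for i in range(k)]
            p = rng.dirichlet(np.ones(k))
            prevalence = dict(zip(cats, map(float, p)))
            rr = {c: float(rng.uniform(1.0, 10.0)) for c in cats}
            rr[cats[0]] = 1.0
            assert paf(prevalence, rr) == pytest.approx(
                expected_risk_paf(prevalence, rr), abs=1e-12
            )

    @given(
        p_exposed=st.floats(0.0, 1.0),
        rr_lo=st.floats(1.0, 10.0),
        bump=st.floats(0.0, 5.0),
    )
    @settings(derandomize=True, max_examples=200)
    def test_monotone_in_relative_risk(self, p_exposed, rr_lo, bump):
        prev = {"ref": 1.0 - p_exposed, "exp": p_exposed}
        low = paf(prev, {"ref": 1.0, "exp": rr_lo})
        high = paf(prev, {"ref": 1.0, "exp": rr_lo + bump})
        assert high >= low - 1e-15

    @given(
        p=st.floats(0.0, 0.5),
        shift=st.floats(0.0, 0.5),
        rr=st.floats(1.0, 10.0),
    )
    @settings(derandomize=True, max_examples=200)
    def test_monotone_in_exposure_shift_from_reference(self, p, shift, rr):
        before = paf({"ref": 1.0 - p, "exp": p}, {"ref": 1.0, "exp": rr})
        after = paf({"ref": 1.0 - p - shift, "exp": p + shift}, {"ref": 1.0, "exp": rr})
        assert after >= before - 1e-15

    @given(
        p=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=5),
        rr=st.lists(st.floats(1.0, 20.0), min_size=5, max_size=5),
    )
    @settings(derandomize=True, max_examples=200)
    def test_bounded_below_one_when_all_rr_at_least_one(self, p, rr):
        total = sum(p)
        prevalence = {f"c{i}": v / total for i, v in enumerate(p)}
        table = {f"c{i}": rr[i] for i in range(len(p))}
        table["c0"] = 1.0
        value = paf(prevalence, table)
        assert 0.0 <= value < 1.0


class TestChildPathway:
    def test_zero_paf_in_both_bands_gives_zero_burden(self, profile):
        for key in ("diarrhoea_0_5m", "diarrhoea_6_23m"):
            profile.relative_risks.tables[key] = {
                c: 1.0 for c in profile.relative_risks.tables[key]
            }
        pb = child_pathway_burden(profile, "diarrhoea_0_23m")
        assert pb.attributable_cases == 0.0 and pb.attributable_deaths == 0.0

    def test_band_pooling_weights_by_case_shares(self, profile):
        # band PAFs 0.5 (all-none at RR 2) and 0.25 (all-none at RR 4/3)
        profile.prevalence.band_0_5m = {
            "exclusive": 0.0, "predominant": 0.0, "partial": 0.0, "none": 1.0,
        }
        profile.prevalence.band_6_23m = {"any": 0.0, "none": 1.0}
        profile.relative_risks.tables["diarrhoea_0_5m"] = {
            "exclusive": 1.0, "predominant": 1.0, "partial": 1.0, "none": 2.0,
        }
        profile.relative_risks.tables["diarrhoea_6_23m"] = {"any": 1.0, "none": 4.0 / 3.0}
        pb = child_pathway_burden(profile, "diarrhoea_0_23m")
        # incidence 100 000 split evenly -> 0.5*0.5 + 0.5*0.25 = 0.375
        assert pb.attributable_cases == pytest.approx(37_500.0)

    def test_single_band_deaths(self, profile):
        # all deaths in the 0-5 m band whose PAF is 0.4 (all-none at RR 5/3)
        profile.prevalence.band_0_5m = {
            "exclusive": 0.0, "predominant": 0.0, "partial": 0.0, "none": 1.0,
        }
        profile.relative_risks.tables["diarrhoea_0_5m"] = {
            "exclusive": 1.0, "predominant": 1.0, "partial": 1.0, "none": 5.0 / 3.0,
        }
        profile.epidemiology.pathways["diarrhoea_0_23m"].share_deaths_0_5m = 1.0
        pb = child_pathway_burden(profile, "diarrhoea_0_23m")
        assert pb.attributable_deaths == pytest.approx(400.0)

    def test_attributable_never_exceeds_observed(self, profile):
        for pathway in ("diarrhoea_0_23m", "pneumonia_0_23m"):
            pb = child_pathway_burden(profile, pathway)
            epi = profile.epidemiology.get(pathway)
            assert 0.0 <= pb.attributable_cases <= epi.incidence_annual
            assert 0.0 <= pb.attributable_deaths <= epi.deaths_annual

    def test_missing_epidemiology_returns_not_computed(self, profile):
        del profile.epidemiology.pathways["pneumonia_0_23m"]
        assert child_pathway_burden(profile, "pneumonia_0_23m") is None

    def test_unknown_pathway_rejected(self, profile):
        with pytest.raises(ValueError):
            child_pathway_burden(profile, "obesity_child")


class TestObesity:
    def test_everyone_ever_breastfed_gives_zero(self, profile):
        profile.prevalence.ever_breastfed = 1.0
        assert obesity_burden(profile).attributable_cases == 0.0

    def test_levin_two_category_value(self, profile):
        profile.prevalence.ever_breastfed = 0.5
        profile.epidemiology.pathways["obesity_child"].incidence_annual = 10_000.0
        pb = obesity_burden(profile)
        assert pb.attributable_cases == pytest.approx(10_000.0 * (1.2 - 1.0) / 1.2)
        assert pb.attributable_deaths is None  # cases only for this pathway

    def test_null_relative_risk_gives_zero(self, profile):
        profile.relative_risks.tables["obesity_child"]["never"] = 1.0
        assert obesity_burden(profile).attributable_cases == 0.0


class TestMaternal:
    def test_counterfactual_already_met(self, profile):
        profile.prevalence.lifetime_duration_level = 1.0
        pb = maternal_pathway_burden(profile, "breast_cancer_f")
        assert pb.attributable_cases == 0.0 and pb.attributable_deaths == 0.0

    def test_levin_value_on_deaths(self, profile):
        profile.prevalence.lifetime_duration_level = 0.4  # 60% exposed
        profile.relative_risks.tables["breast_cancer_f"]["not_recommended"] = 1.3
        profile.epidemiology.pathways["breast_cancer_f"].deaths_annual = 2_000.0
        pb = maternal_pathway_burden(profile, "breast_cancer_f")
        assert pb.attributable_deaths == pytest.approx(2_000.0 * 0.18 / 1.18)

    def test_mortality_uses_same_fraction_as_morbidity(self, profile):
        pb = maternal_pathway_burden(profile, "t2dm_f")
        epi = profile.epidemiology.get("t2dm_f")
        assert pb.attributable_cases / epi.incidence_annual == pytest.approx(
            pb.attributable_deaths / epi.deaths_annual
        )

    def test_rr_one_gives_zero(self, profile):
        profile.relative_risks.tables["ovarian_cancer_f"]["not_recommended"] = 1.0
        pb = maternal_pathway_burden(profile, "ovarian_cancer_f")
        assert pb.attributable_deaths == 0.0

    def test_literal_mode_applies_excess_risk_product(self, profile):
        profile.prevalence.lifetime_duration_level = 0.4
        profile.relative_risks.tables["breast_cancer_f"]["not_recommended"] = 1.3
        profile.epidemiology.pathways["breast_cancer_f"].deaths_annual = 2_000.0
        pb = maternal_pathway_burden(profile, "breast_cancer_f", mode="literal")
        assert pb.attributable_deaths == pytest.approx(2_000.0 * 0.3 * 0.6)
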