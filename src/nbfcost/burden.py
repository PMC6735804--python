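"""Attributable burden under a universal-breastfeeding counterfactual.

Each disease pathway combines the population distribution over
breastfeeding-exposure categories with published relative risks through the
multi-category Levin population attributable fraction

    PAF = (sum_c p_c RR_c - 1) / (sum_c p_c RR_c),

with the recommended practice as the reference category (RR = 1).  The PAF is
then applied to observed incidence and deaths.  Child infectious pathways
(diarrhoea, pneumonia, ages 0-23 months) pool a 0-5-month and a 6-23-month
band PAF weighted by each band's share of the burden; the obesity pathway
contrasts ever- vs never-breastfed; maternal pathways (breast cancer, ovarian
cancer, type II diabetes in women) contrast lifetime breastfeeding per
recommendation vs not, with the mortality effect assumed equal in magnitude
to the morbidity effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping

from .domain import (
    CHILD_INFECTIOUS_PATHWAYS,
    MATERNAL_PATHWAYS,
    OBESITY_PATHWAY,
    CountryProfile,
)

_SUM_TOL = 1e-9


@dataclass
class PathwayBurden:
    """Attributable cases and deaths for one pathway.

    ``paf_used`` is the fraction applied to cases; ``paf_deaths_used`` the
    fraction applied to deaths (they differ for child pathways when the two
    age bands carry different shares of cases and deaths).  ``None`` marks a
    quantity that was not computed for lack of inputs.
    """

    pathway: str
    attributable_cases: float | None
    attributable_deaths: float | None
    paf_used: float | None
    paf_deaths_used: float | None = None

    def __post_init__(self) -> None:
        if self.paf_deaths_used is None:
            self.paf_deaths_used = self.paf_used


def paf(prevalence: Mapping[str, float], rr: Mapping[str, float]) -> float:
    """Levin population attributable fraction over exposure categories.

    Parameters
    ----------
    prevalence
        Category → population fraction; must sum to 1.
    rr
        Category → relative risk over the same categories, with one
        reference category at RR = 1.

    Returns
    -------
    float
        ``(sum p_c RR_c - 1) / (sum p_c RR_c)`` — in ``[0, 1)`` whenever all
        RR >= 1.

    Raises
    ------
    KeyError
        If the category sets of the two maps differ.
    ValueError
        If the prevalence does not sum to 1, or no reference RR = 1 exists.
    """
    if set(prevalence) != set(rr):
        missing = set(prevalence) ^ set(rr)
        raise KeyError(f"prevalence/RR category mismatch: {sorted(missing)}")
    total = sum(prevalence.values())
    if abs(total - 1.0) > _SUM_TOL:
        raise ValueError(f"prevalence sums to {total!r}, expected 1")
    if not any(math.isclose(v, 1.0, rel_tol=0, abs_tol=1e-12) for v in rr.values()):
        raise ValueError("relative-risk table has no reference category with RR = 1")
    # (sum p RR - sum p) / sum p RR: identical to the Levin form when the
    # prevalence sums to 1 exactly, but exactly 0 (not float noise) when all
    # RR = 1, and nonnegative whenever all RR >= 1.
    expected_risk = math.fsum(prevalence[c] * rr[c] for c in prevalence)
    return (expected_risk - math.fsum(prevalence.values())) / expected_risk


def _two_category_paf(p_exposed: float, rr_exposed: float) -> float:
    return paf(
        {"recommended": 1.0 - p_exposed, "not_recommended": p_exposed},
        {"recommended": 1.0, "not_recommended": rr_exposed},
    )


def child_pathway_burden(
    profile: CountryProfile,
    pathway: str,
    band_weights: tuple[float, float] | None = None,
) -> PathwayBurden | None:
    """Attributable cases and deaths for a child infectious pathway.

    Band PAFs for 0-5 months and 6-23 months are pooled with weights equal to
    each band's share of cases (resp. deaths); ``band_weights`` overrides the
    (cases, deaths) 0-5-month shares.  Returns ``None`` (component not
    computed) when prevalence, relative risks or epidemiology are missing.
    """
    if pathway not in CHILD_INFECTIOUS_PATHWAYS:
        raise ValueError(f"not a child infectious pathway: {pathway!r}")
    prev = profile.prevalence
    rr = profile.relative_risks
    epi = profile.epidemiology.get(pathway) if profile.epidemiology else None
    if prev is None or rr is None or epi is None:
        return None
    stem = pathway.removesuffix("_0_23m")
    rr_05 = rr.get(f"{stem}_0_5m")
    rr_623 = rr.get(f"{stem}_6_23m")
    if rr_05 is None or rr_623 is None:
        return None

    paf_05 = paf(prev.band_0_5m, rr_05)
    paf_623 = paf(prev.band_6_23m, rr_623)

    if band_weights is not None:
        w_cases, w_deaths = band_weights
    else:
        w_cases = epi.share_cases_0_5m if epi.share_cases_0_5m is not None else 0.5
        w_deaths = epi.share_deaths_0_5m if epi.share_deaths_0_5m is not None else 0.5
    paf_cases = w_cases * paf_05 + (1.0 - w_cases) * paf_623
    paf_deaths = w_deaths * paf_05 + (1.0 - w_deaths) * paf_623

    cases = epi.incidence_annual * paf_cases if epi.incidence_annual is not None else None
    deaths = epi.deaths_annual * paf_deaths if epi.deaths_annual is not None else None
    if cases is None and deaths is None:
        return None
    return PathwayBurden(pathway, cases, deaths, paf_cases, paf_deaths)


def obesity_burden(profile: CountryProfile) -> PathwayBurden | None:
    """Attributable childhood-obesity cases (never- vs ever-breastfed).

    Deaths are not computed for this pathway.
    """
    prev = profile.prevalence
    rr = profile.relative_risks
    epi = profile.epidemiology.get(OBESITY_PATHWAY) if profile.epidemiology else None
    table = rr.get(OBESITY_PATHWAY) if rr else None
    if prev is None or table is None or epi is None or epi.incidence_annual is None:
        return None
    p_never = 1.0 - prev.ever_breastfed
    frac = paf(
        {"ever": 1.0 - p_never, "never": p_never},
        {"ever": table["ever"], "never": table["never"]},
    )
    return PathwayBurden(OBESITY_PATHWAY, epi.incidence_annual * frac, None, frac)


def maternal_pathway_burden(
    profile: CountryProfile,
    pathway: str,
    mode: Literal["paf", "literal"] = "paf",
) -> PathwayBurden | None:
    """Attributable burden for a maternal pathway.

    Default ``"paf"`` mode uses a two-category Levin PAF with exposure
    prevalence ``1 - lifetime_duration_level`` and the pathway's RR for not
    breastfeeding per recommendation, applied identically to incidence and to
    deaths (the mortality effect is assumed equal in magnitude to the
    morbidity effect).  ``"literal"`` mode instead applies the excess-risk
    product ``observed x (RR - 1) x exposure shortfall``, kept for audit
    comparison runs.
    """
    if pathway not in MATERNAL_PATHWAYS:
        raise ValueError(f"not a maternal pathway: {pathway!r}")
    prev = profile.prevalence
    rr = profile.relative_risks
    epi = profile.epidemiology.get(pathway) if profile.epidemiology else None
    table = rr.get(pathway) if rr else None
    if prev is None or table is None or epi is None:
        return None

    p_exposed = 1.0 - prev.lifetime_duration_level
    rr_exposed = table["not_recommended"]
    if mode == "paf":
        frac = _two_category_paf(p_exposed, rr_exposed)
    elif mode == "literal":
        frac = (rr_exposed - 1.0) * p_exposed
    else:
        raise ValueError(f"unknown mode {mode!r}")

    cases = epi.incidence_annual * frac if epi.incidence_annual is not None else None
    deaths = epi.deaths_annual * frac if epi.deaths_annual is not None else None
    if cases is None and deaths is None:
        return None
    return PathwayBurden(pathway, cases, deaths, frac)
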