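"""Long-format CSV ingestion and emission, run configuration and pipeline.

Every indicator family lives in one long-format CSV with columns
``country_code, indicator, stratum, value, year, source`` (UTF-8, comma
separated, ``.`` decimal; thousands separators written as spaces are
stripped on read).  ``countries.csv`` carries the region / income-group
labels.  Floats are written with ``repr`` so a written dataset re-reads to
exactly equal profiles.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable

from pydantic import BaseModel, ConfigDict

from .aggregate import aggregate, run_sensitivity
from .domain import (
    ALL_PATHWAYS,
    BreastfeedingPrevalence,
    CareSeeking,
    CareSeekingCascade,
    CountryProfile,
    CountryResult,
    DiseaseEpidemiology,
    EconomicAssumptions,
    IncomeGroup,
    PathwayEpi,
    Region,
    RelativeRiskTable,
    Scenario,
    UnitCosts,
    DEFAULT_SCENARIOS,
    validate_profile,
)
from .pipeline import estimate_countries

logger = logging.getLogger("nbfcost")

MANDATORY_FILES = (
    "countries.csv",
    "demography.csv",
    "economy.csv",
    "breastfeeding.csv",
    "epidemiology.csv",
    "relative_risks.csv",
)
OPTIONAL_FILES = ("care_seeking.csv", "unit_costs.csv")

_HEADER = ("country_code", "indicator", "stratum", "value", "year", "source")
DEFAULT_YEAR = 2017


class DataLoadError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Writing


def _rows_for_profile(profile: CountryProfile) -> dict[str, list[tuple]]:
    """Long-format rows per file for one profile."""
    rows: dict[str, list[tuple]] = {name: [] for name in MANDATORY_FILES + OPTIONAL_FILES}
    cc = profile.country_code

    def put(fname: str, indicator: str, stratum: str, value) -> None:
        if value is None:
            return
        rows[fname].append((cc, indicator, stratum, repr(float(value)), DEFAULT_YEAR, "synthetic"))

    rows["countries.csv"].append((cc, profile.region.value, profile.income_group.value))

    put("demography.csv", "births_annual", "", profile.births_annual)
    put("demography.csv", "children_0_23m", "", profile.children_0_23m)
    for name in (
        "gni_total", "gni_per_capita", "life_expectancy", "retirement_age",
        "wage_share", "lfpr_female", "mean_monthly_wage", "cpi_cumulative_2008_2017",
    ):
        put("economy.csv", name, "", getattr(profile, name))

    prev = profile.prevalence
    if prev is not None:
        for cat, v in prev.band_0_5m.items():
            put("breastfeeding.csv", "prevalence_0_5m", cat, v)
        for cat, v in prev.band_6_23m.items():
            put("breastfeeding.csv", "prevalence_6_23m", cat, v)
        put("breastfeeding.csv", "ever_breastfed", "", prev.ever_breastfed)
        put("breastfeeding.csv", "bf_at_6m", "", prev.bf_at_6m)
        put("breastfeeding.csv", "lifetime_duration_level", "", prev.lifetime_duration_level)

    if profile.epidemiology is not None:
        for pw, epi in profile.epidemiology.pathways.items():
            for f in dataclasses.fields(epi):
                put("epidemiology.csv", f.name, pw, getattr(epi, f.name))

    if profile.relative_risks is not None:
        for key, table in profile.relative_risks.tables.items():
            for cat, rr in table.items():
                put("relative_risks.csv", "relative_risk", f"{key}:{cat}", rr)

    if profile.cascade is not None:
        for pw, cs in profile.cascade.pathways.items():
            put("care_seeking.csv", "pct_taken_to_facility", pw, cs.pct_taken_to_facility)
            put("care_seeking.csv", "pct_inpatient_given_care", pw, cs.pct_inpatient_given_care)
            for lvl, w in cs.facility_mix_outpatient.items():
                put("care_seeking.csv", "facility_mix_outpatient", f"{pw}:{lvl}", w)
            for lvl, w in cs.facility_mix_inpatient.items():
                put("care_seeking.csv", "facility_mix_inpatient", f"{pw}:{lvl}", w)
            put("care_seeking.csv", "visits_per_outpatient_case", pw, cs.visits_per_outpatient_case)
            put("care_seeking.csv", "bed_days_per_inpatient_case", pw, cs.bed_days_per_inpatient_case)

    uc = profile.unit_costs
    if uc is not None:
        for lvl, c in uc.outpatient_visit_cost.items():
            put("unit_costs.csv", "outpatient_visit_cost", lvl, c)
        for lvl, c in uc.inpatient_day_cost.items():
            put("unit_costs.csv", "inpatient_day_cost", lvl, c)
        put("unit_costs.csv", "t2dm_expenditure_per_case", "", uc.t2dm_expenditure_per_case)
        put("unit_costs.csv", "pct_t2dm_diagnosed", "", uc.pct_t2dm_diagnosed)
        put("unit_costs.csv", "formula_price_per_900g", "", uc.formula_price_per_900g)
        put("unit_costs.csv", "formula_containers_birth_to_24m", "", uc.formula_containers_birth_to_24m)

    return rows


def write_country_tables(profiles: Iterable[CountryProfile], directory: str | Path) -> None:
    """Write the long-format CSV dataset for a set of country profiles."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    all_rows: dict[str, list[tuple]] = {f: [] for f in MANDATORY_FILES + OPTIONAL_FILES}
    for profile in profiles:
        for fname, rows in _rows_for_profile(profile).items():
            all_rows[fname].extend(rows)
    for fname, rows in all_rows.items():
        with open(directory / fname, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            if fname == "countries.csv":
                writer.writerow(("country_code", "region", "income_group"))
            else:
                writer.writerow(_HEADER)
            writer.writerows(rows)


# ---------------------------------------------------------------------------
# Reading


def _read_long(path: Path) -> dict[str, dict[tuple[str, str], float]]:
    """country_code → {(indicator, stratum): value}; raises on malformed rows."""
    out: dict[str, dict[tuple[str, str], float]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            raw = (row.get("value") or "").replace(" ", "")
            try:
                value = float(raw)
            except ValueError:
                raise DataLoadError(
                    f"{path.name}:{lineno}: non-numeric value {row.get('value')!r} "
                    f"for indicator {row.get('indicator')!r}"
                ) from None
            cc = row["country_code"]
            out.setdefault(cc, {})[(row["indicator"], row["stratum"] or "")] = value
    return out


def read_country_tables(directory: str | Path) -> list[CountryProfile]:
    """Assemble one :class:`CountryProfile` per country from a dataset dir.

    Mandatory files must exist; optional ones (care seeking, unit costs)
    merely set availability flags when absent.  A country present in one
    indicator file but absent in another is flagged partially available.
    """
    directory = Path(directory)
    missing = [f for f in MANDATORY_FILES if not (directory / f).exists()]
    if missing:
        raise DataLoadError(f"missing mandatory file(s) in {directory}: {', '.join(missing)}")

    meta: dict[str, tuple[Region, IncomeGroup]] = {}
    with open(directory / "countries.csv", newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            try:
                meta[row["country_code"]] = (
                    Region(row["region"]),
                    IncomeGroup(row["income_group"]),
                )
            except ValueError as exc:
                raise DataLoadError(f"countries.csv:{lineno}: {exc}") from None

    data = {}
    for fname in MANDATORY_FILES[1:] + OPTIONAL_FILES:
        path = directory / fname
        data[fname] = _read_long(path) if path.exists() else {}

    profiles = []
    for cc, (region, income) in meta.items():
        demo = data["demography.csv"].get(cc, {})
        econ = data["economy.csv"].get(cc, {})
        bf = data["breastfeeding.csv"].get(cc, {})
        epi_rows = data["epidemiology.csv"].get(cc, {})
        rr_rows = data["relative_risks.csv"].get(cc, {})
        care_rows = data["care_seeking.csv"].get(cc, {})
        cost_rows = data["unit_costs.csv"].get(cc, {})

        flags = {
            "demography": bool(demo),
            "economy": bool(econ),
            "prevalence": bool(bf),
            "epidemiology": bool(epi_rows),
            "relative_risks": bool(rr_rows),
            "cascade": bool(care_rows),
            "unit_costs": bool(cost_rows),
        }

        prevalence = None
        if bf:
            prevalence = BreastfeedingPrevalence(
                band_0_5m={k[1]: v for k, v in bf.items() if k[0] == "prevalence_0_5m"},
                band_6_23m={k[1]: v for k, v in bf.items() if k[0] == "prevalence_6_23m"},
                ever_breastfed=bf.get(("ever_breastfed", ""), 0.0),
                bf_at_6m=bf.get(("bf_at_6m", ""), 0.0),
                lifetime_duration_level=bf.get(("lifetime_duration_level", ""), 0.0),
            )

        epidemiology = None
        if epi_rows:
            pathways: dict[str, PathwayEpi] = {}
            for (indicator, pw), value in epi_rows.items():
                epi = pathways.setdefault(pw, PathwayEpi())
                setattr(epi, indicator, value)
            epidemiology = DiseaseEpidemiology(pathways=pathways)

        relative_risks = None
        if rr_rows:
            tables: dict[str, dict[str, float]] = {}
            for (_, stratum), value in rr_rows.items():
                key, _, cat = stratum.rpartition(":")
                tables.setdefault(key, {})[cat] = value
            relative_risks = RelativeRiskTable(tables=tables)

        cascade = None
        if care_rows:
            by_pw: dict[str, dict] = {}
            for (indicator, stratum), value in care_rows.items():
                if ":" in stratum:
                    pw, _, lvl = stratum.partition(":")
                    by_pw.setdefault(pw, {}).setdefault(indicator, {})[lvl] = value
                else:
                    by_pw.setdefault(stratum, {})[indicator] = value
            cascade = CareSeekingCascade(
                pathways={
                    pw: CareSeeking(
                        pct_taken_to_facility=d.get("pct_taken_to_facility", 0.0),
                        pct_inpatient_given_care=d.get("pct_inpatient_given_care", 0.0),
                        facility_mix_outpatient=d.get("facility_mix_outpatient", {}),
                        facility_mix_inpatient=d.get("facility_mix_inpatient", {}),
                        visits_per_outpatient_case=d.get("visits_per_outpatient_case", 1.0),
                        bed_days_per_inpatient_case=d.get("bed_days_per_inpatient_case", 3.0),
                    )
                    for pw, d in by_pw.items()
                }
            )

        unit_costs = None
        if cost_rows:
            out_costs = {k[1]: v for k, v in cost_rows.items() if k[0] == "outpatient_visit_cost"}
            day_costs = {k[1]: v for k, v in cost_rows.items() if k[0] == "inpatient_day_cost"}
            unit_costs = UnitCosts(
                outpatient_visit_cost=out_costs,
                inpatient_day_cost=day_costs,
                t2dm_expenditure_per_case=cost_rows.get(("t2dm_expenditure_per_case", "")),
                pct_t2dm_diagnosed=cost_rows.get(("pct_t2dm_diagnosed", "")),
                formula_price_per_900g=cost_rows.get(("formula_price_per_900g", "")),
                formula_containers_birth_to_24m=cost_rows.get(
                    ("formula_containers_birth_to_24m", ""), 50.0
                ),
            )
        flags["formula_price_per_900g"] = (
            unit_costs is not None and unit_costs.formula_price_per_900g is not None
        )

        profiles.append(
            CountryProfile(
                country_code=cc,
                region=region,
                income_group=income,
                births_annual=demo.get(("births_annual", ""), 0.0),
                children_0_23m=demo.get(("children_0_23m", ""), 0.0),
                gni_total=econ.get(("gni_total", "")),
                gni_per_capita=econ.get(("gni_per_capita", "")),
                life_expectancy=econ.get(("life_expectancy", "")),
                retirement_age=econ.get(("retirement_age", ""), 65.0),
                wage_share=econ.get(("wage_share", "")),
                lfpr_female=econ.get(("lfpr_female", "")),
                mean_monthly_wage=econ.get(("mean_monthly_wage", "")),
                cpi_cumulative_2008_2017=econ.get(("cpi_cumulative_2008_2017", ""), 1.0),
                prevalence=prevalence,
                epidemiology=epidemiology,
                relative_risks=relative_risks,
                cascade=cascade,
                unit_costs=unit_costs,
                data_flags=flags,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# Run configuration and pipeline


class RunConfig(BaseModel):
    """Effective configuration of one estimation run.

    Unknown keys are rejected, and the effective configuration is echoed
    into the run log so any output can be reproduced from it.
    """

    model_config = ConfigDict(extra="forbid")

    input_dir: str
    output_dir: str
    discount_rate: float = 0.03
    gdp_growth: float = 0.03
    cognitive_exposure_mode: str = "exclusive_lt6m"
    apply_wage_share: bool = False
    apply_lfpr: bool = False
    grouping: str = "region"
    scenarios: list[str] = ["default", "conservative", "optimistic"]
    log_level: str = "INFO"

    def assumptions(self) -> EconomicAssumptions:
        return EconomicAssumptions(
            discount_rate=self.discount_rate,
            gdp_growth=self.gdp_growth,
            cognitive_exposure_mode=self.cognitive_exposure_mode,
            apply_wage_share=self.apply_wage_share,
            apply_lfpr=self.apply_lfpr,
        )

    def scenario_objects(self) -> list[Scenario]:
        out = []
        for label in self.scenarios:
            if label not in DEFAULT_SCENARIOS:
                raise ValueError(f"unknown scenario {label!r}")
            out.append(DEFAULT_SCENARIOS[label])
        return out


def results_to_rows(results: Iterable[CountryResult]) -> list[dict]:
    rows = []
    for r in results:
        row: dict = {
            "country_code": r.country_code,
            "region": r.region.value if r.region else "",
            "income_group": r.income_group.value if r.income_group else "",
            "gni_total": r.gni_total,
        }
        for pw in ALL_PATHWAYS:
            row[f"cases_{pw}"] = r.attributable_cases.get(pw)
            row[f"deaths_{pw}"] = r.attributable_deaths.get(pw)
        for comp, v in r.health_cost.items():
            row[f"health_cost_{comp}"] = v
        row.update(
            health_cost_total=r.health_cost_total,
            formula_cost_share_of_wages=r.formula_cost_share_of_wages,
            loss_child_mortality=r.loss_child_mortality,
            loss_maternal_mortality=r.loss_maternal_mortality,
            loss_cognitive=r.loss_cognitive,
            loss_total=r.loss_total,
            loss_total_pct_gni=r.loss_total_pct_gni,
            missing_components=";".join(r.missing_components),
        )
        rows.append(row)
    return rows


def run_pipeline(config: RunConfig):
    """Read a dataset, estimate every country, aggregate, and write reports.

    Writes ``country_results.csv``, per-grouping aggregate CSVs, a scenario
    sensitivity CSV and ``run_log.json`` (with the effective config echoed)
    into ``config.output_dir``.  Countries with validation violations are
    logged and still processed where possible.
    """
    import pandas as pd

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    profiles = read_country_tables(config.input_dir)
    excluded: dict[str, list[str]] = {}
    for p in profiles:
        violations = validate_profile(p)
        if violations:
            excluded[p.country_code] = violations
            logger.warning("%s: %d validation violation(s)", p.country_code, len(violations))

    assumptions = config.assumptions()
    results = estimate_countries(profiles, assumptions)
    aggregates = {
        grouping: aggregate(results, grouping)  # type: ignore[arg-type]
        for grouping in ("region", "income", "global")
    }
    sensitivity = run_sensitivity(
        profiles, config.scenario_objects(), assumptions, grouping="global"
    )

    pd.DataFrame(results_to_rows(results)).to_csv(out_dir / "country_results.csv", index=False)
    for grouping, groups in aggregates.items():
        rows = []
        for label, agg in groups.items():
            row = {"group": label, "n_countries": agg.n_countries}
            for pw, v in agg.attributable_cases.items():
                row[f"cases_{pw}"] = v
            for pw, v in agg.attributable_deaths.items():
                row[f"deaths_{pw}"] = v
            for comp, v in agg.health_cost.items():
                row[f"health_cost_{comp}"] = v
            row.update(
                health_cost_total=agg.health_cost_total,
                loss_child_mortality=agg.loss_child_mortality,
                loss_maternal_mortality=agg.loss_maternal_mortality,
                loss_cognitive=agg.loss_cognitive,
                loss_total=agg.loss_total,
                pct_gni=agg.pct_gni,
            )
            rows.append(row)
        pd.DataFrame(rows).to_csv(out_dir / f"aggregate_{grouping}.csv", index=False)

    sens_rows = [
        {
            "scenario": label,
            "group": g,
            "loss_child_mortality": agg.loss_child_mortality,
            "loss_maternal_mortality": agg.loss_maternal_mortality,
            "loss_cognitive": agg.loss_cognitive,
            "loss_total": agg.loss_total,
            "pct_gni": agg.pct_gni,
        }
        for label, groups in sensitivity.items()
        for g, agg in groups.items()
    ]
    pd.DataFrame(sens_rows).to_csv(out_dir / "sensitivity.csv", index=False)

    log = {
        "config": config.model_dump(),
        "n_countries": len(profiles),
        "countries_with_violations": excluded,
        "missing_components": {
            r.country_code: r.missing_components for r in results if r.missing_components
        },
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return results, aggregates, sensitivity
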