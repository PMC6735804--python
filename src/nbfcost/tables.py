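"""Packaged reporting-table rows for aggregation verification.

The package ships the published regional and income-group rows of the four
global reporting tables (annual morbidity cases, annual deaths, health-system
treatment costs in US$ millions, and discounted economic losses in US$
billions under the default / conservative / optimistic scenarios).  These
rows are verification fixtures: feeding them through the same aggregation
operation used for country results must reproduce the printed grand totals.
The underlying ~130 raw country datasets are not bundled.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .domain import AggregateResult, CountryResult, IncomeGroup, Region

_CHECKSUMS = {
    "table1_morbidity_cases.csv": "5212dc793f60e0285d65127b222fbd3c3d6e252d2b53aacf298044d788496f35",
    "table2_deaths.csv": "4309e7ff83c466b42fb76f53ebad9bc6ac15052ab15780de0ce732a64e4153c6",
    "table3_health_costs_usd_m.csv": "3a0718a709f86dc89e8aa64af94a079c7c061a6ca4774e9f133db9b5182be5ca",
    "table4_losses_usd_b.csv": "3b0aed79b01ad442f6f643cd673c6dfd36d5c5f7fb0a5912144c407d8268ff64",
}

TABLE_FILES = {
    "morbidity": "table1_morbidity_cases.csv",
    "deaths": "table2_deaths.csv",
    "health_costs": "table3_health_costs_usd_m.csv",
    "losses": "table4_losses_usd_b.csv",
}


class TableChecksumError(RuntimeError):
    """Raised when a packaged table file does not match its recorded hash."""


def _read_packaged(filename: str) -> pd.DataFrame:
    ref = resources.files("nbfcost.data") / filename
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[filename]:
        raise TableChecksumError(
            f"{filename}: sha256 {digest} != expected {_CHECKSUMS[filename]}"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


def load_published_tables() -> dict[str, pd.DataFrame]:
    """Load the packaged table rows, verifying each file's checksum.

    Returns a mapping with keys ``morbidity``, ``deaths``, ``health_costs``
    and ``losses``.  Each frame carries a ``group_type`` column
    (``region`` / ``income`` / ``income_combined`` / ``total``); the
    ``total`` row is the published grand total and the ``income_combined``
    row (low- and middle-income) overlaps the income groups, so neither
    belongs in a sum over rows.
    """
    return {key: _read_packaged(fname) for key, fname in TABLE_FILES.items()}


def _enum_or_none(enum_cls, label: str):
    try:
        return enum_cls(label)
    except ValueError:
        return None


def table_rows_as_results(
    tables: dict[str, pd.DataFrame] | None = None,
    group_type: str = "region",
    scenario: str = "default",
) -> list[CountryResult]:
    """Convert printed table rows into aggregatable result records.

    Each region (or income-group) row becomes one record holding that row's
    printed cells — morbidity cases, deaths, health costs (US$ m) and losses
    (US$ b) under ``scenario`` — so that :func:`nbfcost.aggregate.aggregate`
    over the records reproduces the printed grand totals.  These records mix
    the tables' printed units and are for aggregation verification only.
    """
    if tables is None:
        tables = load_published_tables()
    if group_type not in ("region", "income"):
        raise ValueError(f"group_type must be 'region' or 'income', got {group_type!r}")

    morb = tables["morbidity"].set_index("group")
    deaths = tables["deaths"].set_index("group")
    costs = tables["health_costs"].set_index("group")
    losses = tables["losses"].set_index("group")

    groups = [
        g for g, t in zip(tables["morbidity"]["group"], tables["morbidity"]["group_type"])
        if t == group_type
    ]
    records: list[CountryResult] = []
    for g in groups:
        m, d, c, lo = morb.loc[g], deaths.loc[g], costs.loc[g], losses.loc[g]
        rec = CountryResult(
            country_code=g,
            region=_enum_or_none(Region, g),
            income_group=_enum_or_none(IncomeGroup, g),
            attributable_cases={
                pw: float(m[pw])
                for pw in (
                    "diarrhoea_0_23m", "pneumonia_0_23m", "obesity_child",
                    "breast_cancer_f", "ovarian_cancer_f", "t2dm_f",
                )
            },
            attributable_deaths={
                pw: float(d[pw])
                for pw in (
                    "diarrhoea_0_23m", "pneumonia_0_23m", "total_child",
                    "breast_cancer_f", "ovarian_cancer_f", "t2dm_f", "total_maternal",
                )
            },
            health_cost={k: float(c[k]) for k in ("diarrhoea", "pneumonia", "t2dm")},
            health_cost_total=float(c["total"]),
            loss_child_mortality=float(lo[f"child_mortality_{scenario}"]),
            loss_maternal_mortality=float(lo[f"maternal_mortality_{scenario}"]),
            loss_cognitive=float(lo[f"cognitive_{scenario}"]),
            loss_total=float(lo[f"total_{scenario}"]),
        )
        # Implied group GNI from the printed total and its %-of-GNI share,
        # letting the global % of GNI be recomputed from rows.
        pct = float(lo[f"pct_gni_{scenario}"])
        rec.gni_total = rec.loss_total / (pct / 100.0) if pct > 0 else None
        records.append(rec)
    return records


def printed_totals(
    tables: dict[str, pd.DataFrame] | None = None, scenario: str = "default"
) -> AggregateResult:
    """The published grand-total row, as an :class:`AggregateResult` for
    comparison against recomputed aggregates."""
    if tables is None:
        tables = load_published_tables()
    m = tables["morbidity"].set_index("group").loc["Total"]
    d = tables["deaths"].set_index("group").loc["Total"]
    c = tables["health_costs"].set_index("group").loc["Total"]
    lo = tables["losses"].set_index("group").loc["Total"]
    agg = AggregateResult(label="printed-total")
    agg.attributable_cases = {
        pw: float(m[pw])
        for pw in (
            "diarrhoea_0_23m", "pneumonia_0_23m", "obesity_child",
            "breast_cancer_f", "ovarian_cancer_f", "t2dm_f",
        )
    }
    agg.attributable_deaths = {
        pw: float(d[pw])
        for pw in (
            "diarrhoea_0_23m", "pneumonia_0_23m", "total_child",
            "breast_cancer_f", "ovarian_cancer_f", "t2dm_f", "total_maternal",
        )
    }
    agg.health_cost = {k: float(c[k]) for k in ("diarrhoea", "pneumonia", "t2dm")}
    agg.health_cost_total = float(c["total"])
    agg.loss_child_mortality = float(lo[f"child_mortality_{scenario}"])
    agg.loss_maternal_mortality = float(lo[f"maternal_mortality_{scenario}"])
    agg.loss_cognitive = float(lo[f"cognitive_{scenario}"])
    agg.loss_total = float(lo[f"total_{scenario}"])
    agg.pct_gni = float(lo[f"pct_gni_{scenario}"]) / 100.0
    return agg
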