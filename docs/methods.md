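# Methods

This note documents the model implemented by `nbfcost`, its assumptions,
the numerical choices made where the design was genuinely open, and what
the synthetic data generator does and does not emulate.

## Estimation framework

The engine values one annual cohort of births (and their mothers) under the
counterfactual of universal breastfeeding per WHO/UNICEF recommendation.
Three indicator families are computed per country and summed:

1. **morbidity and mortality** attributable to sub-recommendation
   breastfeeding, per disease pathway;
2. **health-system and household costs** of treating the attributable
   cases and of purchasing formula;
3. **future economic losses** — discounted foregone earnings from premature
   mortality and from cognitive deficit — projected over the cohort's
   productive years.

All monetary values are nominal US$ in a single configurable base year
(default 2017); CPI adjustment (`cpi_cumulative_2008_2017`) is applied only
to the WHO-CHOICE-style facility unit costs, which are published on a 2008
price base.

### Attributable fraction

The exposure–risk combination is the multi-category Levin population
attributable fraction, PAF = (Σp·RR − 1)/(Σp·RR), with the recommended
practice as the RR = 1 reference.  The implementation evaluates
(Σp·RR − Σp)/(Σp·RR) with compensated summation, which is algebraically
identical on a unit simplex but returns exactly zero when no category
carries excess risk and is guaranteed nonnegative when all RR ≥ 1.  A
`literal` mode for maternal pathways applies the unbounded excess-risk
product `observed × (RR − 1) × shortfall` instead; it exists for audit
comparisons and is never the default, because it is not bounded by the
observed burden.

Child infectious pathways (diarrhoea, pneumonia; ages 0–23 months) compute
one PAF per age band — 0–5 months over {exclusive, predominant, partial,
none}, 6–23 months over {any, none} — and pool them with weights equal to
each band's share of cases (respectively deaths).  The band shares travel
with the epidemiology record; when a source does not stratify, the bands
are weighted equally (0.5), and callers can override the weights.

Childhood obesity uses a two-category contrast (ever vs never breastfed)
and reports cases only.  Maternal pathways (breast cancer, ovarian cancer,
type II diabetes in women) use exposure prevalence 1 − lifetime duration
attainment; the same fraction is applied to incidence and to deaths — the
mortality effect is assumed equal in magnitude to the morbidity effect.

### Treatment cascade

Attributable cases × `pct_taken_to_facility` split into inpatient
(`pct_inpatient_given_care`) and outpatient care, each distributed over
four facility levels (health centre, primary, secondary, tertiary
hospital).  Outpatient episodes are priced per visit
(`visits_per_outpatient_case`, default 1) and inpatient episodes per bed
day (`bed_days_per_inpatient_case`, default 3); neither count is stated by
the published sources, so both are explicit configuration and every shipped
fixture sets its own values.  The cascade conserves cases: outpatient +
inpatient = cases × pct_taken_to_facility.  A facility level carrying
nonzero mix weight but no unit cost marks the component "not computed"
rather than pricing it at zero.

Diabetes treatment is cases × share diagnosed × annual expenditure per
diagnosed case.  Formula affordability is containers (default 50 × 900 g,
the quantity advised by manufacturers for birth-to-two feeding) × unit
price ÷ 24 months of mean earnings; the 24-month denominator is a package
choice — the source prose says only "divided by the nominal wage".
Countries without a formula price use the mean of the available prices,
which is the stated proxy rule.

### Discounted earnings streams

Present value of one person's earnings stream:

PV = Σ over whole age-years a ∈ [start, end) of
base × scale × ((1+g)/(1+r))^a,

with a fractional terminal (or initial) year pro-rated.  Conventions the
sources leave open, fixed here: annual compounding, end-of-year cash flows,
discounting to the person's birth year (growth is projected from the same
reference, so only the ratio (1+g)/(1+r) matters).  With g = r the ratio is
exactly 1 in floating point and PV = base × scale × (end − start) exactly.

* Child mortality: deaths × PV over [18, min(65, life expectancy)).
* Maternal mortality: per pathway, deaths × PV over [mean age at
  cause-specific death, min(65, life expectancy)); zero when the mean age
  of death already exceeds the endpoint.
* Cognitive loss: children not breastfed per recommendation × PV over the
  working ages × 2.62 IQ points × 1.067% earnings per point.  The default
  exposure definition is "not exclusively breastfed below 6 months"; the
  alternative (`bf_at_6m`) counts children not breastfed at 6 months.

GNI per capita at the base year proxies annual earnings; a single long-term
growth rate applies to every country (no country-specific growth paths).
The wage-share and labour-force-participation multipliers are available as
toggles but **off by default**, reproducing the plain GNI-per-capita
formulation; the LFPR toggle applies to maternal (all-female) streams only,
because the input record carries only the female participation rate and
applying it to a mixed-sex child cohort would be wrong.

Default economic assumptions: discount 3%, growth 3%, working ages 18–65.
Sensitivity scenarios re-run only the discount/growth-dependent components:
conservative (5%, 1.5%) and optimistic (1.5%, 5%).  Burden and health costs
are scenario-invariant by construction.

### Aggregation without extrapolation

A missing indicator is represented explicitly (`None` + a data flag) and
propagates as "component not computed", never as zero.  Group totals
(region, income group, global) sum each field over the countries where it
was computed; the %-of-GNI uses the summed GNI of the same included set.
Nothing is scaled to a group's full population, so the inclusion sets are
part of the result and are logged per run.

## Packaged reporting-table fixture

The published regional and income-group table rows (four tables: morbidity
cases, deaths, health-system costs in US$ m, losses in US$ b for the three
scenarios) are shipped as checksummed CSVs.  Feeding them through the same
aggregation operation reproduces the published grand totals.  Two
publication quirks are handled openly rather than hidden:

* The printed totals round consistently with the *income-group* rows for
  the count tables (e.g. total child deaths 595 379; the regional rows sum
  to 595 381) but with the *regional* rows for the monetary tables
  (health cost 1 146.81; income rows sum to 1 146.82).  Reproduction uses
  the consistent grouping per table and asserts the other within ±0.02 on
  2-dp billion/million sums (±2 on counts).
* The cognitive-loss column's own rows sum to 285.40 against a printed
  285.39 (one rounding ulp); the test band for that column is ±0.02.
* The table of losses labels its parenthetical bounds inconsistently with
  their values; the fixture labels the smaller bound conservative
  (5% discount, 1.5% growth) and the larger optimistic, consistent with the
  monotonicity of present value in the two rates.

Display rounding follows the tables (monetary billions and %GNI to 2 dp,
counts to integers); internal arithmetic is full precision.

## Synthetic data generator

`FixtureSpec`/`generate_countries` produce complete, internally consistent
country records: log-uniform GNI per capita (US$500–60 000) with
income-group assignment at World-Bank-style thresholds, life expectancy
50–85 y rising with income, births 20 000–3 M, exclusive-breastfeeding
prevalence 10–60% with Dirichlet-distributed remainder categories,
GBD-shaped incidence and cause-specific mortality whose infectious burden
and case fatality fall with income, MICS-shaped care-seeking cascades,
WHO-CHOICE-shaped unit costs rising with facility level and income, and
formula prices US$8–32 with a 20% missing share to exercise the
global-mean proxy.  Relative risks are placeholders drawn within
literature-plausible ranges supplied as configuration (e.g. diarrhoea
0–5 m "none" category up to 4.5, maternal pathways 1.1–1.55); no specific
published RR is hard-coded.  All ranges can be overridden per indicator,
and a `universal_breastfeeding` switch produces the counterfactual world in
which every attributable quantity must be zero.

The generator is deterministic in its seed and every generated profile
passes validation.  What it does **not** emulate: within-country
correlation structures beyond the income gradients above, time trends,
survey measurement error, and the actual joint distribution of real
countries' indicators.  Passing tests on synthetic data therefore
demonstrate the engine's arithmetic, invariants and plumbing — not the
realism of any particular country estimate.

Test and verification problem sizes: 130 synthetic countries (the size of
a realistic full run) for end-to-end, aggregation-associativity and
scenario-ordering checks; 1 000 random draws for the PAF and present-value
oracle-equivalence checks (tolerances 1e-12 absolute and 1e-9 relative
respectively).

## Known limitations

* No uncertainty intervals on relative risks or epidemiology; the scenario
  grid varies only the discount and growth rates.
* Diseases with thinner data linkage (childhood diabetes and cancers,
  SIDS, necrotizing enterocolitis, preterm birth, post-partum haemorrhage
  and depression) are out of scope, as are caregiver-time and
  transportation costs — the estimates are conservative in that sense.
* The exact arithmetic by which the original spreadsheet implementation
  combined maternal prevalence and RR cannot be recovered from its
  published description; the bounded PAF default and the `literal` audit
  mode bracket the plausible readings.
* Ingestion is file-based (long-format CSV); there are no live clients for
  the GBD/WDI/ILOSTAT/UNICEF APIs.
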