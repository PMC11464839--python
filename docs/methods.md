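# Methods

## Analysis unit and data model

The counting unit throughout is the ICSR: one report contributes at most
one count to any cell of any 2×2 table, regardless of how many drug
mentions or reaction terms it carries. Reports are linked from four
delimited tables (demographics, drugs, reactions, outcomes) sharing a
report id, mirroring the FAERS quarterly layout. Two dialects are bundled
(`faers`: `$`-delimited, `YYYYMMDD` dates; `csv`: comma, ISO-8601); the
dialect is explicit configuration because real-world extracts vary. Rows
that fail to parse, and demographics rows left without any drug or reaction
after linking, are quarantined with a per-row reason rather than dropped,
so linked + quarantined always equals rows read — spontaneous-report
pipelines must be auditable. Case versioning (several reports per case id)
is supported by a keep-highest-version dedup, but it is **off by default**:
the default treats every ICSR as a distinct adverse-event record.

## Case definition and filtering

A case is a report with at least one reaction whose MedDRA Preferred Term
belongs to the event term set. The bundled default set holds the ten
congenital external-ear anomaly PTs (accessory auricle, anomaly of external
ear congenital, anotia, congenital aural fistula, constricted ear
deformity, external auditory canal atresia, low set ears, macrotia,
microtia, protuberant ear). Matching is case-insensitive **by name first**;
a numeric code match is accepted only as an alternative when both sides
carry codes. Names are authoritative because printed code lists for this
term set are unreliable: one code is missing outright and one value is
printed for two different terms, so the bundled file records those two
codes as absent.

Report-level defaults follow the study design the package operationalizes:
universe = direct-type reports (consumer/health-professional submissions,
less subject to manufacturer-channel confounding), exposure = drugs in the
primary-suspect role only. Both are configurable sets. A
`require_outcome_serious` switch exists for the "severe adverse events"
notion but is off by default, since that notion has no standard
operationalization; when on, it requires any outcome code on the report.

Drug names are normalized to generics through a bundled many-to-one
brand→generic CSV (a static stand-in for a registry lookup). Mentions
whose raw name has no entry are removed and logged — the drop-and-log
analogue of manually eliminating unresolvable names — and every generic
name is accepted as its own key, which makes normalization idempotent.

## Descriptive statistics

Frequency tables cover sex, age band, reporter, country (top-k plus
"Other") and outcome codes (with a cases-or-occurrences denominator
switch). Age bands are half-open — <1, [1, 4), [4, 10), ≥10, unknown — to
resolve the overlapping "1–4 / 4–10" labels common in published tables.
Quantiles use linear interpolation (the type-7 convention, numpy/R
default); the convention matters at these small n and is fixed rather than
configurable. Yearly series count by receipt year and report pairwise
percent changes with the largest consecutive-year increase. Time to onset
is the days from the earliest primary-suspect start date to the earliest
event date; negative gaps are data-entry artifacts and are returned as
missing with a warning.

## Disproportionality statistics

ROR = ad/(bc) with CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`;
PRR = a(c+d)/(c(a+b)); χ² is the uncorrected Pearson statistic in its
(ad−bc)² form. The PRR 95% CI uses the standard log-scale Wald variance
`1/a + 1/c − 1/(a+b) − 1/(c+d)`; published PRR intervals are not always
reproducible from any single textbook form, so no validation quantity
depends on PRR CI bounds. Criteria: ROR rule (CI low > 1, a ≥ 3), PRR rule
(PRR ≥ 2, χ² ≥ 4, a ≥ 3), and the headline signal rule (PRR CI low > 1,
a ≥ 3); the a-gate (`min_a`) is configurable. Zero cells make the ratios
undefined; an optional Haldane–Anscombe +0.5 correction exists (off by
default) and, when enabled, is applied to one corrected table used for all
statistics of that drug, so ratios, CIs and χ² stay mutually consistent.
Ranking sorts descending by ROR, PRR or a with ties broken by larger case
count then name, making output order permutation-invariant. **No
multiplicity adjustment is applied** — the statistics are
hypothesis-generating screens, and a screened list of dozens of drugs at
nominal 95% levels will contain false positives by construction.

## Inversion of published rows

Published signal tables print (a, ROR, PRR, CIs, χ²) but not b, c, d.
Given the universe size N, eliminating c through the PRR equation gives
d/c = (PRR(a+b) − a)/a, which collapses the ROR equation to a linear
equation in b:

    b = a(PRR − 1)/(ROR − PRR),  c = a(N − a − b)/(PRR(a + b)),  d = N − a − b − c.

The solution is exact; a positive one exists iff PRR − 1 and ROR − PRR
share a sign, which holds for every genuine table (both equal the sign of
ad − bc), and ROR = PRR leaves b unidentified (reported as non-converged
with diagnostics, never an exception). Cells are recovered as positive
reals: the printed inputs are rounded to two decimals, so integer recovery
is ill-posed; nearest integers are reported alongside. Plug-back residuals
are computed against the printed pair, with convergence declared below
1e-6 relative error. Predicted χ² and ROR CI are then evaluated on the
recovered cells *through the same code path as the forward engine*, and a
row is consistent when both agree with the printed values within 1% —
about the agreement achievable given two-decimal rounding of the inputs.
N defaults to 20,754,281 (the analysis denominator of the 2004–2024 study
window this package re-implements) and is configurable. The bundled
`published_signal_table.csv` transcribes the 49 published rows that survive in the source
text; transcription ambiguities were resolved by arithmetic plausibility
and the known-ambiguous rows play no part in validation.

## Synthetic report generator

The generator defines the package's test conditions. Each report draws one
primary-suspect drug from a drug marginal (probabilities sum to 1);
each event PT occurs independently with its background probability,
multiplied by the rate ratio of a matching injected signal and capped at 1.
This risk-ratio parameterization means the empirical ROR approximates the
injected rate ratio only when the event is rare; expected cells are exact
and closed-form (`expected_table`), with a-cells `n·p_drug·min(rr·p_event, 1)`
and the rest fixed by margins. Reports that draw no event receive a filler
background PT ("Drug ineffective", outside any term set) so reactions are
never empty; report-level cells of modelled pairs are unaffected.

Demographic strata defaults mirror an infant congenital-anomaly case
series: sex ≈ 35/42/23% female/male/unknown; age mass 88% under 1 year
(bands drawn uniformly within); weight lognormal around a 2.75 kg median
(σ = 0.333 on the log scale, set from a 2.17–3.40 IQR); onset gap
lognormal around a 273-day median with σ = 0.61 set from the 137–311 IQR
ratio — a lognormal cannot match that asymmetric IQR around its median
exactly, so the spread, not both quartiles, is matched. Reporter, country
and outcome mixes follow the same case-series profile. The report-type mix
(direct 0.6 / expedited 0.3 / periodic 0.1) is a package choice made so
that type-filtered universes remain informative. Receipt dates are drawn
uniformly (or by configurable year weights) over 2004–2024; event dates
precede receipt by a uniform 0–60-day reporting delay and drug start dates
precede events by the onset gap, so a generated report's time-to-onset
equals its drawn gap.

What the generator does **not** emulate: drug co-prescription structure
(at most one concomitant mention, optional, default off), report-level
correlation between events, duplicate submissions, reporting waves or
secular trends, and within-report dependence of demographics on drug or
event. Tests passing on this model therefore validate the *computational
chain* — counting, filtering, statistics, criteria — not robustness to the
confounding and reporting biases of real spontaneous data.

Determinism: all randomness flows through one numpy Generator seeded from
`params.seed`, draws occur in a fixed order, and replicate seeds are
derived arithmetically from a base seed, so identical parameters give
byte-identical output files.

## Operating characteristics and problem sizes

`recovery_experiment` repeatedly runs generate → select → build table →
criteria and summarizes flag rates with Wilson binomial CIs. The bundled
validation uses: null calibration at expected a = 5 (drug 0.05 × event
0.025 × n = 4,000) over 1,000 replicates, where the headline rule fires in
well under 5% of replicates (nominal one-sided 2.5% plus the a ≥ 3 gate);
and recovery of a rate-ratio-50 signal at expected a = 20 (drug 0.02 ×
event 0.1 × n = 10,000) over 50 replicates, with sensitivity ≥ 95% and the
injected drug ranked first by ROR. These sizes were chosen once from the
criteria they instantiate (expected a ≥ 5 under the null, ≥ 10 under the
signal). Formula implementations are additionally cross-checked against
exact rational arithmetic on a seeded 100,000-table random sample of the
cells-in-1..50 grid, and in unit tests against independent library
implementations of the odds ratio and the chi-squared test.

## Known limitations

- Real published counts from the full FAERS extract are not reproducible
  here; the inversion surface validates the statistics engine against
  printed rows, which is a consistency check, not a replication.
- The synonym map is a small static table, not a drug registry; real
  FAERS name normalization is far messier.
- The PRR CI formula in the wild varies between tools; only ROR CI and χ²
  are used for row validation.
- No Bayesian detectors (BCPNN, EBGM), no stratified/adjusted RORs, no
  drug–drug interaction signals, and no multiplicity control.
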