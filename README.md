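# auricle

Disproportionality signal detection for drug-associated **congenital
anomalies of the external ear** (microtia, anotia, accessory auricle, …) in
spontaneous adverse-event report databases, built as a reusable, fully
tested pipeline over FAERS-style individual case safety reports (ICSRs).

Spontaneous-report databases such as the FDA Adverse Event Reporting System
collect millions of suspected adverse drug reaction reports. To screen them
for teratogenic associations, each drug–event pair is cross-classified over
the report universe into a 2×2 table —

|                | event of interest | other events |
|----------------|-------------------|--------------|
| suspect drug   | a                 | c            |
| other drugs    | b                 | d            |

— and two frequentist disproportionality statistics are computed:

- reporting odds ratio, **ROR = ad/bc**, with 95% CI
  `exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d))`;
- proportional reporting ratio, **PRR = a(c+d)/(c(a+b))**, with a log-scale
  Wald 95% CI, plus the uncorrected Pearson
  **χ² = (ad−bc)²·n / ((a+b)(c+d)(a+c)(b+d))**.

A drug is flagged as a *signal* when the lower bound of the 95% PRR CI
exceeds 1 and at least 3 cases are reported (the headline rule); the
classical ROR rule (CI lower bound > 1, a ≥ 3) and PRR rule (PRR ≥ 2,
χ² ≥ 4, a ≥ 3) are evaluated alongside.

The package is aimed at pharmacovigilance analysts and methodologists who
want the full chain — case definition by MedDRA Preferred Terms, report
filtering (direct reports, primary-suspect drugs), drug-name normalization,
descriptive epidemiology, signal statistics, ranking — as testable library
code rather than a web query, plus two validation instruments:

- **`auricle.inversion`** — published signal tables print only
  (a, ROR, PRR, CIs, χ²). Given the universe size N, the two defining
  equations invert in closed form (`b = a(PRR−1)/(ROR−PRR)`), recovering
  the unprinted cells; re-evaluating the statistics on the recovered cells
  checks any published row for internal consistency.
- **`auricle.synthetic`** — a generator of FAERS-like report collections
  with known background rates and injected drug–event signals, so every
  pipeline stage can be tested against planted ground truth without
  downloading anything.

## Worked example

Simulate a report collection with two injected teratogenic signals, run the
study pipeline on it, and read the ranked signal table:

```bash
auricle simulate --out sim --seed 7 --n-reports 8000
auricle run --config study.yaml        # paths pointing at sim/, see below
```

with `study.yaml`:

```yaml
demo_path: sim/DEMO.txt
drug_path: sim/DRUG.txt
reac_path: sim/REAC.txt
outc_path: sim/OUTC.txt
filters: {report_types: [direct, expedited, periodic]}
criteria: {haldane_correction: true}
out_dir: studydir
```

The run prints the stage manifest:

```json
{
  "status": "ok",
  "counts": {
    "demo_rows_read": 8000,
    "reports_linked": 8000,
    "universe": 8000,
    "cases": 12,
    "drugs_screened": 5,
    "signals": 0
  }
}
```

`reports_linked` is the number of ICSRs assembled from the four tables,
`universe` the denominator after the report-type filter, `cases` the
reports matching the external-ear term set, and `signals` the drugs meeting
the headline rule. `studydir/signals.csv` then holds the ranked signal
table (the shape of a published top-drugs table); its head on this run:

```
generic_name,a,ROR,ROR_CI_low,ROR_CI_high,PRR,PRR_CI_low,PRR_CI_high,chi2,...
valproic acid,1,11.92,2.15,66.19,10.66,2.33,48.71,13.05,...
```

(valproic acid tops the ranking but, with a single case, correctly fails
the a ≥ 3 gate — no signal is declared at this sample size).

Checking a published table for internal consistency:

```bash
auricle invert-published --out inversion.csv
# 49 rows inverted; 23 inconsistent (written to inversion.csv)
```

For each printed row this recovers the unprinted cells from
(a, ROR, PRR, N) and compares the implied χ² and ROR CI with the printed
ones; rows whose own numbers cannot coexist (e.g. the 122-case valproic
acid row, whose printed χ² is 12× smaller than its own ROR/PRR imply) are
flagged.

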