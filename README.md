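# ereckit

Effective refractive error coverage (eREC) from population-based eye
health surveys.

Uncorrected refractive error is a leading, easily treatable cause of
vision impairment, and universal-health-coverage monitoring asks not just
whether people have spectacles but whether those spectacles actually
restore sight. `ereckit` is for epidemiologists and survey analysts: it
takes individual-level survey records — correction-wearing status and a
per-eye visual-acuity battery (uncorrected, corrected, pinhole,
best-corrected) — classifies every participant into a need category, and
computes the coverage indicators with survey weights, stratification,
direct age–sex standardisation and confidence intervals.

## The indicators

Each participant is classified from better-eye acuities against a *need*
threshold (default 6/12) and an *outcome* threshold (default 6/12):

- **no need** — uncorrected acuity 6/12 or better (even if they own correction);
- **met need (a)** — impaired without correction, but their own correction
  reaches the outcome threshold;
- **under-met need (b)** — correction owned, outcome threshold not reached,
  yet pinhole over the correction (or a fresh refraction) reaches the need
  threshold;
- **unmet need (c)** — impaired, no correction, pinhole shows the
  impairment is refractive;
- **other vision impairment** — pinhole/refraction cannot restore the need
  threshold (e.g. cataract); excluded from the coverage ratios;
- **indeterminate** — a deciding measurement is missing; reported, never imputed.

From the tallies:

    eREC (%) = a / (a + b + c) × 100
    REC  (%) = (a + b) / (a + b + c) × 100
    Relative Quality Gap (%) = (1 − eREC / REC) × 100

eREC captures access *and* quality; REC captures access alone; the quality
gap is the share of coverage that is under-met.

## Worked example

The package ships a 100-person demonstration cohort (50 unmet need, 20
correction wearers without impairment, 5 under-met, 25 met):

```sh
erec compute --input src/ereckit/data/worked_example.csv --out report.json
```

which logs

```
INFO classified 100 records: {'MET': 25, 'NO_NEED': 20, 'UNDER_MET': 5, 'UNMET': 50}; indeterminate fraction 0.000
INFO records: 100; categories at ('6/12', '6/12'): {'met_a': 25, 'under_met_b': 5, 'unmet_c': 50, 'no_need': 20, 'other_vi': 0, 'indeterminate': 0}
```

and writes a report whose overall estimates are eREC 31.25% (95% Wilson CI
22.2–42.1%), REC 37.5% and quality gap 16.7%: of the 80 people with
vision-impairing refractive error, 25 are effectively covered, 30 have
correction at all, and one-sixth of that coverage fails to deliver a good
visual outcome. The same numbers are available from Python:

```python
from ereckit import classify_all, tabulate_need, erec, rec, quality_gap
from ereckit.datasets import worked_example_cohort

cohort = worked_example_cohort()
cats = classify_all(cohort)
summary = tabulate_need([(p, c) for p, (_, c) in zip(cohort, cats)])
e, r = erec(summary), rec(summary)
print(e.value_pct, r.value_pct, quality_gap(e, r).value_pct)
# 31.25 37.5 16.666666666666664
```

`erec simulate` generates synthetic cohorts with known true coverage
(possession × good-outcome probability) for validation, and
`erec fixtures` writes the demonstration cohort with its column-mapping
template. Real surveys are read through a YAML/JSON column mapping
(`src/ereckit/data/mapping_template.yaml`) covering column names, acuity
dialects (6-metre Snellen, 20-foot Snellen, decimal logMAR) and coded
value maps.

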