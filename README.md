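# recoverydebt

Tools for quantifying the **recovery debt** of ecosystems — the interim
per-annum deficit in biodiversity or biogeochemical function that accumulates
while an ecosystem recovers from an anthropogenic disturbance — and for
pooling those deficits across studies with a three-level random-effects
meta-analysis.

The package is aimed at ecologists and meta-analysts who have, for each
outcome measure, a start value `X_s` (at recovery onset), an end value `X_e`
(after `T` years of recovery) and a reference value `X_r` (the pre-disturbance
state or a comparable undisturbed system), and who want defensible pooled
estimates of how far below reference recovering systems run, per year.

## The effect size

The trajectory between the two observations is interpolated with an
exponential, `f(t) = X_s e^{rt}` with `r = ln(X_e/X_s)/T` (a linear
interpolation is available as a sensitivity check). The debt over `(0, T)` is
`RD = X_r·T − AUC`, where the exponential area has the closed form

    AUC = (X_e − X_s) · T / ln(X_e / X_s)        (AUC = X_s·T when X_e = X_s)

Per annum, `RDt = RD / T`, homogenized across heterogeneous outcome measures
as the **debt ratio** `100 · RDt / |X_r|` (percent of reference). Values above
the reference are treated as equivalent deficits by the multiplicative
reflection `Z = X_r² / X`, which also caps every ratio at a realistic
recovery threshold of 100%; `RDt > |X_r|` is handled by the same principle.
Zero endpoints or references, which break the logarithmic rate, receive a
small additive constant selected among nine candidate strategies by
Mann–Whitney comparison against the zero-free remainder of the database.

Debt ratios are then pooled with the three-level model

    y_ij = β + u_j + w_ij + e_ij,   u_j ~ N(0, τ²_study),
    w_ij ~ N(0, τ²_effect),          e_ij ~ N(0, v_ij known)

estimated by REML, with missing sampling variances (the common case in
ecological meta-analysis) imputed as the per-metric mean of observed ones.
Moderators (ecosystem, disturbance category) are tested with the Q_M omnibus
Wald test and summarized with no-intercept per-category fits; heterogeneity
on the variance-reporting subset is reported as I².

## Worked example

```python
from recoverydebt import OutcomeMeasure, exponential_debt, linear_debt

rec = OutcomeMeasure(
    study_id="S1", outcome_id="om1", metric="abundance",
    x_start=2.0, x_end=8.0, x_ref=10.0, t_years=10.0,
)
res = exponential_debt(rec)
print(f"scenario {res.scenario}: r = {res.r:.4f} /yr, AUC = {res.auc:.2f}")
print(f"per-annum debt {res.rd_per_annum:.3f} -> ratio {res.ratio_pct:.2f}% of reference")
print(f"linear ratio: {linear_debt(rec).ratio_pct:.1f}%")
```

prints

```
scenario a: r = 0.1386 /yr, AUC = 43.28
per-annum debt 5.672 -> ratio 56.72% of reference
linear ratio: 50.0%
```

i.e. an ecosystem attribute recovering from 2 to 8 against a reference of 10
over a decade ran, on average, a 56.7% annual deficit (50% under the more
conservative linear interpolation).

A full analysis over a database (here a synthetic one with known truth):

```python
from recoverydebt import (SyntheticConfig, generate_dataset,
                          run_full_analysis, write_report)

ds = generate_dataset(SyntheticConfig(n_studies=150, seed=7))
report = run_full_analysis(ds.records)
write_report(report, "out/")
```

whose `out/summary.txt` reads (this run generated ~1,700 outcome measures
with true means abundance 48.5%, diversity 30%, carbon 37%, nitrogen 36%):

```
Per-annum recovery debt (percent of reference, 95% CI):
  abundance  45-49% (mean 47%, k=859, studies=145)
  carbon     34-38% (mean 36%, k=223, studies=110)
  diversity  27-31% (mean 29%, k=480, studies=136)
  nitrogen   31-36% (mean 34%, k=112, studies=80)
```

Each interval covers its generating mean. `out/` also holds per-category
moderator tables, Q_M tests, I² values, recovery-time summaries and the
per-record debt table as CSVs.

The same steps are available from a shell:

```
recovery-debt simulate --n-studies 150 --seed 7 --out db.csv
recovery-debt report db.csv --outdir out/
```

Real databases are ingested with `recovery-debt report db.csv --mapping
columns.yaml ...`, where the YAML config maps canonical field names to the
source file's headers and may add label synonyms.

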