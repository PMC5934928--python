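# rand36val

Rank-invariant analysis of paired ordinal data for validating the RAND-36
health survey (and any other ordered-categorical paired design):
test-retest reliability, responsiveness, and internal consistency, without
pretending questionnaire categories are interval-scaled.

## Who this is for

Psychometricians and outcomes researchers validating a patient-reported
outcome measure in a paired design — the same patients rated at two
occasions — who need:

* **Svensson-style agreement measures** on the square table of paired
  ratings: percentage agreement (PA), relative position (RP), relative
  concentration (RC) and relative rank variance (RV), with jackknife
  standard errors, normal 95% confidence intervals and the
  zero-outside-the-interval significance rule;
* **RAND-36 scoring**: 0–100 recoding, the eight subscales, the ordinal
  Health-change item, and a complete-case missing policy;
* **ordinal alpha**: internal consistency from pairwise polychoric
  correlations rather than Pearson correlations on raw scores;
* **synthetic two-occasion cohorts** from a latent-trait model, so the
  whole pipeline is testable without patient data.

## The statistics in brief

For paired ratings summarised as a C×C table (rows = occasion 1, columns =
occasion 2, higher category = better health), with marginals `p1, p2` and
cumulative distributions `F1, F2`:

* `PA = Σ_i n_ii / n` — identical answers at both occasions;
* `RP = P(Y > X) − P(Y < X) = Σ_j p2_j F1(j−1) − Σ_j p2_j (1 − F1(j))` —
  systematic group-level shift, in [−1, 1], positive for improvement;
* `RC = 4·(c21 − c12)`, `c21 = Σ_j p2_j F1(j−1)(1 − F1(j))` — signed shift
  of concentration toward the scale's centre;
* `RV = (6/n³) Σ_ij n_ij (r̄1_ij − r̄2_ij)²` over augmented mean ranks —
  individual dispersion from the common pattern of change; 0 exactly for
  rank-transformable patterns, values above 0.2 flag heterogeneity.

All four depend only on the ordering of categories (monotone relabelling
changes nothing), which is what makes them legitimate for ordinal
questionnaire data and for mean-based subscale scores treated as ordinal.
See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from rand36val import PairedOrdinalTable, svensson_analysis

counts = np.array([
    [ 5,  2,  0,  0,  0],
    [ 2, 10,  4,  1,  0],
    [ 0,  5, 30,  3,  0],
    [ 0,  1,  4,  6,  2],
    [ 0,  0,  1,  2,  5],
])
table = PairedOrdinalTable(counts, categories=(1, 2, 3, 4, 5))
res = svensson_analysis(table)
print(f"PA = {res.pa:.2f}")
print(f"RP = {res.rp:+.3f}  (95% CI {res.ci_rp[0]:+.3f} to {res.ci_rp[1]:+.3f})  significant: {res.significant_rp}")
print(f"RC = {res.rc:+.3f}  (95% CI {res.ci_rc[0]:+.3f} to {res.ci_rc[1]:+.3f})")
print(f"RV = {res.rv:.3f}")
```

prints

```
PA = 0.67
RP = -0.026  (95% CI -0.105 to +0.054)  significant: False
RC = +0.016  (95% CI -0.058 to +0.090)
RV = 0.039
```

Read: two thirds of the 83 patients answered identically at both occasions;
there is no systematic shift (the RP interval straddles zero) and no
concentration change, and the small RV says individuals stayed close to the
common (here: null) pattern — the signature of good test-retest
reliability.

## The analysis, end to end

The `analysis/` drivers reproduce a full validation study on synthetic
cohorts and write their tables under `results/`:

```bash
python analysis/01_simulate.py               # stable + improving cohorts
python analysis/02_score_and_completeness.py # 0-100 scoring, complete cases
python analysis/03_reliability_analysis.py   # 7-17 day window, Svensson tables
python analysis/04_responsiveness_analysis.py# 50-70 day window, improvement
python analysis/05_internal_consistency.py   # pooled ordinal alpha
```

The same pipeline is scriptable (`rand36val simulate|score|analyze|report`)
and callable as a library (`rand36val.pipeline.run_study`).

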