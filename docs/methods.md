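# Methods

## The problem

Patient-reported outcome questionnaires such as the RAND-36 produce ordered
categorical item responses, aggregated into subscale scores that are still,
strictly, ordinal. Validating such an instrument in a paired design —
test-retest reliability in a clinically stable group, responsiveness in a
group expected to improve — therefore calls for methods that use only the
ordering of the responses, not interval arithmetic on them. This package
implements a rank-invariant analysis of paired ordinal data built on the
square contingency table of the two occasions' ratings, together with the
scoring, internal-consistency and simulation machinery needed to run a
complete validation study end to end.

## Paired ordinal agreement measures

All measures consume a `PairedOrdinalTable`: a C×C count matrix whose rows
index the occasion-1 (baseline) category and columns the occasion-2
(retest/follow-up) category, categories ordered so that higher = better.
Reverse-scored items must be recoded before the table is built; the scoring
module does this for the Health-change item.

With marginal relative frequencies `p1`, `p2` and cumulative distributions
`F1`, `F2` (`F(0) = 0`, `F(C) = 1`):

* **Percentage agreement** `PA = Σ_{|i−j|≤k} n_ij / n`, with `k = 0` by
  default (the diagonal proportion). `k ≥ C` is answered with a warning and
  the trivial value 1.
* **Relative position** `RP = P(Y > X) − P(Y < X)` for independent `X ~ p1`,
  `Y ~ p2`; computed as `Σ_j p2_j F1(j−1) − Σ_j p2_j (1 − F1(j))`. RP lies
  in [−1, 1] and is positive when the second occasion sits systematically
  higher. The cumulative-marginal ROC curve (points `(F1(c), F2(c))`)
  visualises the same contrast: identical marginals give the identity
  diagonal, a systematic shift bows the curve.
* **Relative concentration** `RC = κ·(c21 − c12)` where
  `c21 = Σ_j p2_j F1(j−1)(1 − F1(j))` is the probability that an occasion-2
  draw falls strictly between two independent occasion-1 draws and `c12` is
  its mirror image. Positive RC means the second occasion's answers are
  more concentrated toward the centre of the scale. The normaliser κ = 4 is
  chosen so RC attains ±1 at the maximally concentrated configuration (all
  second-occasion mass strictly between a half/half split of the
  first-occasion mass); it is exposed in `AnalysisConfig` because only the
  range and sign semantics of RC are fixed by convention.
* **Relative rank variance**
  `RV = (6/n³) Σ_ij n_ij (r̄1_ij − r̄2_ij)²`, where `r̄1_ij` is the mean
  augmented rank of cell (i, j) when subjects are ordered primarily by
  occasion-1 category with ties broken by occasion-2 category (mid-ranks
  within a cell: `r̄1_ij = Σ_{k<i} n_k· + Σ_{l<j} n_il + (n_ij + 1)/2`), and
  `r̄2` symmetrically. RV = 0 exactly for rank-transformable patterns —
  any paired distribution explainable by a common monotone shift, including
  all diagonal tables — and grows as individuals cross each other in rank.
  Values above 0.2 are conventionally read as sizable individual deviation
  from the group pattern and trigger a warning. RV is reported unclipped;
  extreme reversal patterns can push it above 1 (e.g. a full 2×2 reversal
  gives 1.5), which warns rather than errors.

Merging two adjacent categories never increases RV (verified empirically on
random tables in the suite), and all four measures are invariant under
strictly monotone relabelling of the categories — the property that makes
analysing mean-based subscale scores on their observed value grid harmless.

## Uncertainty

Standard errors are leave-one-pair-out jackknife estimates: for each
observed pair the statistic is recomputed on the table with that pair
removed, and `SE = sqrt((n−1)/n · Σ_i (θ_(−i) − θ̄)²)`. For PA this
reproduces the closed form `sqrt(p(1−p)/(n−1))` exactly; for RP it agrees
with a multinomial bootstrap to well within 15% at n = 1000 (tested).
Confidence intervals are normal-approximation `estimate ± z·SE`
(z = 1.959964 at 95%), and a change is called significant exactly when zero
lies outside the interval. Samples below about 12 pairs trigger a warning
rather than a refusal — the method remains usable in very small groups, but
the normal approximation becomes optimistic.

The jackknife/normal choice is a documented design decision: published
applications print SEs and CIs without formulas, so no external target
exists to reproduce digit-for-digit; the suite instead certifies internal
correctness (closed form, bootstrap agreement, CI coverage on synthetic
cohorts).

## RAND-36 scoring

Items are recoded to 0–100 by the standard RAND lookup (shipped as plain
data in `RECODE_TABLE` so a dialect can be swapped without code changes);
higher always means better health after recoding. The eight subscales
average their member items — Physical functioning (items 3–12), Role
physical (13–16), Pain (21, 22), General health (1, 33–36), Energy/fatigue
(23, 27, 29, 31), Social functioning (20, 32), Role emotional (17–19),
Emotional well-being (24, 25, 26, 28, 30) — with the median available as an
alternative aggregator. The default missing policy is complete-case: a
subscale with any missing member item is not scored, so downstream paired
analyses only ever see fully answered subscales. The RAND half-rule is
available but not default. Item 2 (Health change) is kept ordinal and
reverse-recoded to higher-is-better (category `6 − raw`); consequently
"improved" means above the diagonal in this package's cross-tables, whereas
presentations that keep the raw best-to-worst coding show improvement below
the diagonal — the triangle labels, not positions, are what matters.

## Polychoric correlation and ordinal alpha

Each ordinal item is modelled as a discretised standard normal variable.
Pairwise latent correlations are estimated by two-step ML: thresholds fixed
at the normal quantiles of the margins, then the correlation maximising the
multinomial likelihood with bivariate-normal rectangle probabilities
(computed by scipy's bivariate normal CDF, thresholds truncated at ±8;
bounded scalar search over [−0.999, 0.999], tolerance 1e-8). Two-step
rather than joint ML is standard and ample for an internal-consistency
coefficient. Empty cells contribute nothing to the likelihood and need no
correction; a classical 0.5 continuity correction is available as an
option. Near-degenerate (perfectly concordant) tables estimate at the
±0.999 bound with a warning. Ordinal alpha applies
`alpha = k/(k−1)·(1 − k/Σ R)` to the pairwise matrix with unit diagonal;
for a constant off-diagonal r̄ this reduces to the standardised form
`k·r̄/(1 + (k−1)·r̄)`, which the suite uses as a closed-form target.
Rows with any missing item are dropped, mirroring the complete-case
scoring rule. Alpha uses baseline records by default; pooling occasions or
groups is a pipeline option, since pooled-versus-baseline is a reporting
choice, not a statistical one.

## Synthetic cohorts

The generator emulates the two study designs so every stage runs without
patient data. Per subscale (and for the stand-alone Health-change item):
subject trait `θ ~ N(0,1)`; occasion factor
`f_t = √r·θ + √(1−r)·ε_t + δ·1(t=2)`; item latent
`z = λ·f_t + √(1−λ²)·e`; observed category = `z` cut at the item's
thresholds, mapped onto the item's native raw scale (reversed where the raw
scale runs best-to-worst). Single-item groups use λ = 1 — the item is its
own construct, and diluting it through a loading would understate its
test-retest stability.

Defaults, chosen once as realistic study conditions:

| parameter | default | rationale |
|---|---|---|
| n_subjects | 84 (stable) / 97 (improving) | the two cohorts' analysed sizes |
| window offsets | uniform 7–17 / 50–70 days | the designs' eligibility windows |
| contamination | 15 extra pairs at 71–120 days (improving design) | late mail-back responders, to exercise the filter |
| retest r | 0.85 / 0.70 | high short-interval stability; lower over 2 months with real change |
| shift δ | 0 / +0.6 SD | stability vs. an improvement producing subscale RPs ≈ 0.2–0.35 |
| loading λ | 0.8 | gives subscale alphas ≈ 0.78–0.96, the usual validated-instrument band |
| missing rate | 0.0075 per item-occasion | reproduces ~85–100% per-subscale complete cases |
| thresholds | equiprobable per item | neutral default; configurable per item |

Missingness is MCAR only, and subscale factors are mutually independent.
Real questionnaire data have skewed margins, ceiling effects, correlated
subscales and possibly informative nonresponse; passing tests on these
cohorts therefore certify the *estimators* (recovery, coverage,
monotonicity in δ), not any claim about real patients. Dates are a fixed
baseline plus the offset draw; only the day difference matters downstream.

## Pipeline

`run_study` reads a wide cohort CSV, scores it, tabulates completeness and
per-occasion means (normal-approximation CIs), estimates per-subscale
alpha, pairs occasions, applies the inclusive eligibility window (excluded
pairs are logged individually; eligible + excluded = input always), builds
the Health-change cross-table with whole-percent triangle summary
(half-away-from-zero rounding, so printed percents may not sum to 100), and
runs the Svensson analysis per subscale on the pooled observed score values
as categories. Every reported row equals a direct call of the corresponding
core function — the suite checks there is no hidden transformation — and
identical config + input yields hash-identical outputs. Subscale-score
tables use all observed distinct values as categories; rank invariance
makes this equivalent to any monotone binning.

Problem sizes throughout the tests and drivers match the study designs
(84/97-pair cohorts); oracle-equivalence checks run on 1,000 random tables
with up to 6 categories and 50 pairs, the Monte-Carlo concentration oracle
on 10⁶ triples per table, coverage on 200 replicate cohorts.

## Known limitations

* RC's normaliser and the SE method are documented package choices; printed
  values from other software may differ in those respects even on identical
  data.
* The jackknife SE of RV is a smooth-statistic approximation; RV's sampling
  distribution is skewed near 0, so its CI can undershoot at tiny n.
* Polychoric estimation assumes latent bivariate normality; heavy-tailed or
  strongly skewed constructs will bias alpha.
* The generator does not model practice effects, informative dropout, mode
  effects or cross-subscale correlation (the latter is configurable off by
  design, not a modelling claim).
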