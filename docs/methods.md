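# Methods

## The model

A replicated bilateral trait is modelled by the balanced two-way mixed
ANOVA with factors *sides* (left/right; fixed, 2 levels) and *individuals*
(random, J levels), M replicate measurements per cell:

    y_isk = μ + S_s + I_i + (SI)_is + ε_isk

* the **sides** main effect (df 1) carries directional asymmetry,
* **individuals** (df J−1) carries between-individual size variation,
* the **sides × individuals interaction** (df J−1) carries non-directional
  asymmetry — the FA signal,
* the **within-cell error** (df 2J(M−1)) is measurement error.

Expected mean squares give the two components used throughout:

    σ²ᵢ = (MS_interaction − MS_error) / M      (FA component)
    σ²ₘ = MS_error                             (per-reading ME component)

In this convention the error-free side difference d = R̄ − L̄ has variance
2σ²ᵢ, so for normal FA the expected mean absolute asymmetry is
√(2/π)·√(2σ²ᵢ); that is the FA10a index. FA1 (mean |d|) and FA4a
(√(2/π)·sd(d)) are computed from the replicate-averaged side means and are
*not* ME-corrected — with ME present, FA4a inflates by 2σ²ₘ/M inside the
variance while FA10a does not, which is the reason to prefer FA10a whenever
ME is non-trivial relative to FA. ME3 expresses the ME share of the total
non-directional between-sides variance, 100·σ²ₘ/(σ²ᵢ+σ²ₘ); repeatability is
its complement. A negative raw σ²ᵢ estimate (possible whenever the true FA
component is small relative to ME) is clamped to zero and flagged rather
than propagated, so indices remain real and non-negative while staying
diagnosable.

Only balanced designs are fitted. Balance is produced upstream by
complete-case subsetting per trait: an individual missing any required cell
(either antimere, or any replicate inside the chosen subset) is excluded
from that trait's matrix only, never from the study — real dental samples
retain individuals with partial dentitions, so per-trait sample sizes vary.
Imputation is deliberately out of scope.

## Confounder screening

All screens operate on the per-individual side difference dᵢ (right minus
left, a fixed sign convention) and mean trait size sᵢ:

* **DA** — flagged primarily by the D'Agostino standardized skewness test;
  the conventional one-sample t test of mean(d) = 0 is always computed and
  can be made the flagging rule (`da_rule="t"` or `"either"`). A mean shift
  leaves skewness untouched, so the two rules are complementary: the skew
  rule matches the screening convention for replicated data, the t rule
  catches pure offsets.
* **AS** — one-sided (platykurtic) Anscombe–Glynn kurtosis test. The
  cube-root normalizing transform changes branch for extremely platykurtic
  samples (well-separated bimodal data) and then reports a spuriously
  positive statistic; the implementation re-anchors the statistic's sign to
  the pre-transform standardized fourth moment, so overwhelming bimodality
  yields p → 0 instead of p → 1.
* **Size dependency** — Spearman rank correlation of |dᵢ| with sᵢ, chosen
  over Pearson for robustness to the heavy-tailed |d| scale.
* **Outliers** — iterative two-sided Grubbs test at the screen α; flagged
  individuals are reported, and exclusion is the caller's decision.

Moment tests need J ≥ 8; below that (or for constant d) a trait is reported
not-evaluable with a clean-with-warning verdict. Verdict priority is
DA > AS > size-dependent, mirroring the order in which an analyst would
disqualify a variable.

**Screening α vs elimination α.** Per-trait screens default to α = 0.05.
The elimination pass over a full study roster is a different decision
problem: with ~36 trait variables × 3 screens ≈ 10² tests, a 0.05 rule
would discard several clean variables by chance alone, so
`EliminationRules` defaults to α = 0.001 (and the planted-effect recovery
tests use 10⁻⁴) with `da_rule="either"`. Eliminations should reflect
overwhelming signals, as published eliminations in practice do.

## Replicate-subset ME scan

With many replicate trials taken over a long collection period, early
trials may carry learning error and late trials fatigue error. The scan
rebuilds all trait matrices for each contiguous trial subset and summarizes
per-variable ME3 (mean, median, min, max, range), plus a pooled ME3 in
which components are summed across variables before the ratio,
100·Σσ²ₘ/(Σ(σ²ᵢ+σ²ₘ)). The pooled figure weights variables by their
variance scale and is structurally at or below the mean of per-variable
ratios; both aggregations are reported because published ME summaries of
this design print both a pooled and a mean column without defining the
former.

## Group-level inference

An FA index is itself a dispersion, so group hypotheses about index values
are tested with Levene-type statistics: a one-way ANOVA F on
|value − group center|, one value per trait variable (the published
degrees of freedom — e.g. 1/29 for a two-group test — show the tests were
run on index values, not on individual-level asymmetries). Both centerings
are available:

* `center="median"` (Brown–Forsythe) — the robust general-purpose default
  of `levene_test`, and the default of the R implementation commonly cited
  for this analysis;
* `center="mean"` — the original Levene statistic, and the default of
  `run_hypothesis_suite`, because on the packaged index table the published
  significance pattern of all nine models is reproduced under mean
  centering and *not* under median centering (the sex contrast flips to
  non-significant at the median). `reproduction_report()` always computes
  both and states which is closer to each reference F.

The nine standard models: four exploratory factors (tooth — the nine full
arcade-specific trait codes, df 8; tooth class; arcade; metric), the sex
contrast, and the two life-history contrasts (first molar pooled across
arcades/metrics vs all other variables; third molar likewise), each alone
and crossed with sex (4 groups, df 3). Molar eruption timing differs
little between arcades in the study species, which justifies pooling
mandibular and maxillary molars into single tooth-type groups. No
multiple-testing correction is applied in the standard suite, matching how
such tables are conventionally reported; users can correct downstream.

**Input-precision limit.** The packaged index values are printed at 2
decimal places on a scale of 0.00–0.10, i.e. rounding perturbs each value
by up to 0.005 against a between-variable spread of ~0.02. Deviation-based
F statistics are sensitive to this: recomputing from the 2-dp table
reproduces every degree of freedom and (under mean centering) every
significance verdict of the reference results, and the larger F statistics
within ~5–13% relative error, but several small or near-null F values
(metric, arcade, tooth, M1 main effect) land outside a 15% band under
either centering. This is an information limit of the printed inputs, not
a numerical property of the implementation; the full-precision index values
would be required to do better.

## Synthetic data

For individual i: true size Tᵢ ~ N(trait_mean, trait_sd²); signed asymmetry
Aᵢ = da_offset + FAᵢ + ASᵢ, with FAᵢ ~ N(0, σ_fa·(Tᵢ/trait_mean)^γ) and,
with probability as_prob, ASᵢ = ±as_delta (fair sign); sides
R = T + A/2, L = T − A/2; each reading adds N(0, σ_me,k²) noise (σ_me may
vary by trial to emulate learning/fatigue); (individual, side) cells drop
out with missing_rate. A two-point mixture is the simplest mechanism that
produces the platykurtic/bimodal d distribution that defines antisymmetry;
the size exponent γ plants trait-size dependency as a gentle scale effect.

Generative truth in the ANOVA convention: interaction component
σ²ᵢ = σ_fa²/2 (so true FA10a = √(2/π)·σ_fa), error component σ²ₘ = σ_me²,
and var(d) = σ_fa² + as_prob·as_delta² + 2·mean(σ_me²)/M.

Defaults emulate a replicated dental study: J = 30, M = 10, 10 mm crowns
with 1 mm between-individual SD, σ_fa = 0.03 mm (FA10a ≈ 0.024 mm, the
scale of the published indices), σ_me = 0.02 mm per reading, and no
DA/AS/size dependency unless planted. A multi-trait study derives one
deterministic substream per trait key (CRC-keyed SeedSequence) from a
single global seed, so any trait regenerates identically in isolation.

What the generator does *not* emulate: correlated asymmetry across traits
within an individual, wear- or age-structured error, non-normal size
distributions, and observer effects beyond i.i.d. noise. Passing
recovery tests therefore validates the estimators under the stated model,
not the biology of any particular sample.

## Test design notes

* The ANOVA is checked against a brute-force cell-means oracle (explicit
  summation over all observations) to 1e-10 relative tolerance, including
  sum-of-squares conservation.
* Levene tests are checked against a first-principles one-way ANOVA on
  deviation scores, and against the algebraic identity F = t² for
  two-group mean centering.
* Parameter recovery runs a grid σ_fa ∈ {0.02, 0.04, 0.08} ×
  σ_me ∈ {0.01, 0.04} × J ∈ {50, 200} × M ∈ {2, 10}, 200 replicates per
  cell, asserting ≤ 10% median relative bias of FA10a and ME3 within 5
  points of its closed form wherever the FA component is identifiable
  (σ_fa²/2 ≥ σ_me²/M); outside that region the estimator is dominated by
  clamping and no accuracy claim is made.
* Screen calibration uses 500 null traits at J = 200 (each screen's
  false-positive rate must sit in [0.03, 0.07] at α = 0.05) and 200-run
  power checks: a planted mean shift of 2·sd(d) must be caught by the t
  rule and a full antisymmetric mixture at 3·sd by the kurtosis screen,
  each with ≥ 95% power.
* The planted-elimination experiment uses DA offsets of 0.5 mm at J = 80
  (t-test p ~ 10⁻⁹⁰) and a γ = 1.5 size effect at J = 3000 for the planted
  size-dependent variable — sized, by power analysis, to clear the 10⁻⁴
  elimination threshold with orders-of-magnitude margin while keeping the
  d distribution mild enough not to cross-trigger the moment screens.
  Problem sizes throughout the suite were chosen to keep each experiment's
  Monte-Carlo error far from its decision boundary.

## Known limitations

* Only the FA1/FA4a/FA10a + ME3 corner of the index literature is
  implemented; shape (Procrustes) asymmetry and the remaining index
  catalogue are out of scope.
* Unbalanced designs are handled solely by complete-case subsetting.
* The Levene reproduction depends on printed 2-dp inputs as described
  above.
* ME3's pooled aggregation is one defensible reading of an under-specified
  convention; both aggregations are emitted so users can compare.
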