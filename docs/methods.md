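# Methods

## The estimation problem

Given a child's sex and the Demirjian stage (A–H; first calcified points →
closed apical foramen) of each of the seven left mandibular permanent teeth
(FDI 31–37; the third molar is excluded throughout), estimate the child's
chronological age. Errors are reported as CA − DA, so positive means the
method underestimated. Chronological age is computed from birth and
examination dates as day-count / 365.25, rounded half-to-even to two
decimals once at ingestion; all later arithmetic is full precision. The
365.25-day year is the package's choice — it makes the date conversion
deterministic and is the convention of the age-estimation literature.

A pre-A stage `N` (no visible calcification) extends the classical ladder so
that very immature teeth are representable. All three estimators treat `N`
as "not mature"; Willems-type scoring additionally treats it as a hard
coverage error, because published score tables begin at stage A.

## Estimators

**Quick method.** DA = M − n_imm with n_imm the count of teeth below stage
H. The default M = 16 y encodes the regularity that the quadrant completes
at about 16. The corrected minuend per group g is the closed-form least-bias
fit M̂_g = mean_g(CA + n_imm): the group's mean error on the fitting data is
then exactly zero (closure property, any grouping). Group standard errors
and t confidence intervals come from the group mean's sampling distribution.
DA is kept continuous (minuends carry decimals); it is not re-rounded to
whole years.

**Willems-style scoring.** DA is the sum of seven sex-specific per-tooth
scores looked up by stage. A lookup outside the table is an error, never a
default, and tables must be complete across A–H for every (sex, tooth) they
cover. Score tables are a replaceable CSV asset; the package does not ship
the published Willems 2001 values and cannot certify fidelity to them. A
synthetic, model-derived table is provided (below).

**Atlas matching.** The atlas is represented as a stage schedule — ordered
reference ages each with an expected stage per tooth — not artwork. The
subject's distance to a column is the L1 distance on stage ordinals
(N = 0 … H = 8) summed over the seven teeth; "best-matched" visual judgment
has no printed counterpart, and L1 on the ordinal is the simplest faithful
surrogate. Ties take the arithmetic mean of the tied reference ages:
directionally unbiased, and a unique exact match is returned unchanged. The
half-year "in-between" reading is realised as a 0.5-year grid; whether such
estimates were half-year labels or judgment interpolation is not documented,
and the grid is the chosen reading.

## The synthetic cohort generator

Cohorts emulate a cross-sectional radiograph study population: n = 831,
57.4% girls, ages 10.00–16.99 drawn uniformly on the 0.01-year grid
(optionally re-weighted by whole-year bracket; no default skew is imposed
because per-bracket counts of the emulated study are not published). Ages on
the cent grid guarantee exact two-decimal ages and the inclusive 16.99 upper
bound without rounding artifacts.

Stages come from a latent-maturity threshold model. Tooth t of a child aged
a shows the highest stage k with a + δ + ε_t ≥ τ(sex, t, k), where
δ ~ N(0, σ_subject = 0.6 y) is a shared developmental tempo (inducing the
between-tooth correlation real dentitions show) and ε_t ~ N(0, σ_tooth =
0.4 y) is independent jitter.

Default thresholds:

* **Completion schedule.** One tooth completes its root per year of age from
  10 to 16, in the order 31, 36, 32, 34, 33, 35, 37 (incisors and first
  molar early, second molar last). A tooth assigned to year Y completes
  mid-year: τ_H = Y − 0.5 for boys. This placement makes the zero-noise
  immature count at any exact age a ∈ {9,…,16} equal 16 − a and — because no
  threshold sits on a whole-year age — keeps the symmetric noise unbiased
  around that count (Monte-Carlo mean within 0.15 of 16 − a at 10…15).
* **Earlier stages** sit at fixed offsets below τ_H: G −0.8, F −1.6, E −2.5,
  D −3.6, C −5.0, B −6.9, A −9.3 years. Root-closure stages are dense; crown
  stages stretch back into early childhood so that no tooth of a subject in
  the study age window is still pre-A (stage A of the latest tooth falls at
  6.2 y, more than 5σ below the youngest subjects), while the earliest
  tooth's stage A stays above birth.
* **Sex gap.** Female thresholds are 0.16 y earlier than male throughout,
  the default mirroring the by-sex corrected-minuend gap such studies
  report.

Repeat-rating channels for reliability testing perturb each tooth's stage
independently with probability p by ±1 step (uniform direction, clamped to
N…H). Adjacent-step errors only: the emulated raters are professionals, and
gross misreadings are excluded. The acceptance script uses p = 0.05 for the
intra-observer channel and p = 0.10 for the inter-observer channel — an
experienced rater re-reading their own films disagrees with themselves less
than two raters disagree with each other.

Every public operation takes one seeded random stream; there is no global
random state, and fixed seeds give bitwise-reproducible cohorts and files.

**What the generator does not emulate.** Real stage ratings are made by
humans on images: rating difficulty varies by stage (mid-stages are harder
than A or H), errors correlate between adjacent teeth, and real maturation
timing differs between populations. The generator's misclassification is
uniform and independent, its thresholds are a stylised schedule, and its age
distribution is uniform. Passing tests therefore demonstrate correctness of
the estimators and protocol under the stated model, not the real-data
accuracy of any method.

## Model-derived reference inputs

`build_atlas_from_model` reads the zero-noise stages at each grid age off
the model, giving a schedule that is exactly consistent with the generator —
with zero noise, subjects simulated at grid ages are re-estimated at their
own age exactly (round-trip identity). Grid columns above the last
completion threshold are all identical (all-H); the identity property holds
on the developmentally informative part of the grid where columns are
distinct, and fully mature subjects resolve to the mean of the tied all-H
reference ages.

`build_scoring_table_from_model` scores stage s of a tooth as the midpoint
of its occupancy window [τ(s), τ(next stage)] divided by 7 (stage H uses the
G→H gap as its window). The seven scores then sum to roughly the age while
teeth are still developing. Because a mature tooth always scores its
completion age, the table increasingly underestimates older children — the
same right-censoring bias reported for real staged-scoring methods — which
makes it a qualitatively realistic stand-in, not a calibrated instrument.

## Evaluation protocol

Per stratum (any subset of method × whole-year bracket × sex, plus per-
method overall rows): n, ME ± SD, MAE ± SD, paired t-test of CA vs DA
(two-sided, df = n − 1, 95% CI on the mean difference), and error-band
percentages of |error| in [0,1), [1,2), [2,∞) rounded to one decimal. The
half-open bands make "under one year / one-to-two / two-plus" exhaustive
and exclusive; the rounded percentages sum to 100 within 0.15. All SDs use
the n − 1 denominator. MAE ≥ |ME| on every stratum, with equality only when
all errors share a sign.

Sex differences in error are tested per method with Welch's unequal-variance
t-test (the safer default; pooled-variance is available via `equal_var`).
Reliability uses ICC(2,1) — two-way random effects, absolute agreement,
single rater — computed from the mean-squares decomposition
(MS_R − MS_E) / (MS_R + (k−1)MS_E + k(MS_C − MS_E)/n). The form is fixed but
the input matrix is caller-supplied (dental ages or stage indices), so other
designs reduce to supplying different columns.

Degenerate inputs are explicit, not silent: zero-variance differences give
t = 0, p = 1 when the mean is also zero and an infinite-t warning otherwise;
ICC with no between-subject variance is NaN with a warning; empty strata,
orphan estimates, uncovered scoring keys and empty fit groups raise named
errors. No multiple-testing correction is applied across the bracket × sex ×
method grid (the emulated protocol applies none); the report footer says so.

## Problem sizes and numerical choices

The test suite exercises cohorts of 200–831 subjects and a 5,000-subject
cohort for minuend-parameter recovery; Monte-Carlo checks use 10,000 draws
per age point. These sizes put binomial/standard-error bands well inside the
asserted tolerances while keeping the whole suite around a few seconds. The
minuend-recovery check fits on a cohort spanning 10.00–15.99 years — the
quick method's design range, in which the one-tooth-per-year schedule is
still running. On the full 10.00–16.99 study window the fitted minuends
land a tenth of a year or so above the anchors, because every subject older
than the last completion age contributes CA + 0 > 16; that upward correction
is a property of the method (real cohorts show it too) and is reported as
such by the acceptance script rather than asserted away.

Floating-point: CSV floats are re-read with round-trip precision so that
write→read is lossless; atlas grids are built by index (lo + i·step) to
avoid accumulation; comparisons in tests use explicit tolerances except
where exactness is the property under test (atlas identity, ICC of
identical channels, closure to 1e-9).

## Known limitations

* The quick method saturates outside ~10–16 y (DA ∈ [M − 7, M]); younger
  children need eruption-sequence indicators and older ones third-molar
  methods, both out of scope.
* Shipped reference inputs are synthetic and model-derived; conclusions
  about the published Willems tables or London Atlas artwork require
  loading transcriptions of those sources via the CSV interfaces.
* Records must cover all seven left-quadrant teeth; unilateral tooth loss
  (contralateral substitution) is not representable.
* ICC is implemented for complete matrices only; unbalanced rating designs
  are rejected.
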