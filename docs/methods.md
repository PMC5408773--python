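# Methods

## Setting

A binary classifier assigns each instance a real-valued score, higher
meaning "more positive" (a `reverse` option negates scores first). Given the
scores and true labels of a test set with P positives and N negatives, every
evaluation quantity in this package derives from the cumulative confusion
counts along a descending sweep over *score-wise* thresholds — one candidate
threshold per observed score value — under the fixed prediction rule
"positive iff score ≥ threshold" (closed at the threshold; this makes the
cumulative counts unambiguous).

## Tied scores and missing values

Ties are a policy, not an accident, because tied blocks decide the shape of
the PR curve:

- `equiv` (default): all instances sharing a score are absorbed at one
  threshold, so tp and fp may both jump there. This is deterministic and
  yields the rank-statistic AUC identity below. Thresholds are the unique
  scores, strictly decreasing.
- `first`: tied instances keep input order, one step per instance.
- `random`: tied instances are randomly ordered (seeded; when no seed is
  given one is drawn, logged, and recorded on the result). Under the
  per-instance modes every instance creates its own step, so tied threshold
  values necessarily repeat; the strictly-decreasing-thresholds invariant is
  specific to `equiv`.

Missing scores: `error` (default) refuses them; `drop` removes the pairs;
`worst` replaces them with (observed minimum − 1), i.e. strictly below every
observed score, so the instance ranks last. Missing labels are always
dropped (with a logged count) — no meaningful imputation exists for labels.
Datasets that end up single-class are a hard error rather than a silent
empty curve, since precision, TPR and FPR are then all undefined.

## Curves

ROC raw points are (FPR, TPR) = (fp/N, tp/P) per threshold, anchored at
(0,0) and (1,1); straight lines are the correct connector. PR raw points are
(recall, precision) = (tp/P, tp/(tp+fp)) per threshold, ending at
(1, P/(P+N)).

**Non-linear PR interpolation.** Between adjacent confusion points A and B
with tp_B > tp_A, fractional true positives x accrue together with s·x false
positives, s = (fp_B − fp_A)/(tp_B − tp_A), giving
precision(x) = (tp_A + x)/(tp_A + x + fp_A + s·x). Segments with
tp_B = tp_A are vertical in recall: they are kept as duplicated raw x values
(falling precision) and contribute no area. Within a segment precision is
monotone, so curve extrema always sit at knots.

**First point.** At recall 0 the raw ratio tp/(tp+fp) is 0/0. The package
uses the analytic limit of the interpolant entering the first threshold with
tp > 0: if false positives precede that point the limit is 0; otherwise it
is tp_k/(tp_k + fp_k) of that point (= 1 when the top-ranked block is purely
positive). This rule is continuous with the interpolation scheme rather than
an ad-hoc convention.

**Support grid.** Curves are evaluated on {i/x_bins : i = 0…x_bins}
(x_bins = 1000 by default; spacings are 0.5 and 0.001 at x_bins = 2 and
1000). At a grid x coinciding with a vertical jump the value approached from
the right (larger-x side) is taken. x_bins = 1 switches PR to linear
interpolation between raw points.

**AUC.** Trapezoidal rule over the union of grid points and raw knots,
ordered along the curve (zero-width jumps add nothing). Including the knots
makes ROC AUCs exact for the piecewise-linear curve at any grid resolution;
a grid-only mode (`trapezoid_auc(..., include_knots=False)`) is exposed for
comparison. Under `ties='equiv'` the ROC AUC then equals the Mann–Whitney
statistic with half credit for ties divided by P·N, which the tests verify
to 1e-12 against an independent midrank computation. Computed precision is
clamped to [0,1] only after an internal assertion that any excursion is
below 1e-9 — the clamp absorbs float rounding, never a formula error.

Floating-point note: `error_rate` is computed as 1 − accuracy so the
identity error + accuracy = 1 holds exactly (two separately rounded integer
ratios can miss 1 by one ulp).

## Averaging and confidence bands

When a model has m ≥ 2 test sets, gridded curves are averaged pointwise in y
at fixed x. The default band is the normal-approximation standard-error
band, mean ± z_{1−α/2}·sd/√m (sd with m−1 denominator), clamped to [0,1],
with α = 0.05 by default; a population band (mean ± z·sd) is available via
`band_mode="population"`. With m = 20 the z-based band's true coverage is
the t-distribution value P(|t₁₉| ≤ 1.96) ≈ 93.6%, which the Monte-Carlo
coverage test reproduces. Columns whose pointwise range is exactly zero get
sd exactly 0, so identical test sets yield a zero-width band despite the
1-ulp noise of fl(m·a)/m ≠ a. Both the mean of per-dataset AUCs (the
headline `mean_auc`) and the band's mean curve are reported; the two
integrals agree to grid resolution because averaging and the trapezoid
commute on a shared grid.

## Synthetic data

`gen_binormal(n, prevalence, separation, seed)` draws positive scores from
N(separation, 1) and negative scores from N(0, 1), with the positive count
matched exactly to round(n·prevalence). Its theoretical ROC AUC is
Φ(separation/√2), and the true ROC is TPR = Φ(separation + Φ⁻¹(FPR)) — both
used as closed-form oracles. The generator emulates the score overlap and
class imbalance of real classifier output but not its discreteness,
calibration drift, or within-class heterogeneity; passing tests therefore
demonstrate correctness of the *curve calculations*, not the performance of
any real classifier.

## Accuracy harness

`run_accuracy_suite` scores a curve engine on three built-in cases against
three categories — SE (start/end anchors), Ip (intermediate and interpolated
points), Rg (x/y ranges) — with every expected value derived at run time by
independent oracles (per-threshold double-loop confusion counting; dense
fractional-count subdivision of each PR segment): B1, a small alternating
ranking where the non-linear interpolant visibly leaves the chord; B2, an
all-tied balanced set (diagonal ROC, constant-prevalence PR); B3, a 1:4
imbalanced set with a mixed tied block, the regime where non-linear
interpolation matters most. Tolerances: SE 1e-12, Ip 1e-6 (at grid
resolution 1000), Rg 1e-12. A deliberately simplified linear-PR engine is
included to confirm the harness detects interpolation errors (Ip fails, SE
does not). A timing diagnostic (`bench`, sizes 10²/10³/10⁶) is logged only —
wall-clock numbers are hardware-dependent and never asserted.

## Problem sizes and tolerances used in the checks

- Mann–Whitney identity: 1000 random datasets, n ≤ 200, tolerance 1e-12.
- PR AUC vs subdivision oracle: 100 datasets of n = 100, 10⁵ subdivisions
  per segment, tolerance 1e-3 absolute.
- Precision-range and ROC↔PR bijection fuzz: 10⁴ datasets (n ≤ 80) mixing a
  small tied-score alphabet and 1-vs-rest imbalance; the bound 0 ≤ p ≤ 1 is
  checked exactly, the bijection at 1e-12.
- Band coverage: 1000 replicates of m = 20 binormal test sets of n = 1000
  (the natural medium test-set size for this kind of evaluation study),
  separation 1, probed at interior FPR grid points; expected ≈ 93.6% (see
  above), accepted within 95 ± 3%. ROC bands are used because the binormal
  truth is closed-form; PR coverage would confound band calibration with the
  finite-sample bias of the precision ratio.
- Scale sanity: one 10⁶-instance dataset through both curves and AUCs;
  runtime is logged, never asserted.

## Known limitations

Weighted instances, multi-class settings, partial AUCs, calibration
analysis, and bootstrap/DeLong AUC confidence intervals are out of scope.
The band is a pointwise normal approximation, not a simultaneous band, and
with small m it undercovers slightly (z vs t). The `worst` missing policy
makes the filled value tie-free by construction (min − 1); if several scores
are missing they form a tied block at that value and follow the tie policy.
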