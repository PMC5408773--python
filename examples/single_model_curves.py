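"""Compute ROC and PR curves, AUCs and basic measures for one small ranking.

The dataset ranks four instances; the two positives sit at ranks 1 and 3.
Note the PR AUC exceeds the linear-chord value because the non-linear
interpolant bulges above the chord on the segment that recovers the second
positive.
"""

import numpy as np

from precurve import (
    ScoredDataset,
    basic_measures,
    confusion_series,
    interpolate_to_grid,
    pr_points,
    roc_points,
    support_grid,
)

ds = ScoredDataset(
    scores=np.array([4.0, 3.0, 2.0, 1.0]),
    labels=np.array([True, False, True, False]),
)
cs = confusion_series(ds, ties="equiv")
grid = support_grid(1000)
roc = interpolate_to_grid(roc_points(cs), grid)
pr = interpolate_to_grid(pr_points(cs), grid)

print("thresholds:", cs.thresholds, " tp:", cs.tp, " fp:", cs.fp)
print(f"ROC AUC = {roc.auc:.6f}   (rank statistic of this ordering)")
print(f"PR  AUC = {pr.auc:.6f}   (non-linear interpolation, x_bins=1000)")
linear = float(np.trapezoid(pr.raw_y, pr.raw_x))
print(f"PR  AUC = {linear:.6f}   (linear chords, for comparison)")
print("PR raw points (recall, precision):")
for x, y in zip(pr.raw_x, pr.raw_y):
    print(f"  ({x:.2f}, {y:.4f})")

bm = basic_measures(cs)
print("per-threshold accuracy:", np.round(bm.accuracy, 3))
print("per-threshold precision (ppv):", np.round(bm.ppv, 3))
# The first PR point at recall 0 carries precision 1 because the top-ranked
# instance is a positive; the end point (1, 0.5) is the class prevalence.
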