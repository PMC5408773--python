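"""Data-preparation policies: tied scores and missing values.

Tied scores: 'equiv' absorbs a tied block at one threshold (both tp and fp
jump there), while 'first' and 'random' give every instance its own step.
Missing scores: 'error' refuses them, 'drop' removes the rows, 'worst' ranks
them last.
"""

import numpy as np

from precurve import (
    ScoredDataset,
    confusion_series,
    interpolate_to_grid,
    pr_points,
    support_grid,
)

# a tied block at 0.5 containing one positive and two negatives
scores = np.array([0.9, 0.5, 0.5, 0.5, 0.1])
labels = np.array([True, True, False, False, False])
ds = ScoredDataset(scores, labels)

for ties in ("equiv", "first", "random"):
    cs = confusion_series(ds, ties=ties, seed=0)
    print(f"ties={ties:6s} thresholds={cs.thresholds} tp={cs.tp} fp={cs.fp}")
print("equiv gives one jump for the whole block; the per-instance modes")
print("thread through it one step at a time (random order is seeded).\n")

# PR AUC is tie-policy dependent: the equiv sweep interpolates through the
# block non-linearly, the per-instance orders commit to one path each
grid = support_grid(1000)
for ties in ("equiv", "first"):
    cs = confusion_series(ds, ties=ties, seed=0)
    pr = interpolate_to_grid(pr_points(cs), grid)
    print(f"PR AUC under ties={ties}: {pr.auc:.4f}")
print()

raw = np.array([0.9, np.nan, 0.4, 0.2])
lab = [1, 0, 1, 0]
for policy in ("drop", "worst"):
    d = ScoredDataset.from_raw(raw, lab, missing=policy)
    print(f"missing={policy:5s} -> n={d.n}, scores={d.scores}")
# 'worst' fills the missing score with min-1 = -0.8 so that instance is the
# last ranked; with policy 'error' the same input raises a ValidationError.
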