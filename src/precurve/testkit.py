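"""Synthetic data, independent brute-force oracles, and the accuracy harness.

The oracles here deliberately avoid the cumulative-sweep implementation in
:mod:`precurve.core` / :mod:`precurve.curves`: confusion counts come from a
per-threshold double loop, PR values from dense fractional-count
subdivision.  The accuracy harness scores a curve engine on three built-in
cases against three categories of expectations:

  SE  start and end anchor points,
  Ip  intermediate and interpolated points,
  Rg  x and y value ranges.

Every expected value is produced by the oracles at case-construction time;
nothing is hand-entered.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .core import ConfusionSeries, ScoredDataset, ValidationError, confusion_series
from .curves import interpolate_to_grid, pr_points, roc_points, support_grid, _interp_right

logger = logging.getLogger("precurve")

SE_TOL = 1e-12
IP_TOL = 1e-6
RG_TOL = 1e-12


# ---------------------------------------------------------------------------
# synthetic data

def gen_binormal(
    n: int,
    prevalence: float = 0.5,
    separation: float = 1.0,
    seed: int | None = None,
    *,
    model_id: str = "m1",
    dataset_id: str = "d1",
) -> ScoredDataset:
    """Binormal classifier scores: positives ~ N(separation, 1), negatives ~ N(0, 1).

    The positive count is round(n * prevalence), matched exactly; the
    theoretical ROC AUC of this model is Phi(separation / sqrt(2)).
    Deterministic under ``seed``.
    """
    if n < 2:
        raise ValidationError("need n >= 2")
    if not 0 < prevalence < 1:
        raise ValidationError("prevalence must be in (0, 1)")
    n_pos = int(round(n * prevalence))
    if n_pos == 0 or n_pos == n:
        raise ValidationError("rounded class count of 0; adjust n or prevalence")
    rng = np.random.default_rng(seed)
    scores = np.concatenate([rng.normal(separation, 1.0, n_pos), rng.normal(0.0, 1.0, n - n_pos)])
    labels = np.concatenate([np.ones(n_pos, bool), np.zeros(n - n_pos, bool)])
    perm = rng.permutation(n)
    return ScoredDataset(scores[perm], labels[perm], model_id=model_id, dataset_id=dataset_id)


# ---------------------------------------------------------------------------
# brute-force oracles

def brute_force_series(scores, labels):
    """O(n*t) threshold enumeration: for every unique threshold t, count
    positives and negatives with score >= t.  Returns (thresholds, tp, fp)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    thresholds = np.unique(scores)[::-1]
    tp = np.array([int(np.sum((scores >= t) & labels)) for t in thresholds])
    fp = np.array([int(np.sum((scores >= t) & ~labels)) for t in thresholds])
    return thresholds, tp, fp


def oracle_first_precision(scores, labels) -> float:
    """First-point precision at recall 0, from the brute-force counts: the
    limit along the segment entering the first threshold with tp > 0."""
    _, tp, fp = brute_force_series(scores, labels)
    k = int(np.argmax(tp > 0))
    prev_fp = fp[k - 1] if k > 0 else 0
    prev_tp = tp[k - 1] if k > 0 else 0
    if prev_fp > 0:
        return 0.0
    return float((tp[k] - prev_tp) / ((tp[k] - prev_tp) + (fp[k] - prev_fp)))


def oracle_pr_polyline(cs: ConfusionSeries, subdivisions: int = 1000):
    """Dense (recall, precision) polyline of the exact non-linear PR curve.

    Steps fractional true positives in ``subdivisions`` equal steps per
    confusion segment, adding s * step false positives per step; vertical
    (tp-constant) segments contribute their precision drop at zero width.
    """
    if subdivisions < 1:
        raise ValidationError("subdivisions must be >= 1")
    tp = np.concatenate(([0], cs.tp)).astype(float)
    fp = np.concatenate(([0], cs.fp)).astype(float)
    xs, ys = [], []
    for a in range(len(tp) - 1):
        dtp = tp[a + 1] - tp[a]
        dfp = fp[a + 1] - fp[a]
        if dtp == 0:
            xs.append(tp[a + 1] / cs.P)
            ys.append(tp[a + 1] / (tp[a + 1] + fp[a + 1]))
            continue
        s = dfp / dtp
        step = np.linspace(0.0, dtp, subdivisions + 1)
        t = tp[a] + step
        denom = t + fp[a] + s * step
        with np.errstate(invalid="ignore"):
            p = t / denom
        if tp[a] == 0 and fp[a] == 0:  # limit at recall 0 along this segment
            p[0] = 1.0 / (1.0 + s)
        xs.append(t / cs.P)
        ys.append(p)
    x = np.concatenate([np.atleast_1d(v) for v in xs])
    y = np.concatenate([np.atleast_1d(v) for v in ys])
    if x[0] > 0:  # leading vertical points before any tp: curve starts at (0, .)
        x = np.concatenate(([0.0], x))
        y = np.concatenate(([0.0], y))
    return x, y


def oracle_pr_auc(cs: ConfusionSeries, subdivisions: int = 1000) -> float:
    """Non-linear PR AUC by dense subdivision and the trapezoidal rule."""
    x, y = oracle_pr_polyline(cs, subdivisions)
    return float(np.trapezoid(y, x))


def oracle_pr_precision_at(cs: ConfusionSeries, recall: float, subdivisions: int = 20000) -> float:
    """Precision of the exact PR curve at one recall, from the dense polyline
    (right-hand value at duplicated recalls)."""
    x, y = oracle_pr_polyline(cs, subdivisions)
    j = int(np.searchsorted(x, recall, side="right")) - 1
    if x[j] == recall:
        return float(y[j])
    t = (recall - x[j]) / (x[j + 1] - x[j])
    return float(y[j] + t * (y[j + 1] - y[j]))


def oracle_roc_tpr_at(cs: ConfusionSeries, fpr: float) -> float:
    """TPR of the piecewise-linear ROC at one FPR (right-hand value at jumps),
    by direct segment scan over the brute-force style point list."""
    tp = np.concatenate(([0], cs.tp)) / cs.P
    fp = np.concatenate(([0], cs.fp)) / cs.N
    best = 0.0
    for a in range(len(fp)):
        if fp[a] == fpr:
            best = max(best, tp[a])
        elif a + 1 < len(fp) and fp[a] < fpr < fp[a + 1]:
            t = (fpr - fp[a]) / (fp[a + 1] - fp[a])
            best = max(best, tp[a] + t * (tp[a + 1] - tp[a]))
    return float(best)


# ---------------------------------------------------------------------------
# accuracy harness

@dataclass
class AccuracyCase:
    """One harness case: a small dataset plus oracle-derived expectations.

    ``expected`` items are dicts with keys ``curve_type``, ``category`` (SE,
    Ip or Rg), ``kind`` (start/end/point/x_range/y_range), the expected
    coordinates, and a tolerance.
    """

    case_id: str
    dataset: ScoredDataset
    expected: list = field(default_factory=list)


@dataclass
class AccuracyReport:
    """Successes/totals per case and category, with failure details."""

    per_case: dict = field(default_factory=dict)  # case_id -> {category: [successes, total]}
    failures: list = field(default_factory=list)

    @property
    def per_category(self) -> dict:
        agg: dict[str, list[int]] = {}
        for cats in self.per_case.values():
            for cat, (s, t) in cats.items():
                a = agg.setdefault(cat, [0, 0])
                a[0] += s
                a[1] += t
        return {k: tuple(v) for k, v in agg.items()}

    @property
    def overall_pass(self) -> bool:
        return all(s == t for s, t in self.per_category.values())

    def to_dict(self) -> dict:
        return {
            "per_case": {cid: {c: list(v) for c, v in cats.items()} for cid, cats in self.per_case.items()},
            "per_category": {c: list(v) for c, v in self.per_category.items()},
            "overall_pass": self.overall_pass,
            "failures": self.failures,
        }


def _expectations_for(ds: ScoredDataset) -> list:
    """Oracle-derived SE/Ip/Rg expectations for one dataset."""
    cs = confusion_series(ds, ties="equiv")
    prevalence = cs.P / (cs.P + cs.N)
    px, py = oracle_pr_polyline(cs, subdivisions=20000)
    items = [
        {"curve_type": "ROC", "category": "SE", "kind": "start", "x": 0.0, "y": 0.0, "tol": SE_TOL},
        {"curve_type": "ROC", "category": "SE", "kind": "end", "x": 1.0, "y": 1.0, "tol": SE_TOL},
        {"curve_type": "PR", "category": "SE", "kind": "start", "x": 0.0,
         "y": oracle_first_precision(ds.scores, ds.labels), "tol": SE_TOL},
        {"curve_type": "PR", "category": "SE", "kind": "end", "x": 1.0, "y": prevalence, "tol": SE_TOL},
    ]
    for x in (0.25, 0.5, 0.75):
        items.append({"curve_type": "ROC", "category": "Ip", "kind": "point", "x": x,
                      "y": oracle_roc_tpr_at(cs, x), "tol": IP_TOL})
        items.append({"curve_type": "PR", "category": "Ip", "kind": "point", "x": x,
                      "y": oracle_pr_precision_at(cs, x), "tol": IP_TOL})
    for ctype, ys in (("ROC", np.concatenate(([0.0, 1.0], cs.tp / cs.P))), ("PR", py)):
        items.append({"curve_type": ctype, "category": "Rg", "kind": "x_range",
                      "lo": 0.0, "hi": 1.0, "tol": RG_TOL})
        items.append({"curve_type": ctype, "category": "Rg", "kind": "y_range",
                      "lo": float(np.min(ys)), "hi": float(np.max(ys)), "tol": RG_TOL})
    return items


def builtin_cases() -> list[AccuracyCase]:
    """The three shipped harness cases.

    B1: small mixed ranking (alternating classes) — exercises the non-linear
        interpolant away from its linear chord.
    B2: all scores tied, balanced classes — ROC is the diagonal, PR constant
        at prevalence.
    B3: 1:4 imbalance with a mixed tied block — distant adjacent points where
        non-linear interpolation matters most.
    """
    specs = [
        ("B1", [4.0, 3.0, 2.0, 1.0], [True, False, True, False]),
        ("B2", [0.5] * 8, [True, False] * 4),
        ("B3", [0.9, 0.8, 0.7, 0.5, 0.5, 0.5, 0.5, 0.4, 0.3, 0.2],
         [True, False, False, True, False, False, False, False, False, False]),
    ]
    cases = []
    for cid, scores, labels in specs:
        ds = ScoredDataset(np.array(scores), np.array(labels), model_id=cid, dataset_id=cid)
        cases.append(AccuracyCase(case_id=cid, dataset=ds, expected=_expectations_for(ds)))
    return cases


def default_engine(ds: ScoredDataset, x_bins: int = 1000) -> dict:
    """The shipped curve engine: full non-linear pipeline on a support grid."""
    cs = confusion_series(ds, ties="equiv")
    grid = support_grid(x_bins)
    return {
        "ROC": interpolate_to_grid(roc_points(cs), grid),
        "PR": interpolate_to_grid(pr_points(cs), grid),
    }


def linear_interpolation_engine(ds: ScoredDataset, x_bins: int = 1000) -> dict:
    """A deliberately simplified engine that connects PR points linearly;
    used to confirm the harness detects interpolation errors."""
    out = default_engine(ds, x_bins)
    pr = out["PR"]
    pr.grid_y = _interp_right(pr.raw_x, pr.raw_y, pr.grid_x)
    return out


def _grid_value(pts, x: float) -> float:
    idx = int(np.argmin(np.abs(pts.grid_x - x)))
    if abs(pts.grid_x[idx] - x) > 1e-12:
        raise ValidationError(f"query x={x} is not a support point at x_bins={pts.x_bins_used}")
    return float(pts.grid_y[idx])


def run_accuracy_suite(cases=None, engine=None, x_bins: int = 1000) -> AccuracyReport:
    """Score a curve engine against the SE/Ip/Rg expectations of each case.

    SE compares the curve's first/last raw point to the oracle anchors;
    Ip compares gridded values at interior support points; Rg checks that the
    curve's x and y extents lie in [0, 1] and match the oracle's span.
    Failures become report content, never exceptions.
    """
    cases = builtin_cases() if cases is None else cases
    engine = default_engine if engine is None else engine
    report = AccuracyReport()
    for case in cases:
        curves = engine(case.dataset, x_bins)
        counts = {c: [0, 0] for c in ("SE", "Ip", "Rg")}
        for item in case.expected:
            pts = curves[item["curve_type"]]
            ok, detail = _check_item(pts, item)
            counts[item["category"]][1] += 1
            if ok:
                counts[item["category"]][0] += 1
            else:
                report.failures.append({"case": case.case_id, **item, "detail": detail})
        report.per_case[case.case_id] = {c: tuple(v) for c, v in counts.items()}
    return report


def _check_item(pts, item) -> tuple[bool, str]:
    tol = item["tol"]
    if item["kind"] in ("start", "end"):
        i = 0 if item["kind"] == "start" else -1
        dx = abs(pts.raw_x[i] - item["x"])
        dy = abs(pts.raw_y[i] - item["y"])
        return (dx <= tol and dy <= tol, f"got ({pts.raw_x[i]}, {pts.raw_y[i]})")
    if item["kind"] == "point":
        got = _grid_value(pts, item["x"])
        return (abs(got - item["y"]) <= tol, f"got y={got}")
    # ranges over raw knots and gridded values
    vals = np.concatenate([pts.raw_x, pts.grid_x]) if item["kind"] == "x_range" else \
        np.concatenate([pts.raw_y, pts.grid_y])
    lo, hi = float(np.min(vals)), float(np.max(vals))
    in_unit = lo >= 0.0 and hi <= 1.0
    ok = in_unit and abs(lo - item["lo"]) <= tol and abs(hi - item["hi"]) <= tol
    return (ok, f"got span ({lo}, {hi})")


# ---------------------------------------------------------------------------
# timing diagnostics (never asserted)

def bench(sizes=(100, 1000, 1_000_000), seed: int = 0, x_bins: int = 1000) -> dict:
    """Wall-clock timing of the full two-curve pipeline per dataset size.

    Diagnostics only: results are logged and returned, never asserted, since
    they depend on hardware.
    """
    out = {}
    for n in sizes:
        ds = gen_binormal(int(n), prevalence=0.5, separation=1.0, seed=seed)
        t0 = time.perf_counter()
        default_engine(ds, x_bins)
        out[int(n)] = time.perf_counter() - t0
        logger.info("bench n=%d: %.3f s", n, out[int(n)])
    return out
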