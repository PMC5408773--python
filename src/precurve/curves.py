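"""ROC and precision-recall curve construction, interpolation and AUC.

ROC points may be connected linearly, but precision is a non-linear function
of position between two adjacent confusion-count points: moving from
(tp_A, fp_A) to (tp_B, fp_B) adds true positives at unit rate and false
positives at the local skew rate ``s = (fp_B - fp_A) / (tp_B - tp_A)``, so at
``x`` fractional true positives into the segment

    recall(x)    = (tp_A + x) / P
    precision(x) = (tp_A + x) / (tp_A + x + fp_A + s * x)

Curves are evaluated on a fixed support grid (``x_bins`` equal subdivisions
of [0, 1]) so that curves from different test sets can be averaged pointwise,
and the area under the curve is a trapezoidal sum over the union of the grid
and the raw threshold points (knots), which makes ROC areas exact for the
piecewise-linear curve regardless of grid resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ConfusionSeries, ValidationError

DEFAULT_X_BINS = 1000

# Clamping absorbs float rounding only; a genuine formula error would trip this.
_CLAMP_TOL = 1e-9


@dataclass(frozen=True)
class SupportGrid:
    """Evaluation grid {i / x_bins : i = 0..x_bins} with inclusive endpoints."""

    x_bins: int
    xs: np.ndarray = field(repr=False, default=None)


def support_grid(x_bins: int = DEFAULT_X_BINS) -> SupportGrid:
    """Build the x-axis support grid; spacing is 1/x_bins (0.001 by default)."""
    x_bins = int(x_bins)
    if x_bins < 1:
        raise ValidationError("x_bins must be a positive integer")
    xs = np.arange(x_bins + 1, dtype=float) / x_bins
    return SupportGrid(x_bins=x_bins, xs=xs)


@dataclass
class InterpolationSegment:
    """One confusion-count segment from (tpA, fpA) to (tpB, fpB), tpB > tpA."""

    tpA: float
    fpA: float
    tpB: float
    fpB: float
    P: int

    @property
    def s(self) -> float:
        """Local skew: false positives added per true positive."""
        return (self.fpB - self.fpA) / (self.tpB - self.tpA)


def dg_interpolate(seg: InterpolationSegment, x):
    """Evaluate the non-linear PR interpolant ``x`` true positives into a segment.

    ``x`` may be a scalar or array in [0, tpB - tpA].  Returns
    ``(recall, precision)``; at x = 0 and x = tpB - tpA these are exactly the
    endpoint values.
    """
    if not seg.tpB > seg.tpA:
        raise ValidationError("segment has tpB <= tpA; vertical segments are not interpolated")
    x = np.asarray(x, dtype=float)
    s = seg.s
    tp = seg.tpA + x
    recall = tp / seg.P
    precision = tp / (tp + seg.fpA + s * x)
    return recall, _clamp_unit(precision)


def _clamp_unit(y):
    y = np.asarray(y, dtype=float)
    over = max(float(np.max(y, initial=1.0)) - 1.0, 0.0 - float(np.min(y, initial=0.0)))
    if over > _CLAMP_TOL:
        raise AssertionError(f"interpolated value outside [0,1] by {over:g}; formula error")
    return np.clip(y, 0.0, 1.0)


@dataclass
class CurvePoints:
    """One curve: raw threshold-derived points, optional gridded points, AUC.

    ``raw_x``/``raw_y`` are in curve order and include the anchor points
    (ROC: (0,0) and (1,1); PR: the estimated first point at recall 0 and the
    end point (1, prevalence)).  Vertical jumps are kept as duplicated x
    values.  ``grid_y`` holds the interpolated value at each support-grid x,
    taking the right-hand (larger-x side) limit at jumps.  The confusion
    counts the curve came from are retained so PR segments can be
    re-interpolated onto any grid.
    """

    curve_type: str
    raw_x: np.ndarray
    raw_y: np.ndarray
    P: int
    N: int
    tp: np.ndarray = field(repr=False, default=None)  # with leading virtual origin
    fp: np.ndarray = field(repr=False, default=None)
    grid_x: np.ndarray = field(repr=False, default=None)
    grid_y: np.ndarray = field(repr=False, default=None)
    auc: float | None = None
    x_bins_used: int | None = None


def _counts_with_origin(cs: ConfusionSeries):
    tp = np.concatenate(([0], cs.tp)).astype(float)
    fp = np.concatenate(([0], cs.fp)).astype(float)
    return tp, fp


def roc_points(cs: ConfusionSeries) -> CurvePoints:
    """Raw ROC points (FPR, TPR) per threshold, anchored at (0,0) and (1,1)."""
    tp, fp = _counts_with_origin(cs)
    x = fp / cs.N
    y = tp / cs.P
    if x[-1] != 1.0 or y[-1] != 1.0:  # full sweep always ends at (1,1)
        x = np.append(x, 1.0)
        y = np.append(y, 1.0)
    return CurvePoints("ROC", x, y, cs.P, cs.N, tp=tp, fp=fp)


def pr_first_point(cs: ConfusionSeries) -> float:
    """Precision at recall 0: the limit of the segment entering the first tp>0 point.

    If no false positives precede (or coincide before) the first true
    positive, the limit is tp_k/(tp_k + fp_k) of that point; if false
    positives come first, the limit is 0.
    """
    tp, fp = _counts_with_origin(cs)
    k = int(np.argmax(tp > 0))  # first index with tp > 0; exists since P >= 1
    if fp[k - 1] > 0:
        return 0.0
    dtp = tp[k] - tp[k - 1]
    dfp = fp[k] - fp[k - 1]
    return float(dtp / (dtp + dfp))


def pr_points(cs: ConfusionSeries) -> CurvePoints:
    """Raw PR points (recall, precision), anchored at the estimated first point
    at recall 0 and the end point (1, P/(P+N))."""
    tp, fp = _counts_with_origin(cs)
    recall = cs.tp / cs.P
    precision = cs.tp / (cs.tp + cs.fp)  # tp+fp >= 1 at every real threshold
    x = np.concatenate(([0.0], recall))
    y = np.concatenate(([pr_first_point(cs)], precision))
    # drop exact consecutive duplicates (e.g. leading (0,0) repeats)
    keep = np.ones(x.size, dtype=bool)
    keep[1:] = (x[1:] != x[:-1]) | (y[1:] != y[:-1])
    return CurvePoints("PR", x[keep], _clamp_unit(y[keep]), cs.P, cs.N, tp=tp, fp=fp)


def roc_to_pr_point(fpr: float, tpr: float, P: int, N: int):
    """Map an ROC point to its unique PR counterpart at the same threshold.

    recall = TPR and precision = TPR*P / (TPR*P + FPR*N).  Undefined at
    (0, 0), where no instance is predicted positive.
    """
    fpr = np.asarray(fpr, dtype=float)
    tpr = np.asarray(tpr, dtype=float)
    denom = tpr * P + fpr * N
    if np.any(denom == 0):
        raise ValidationError("undefined PR point: tpr == fpr == 0 (no positive predictions)")
    return tpr, _clamp_unit(tpr * P / denom)


def _interp_right(raw_x: np.ndarray, raw_y: np.ndarray, xq: np.ndarray) -> np.ndarray:
    """Piecewise-linear interpolation with the right-hand limit at duplicated x."""
    j = np.searchsorted(raw_x, xq, side="right") - 1
    j = np.clip(j, 0, raw_x.size - 1)
    y = np.empty(xq.shape, dtype=float)
    exact = raw_x[j] == xq
    y[exact] = raw_y[j[exact]]  # last point at that x = value approached from the right
    inside = ~exact
    if inside.any():
        ji = j[inside]
        x0, x1 = raw_x[ji], raw_x[ji + 1]
        y0, y1 = raw_y[ji], raw_y[ji + 1]
        t = (xq[inside] - x0) / (x1 - x0)
        y[inside] = y0 + t * (y1 - y0)
    return y


def _pr_precision_on_grid(tp: np.ndarray, fp: np.ndarray, P: int, xq: np.ndarray) -> np.ndarray:
    """Non-linear PR interpolant evaluated at recalls ``xq`` from the counts
    series (with leading virtual origin), right-hand limit at jumps."""
    recalls = tp / P
    j = np.searchsorted(recalls, xq, side="right") - 1  # last counts index with recall <= x
    y = np.empty(xq.shape, dtype=float)
    exact = recalls[j] == xq
    je = j[exact]
    with np.errstate(invalid="ignore", divide="ignore"):
        y[exact] = tp[je] / (tp[je] + fp[je])
    # exact hit where tp == 0: first-point limit (0 if fp > 0, else next-segment ratio)
    zero_tp = exact.copy()
    zero_tp[exact] = tp[je] == 0
    if zero_tp.any():
        jz = j[zero_tp]
        lim = np.zeros(jz.shape)
        clean = fp[jz] == 0
        if clean.any():
            nxt = jz[clean] + 1
            dtp = tp[nxt] - tp[jz[clean]]
            dfp = fp[nxt] - fp[jz[clean]]
            lim[clean] = dtp / (dtp + dfp)
        y[zero_tp] = lim
    inside = ~exact
    if inside.any():
        ji = j[inside]
        tpA, fpA = tp[ji], fp[ji]
        dtp = tp[ji + 1] - tpA
        dfp = fp[ji + 1] - fpA
        s = dfp / dtp  # recall strictly increases across the bracketing pair
        xf = np.maximum(xq[inside] * P - tpA, 0.0)
        y[inside] = (tpA + xf) / (tpA + xf + fpA + s * xf)
    return _clamp_unit(y)


def interpolate_to_grid(points: CurvePoints, grid: SupportGrid) -> CurvePoints:
    """Evaluate a raw curve on a support grid and attach its trapezoidal AUC.

    ROC curves use linear interpolation.  PR curves use the non-linear
    confusion-segment interpolant, except when ``x_bins == 1``, where linear
    interpolation between raw points is used.  At a grid x that coincides with
    a vertical jump the value approached from the right is taken; the raw
    points are retained separately.
    """
    xq = grid.xs
    if points.curve_type == "ROC" or grid.x_bins == 1:
        yq = _interp_right(points.raw_x, points.raw_y, xq)
    elif points.curve_type == "PR":
        yq = _pr_precision_on_grid(points.tp, points.fp, points.P, xq)
    else:
        raise ValidationError(f"unknown curve type {points.curve_type!r}")
    out = CurvePoints(
        points.curve_type,
        points.raw_x,
        points.raw_y,
        points.P,
        points.N,
        tp=points.tp,
        fp=points.fp,
        grid_x=xq,
        grid_y=yq,
        x_bins_used=grid.x_bins,
    )
    out.auc = trapezoid_auc(out)
    return out


def trapezoid_auc(points: CurvePoints, include_knots: bool = True) -> float:
    """Area under the gridded curve by the trapezoidal rule.

    By default the integration nodes are the union of the support grid and
    the raw threshold knots, ordered along the curve; vertical jumps
    (duplicated x) have zero width and add no area.  ``include_knots=False``
    integrates over the grid points only, for comparison.
    """
    if points.grid_x is None:
        raise ValidationError("grid the curve first (interpolate_to_grid)")
    if not include_knots:
        return float(np.trapezoid(points.grid_y, points.grid_x))
    x = np.concatenate([points.raw_x, points.grid_x])
    y = np.concatenate([points.raw_y, points.grid_y])
    # stable sort by x; at equal x raw points keep curve order and precede the
    # grid point (whose value is the right-hand limit), so the trapezoid
    # enters each jump at the left limit and leaves at the right limit
    source = np.concatenate([np.zeros(points.raw_x.size), np.ones(points.grid_x.size)])
    order = np.lexsort((source, x))
    return float(np.trapezoid(y[order], x[order]))
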