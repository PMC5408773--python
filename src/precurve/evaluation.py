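"""Evaluation over multiple models and test sets; average curves with bands.

Gridding every curve onto a shared support grid is what makes cross-testset
averaging possible: curves are averaged pointwise in y at fixed x, and the
pointwise confidence band is the normal-approximation standard-error band
mean +/- z_{1-alpha/2} * sd / sqrt(m) over the m test sets (a raw
"population" band mean +/- z * sd is available behind a flag).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .core import (
    BasicMeasures,
    ConfusionSeries,
    PrecurveError,
    ScoredDataset,
    ValidationError,
    basic_measures,
    confusion_series,
)
from .curves import DEFAULT_X_BINS, CurvePoints, interpolate_to_grid, pr_points, roc_points, support_grid

logger = logging.getLogger("precurve")

CURVE_TYPES = ("ROC", "PR")


@dataclass
class EvalRequest:
    """Options and datasets for one evaluation run."""

    datasets: list
    curve_types: tuple = CURVE_TYPES
    x_bins: int = DEFAULT_X_BINS
    ties: str = "equiv"
    missing: str = "error"
    ci_alpha: float = 0.05
    seed: int | None = None
    band_mode: str = "se"  # "se" (standard error) or "population"


@dataclass
class CurveBand:
    """Average curve over m test sets with pointwise confidence bounds."""

    curve_type: str
    model_id: str
    grid_x: np.ndarray
    mean_y: np.ndarray
    lower_y: np.ndarray
    upper_y: np.ndarray
    m: int
    alpha: float
    mean_auc: float
    auc_sd: float
    band_mode: str = "se"


@dataclass
class EvalResult:
    """Curves, measures, AUCs and bands for every requested combination.

    ``curves`` is keyed by (model_id, dataset_id, curve_type); ``measures``
    by (model_id, dataset_id); ``bands`` by (model_id, curve_type).  A
    dataset that fails validation or computation is recorded in ``failures``
    rather than aborting the run.
    """

    curves: dict = field(default_factory=dict)
    measures: dict = field(default_factory=dict)
    bands: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def auc_table(self) -> pd.DataFrame:
        rows = [
            {
                "model": m,
                "dataset": d,
                "curve_type": c,
                "auc": pts.auc,
                "x_bins": pts.x_bins_used,
            }
            for (m, d, c), pts in sorted(self.curves.items())
        ]
        return pd.DataFrame(rows, columns=["model", "dataset", "curve_type", "auc", "x_bins"])


def average_curves(gridded: list[CurvePoints], alpha: float = 0.05, band_mode: str = "se",
                   model_id: str = "") -> CurveBand:
    """Pointwise mean of >= 2 gridded curves with a confidence band.

    All curves must share the same grid and curve type.  The band is
    mean +/- z_{1-alpha/2} * sd / sqrt(m) (sd with m-1 denominator), clamped
    to [0, 1]; ``band_mode='population'`` drops the sqrt(m) factor.
    """
    if len(gridded) < 2:
        raise ValidationError("band requires >=2 test sets")
    if not 0 < alpha < 1:
        raise ValidationError("ci_alpha must be in (0, 1)")
    if band_mode not in ("se", "population"):
        raise ValidationError(f"unknown band_mode {band_mode!r}")
    ctype = gridded[0].curve_type
    gx = gridded[0].grid_x
    for g in gridded[1:]:
        if g.curve_type != ctype:
            raise ValidationError("cannot average curves of different types")
        if g.grid_x is None or not np.array_equal(g.grid_x, gx):
            raise ValidationError("curves must share a common support grid")
    ys = np.vstack([g.grid_y for g in gridded])
    m = ys.shape[0]
    mean_y = ys.mean(axis=0)
    sd_y = ys.std(axis=0, ddof=1)
    # all-equal columns have exactly zero spread; guard against the 1-ulp
    # noise of fl(m*a)/m != a so identical curves give a zero-width band
    sd_y[np.ptp(ys, axis=0) == 0.0] = 0.0
    z = float(stats.norm.ppf(1.0 - alpha / 2.0))
    half = z * sd_y / (np.sqrt(m) if band_mode == "se" else 1.0)
    aucs = np.array([g.auc for g in gridded], dtype=float)
    auc_sd = 0.0 if np.ptp(aucs) == 0.0 else float(aucs.std(ddof=1))
    return CurveBand(
        curve_type=ctype,
        model_id=model_id,
        grid_x=gx,
        mean_y=mean_y,
        lower_y=np.clip(mean_y - half, 0.0, 1.0),
        upper_y=np.clip(mean_y + half, 0.0, 1.0),
        m=m,
        alpha=alpha,
        mean_auc=float(aucs.mean()),
        auc_sd=auc_sd,
        band_mode=band_mode,
    )


def evaluate(req, **options) -> EvalResult:
    """Run the full pipeline over every (model, test set) pair.

    ``req`` may be an :class:`EvalRequest` or a list of
    :class:`~precurve.core.ScoredDataset` (options then given as keywords).
    Per pair: one confusion sweep, then every requested curve gridded on the
    shared support grid with its AUC, plus the basic measures.  Models with
    >= 2 successfully evaluated test sets also get a :class:`CurveBand` per
    curve type.  Individual failures are recorded; the run only raises if
    every pair fails.
    """
    if not isinstance(req, EvalRequest):
        req = EvalRequest(datasets=list(req), **options)
    for c in req.curve_types:
        if c not in CURVE_TYPES:
            raise ValidationError(f"unknown curve type {c!r}")
    seen = set()
    for ds in req.datasets:
        key = (ds.model_id, ds.dataset_id)
        if key in seen:
            raise ValidationError(f"duplicate (model, dataset) pair {key}")
        seen.add(key)
    grid = support_grid(req.x_bins)
    res = EvalResult(
        provenance={
            "version": __version__,
            "x_bins": grid.x_bins,
            "ties": req.ties,
            "missing": req.missing,
            "curve_types": list(req.curve_types),
            "ci_alpha": req.ci_alpha,
            "seed": req.seed,
            "band_mode": req.band_mode,
        }
    )
    by_model: dict[str, dict[str, list]] = {}
    for ds in req.datasets:
        key = (ds.model_id, ds.dataset_id)
        try:
            cs = confusion_series(ds, ties=req.ties, seed=req.seed)
            res.measures[key] = basic_measures(cs)
            for ctype in req.curve_types:
                raw = roc_points(cs) if ctype == "ROC" else pr_points(cs)
                pts = interpolate_to_grid(raw, grid)
                res.curves[(ds.model_id, ds.dataset_id, ctype)] = pts
                by_model.setdefault(ds.model_id, {}).setdefault(ctype, []).append(pts)
        except PrecurveError as exc:
            logger.warning("evaluation failed for %s: %s", key, exc)
            res.failures[key] = str(exc)
    if not res.curves:
        raise ValidationError(
            "all (model, dataset) pairs failed: "
            + "; ".join(f"{k}: {v}" for k, v in res.failures.items())
        )
    for model_id, per_type in by_model.items():
        for ctype, members in per_type.items():
            if len(members) >= 2:
                res.bands[(model_id, ctype)] = average_curves(
                    members, alpha=req.ci_alpha, band_mode=req.band_mode, model_id=model_id
                )
    return res
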