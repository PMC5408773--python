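"""Input validation, label coercion, tie/missing policies and the confusion sweep.

The central primitive is the *score-wise* threshold sweep: one candidate
threshold per observed score value (rather than a fixed binning of the score
range), with the prediction rule "positive iff score >= threshold".  A single
descending pass over the sorted scores yields cumulative true/false positive
counts from which every downstream curve and measure is derived.
"""

from __future__ import annotations

import logging
import math
import secrets
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("precurve")

TIE_MODES = ("equiv", "random", "first")
MISSING_POLICIES = ("error", "drop", "worst")


class PrecurveError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(PrecurveError, ValueError):
    """Input data or options failed validation."""


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, (float, np.floating)) and math.isnan(value):
        return True
    return False


def coerce_labels(raw, pos_label=None) -> np.ndarray:
    """Map a two-level label vector onto a boolean positive-class mask.

    Parameters
    ----------
    raw
        Sequence with at most two distinct non-missing values, e.g. ``{0, 1}``,
        ``{-1, 1}`` or two text levels.
    pos_label
        The value to treat as positive.  When omitted, the larger of the two
        observed values under natural ordering is positive (1 over 0, 1 over
        -1, the lexicographically larger of two strings).

    Returns
    -------
    numpy.ndarray of bool, True marking positives.

    Raises
    ------
    ValidationError
        If more than two distinct values are present ("ambiguous labels") or
        coercion leaves a single class ("single-class data").
    """
    values = [v.item() if isinstance(v, np.generic) else v for v in np.ravel(np.asarray(raw, dtype=object))]
    if any(_is_missing(v) for v in values):
        raise ValidationError("labels contain missing values; drop them before coercion")
    distinct = set(values)
    if len(distinct) > 2:
        raise ValidationError(
            f"ambiguous labels: {len(distinct)} distinct values {sorted(map(str, distinct))}"
        )
    if pos_label is None:
        if len(distinct) < 2:
            raise ValidationError("single-class data: only one label value present")
        a, b = distinct
        try:
            pos_label = b if a < b else a
        except TypeError:  # mixed types: fall back to text ordering
            pos_label = max(distinct, key=str)
    out = np.fromiter((v == pos_label for v in values), dtype=bool, count=len(values))
    if out.all() or not out.any():
        raise ValidationError("single-class data after label coercion")
    return out


def apply_missing_policy(scores, labels, policy: str = "error"):
    """Resolve missing (NaN) scores according to ``policy``.

    ``error``  raise on any missing score.
    ``drop``   remove instances with a missing score.
    ``worst``  replace missing scores with a value strictly below the minimum
               observed score, so the instance ranks last.

    Missing *labels* are not handled here; drop them before coercion
    (see :meth:`ScoredDataset.from_raw`).
    """
    if policy not in MISSING_POLICIES:
        raise ValidationError(f"unknown missing policy {policy!r}; expected one of {MISSING_POLICIES}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels differ in length")
    missing = np.isnan(scores)
    if not missing.any():
        return scores, labels
    if policy == "error":
        raise ValidationError(f"{missing.sum()} missing score(s) with policy='error'")
    if policy == "drop":
        keep = ~missing
        if not keep.any():
            raise ValidationError("empty dataset: all instances removed by missing-score policy")
        logger.debug("dropped %d instance(s) with missing scores", int(missing.sum()))
        return scores[keep], labels[keep]
    # worst
    observed = scores[~missing]
    if observed.size == 0:
        raise ValidationError("empty dataset: no observed scores to rank missing ones below")
    fill = observed.min() - 1.0
    out = scores.copy()
    out[missing] = fill
    logger.debug("imputed %d missing score(s) with %g (ranked last)", int(missing.sum()), fill)
    return out, labels


@dataclass
class ScoredDataset:
    """Validated scores and binary labels for one (model, test set) pair.

    Invariants enforced at construction: equal lengths of at least two, no NaN
    scores, and at least one instance of each class.  Higher scores mean "more
    positive"; use ``reverse=True`` in :meth:`from_raw` for the opposite
    convention.
    """

    scores: np.ndarray
    labels: np.ndarray
    model_id: str = "m1"
    dataset_id: str = "d1"

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.scores.ndim != 1 or self.labels.ndim != 1:
            raise ValidationError("scores and labels must be one-dimensional")
        if self.scores.shape != self.labels.shape:
            raise ValidationError("scores and labels differ in length")
        if self.scores.size < 2:
            raise ValidationError("need at least two instances")
        if np.isnan(self.scores).any():
            raise ValidationError("scores contain missing values; apply a missing policy first")
        if self.labels.all() or not self.labels.any():
            raise ValidationError("single-class data: need at least one positive and one negative")

    @property
    def n(self) -> int:
        return int(self.scores.size)

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int((~self.labels).sum())

    @classmethod
    def from_raw(
        cls,
        scores,
        labels,
        *,
        pos_label=None,
        missing: str = "error",
        reverse: bool = False,
        model_id: str = "m1",
        dataset_id: str = "d1",
    ) -> "ScoredDataset":
        """Build a dataset from raw columns, applying the full input pipeline.

        Missing labels are always dropped (with a logged count) together with
        their scores; the missing-score policy then applies; labels are coerced
        with :func:`coerce_labels`; ``reverse`` negates scores so that a
        lower-is-better score column can be used directly.
        """
        raw_labels = [v.item() if isinstance(v, np.generic) else v for v in np.ravel(np.asarray(labels, dtype=object))]
        scores = np.asarray(scores, dtype=float)
        if scores.ndim != 1 or scores.size != len(raw_labels):
            raise ValidationError("scores and labels differ in length")
        keep = np.fromiter((not _is_missing(v) for v in raw_labels), dtype=bool, count=len(raw_labels))
        if not keep.all():
            logger.debug("dropped %d instance(s) with missing labels", int((~keep).sum()))
            scores = scores[keep]
            raw_labels = [v for v, k in zip(raw_labels, keep) if k]
        if len(raw_labels) == 0:
            raise ValidationError("empty dataset: all labels missing")
        lab = coerce_labels(raw_labels, pos_label=pos_label)
        scores, lab = apply_missing_policy(scores, lab, policy=missing)
        if reverse:
            scores = -scores
        return cls(scores=scores, labels=lab, model_id=model_id, dataset_id=dataset_id)


@dataclass
class ConfusionSeries:
    """Cumulative confusion counts along the descending score-wise sweep.

    ``tp[i]``/``fp[i]`` count instances predicted positive (score >=
    ``thresholds[i]``) that are truly positive/negative.  ``tn`` and ``fn``
    are derived, never stored.  Under ``ties='equiv'`` thresholds are the
    unique scores (strictly decreasing) and a tied block is absorbed at one
    threshold; under ``'first'``/``'random'`` every instance is its own step
    and tied thresholds repeat.
    """

    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    P: int
    N: int
    ties: str = "equiv"
    seed_used: int | None = None

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.tp = np.asarray(self.tp, dtype=np.int64)
        self.fp = np.asarray(self.fp, dtype=np.int64)
        t = self.thresholds
        if self.ties == "equiv" and t.size > 1 and not (np.diff(t) < 0).all():
            raise ValidationError("thresholds must be strictly decreasing under ties='equiv'")
        if t.size > 1 and (np.diff(t) > 0).any():
            raise ValidationError("thresholds must be non-increasing")
        for name, v, total in (("tp", self.tp, self.P), ("fp", self.fp, self.N)):
            if (np.diff(v) < 0).any():
                raise ValidationError(f"{name} must be non-decreasing")
            if v.size and (v[0] < 0 or v[-1] != total):
                raise ValidationError(f"{name} must start >=0 and end at {total}")

    @property
    def tn(self) -> np.ndarray:
        return self.N - self.fp

    @property
    def fn(self) -> np.ndarray:
        return self.P - self.tp


def confusion_series(
    ds: ScoredDataset, ties: str = "equiv", seed: int | None = None
) -> ConfusionSeries:
    """Compute cumulative TP/FP counts at every score-wise threshold.

    Parameters
    ----------
    ds
        A validated :class:`ScoredDataset`.
    ties
        ``'equiv'`` (default): instances sharing a score are absorbed at one
        threshold, so tp and fp may both jump there.  ``'first'``: tied
        instances keep input order, one step each.  ``'random'``: tied
        instances are randomly ordered (seeded), one step each.
    seed
        Used only by ``ties='random'``.  When omitted, a fresh seed is drawn,
        logged, and recorded on the returned series for reproducibility.
    """
    if ties not in TIE_MODES:
        raise ValidationError(f"unknown ties mode {ties!r}; expected one of {TIE_MODES}")
    scores, labels = ds.scores, ds.labels
    P, N = ds.n_pos, ds.n_neg
    if ties == "equiv":
        uniq, inv = np.unique(scores, return_inverse=True)  # ascending
        k = uniq.size
        pos_at = np.bincount(inv, weights=labels.astype(float), minlength=k).astype(np.int64)
        tot_at = np.bincount(inv, minlength=k).astype(np.int64)
        thresholds = uniq[::-1]
        tp = np.cumsum(pos_at[::-1])
        fp = np.cumsum((tot_at - pos_at)[::-1])
        return ConfusionSeries(thresholds, tp, fp, P, N, ties=ties)
    seed_used = None
    if ties == "random":
        if seed is None:
            seed_used = secrets.randbelow(2**31)
            logger.info("ties='random' without seed: using recorded seed %d", seed_used)
        else:
            seed_used = int(seed)
        rng = np.random.default_rng(seed_used)
        tiebreak = rng.permutation(scores.size)
        order = np.lexsort((tiebreak, -scores))
    else:  # first: stable sort keeps input order within tied blocks
        order = np.argsort(-scores, kind="stable")
    lab_sorted = labels[order]
    thresholds = scores[order]
    tp = np.cumsum(lab_sorted).astype(np.int64)
    fp = np.cumsum(~lab_sorted).astype(np.int64)
    return ConfusionSeries(thresholds, tp, fp, P, N, ties=ties, seed_used=seed_used)


@dataclass
class BasicMeasures:
    """Per-threshold confusion-matrix measures, each in [0, 1].

    ``ppv`` (positive predictive value, i.e. precision) is NaN wherever
    ``ppv_defined`` is False, which happens exactly when tp + fp == 0.
    """

    thresholds: np.ndarray
    error_rate: np.ndarray
    accuracy: np.ndarray
    specificity: np.ndarray
    sensitivity: np.ndarray
    ppv: np.ndarray
    ppv_defined: np.ndarray = field(repr=False, default=None)


def basic_measures(cs: ConfusionSeries) -> BasicMeasures:
    """Error rate, accuracy, specificity, sensitivity and PPV per threshold.

    error_rate is computed as 1 - accuracy so the identity
    ``error_rate + accuracy == 1`` holds exactly in floating point (the two
    integer-ratio quotients can otherwise disagree by one ulp).
    """
    n = cs.P + cs.N
    tp, fp = cs.tp.astype(float), cs.fp.astype(float)
    tn, fn = cs.tn.astype(float), cs.fn.astype(float)
    accuracy = (tp + tn) / n
    sensitivity = tp / cs.P
    specificity = tn / cs.N
    denom = tp + fp
    defined = denom > 0
    ppv = np.full_like(tp, np.nan)
    np.divide(tp, denom, out=ppv, where=defined)
    return BasicMeasures(
        thresholds=cs.thresholds.copy(),
        error_rate=1.0 - accuracy,
        accuracy=accuracy,
        specificity=specificity,
        sensitivity=sensitivity,
        ppv=ppv,
        ppv_defined=defined,
    )
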