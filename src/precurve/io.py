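"""Reading scored tables (CSV/TSV) and writing curve/AUC/band results.

All numeric output is written at 17 significant digits, which round-trips
IEEE doubles exactly; the JSON mirror therefore reloads bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ScoredDataset, ValidationError

logger = logging.getLogger("precurve")

_FLOAT_FMT = "%.17g"


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_scored_table(
    path,
    score_columns: list[str] | None = None,
    label_column: str = "label",
    *,
    delimiter: str | None = None,
    pos_label=None,
    missing: str = "error",
    reverse: bool = False,
    dataset_id: str | None = None,
) -> list[ScoredDataset]:
    """Read a delimited table with a header into one dataset per score column.

    The delimiter is taken from the extension (.csv -> comma, .tsv -> tab)
    unless given.  ``score_columns`` defaults to every column except the
    label column.  The dataset_id is the file stem, the model_id the column
    name.  Empty score cells become missing values for the missing policy;
    non-numeric score cells are an error reported with their row number
    (1-based, counting the header as row 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_delimiter_for(path, delimiter), dtype=object,
                         keep_default_na=True, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: no rows") from None
    if df.shape[0] == 0:
        raise ValidationError(f"{path}: no rows")
    if label_column not in df.columns:
        raise ValidationError(f"{path}: missing label column {label_column!r}")
    if score_columns is None:
        score_columns = [c for c in df.columns if c != label_column]
        if not score_columns:
            raise ValidationError(f"{path}: no score columns")
    for col in score_columns:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing score column {col!r}")
    labels = df[label_column].to_numpy(dtype=object)
    n_levels = df[label_column].dropna().nunique()
    if n_levels > 2:
        raise ValidationError(f"{path}: label column {label_column!r} has {n_levels} distinct values")
    dataset_id = dataset_id if dataset_id is not None else path.stem
    out = []
    for col in score_columns:
        raw = df[col]
        scores = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float)
        bad = np.isnan(scores) & raw.notna().to_numpy()
        if bad.any():
            row = int(np.argmax(bad)) + 2  # +1 header, +1 one-based
            raise ValidationError(
                f"{path}: unparseable score {raw.iloc[row - 2]!r} in column {col!r}, row {row}"
            )
        out.append(
            ScoredDataset.from_raw(
                scores,
                labels,
                pos_label=pos_label,
                missing=missing,
                reverse=reverse,
                model_id=str(col),
                dataset_id=dataset_id,
            )
        )
    return out


def _curves_frame(res) -> pd.DataFrame:
    rows = []
    for (model, dataset, ctype), pts in sorted(res.curves.items()):
        for x, y in zip(pts.raw_x, pts.raw_y):
            rows.append((ctype, model, dataset, x, y, True))
        if pts.grid_x is not None:
            for x, y in zip(pts.grid_x, pts.grid_y):
                rows.append((ctype, model, dataset, x, y, False))
    return pd.DataFrame(rows, columns=["curve_type", "model", "dataset", "x", "y", "is_raw_knot"])


def _measures_frame(res) -> pd.DataFrame:
    rows = []
    for (model, dataset), bm in sorted(res.measures.items()):
        for i in range(bm.thresholds.size):
            rows.append(
                (model, dataset, bm.thresholds[i], bm.error_rate[i], bm.accuracy[i],
                 bm.specificity[i], bm.sensitivity[i], bm.ppv[i])
            )
    return pd.DataFrame(
        rows,
        columns=["model", "dataset", "threshold", "error_rate", "accuracy",
                 "specificity", "sensitivity", "ppv"],
    )


def _bands_frame(res) -> pd.DataFrame:
    rows = []
    for (model, ctype), band in sorted(res.bands.items()):
        for i in range(band.grid_x.size):
            rows.append(
                (ctype, model, band.grid_x[i], band.mean_y[i], band.lower_y[i],
                 band.upper_y[i], band.m, band.alpha)
            )
    return pd.DataFrame(
        rows, columns=["curve_type", "model", "x", "mean", "lower", "upper", "m", "alpha"]
    )


def write_results(res, out_dir, formats=("tsv", "json")) -> list[Path]:
    """Write an :class:`~precurve.evaluation.EvalResult` to ``out_dir``.

    TSV output: ``curves.tsv``, ``aucs.tsv``, ``measures.tsv`` and, when any
    model has multiple test sets, ``bands.tsv``.  JSON output: a single
    ``results.json`` mirroring all of the above plus provenance.  Returns the
    list of files written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "tsv" in formats:
        frames = {
            "curves.tsv": _curves_frame(res),
            "aucs.tsv": res.auc_table(),
            "measures.tsv": _measures_frame(res),
        }
        if res.bands:
            frames["bands.tsv"] = _bands_frame(res)
        for name, frame in frames.items():
            p = out_dir / name
            frame.to_csv(p, sep="\t", index=False, float_format=_FLOAT_FMT)
            written.append(p)
    if "json" in formats:
        p = out_dir / "results.json"
        with open(p, "w") as fh:
            json.dump(_to_jsonable(res), fh, indent=1)
        written.append(p)
    return written


def _to_jsonable(res) -> dict:
    doc = {"provenance": res.provenance, "curves": [], "measures": [], "bands": [],
           "failures": [{"model": m, "dataset": d, "reason": r} for (m, d), r in sorted(res.failures.items())]}
    for (model, dataset, ctype), pts in sorted(res.curves.items()):
        doc["curves"].append(
            {
                "model": model,
                "dataset": dataset,
                "curve_type": ctype,
                "raw_x": pts.raw_x.tolist(),
                "raw_y": pts.raw_y.tolist(),
                "grid_x": pts.grid_x.tolist() if pts.grid_x is not None else None,
                "grid_y": pts.grid_y.tolist() if pts.grid_y is not None else None,
                "auc": pts.auc,
                "x_bins": pts.x_bins_used,
            }
        )
    for (model, dataset), bm in sorted(res.measures.items()):
        doc["measures"].append(
            {
                "model": model,
                "dataset": dataset,
                "threshold": bm.thresholds.tolist(),
                "error_rate": bm.error_rate.tolist(),
                "accuracy": bm.accuracy.tolist(),
                "specificity": bm.specificity.tolist(),
                "sensitivity": bm.sensitivity.tolist(),
                "ppv": [None if not d else v for v, d in zip(bm.ppv.tolist(), bm.ppv_defined.tolist())],
            }
        )
    for (model, ctype), band in sorted(res.bands.items()):
        doc["bands"].append(
            {
                "model": model,
                "curve_type": ctype,
                "grid_x": band.grid_x.tolist(),
                "mean_y": band.mean_y.tolist(),
                "lower_y": band.lower_y.tolist(),
                "upper_y": band.upper_y.tolist(),
                "m": band.m,
                "alpha": band.alpha,
                "mean_auc": band.mean_auc,
                "auc_sd": band.auc_sd,
                "band_mode": band.band_mode,
            }
        )
    return doc


def read_results_json(path) -> dict:
    """Reload a ``results.json`` written by :func:`write_results`."""
    with open(path) as fh:
        return json.load(fh)
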