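"""Evaluation metrics for per-read gene prediction.

Binary detection follows the read-level convention: a true positive is a
gene detected anywhere in a read that truly carries one (types A, B, C),
a false positive is a gene predicted in a fully non-coding read (type D),
a false negative is a coding read called non-coding, and a true negative
a non-coding read called non-coding.  From the confusion counts come
sensitivity TP/(TP+FN), specificity TN/(TN+FP), their harmonic-mean
f-measure 2·sens·spec/(sens+spec) (deliberately over sensitivity and
specificity, not precision/recall), PPV TP/(TP+FP), and accuracy.

Coordinate quality is the annotation error: for a read with reference
coding interval [Lgb, Rgb) and predicted interval [Lp, Rp),

    error% = 100 · (|Lp − Lgb| + |Rp − Rgb|) / |Fgb|,

with |Fgb| the reference coding segment's length within the read.  The
ROC here sweeps read length (each length contributes one operating point
(1 − specificity, sensitivity)); the AUC of that curve summarizes a
method independent of read length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from fragbench.fragsim import BenchmarkSet, Fragment
from fragbench.predict import GenePrediction, PredictionSet

CODING_TYPES = ("A", "B", "C")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


class Rates(NamedTuple):
    """Detection rates; a None entry marks an undefined rate (zero denominator)."""

    sensitivity: float | None
    specificity: float | None
    f_measure: float | None
    ppv: float | None
    accuracy: float | None


def confusion(
    bench: BenchmarkSet,
    preds: PredictionSet,
    read_length: int | None = None,
    ftype: str | None = None,
) -> ConfusionCounts:
    """Tally TP/FP/FN/TN over a stratum (or the whole benchmark)."""
    frags = bench.stratum(read_length, ftype)
    if not frags:
        raise ValueError(
            f"empty stratum (read_length={read_length}, ftype={ftype})"
        )
    tp = fp = fn = tn = 0
    for frag in frags:
        called = preds.is_coding(frag.read_id)
        if frag.is_coding:
            tp += called
            fn += not called
        else:
            fp += called
            tn += not called
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def rates(counts: ConfusionCounts) -> Rates:
    """Sensitivity, specificity, f-measure, PPV and accuracy from counts.

    Zero-denominator rates come back as None, never silently as 0.
    """

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    sens = ratio(counts.tp, counts.tp + counts.fn)
    spec = ratio(counts.tn, counts.tn + counts.fp)
    if sens is None or spec is None or sens + spec == 0:
        f = None
    else:
        f = 2 * sens * spec / (sens + spec)
    ppv = ratio(counts.tp, counts.tp + counts.fp)
    acc = ratio(counts.tp + counts.tn, counts.total)
    return Rates(sens, spec, f, ppv, acc)


def annotation_error(
    pred: GenePrediction,
    truth: Fragment,
    normalize_by_read_length: bool = False,
) -> float | None:
    """Start/stop annotation error of one prediction, in percent.

    Returns None when the read carries no reference gene (type D) or the
    prediction has no interval to compare.  The error is uncapped and can
    exceed 100%.  By default the normalizer |Fgb| is the reference coding
    segment's length within the read (read_length for type B, half for
    types A and C); normalize_by_read_length switches it to the full read
    length.
    """
    if truth.truth_interval is None:
        return None
    interval = pred.selected_interval(truth.truth_interval)
    if interval is None:
        return None
    lgb, rgb = truth.truth_interval
    fgb = truth.read_length if normalize_by_read_length else rgb - lgb
    return 100.0 * (abs(interval.start - lgb) + abs(interval.end - rgb)) / fgb


def mean_annotation_error(
    bench: BenchmarkSet,
    preds: PredictionSet,
    read_length: int | None = None,
    ftype: str | None = None,
    normalize_by_read_length: bool = False,
) -> tuple[float | None, int, int]:
    """(mean error %, n_annotated, n_missed) over the coding reads of a stratum.

    Only reads where both the truth and the prediction carry an interval
    enter the mean; coding reads the predictor missed (or called coding
    without coordinates) are counted in n_missed.  Returns None for the
    mean when no read could be scored.
    """
    errors = []
    n_missed = 0
    for frag in bench.stratum(read_length, ftype):
        if frag.truth_interval is None:
            continue
        err = annotation_error(preds.get(frag.read_id), frag, normalize_by_read_length)
        if err is None:
            n_missed += 1
        else:
            errors.append(err)
    mean = float(np.mean(errors)) if errors else None
    return mean, len(errors), n_missed


def roc_points(bench: BenchmarkSet, preds: PredictionSet) -> list[tuple[float, float]]:
    """One (FPR, TPR) operating point per read length in the benchmark."""
    points = []
    for L in bench.read_lengths:
        r = rates(confusion(bench, preds, read_length=L))
        if r.sensitivity is None or r.specificity is None:
            continue
        points.append((1.0 - r.specificity, r.sensitivity))
    return points


def roc_auc(points: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal AUC over operating points, anchored at (0,0) and (1,1)."""
    if not points:
        raise ValueError("need at least one ROC point")
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or not np.isfinite(arr).all():
        raise ValueError("ROC points must be finite (fpr, tpr) pairs")
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("ROC points must lie in the unit square")
    order = np.lexsort((arr[:, 1], arr[:, 0]))
    arr = arr[order]
    fpr = np.concatenate(([0.0], arr[:, 0], [1.0]))
    tpr = np.concatenate(([0.0], arr[:, 1], [1.0]))
    return float(np.trapezoid(tpr, fpr))


def metric_table(
    bench: BenchmarkSet,
    prediction_sets: Sequence[PredictionSet],
    per_type: bool = True,
    disjoint_counts: Mapping[str, int] | None = None,
    normalize_by_read_length: bool = False,
) -> pd.DataFrame:
    """The full evaluation table: one row per (method, read_length, stratum).

    Stratum "ALL" pools the four types; undefined rates surface as NaN
    cells.  Annotation error is computed over coding strata only (the
    ALL row averages types A-C).  disjoint_counts lets the caller attach
    the number of coding-but-coordinate-free reads a combiner produced.
    """
    disjoint_counts = disjoint_counts or {}
    rows = []
    strata: list[str | None] = ["ALL"]
    if per_type:
        strata += list("ABCD")
    for pset in prediction_sets:
        for L in bench.read_lengths:
            for st in strata:
                ftype = None if st == "ALL" else st
                counts = confusion(bench, pset, read_length=L, ftype=ftype)
                r = rates(counts)
                if st in ("ALL", *CODING_TYPES):
                    err, n_ann, n_missed = mean_annotation_error(
                        bench, pset, read_length=L, ftype=ftype,
                        normalize_by_read_length=normalize_by_read_length,
                    )
                else:
                    err, n_ann, n_missed = None, 0, 0
                rows.append(
                    {
                        "method": pset.predictor_name,
                        "read_length": L,
                        "stratum": st,
                        "tp": counts.tp,
                        "fp": counts.fp,
                        "fn": counts.fn,
                        "tn": counts.tn,
                        "sensitivity": np.nan if r.sensitivity is None else r.sensitivity,
                        "specificity": np.nan if r.specificity is None else r.specificity,
                        "f_measure": np.nan if r.f_measure is None else r.f_measure,
                        "ppv": np.nan if r.ppv is None else r.ppv,
                        "accuracy": np.nan if r.accuracy is None else r.accuracy,
                        "mean_annotation_error": np.nan if err is None else err,
                        "n_annotated": n_ann,
                        "n_missed": n_missed,
                        "n_disjoint": disjoint_counts.get(pset.predictor_name, 0),
                    }
                )
    return pd.DataFrame(rows)
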