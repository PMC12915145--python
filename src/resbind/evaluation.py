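"""Residue-level and protein-level metrics, calibration, run aggregation.

Two reporting scopes are supported: *pooled* (all masked-in residues of
all proteins thrown together, the default for most binding-site tasks)
and *per-protein/macro* (metrics computed per protein and averaged, the
protocol used for carbohydrate binding sites).  Threshold-free metrics
(AUROC/AUPRC) are undefined on single-class inputs and reported as
``None`` rather than a number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .datamodel import LabelTrack, PredictionTable

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "CalibrationBins",
    "RunAggregate",
    "confusion",
    "accuracy",
    "precision",
    "recall",
    "mcc",
    "f1",
    "dice",
    "auroc",
    "auprc",
    "brier",
    "reliability_bins",
    "metric_report",
    "pooled_arrays",
    "per_protein_metrics",
    "mcc_win_rate",
    "aggregate_runs",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    """One row of evaluation results; ``None`` marks undefined metrics."""

    acc: float | None = None
    precision: float | None = None
    recall: float | None = None
    auroc: float | None = None
    auprc: float | None = None
    f1: float | None = None
    mcc: float | None = None
    dice: float | None = None
    brier: float | None = None
    scope: str = "pooled"
    n_residues: int = 0

    def metric_names(self) -> list:
        return [f.name for f in fields(self) if f.name not in ("scope", "n_residues")]

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.metric_names()}


@dataclass
class CalibrationBins:
    """Equal-width reliability-diagram bins over [0, 1]."""

    edges: np.ndarray  # (n_bins + 1,)
    counts: np.ndarray  # (n_bins,)
    mean_predicted: np.ndarray  # (n_bins,), nan for empty bins
    observed_fraction: np.ndarray  # (n_bins,), nan for empty bins


@dataclass
class RunAggregate:
    """Mean and sample standard deviation over repeated runs."""

    mean: MetricReport
    sd: MetricReport | None
    n_runs: int


def _validate(probabilities, labels):
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("probabilities and labels must be aligned 1-D arrays")
    return p, y.astype(np.int8)


def confusion(probabilities, labels, threshold: float = 0.5) -> ConfusionCounts:
    p, y = _validate(probabilities, labels)
    calls = p >= threshold
    return ConfusionCounts(
        tp=int(np.sum(calls & (y == 1))),
        fp=int(np.sum(calls & (y == 0))),
        tn=int(np.sum(~calls & (y == 0))),
        fn=int(np.sum(~calls & (y == 1))),
    )


def accuracy(c: ConfusionCounts) -> float | None:
    return (c.tp + c.tn) / c.total if c.total else None


def precision(c: ConfusionCounts) -> float | None:
    return c.tp / (c.tp + c.fp) if (c.tp + c.fp) else None


def recall(c: ConfusionCounts) -> float | None:
    return c.tp / (c.tp + c.fn) if (c.tp + c.fn) else None


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation; 0 by convention when a marginal is zero."""
    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def f1(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fp + c.fn
    return 2 * c.tp / denom if denom else 0.0


def dice(c: ConfusionCounts) -> float:
    """Dice similarity coefficient, identical to F1 on the same counts."""
    return f1(c)


def auroc(probabilities, labels) -> float | None:
    p, y = _validate(probabilities, labels)
    if len(np.unique(y)) < 2:
        return None
    return float(roc_auc_score(y, p))


def auprc(probabilities, labels) -> float | None:
    p, y = _validate(probabilities, labels)
    if len(np.unique(y)) < 2:
        return None
    return float(average_precision_score(y, p))


def brier(probabilities, labels) -> float:
    p, y = _validate(probabilities, labels)
    if p.size == 0:
        raise ValueError("brier score of an empty prediction set is undefined")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((p - y) ** 2))


def reliability_bins(probabilities, labels, n_bins: int = 10) -> CalibrationBins:
    """Equal-width bins on [0, 1]; the last bin includes its right edge."""
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    p, y = _validate(probabilities, labels)
    idx = np.minimum((p * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    mean_pred = np.full(n_bins, np.nan)
    observed = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            mean_pred[b] = p[sel].mean()
            observed[b] = y[sel].mean()
    return CalibrationBins(
        edges=np.linspace(0.0, 1.0, n_bins + 1),
        counts=counts,
        mean_predicted=mean_pred,
        observed_fraction=observed,
    )


def metric_report(probabilities, labels, threshold: float = 0.5, scope: str = "pooled") -> MetricReport:
    p, y = _validate(probabilities, labels)
    c = confusion(p, y, threshold)
    return MetricReport(
        acc=accuracy(c),
        precision=precision(c),
        recall=recall(c),
        auroc=auroc(p, y),
        auprc=auprc(p, y),
        f1=f1(c),
        mcc=mcc(c),
        dice=dice(c),
        brier=brier(p, y) if p.size else None,
        scope=scope,
        n_residues=int(p.size),
    )


def pooled_arrays(table: PredictionTable, tracks: dict) -> tuple:
    """Aligned (probabilities, labels) over masked-in residues only."""
    probs, labels = [], []
    for row in table.rows:
        track: LabelTrack = tracks[row.protein_id]
        if track.mask[row.position]:
            probs.append(row.probability)
            labels.append(track.labels[row.position])
    return np.asarray(probs, dtype=np.float64), np.asarray(labels, dtype=np.int8)


def per_protein_metrics(table: PredictionTable, tracks: dict, threshold: float = 0.5):
    """Per-protein reports plus macro means.

    Proteins without any true positive are excluded from the recall and
    DICE macro averages; proteins with a single observed class yield
    undefined AUROC/AUPRC and are likewise excluded from those means.
    Returns (per_protein_reports, macro_report, exclusion_counts).
    """
    ids = table.protein_ids()
    if not ids:
        raise ValueError("no proteins to evaluate")
    reports: dict = {}
    for pid in ids:
        probs, labels = pooled_arrays(table.for_protein(pid), tracks)
        reports[pid] = metric_report(probs, labels, threshold, scope="per_protein")
    macro = MetricReport(scope="macro_mean")
    exclusions: dict = {}
    for name in macro.metric_names():
        values = []
        excluded = 0
        for pid in ids:
            rep = reports[pid]
            value = getattr(rep, name)
            no_positives = tracks[pid].n_positive == 0
            if value is None or (name in ("recall", "dice") and no_positives):
                excluded += 1
                continue
            values.append(value)
        setattr(macro, name, float(np.mean(values)) if values else None)
        exclusions[name] = excluded
    macro.n_residues = sum(r.n_residues for r in reports.values())
    return reports, macro, exclusions


def mcc_win_rate(table_a: PredictionTable, table_b: PredictionTable, tracks: dict,
                 threshold: float = 0.5) -> float:
    """Fraction of proteins where A's MCC strictly exceeds B's."""
    ids = table_a.protein_ids()
    if set(ids) != set(table_b.protein_ids()):
        raise ValueError("the two prediction sets cover different proteins")
    wins = 0
    for pid in ids:
        pa, ya = pooled_arrays(table_a.for_protein(pid), tracks)
        pb, yb = pooled_arrays(table_b.for_protein(pid), tracks)
        if mcc(confusion(pa, ya, threshold)) > mcc(confusion(pb, yb, threshold)):
            wins += 1
    return wins / len(ids)


def aggregate_runs(reports) -> RunAggregate:
    """Per-metric mean and sample SD (n-1 denominator) over repeated runs."""
    reports = list(reports)
    if not reports:
        raise ValueError("no runs to aggregate")
    scopes = {r.scope for r in reports}
    if len(scopes) != 1:
        raise ValueError(f"runs have mixed scopes: {sorted(scopes)}")
    mean_rep = MetricReport(scope=scopes.pop())
    sd_rep = MetricReport(scope=mean_rep.scope) if len(reports) > 1 else None
    for name in mean_rep.metric_names():
        values = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        if not values:
            continue
        setattr(mean_rep, name, float(np.mean(values)))
        if sd_rep is not None and len(values) > 1:
            setattr(sd_rep, name, float(np.std(values, ddof=1)))
    mean_rep.n_residues = int(np.mean([r.n_residues for r in reports]))
    return RunAggregate(mean=mean_rep, sd=sd_rep, n_runs=len(reports))
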