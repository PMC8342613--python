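"""ROC, Youden and precision-based similarity-threshold calibration.

A query is *assigned* at threshold t iff its top-hit similarity is
strictly greater than t.  Candidate thresholds are the observed
similarity values (plus a sentinel below the minimum for the ROC
endpoint), so reported thresholds are always interpretable as observed
scores.  Counts at a threshold follow the usual confusion scheme:

* TP — correct identification, assigned (similarity > t)
* FP — incorrect identification, assigned
* FN — correct identification, left unassigned
* TN — incorrect identification, left unassigned

The precision-based thresholds P100/P99/P95 allow 0%, 1% and 5% error in
the accepted (assigned) class: the smallest candidate t such that
precision >= the criterion at t and at every higher candidate.  If the
criterion holds everywhere the threshold falls to the minimum observed
similarity, assigning (almost) everything.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .identification import IdentificationResult, results_to_frame

_CRITERIA = {"p100": 0.0, "p99": 0.01, "p95": 0.05}


def _hits_frame(results, rank: str) -> pd.DataFrame:
    if rank not in ("order", "family"):
        raise ValueError("rank must be 'order' or 'family'")
    df = results if isinstance(results, pd.DataFrame) else results_to_frame(results)
    return df[df["hit_id"].notna()].copy()


def _sims_correct(results, rank: str) -> tuple[np.ndarray, np.ndarray]:
    hits = _hits_frame(results, rank)
    sims = hits["similarity"].to_numpy(dtype=float)
    correct = hits[f"correct_{rank}"].to_numpy(dtype=bool)
    return sims, correct


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_at_threshold(results, t: float, rank: str) -> ConfusionCounts:
    """Confusion counts at threshold ``t`` (assignment rule: similarity > t)."""
    sims, correct = _sims_correct(results, rank)
    assigned = sims > t
    return ConfusionCounts(
        tp=int((correct & assigned).sum()),
        fp=int((~correct & assigned).sum()),
        tn=int((~correct & ~assigned).sum()),
        fn=int((correct & ~assigned).sum()),
    )


@dataclass
class ROCCurve:
    """TPR/FPR at every candidate threshold, with trapezoidal AUC.

    ``thresholds`` are descending observed similarities followed by a
    sentinel below the minimum (the (1, 1) endpoint).  ``auc`` is NaN when
    one outcome class is absent; ``note`` says why.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    note: str = ""


def roc_curve(results, rank: str) -> ROCCurve:
    sims, correct = _sims_correct(results, rank)
    if sims.size == 0:
        return ROCCurve(np.array([]), np.array([]), np.array([]), math.nan,
                        "no results with a hit")
    cands = np.unique(sims)[::-1]
    thresholds = np.append(cands, cands[-1] - 1.0)  # sentinel -> assign all
    n_pos = int(correct.sum())
    n_neg = int((~correct).sum())
    tpr = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for k, t in enumerate(thresholds):
        assigned = sims > t
        tpr[k] = (correct & assigned).sum() / n_pos if n_pos else math.nan
        fpr[k] = (~correct & assigned).sum() / n_neg if n_neg else math.nan
    if n_pos == 0 or n_neg == 0:
        missing = "correct" if n_pos == 0 else "incorrect"
        return ROCCurve(thresholds, tpr, fpr, math.nan,
                        f"no {missing} identifications; AUC undefined")
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds, tpr, fpr, auc)


def concordance_auc(results, rank: str) -> float:
    """Rank-pair (Mann-Whitney) AUC: fraction of (correct, incorrect)
    similarity pairs ranked concordantly, ties counted 1/2.  Used as an
    independent cross-check of the trapezoidal AUC."""
    sims, correct = _sims_correct(results, rank)
    pos = sims[correct]
    neg = sims[~correct]
    if pos.size == 0 or neg.size == 0:
        return math.nan
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def youden_threshold(roc: ROCCurve) -> tuple[float, float]:
    """Threshold maximizing J = TPR - FPR over the observed candidates
    (ties resolved toward the largest, most conservative, threshold)."""
    if roc.thresholds.size == 0 or math.isnan(roc.auc):
        return math.nan, math.nan
    cands = roc.thresholds[:-1]  # exclude the sentinel
    j = roc.tpr[:-1] - roc.fpr[:-1]
    best = float(j.max())
    # thresholds are descending: first maximizer is the largest t
    k = int(np.flatnonzero(j == best)[0])
    return float(cands[k]), best


def precision_threshold(results, rank: str, allowed_error: float) -> float:
    """Smallest candidate t whose precision criterion (>= 1 - allowed_error)
    holds at t and at every higher candidate.  Candidates with no assigned
    query satisfy the criterion vacuously.  When the criterion holds at all
    candidates the threshold is the minimum observed similarity."""
    if not 0.0 <= allowed_error < 1.0:
        raise ValueError("allowed_error must be in [0, 1)")
    sims, correct = _sims_correct(results, rank)
    if sims.size == 0:
        return math.nan
    target = 1.0 - allowed_error
    cands = np.unique(sims)[::-1]  # descending
    best = math.nan
    for t in cands:
        assigned = sims > t
        n_assigned = int(assigned.sum())
        if n_assigned:
            prec = (correct & assigned).sum() / n_assigned
            if prec < target:
                break
        best = float(t)
    if math.isnan(best):
        # even the top candidate fails; cannot happen under strict > since
        # nothing is assigned above the maximum, but guard anyway
        return float(cands[0])
    return best


@dataclass
class ThresholdMetrics:
    """Operating characteristics of one threshold."""

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    tpr: float
    fpr: float
    precision: float
    accuracy: float
    assigned_fraction: float


def metrics_at(results, t: float, rank: str) -> ThresholdMetrics:
    c = confusion_at_threshold(results, t, rank)
    n = c.n
    assigned = c.tp + c.fp
    return ThresholdMetrics(
        threshold=float(t),
        tp=c.tp, fp=c.fp, tn=c.tn, fn=c.fn,
        tpr=c.tp / (c.tp + c.fn) if c.tp + c.fn else math.nan,
        fpr=c.fp / (c.fp + c.tn) if c.fp + c.tn else math.nan,
        precision=c.tp / assigned if assigned else math.nan,
        accuracy=(c.tp + c.tn) / n if n else math.nan,
        assigned_fraction=assigned / n if n else math.nan,
    )


@dataclass
class ThresholdReport:
    """Calibration summary for one result set at one rank."""

    rank: str
    scope: str
    n_hits: int
    n_unassignable: int
    auc: float
    auc_note: str
    youden_j: float
    youden: ThresholdMetrics | None
    p100: ThresholdMetrics | None
    p99: ThresholdMetrics | None
    p95: ThresholdMetrics | None

    def to_dict(self) -> dict:
        def _clean(x):
            if isinstance(x, float) and math.isnan(x):
                return None
            if isinstance(x, dict):
                return {k: _clean(v) for k, v in x.items()}
            return x

        return _clean(asdict(self))


def calibrate(results, rank: str, scope: str = "all"):
    """Full threshold report; ``scope='per-order'`` calibrates each order
    independently on the queries whose *true* order is that order."""
    df = results if isinstance(results, pd.DataFrame) else results_to_frame(results)
    if scope == "per-order":
        return {
            order: _calibrate_one(sub, rank, scope=order)
            for order, sub in df.groupby("true_order", sort=True)
        }
    if scope != "all":
        raise ValueError("scope must be 'all' or 'per-order'")
    return _calibrate_one(df, rank, scope="all")


def _calibrate_one(df: pd.DataFrame, rank: str, scope: str) -> ThresholdReport:
    hits = df[df["hit_id"].notna()]
    n_hits = len(hits)
    n_unassignable = len(df) - n_hits
    roc = roc_curve(df, rank)
    yt, j = youden_threshold(roc)
    p_ts = {
        name: precision_threshold(df, rank, err) for name, err in _CRITERIA.items()
    }
    return ThresholdReport(
        rank=rank,
        scope=scope,
        n_hits=n_hits,
        n_unassignable=n_unassignable,
        auc=roc.auc,
        auc_note=roc.note,
        youden_j=j,
        youden=metrics_at(df, yt, rank) if not math.isnan(yt) else None,
        p100=metrics_at(df, p_ts["p100"], rank) if not math.isnan(p_ts["p100"]) else None,
        p99=metrics_at(df, p_ts["p99"], rank) if not math.isnan(p_ts["p99"]) else None,
        p95=metrics_at(df, p_ts["p95"], rank) if not math.isnan(p_ts["p95"]) else None,
    )


def threshold_table(results, rank: str) -> pd.DataFrame:
    """Per-candidate operating characteristics (one row per observed
    similarity plus the assign-everything sentinel)."""
    sims, _ = _sims_correct(results, rank)
    if sims.size == 0:
        raise ValueError("no results with a hit")
    cands = np.unique(sims)[::-1]
    thresholds = np.append(cands, cands[-1] - 1.0)
    rows = [asdict(metrics_at(results, t, rank)) for t in thresholds]
    return pd.DataFrame(rows)


def report_to_json(reports: dict, path) -> None:
    """Serialize nested {rank: {scope: report}} structures to JSON."""

    def _conv(obj):
        if isinstance(obj, ThresholdReport):
            return obj.to_dict()
        if isinstance(obj, dict):
            return {k: _conv(v) for k, v in obj.items()}
        return obj

    with open(path, "w") as fh:
        json.dump(_conv(reports), fh, indent=2)
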