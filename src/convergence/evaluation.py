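"""Precision-recall benchmarking of site detectors and tied site ranking."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .detectors import SiteScores


@dataclass
class PRCurve:
    """Precision-recall curve over score thresholds (one point per distinct
    defined score, plus a recall-0 endpoint and the all-positive call)."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "precision": self.precision,
                             "recall": self.recall})


def _score_vector(scores) -> np.ndarray:
    if isinstance(scores, SiteScores):
        s = scores.score if scores.score is not None else scores.raw
    else:
        s = scores
    return np.asarray(s, dtype=float)


def _label_vector(truth) -> np.ndarray:
    labels = getattr(truth, "labels", truth)
    return np.asarray(labels, dtype=bool)


def pr_curve(scores, truth) -> PRCurve:
    """Precision-recall curve of a score vector against ground truth.

    Thresholds sit at each distinct defined score (ties collapse).
    Undefined (NaN) scores are never called: they contribute to the
    positive total but never to true or false positives, except at the
    final all-positive point (threshold -inf, recall 1, precision =
    prevalence).
    """
    s = _score_vector(scores)
    y = _label_vector(truth)
    if len(s) != len(y):
        raise ValueError("scores and truth have different lengths")
    total_pos = int(y.sum())
    if total_pos == 0:
        raise ValueError("no positive sites in truth; precision-recall is "
                         "undefined")
    defined = ~np.isnan(s)
    sd, yd = s[defined], y[defined]
    order = np.argsort(-sd, kind="stable")
    sd, yd = sd[order], yd[order]
    tp = np.cumsum(yd)
    calls = np.arange(1, len(sd) + 1)
    # keep the last index of each tie group
    last = np.ones(len(sd), dtype=bool)
    last[:-1] = sd[1:] != sd[:-1]
    thr = sd[last]
    precision = tp[last] / calls[last]
    recall = tp[last] / total_pos
    # endpoints: recall 0 at +inf, all-positive call at -inf
    first_prec = precision[0] if len(precision) else y.mean()
    thr = np.concatenate([[np.inf], thr, [-np.inf]])
    precision = np.concatenate([[first_prec], precision, [y.mean()]])
    recall = np.concatenate([[0.0], recall, [1.0]])
    return PRCurve(thresholds=thr, precision=precision, recall=recall)


def auc_pr(curve: PRCurve) -> float:
    """Area under the PR curve, trapezoid over recall; ties in recall take
    the maximum precision."""
    df = pd.DataFrame({"recall": curve.recall, "precision": curve.precision})
    agg = df.groupby("recall", sort=True)["precision"].max()
    area = float(np.trapezoid(agg.to_numpy(), agg.index.to_numpy()))
    return min(max(area, 0.0), 1.0)


def sensitivity_at_precision(curve: PRCurve, threshold: float = 0.90) -> float:
    """Maximum recall among curve points with precision >= threshold
    (0 when the curve never reaches it)."""
    ok = curve.precision >= threshold
    return float(curve.recall[ok].max()) if ok.any() else 0.0


def rank_sites(scores, site_ids=None) -> pd.DataFrame:
    """Rank sites by score, best = rank 1; tied scores all receive the
    highest (worst) rank of their tie group. Undefined scores rank last.

    Returns a frame (site, score, rank) restricted to ``site_ids`` when
    given (unknown ids raise).
    """
    s = _score_vector(scores)
    filled = np.where(np.isnan(s), -np.inf, s)
    ranks = rankdata(-filled, method="max").astype(int)
    n = len(s)
    if site_ids is None:
        site_ids = np.arange(n)
    site_ids = np.asarray(site_ids, dtype=int)
    if site_ids.min(initial=0) < 0 or site_ids.max(initial=-1) >= n:
        raise ValueError("unknown site id in query")
    return pd.DataFrame({"site": site_ids, "score": s[site_ids],
                         "rank": ranks[site_ids]})


@dataclass
class BenchmarkResult:
    """Per-method PR summaries for one benchmark run."""

    auc: dict[str, float]
    sensitivity: dict[str, float]
    precision_threshold: float = 0.90
    curves: dict[str, PRCurve] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        methods = sorted(self.auc, key=lambda m: -self.auc[m])
        return pd.DataFrame({
            "method": methods,
            "auc": [self.auc[m] for m in methods],
            f"sensitivity_at_{self.precision_threshold:g}_precision":
                [self.sensitivity[m] for m in methods],
        })

    def to_json(self, path: str) -> None:
        payload = {
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "precision_threshold": self.precision_threshold,
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def evaluate_methods(scores_by_method: dict[str, SiteScores], truth,
                     precision_threshold: float = 0.90,
                     metadata: dict | None = None) -> BenchmarkResult:
    """AUC and sensitivity-at-precision for each method's scores.

    Metadata records the AUC estimator (trapezoid over recall) so the
    numbers can be compared against alternative step-wise estimates.
    """
    aucs, sens, curves = {}, {}, {}
    for name, scores in scores_by_method.items():
        curve = pr_curve(scores, truth)
        curves[name] = curve
        aucs[name] = auc_pr(curve)
        sens[name] = sensitivity_at_precision(curve, precision_threshold)
    meta = {"auc_estimator": "trapezoid_over_recall"}
    meta.update(metadata or {})
    return BenchmarkResult(auc=aucs, sensitivity=sens,
                           precision_threshold=precision_threshold,
                           curves=curves, metadata=meta)
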