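"""Comparator scorers: two-sample t, Mann-Whitney AUC, and SAM-style penalized t.

All three return a nonnegative per-marker magnitude (larger = more relevant)
so they can be ranked and compared against the rerank score on equal terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .data import FeatureMatrix, InvalidInputError

__all__ = ["BaselineScores", "t_scores", "auc_scores", "sam_scores"]


@dataclass(frozen=True)
class BaselineScores:
    method: str              # "t", "auc" or "sam"
    score: np.ndarray        # length-p magnitudes
    marker_ids: np.ndarray
    params: dict = field(default_factory=dict)


def _group_stats(data: FeatureMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker |mean difference| and pooled standard error of the difference."""
    x1 = data.values[data.case_mask]
    x0 = data.values[data.control_mask]
    n1, n0 = x1.shape[0], x0.shape[0]
    if n1 < 2 or n0 < 2:
        raise InvalidInputError("need at least 2 rows per group for a variance estimate")
    diff = x1.mean(axis=0) - x0.mean(axis=0)
    sp2 = ((n1 - 1) * x1.var(axis=0, ddof=1) + (n0 - 1) * x0.var(axis=0, ddof=1)) / (
        n1 + n0 - 2
    )
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    return np.abs(diff), se, diff


def t_scores(data: FeatureMatrix, welch: bool = False) -> BaselineScores:
    """Absolute two-sample t statistic per marker.

    Pooled-variance (Student) t by default; ``welch=True`` uses per-group
    variances.  Zero-variance markers score 0 when the group means agree and
    +inf when they differ (those sort first).
    """
    x1 = data.values[data.case_mask]
    x0 = data.values[data.control_mask]
    n1, n0 = x1.shape[0], x0.shape[0]
    if n1 < 2 or n0 < 2:
        raise InvalidInputError("need at least 2 rows per group for a t statistic")
    diff = x1.mean(axis=0) - x0.mean(axis=0)
    if welch:
        se = np.sqrt(x1.var(axis=0, ddof=1) / n1 + x0.var(axis=0, ddof=1) / n0)
    else:
        _, se, _ = _group_stats(data)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(diff) / se
    t[(se == 0) & (diff == 0)] = 0.0
    t[(se == 0) & (diff != 0)] = np.inf
    return BaselineScores(
        method="t", score=t, marker_ids=data.marker_ids, params={"welch": welch}
    )


def auc_scores(data: FeatureMatrix) -> BaselineScores:
    """Midrank Mann-Whitney AUC per marker, reported as |AUC - 0.5|.

    With n1 cases and n0 controls there are at most n0*n1 distinct AUC values,
    so for p >> n0*n1 the scores are massively tied — the weakness this
    comparator illustrates.
    """
    n1, n0 = data.n1, data.n0
    ranks = rankdata(data.values, axis=0, method="average")
    r1 = ranks[data.case_mask].sum(axis=0)
    auc = (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return BaselineScores(
        method="auc", score=np.abs(auc - 0.5), marker_ids=data.marker_ids,
        params={"auc": auc},
    )


def sam_scores(data: FeatureMatrix, s0: float) -> BaselineScores:
    """SAM-style penalized t: |mean difference| / (pooled SE + s0).

    ``s0 = 0`` recovers the pooled |t| ordering; ``s0 -> inf`` converges to
    the |mean difference| (fold-change-like) ordering.  The choice of s0 is
    left to the caller — the automatic quantile-based estimate of the samr
    package is out of scope here.
    """
    if s0 < 0:
        raise InvalidInputError(f"s0 must be >= 0, got {s0}")
    absdiff, se, _ = _group_stats(data)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = absdiff / (se + s0)
    score[(se + s0 == 0) & (absdiff == 0)] = 0.0
    score[(se + s0 == 0) & (absdiff != 0)] = np.inf
    return BaselineScores(
        method="sam", score=score, marker_ids=data.marker_ids, params={"s0": s0}
    )
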