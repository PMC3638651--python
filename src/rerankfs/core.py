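"""Centered rank-over-variable statistic.

The per-marker score is built in three steps.  Each marker is first centered
by its overall sample mean (cases and controls pooled),

    x*_ij = x_ij - mu_j,      mu_j = (1/n) sum_i x_ij,

then, *within each subject*, the centered values are ranked across markers in
decreasing order (rank 1 = largest; ties receive midranks).  The score of
marker j is the absolute difference of the group mean ranks,

    S_j = | mean_{cases} R(i, j) - mean_{controls} R(i, j) |,

which lies in [0, p - 1].  Ranking over variables (rather than over samples)
avoids the massive tie problem of AUC-type statistics when p >> n, while the
centering step is what lets a mean shift in a single marker show up as a rank
reversal between the groups.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import rankdata

from .data import FeatureMatrix, InvalidInputError

__all__ = ["RankTables", "ScoreVector", "center", "rank_over_variable", "score_S", "rank_scores"]


@dataclass(frozen=True)
class RankTables:
    """Intermediate tables: per-marker means, centered values, within-row ranks."""

    mu: np.ndarray                  # (p,) overall per-marker means
    centered: np.ndarray            # (n, p) values - mu
    marker_ids: np.ndarray
    ranks: np.ndarray | None = None  # (n, p) within-row ranks, 1 = largest


@dataclass(frozen=True)
class ScoreVector:
    """Nonnegative per-marker scores; larger = stronger group separation."""

    s: np.ndarray
    marker_ids: np.ndarray


def center(data: FeatureMatrix) -> RankTables:
    """Center every marker by its overall (pooled cases + controls) mean."""
    mu = data.values.mean(axis=0)
    return RankTables(mu=mu, centered=data.values - mu, marker_ids=data.marker_ids)


def rank_over_variable(tables: RankTables) -> RankTables:
    """Rank the centered values across markers within each subject.

    Rank 1 is the largest centered value ("decreasing order"); ties get
    midranks, so every row of the result sums to p(p+1)/2.
    """
    ranks = rankdata(-tables.centered, axis=1, method="average")
    return replace(tables, ranks=ranks)


def score_S(tables: RankTables, labels: np.ndarray) -> ScoreVector:
    """Absolute difference of group mean ranks per marker."""
    if tables.ranks is None:
        raise InvalidInputError("ranks not filled; call rank_over_variable first")
    labels = np.asarray(labels)
    case = labels == 1
    ctrl = labels == 0
    if case.sum() == 0 or ctrl.sum() == 0:
        raise InvalidInputError("both groups must be non-empty")
    s = np.abs(tables.ranks[case].mean(axis=0) - tables.ranks[ctrl].mean(axis=0))
    return ScoreVector(s=s, marker_ids=tables.marker_ids)


def rank_scores(data: FeatureMatrix) -> ScoreVector:
    """Convenience: centering, within-subject ranking and scoring in one call."""
    return score_S(rank_over_variable(center(data)), data.labels)
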