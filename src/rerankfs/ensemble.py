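"""Random-subset averaging and iterative rerank aggregation.

The raw rank-over-variable score of a relevant marker is diluted when the
vast majority of markers carry no signal.  Two ensemble devices sharpen it:

**Random subset.**  Draw B random marker subsets of half the active size,
recompute the score within each subset (ranks are recomputed inside the
subset; the centering means are subset-independent), and average each
marker's score over the subsets that contained it:

    S*_j = mean_b { S_j^(b) : j in subset b }.

**Rerank.**  Starting from the full active set I_0, iteration t computes
S*^(t) on I_t, keeps the top q% to form I_{t+1}, and repeats until the next
set would fall below a stopping size.  Each iteration contributes the
size-normalized score S*_j^(t) / p_t weighted by the iteration's mean

    w_t = (1/p_t) sum_{j in I_t} S*_j^(t) / p_t ,

and the final score is the weighted sum over the iterations that contained
the marker:

    S**_j = sum_{t : j in I_t} w_t * S*_j^(t) / p_t .

A cheap two-sample t prescreen (top M0 by |t|) can cut the marker set before
the ensemble machinery runs; with default M0 = 5000 it is a no-op for
p <= 5000.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernel
from .data import FeatureMatrix, InvalidInputError

__all__ = [
    "SubsetScore",
    "IterationRecord",
    "RerankResult",
    "RerankConfig",
    "PipelineResult",
    "subset_size",
    "retain_count",
    "random_subset_scores",
    "rerank",
    "prescreen",
    "full_pipeline",
]


# --------------------------------------------------------------------------- #
# result containers
# --------------------------------------------------------------------------- #
@dataclass(frozen=True)
class SubsetScore:
    """Subset-averaged scores over an active marker set."""

    s_star: np.ndarray            # aligned with `active`
    inclusion_counts: np.ndarray  # subsets containing each marker (>= 1)
    active: np.ndarray            # column indices into the parent matrix
    B: int                        # requested number of uniform draws


@dataclass(frozen=True)
class IterationRecord:
    active: np.ndarray    # I_t as column indices (marker-id order)
    p_t: int
    s_star: np.ndarray    # S*^(t), aligned with `active`
    w_t: float


@dataclass(frozen=True)
class RerankResult:
    """Final S** scores plus per-iteration bookkeeping."""

    s_star_star: np.ndarray          # length p of the parent matrix; 0 off the active set
    iterations: list[IterationRecord]
    T: int                           # index of the last iteration computed
    q: float
    B: int
    stop_floor: int
    seed: object
    active0: np.ndarray              # I_0 (column indices)
    dropped_at: np.ndarray           # length p; t of first exclusion, -1 = survived
                                     # to I_T, -2 = never in the active set


@dataclass(frozen=True)
class RerankConfig:
    """Tuning parameters of the full ranking pipeline.

    Defaults follow the method's standard settings: ``M0 = 5000`` prescreened
    markers, ``B = 100`` subsets per iteration, retention ``q = 87.5`` percent.
    ``stop_floor`` ends the iteration once the next active set would fall
    below it; set it to the expected number of relevant markers when known.
    """

    M0: int | None = 5000
    B: int = 100
    q: float = 87.5
    stop_floor: int = 10
    seed: int = 0
    engine: str = "auto"


@dataclass(frozen=True)
class PipelineResult:
    """A total order over all p markers plus the per-marker report."""

    order: np.ndarray        # column indices, best first
    table: pd.DataFrame      # rank, marker_id, s_star_star, t_score, screened, dropped_at
    rerank: RerankResult
    screened: np.ndarray     # column indices that entered the rerank
    t_scores: np.ndarray


# --------------------------------------------------------------------------- #
# sizing rules
# --------------------------------------------------------------------------- #
def subset_size(p_active: int) -> int:
    """Half the active set, at least 2 (a 1-marker subset is degenerate)."""
    return max(2, math.ceil(p_active / 2))


def retain_count(p_t: int, q: float) -> int:
    """Top q% of p_t markers, capped at p_t - 1 to force strict shrinkage."""
    if not 0.0 < q < 100.0:
        raise InvalidInputError(f"q must lie in (0, 100), got {q}")
    return min(math.ceil(q / 100.0 * p_t), p_t - 1)


def _child_seq(seed, *key: int) -> np.random.SeedSequence:
    """Derive a child SeedSequence without mutating the parent."""
    if isinstance(seed, np.random.SeedSequence):
        return np.random.SeedSequence(
            entropy=seed.entropy, spawn_key=tuple(seed.spawn_key) + tuple(key)
        )
    return np.random.SeedSequence(entropy=seed, spawn_key=tuple(key))


def _canonical_active(data: FeatureMatrix, active) -> np.ndarray:
    """Active column indices listed in marker-id order.

    Subset draws and retention operate on this canonical listing, which makes
    ensemble scores invariant to the column order of the input matrix.
    """
    if active is None:
        idx = np.arange(data.p)
    else:
        idx = np.asarray(active, dtype=np.intp)
        if idx.ndim != 1 or len(np.unique(idx)) != idx.size:
            raise InvalidInputError("active must be a 1-D set of distinct column indices")
    if idx.size < 2:
        raise InvalidInputError(f"need at least 2 active markers, got {idx.size}")
    return idx[np.argsort(data.marker_ids[idx].astype(str), kind="stable")]


def _sign_vector(data: FeatureMatrix) -> np.ndarray:
    sign = np.where(data.case_mask, 1.0 / data.n1, -1.0 / data.n0)
    return np.ascontiguousarray(sign)


def _draw_memberships(pa: int, k: int, B: int, rng: np.random.Generator) -> np.ndarray:
    """B uniform size-k subsets of {0..pa-1}, plus forced draws until every
    marker is covered at least once (Monte-Carlo average must be total)."""
    # the k smallest of iid uniforms index a uniform size-k subset
    u = rng.random((B, pa))
    kth = np.partition(u, k - 1, axis=1)[:, k - 1 : k]
    memb = u <= kth
    uncovered = np.flatnonzero(memb.sum(axis=0) == 0)
    extra = []
    for c in uncovered:  # astronomically rare for B >= a few dozen
        row = np.zeros(pa, dtype=bool)
        row[c] = True
        others = np.delete(np.arange(pa), c)
        row[rng.permutation(others)[: k - 1]] = True
        extra.append(row)
    if extra:
        memb = np.vstack([memb, np.array(extra)])
    return memb


def _subset_scores(
    x_sub: np.ndarray,
    case_mask: np.ndarray,
    B: int,
    rng: np.random.Generator,
    engine: str,
    order: np.ndarray | None = None,
    has_ties: bool | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """S* and inclusion counts on a centered, column-restricted matrix."""
    pa = x_sub.shape[1]
    memb = _draw_memberships(pa, subset_size(pa), B, rng)
    s_b = _kernel.subset_stat(
        x_sub, memb, case_mask, engine=engine, order=order, has_ties=has_ties
    )
    counts = memb.sum(axis=0)
    s_star = s_b.sum(axis=0) / counts
    return s_star, counts


# --------------------------------------------------------------------------- #
# public operations
# --------------------------------------------------------------------------- #
def random_subset_scores(
    data: FeatureMatrix,
    active: np.ndarray | None = None,
    B: int = 100,
    seed: int | np.random.SeedSequence = 0,
    engine: str = "auto",
) -> SubsetScore:
    """Average the rank-over-variable score over B random half-size subsets."""
    if B < 1:
        raise InvalidInputError(f"B must be >= 1, got {B}")
    act = _canonical_active(data, active)
    mu = data.values.mean(axis=0)
    x_sub = np.ascontiguousarray(data.values[:, act] - mu[act])
    rng = np.random.default_rng(_child_seq(seed, 0))
    s_star, counts = _subset_scores(x_sub, data.case_mask, B, rng, engine)
    return SubsetScore(s_star=s_star, inclusion_counts=counts, active=act, B=B)


def rerank(
    data: FeatureMatrix,
    active: np.ndarray | None = None,
    q: float = 87.5,
    B: int = 100,
    stop_floor: int = 10,
    seed: int | np.random.SeedSequence = 0,
    engine: str = "auto",
) -> RerankResult:
    """Iterative top-q% rerank aggregation of subset-averaged scores."""
    if stop_floor < 2:
        raise InvalidInputError(f"stop_floor must be >= 2, got {stop_floor}")
    if not 0.0 < q < 100.0:
        raise InvalidInputError(f"q must lie in (0, 100), got {q}")
    act0 = _canonical_active(data, active)
    case_mask = data.case_mask
    mu = data.values.mean(axis=0)
    centered = data.values - mu

    s_star_star = np.zeros(data.p)
    dropped_at = np.full(data.p, -2, dtype=np.int64)
    dropped_at[act0] = -1
    iterations: list[IterationRecord] = []

    # On tie-free data the per-row sort order is computed once and filtered as
    # the active set shrinks; tied or reference runs re-derive it per iteration.
    eff_engine = engine
    if engine == "auto":
        eff_engine = "fast" if _kernel.HAVE_NUMBA else "reference"
    current = act0
    cur_x = np.ascontiguousarray(centered[:, current])
    cur_order: np.ndarray | None = None
    has_ties: bool | None = None
    if eff_engine == "fast":
        cur_order = _kernel.descending_order(cur_x)
        has_ties = _kernel.rows_have_ties(cur_x, cur_order)
        if has_ties:
            cur_order = None
            has_ties = None

    t = 0
    while True:
        p_t = current.size
        rng = np.random.default_rng(_child_seq(seed, t))
        s_star, _ = _subset_scores(
            cur_x, case_mask, B, rng, eff_engine, order=cur_order, has_ties=has_ties
        )
        w_t = float(s_star.mean() / p_t)
        s_star_star[current] += w_t * s_star / p_t
        iterations.append(IterationRecord(active=current, p_t=p_t, s_star=s_star, w_t=w_t))

        r = retain_count(p_t, q)
        if r < stop_floor:
            break
        keep = np.sort(np.argsort(-s_star, kind="stable")[:r])
        dropped_at[current[np.setdiff1d(np.arange(p_t), keep, assume_unique=True)]] = t + 1
        current = current[keep]
        cur_x = np.ascontiguousarray(cur_x[:, keep])
        if cur_order is not None:
            new_id = np.full(p_t, -1, dtype=np.int32)
            new_id[keep] = np.arange(r, dtype=np.int32)
            cur_order = _kernel.filter_order(cur_order, new_id, r)
        t += 1

    return RerankResult(
        s_star_star=s_star_star,
        iterations=iterations,
        T=t,
        q=q,
        B=B,
        stop_floor=stop_floor,
        seed=seed,
        active0=act0,
        dropped_at=dropped_at,
    )


def prescreen(data: FeatureMatrix, M0: int) -> np.ndarray:
    """Indices (ascending) of the min(M0, p) largest |t| markers.

    Ties are broken toward the smaller column index.  Cuts the marker set
    before the expensive ensemble machinery; the downstream ranking is not
    affected much as long as M0 is conservative.
    """
    from .baselines import t_scores

    if M0 < 2:
        raise InvalidInputError(f"M0 must be >= 2, got {M0}")
    t = t_scores(data).score
    order = np.argsort(-t, kind="stable")
    return np.sort(order[: min(M0, data.p)])


def full_pipeline(data: FeatureMatrix, config: RerankConfig | None = None) -> PipelineResult:
    """Prescreen, rerank and assemble the final total order over all markers.

    Screened markers come first, ordered by S** descending (ties by |t|, then
    column index); markers cut by the prescreen follow, ordered by |t|.
    """
    from .baselines import t_scores

    cfg = config or RerankConfig()
    tsc = t_scores(data).score if data.n1 >= 2 and data.n0 >= 2 else np.zeros(data.p)
    if cfg.M0 is not None and cfg.M0 < data.p:
        screened = prescreen(data, cfg.M0)
    else:
        screened = np.arange(data.p)
    rr = rerank(
        data,
        active=screened,
        q=cfg.q,
        B=cfg.B,
        stop_floor=cfg.stop_floor,
        seed=cfg.seed,
        engine=cfg.engine,
    )
    idx = np.arange(data.p)
    in_screen = np.zeros(data.p, dtype=bool)
    in_screen[screened] = True

    scr = idx[in_screen]
    scr = scr[np.lexsort((scr, -tsc[scr], -rr.s_star_star[scr]))]
    rest = idx[~in_screen]
    rest = rest[np.lexsort((rest, -tsc[rest]))]
    order = np.concatenate([scr, rest])

    table = pd.DataFrame(
        {
            "rank": np.arange(1, data.p + 1),
            "marker_id": data.marker_ids[order].astype(str),
            "s_star_star": rr.s_star_star[order],
            "t_score": tsc[order],
            "screened": in_screen[order],
            "dropped_at": rr.dropped_at[order],
        }
    )
    return PipelineResult(order=order, table=table, rerank=rr, screened=screened, t_scores=tsc)
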