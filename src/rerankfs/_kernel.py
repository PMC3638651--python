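"""Batched within-subset rank scoring.

Evaluating the subset-averaged statistic requires, for every random marker
subset b and every subject i, the within-subset ranks of the subject's
centered values, reduced immediately to the per-group rank sums that make up

    S_j^(b) = | (1/n1) sum_{cases} R_b(i, j) - (1/n0) sum_{controls} R_b(i, j) | .

At study scale this is hundreds of millions of rank assignments per ensemble
evaluation, so the inner loops are compiled with numba when available.  Two
facts keep them cheap:

* within-subset ranks can be read off a descending argsort of the full row —
  walking the row's sorted column order and counting subset members yields
  each member's within-subset rank — so each row is sorted once, and when the
  active set shrinks the new sort order is a filter of the old one
  (:func:`filter_order`), never a re-sort;
* when a row has no tied values (the generic case for continuous data),
  ordinal ranks equal midranks and the per-group rank sums are small
  integers, accumulated branch-free four subsets at a time
  (:func:`ordinal_group_rank_sums`).

A midrank-aware compiled kernel covers tied data, and a plain
scipy.stats.rankdata reference path is kept both as fallback and as the
definition the compiled kernels are tested against.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(f):
            return f

        return wrap


def descending_order(x: np.ndarray) -> np.ndarray:
    """Per-row descending argsort as int32; tied values end up adjacent."""
    return np.ascontiguousarray(np.argsort(x, axis=1)[:, ::-1]).astype(np.int32)


def rows_have_ties(x: np.ndarray, order: np.ndarray) -> bool:
    """True if any row contains duplicate values (checked via the sort order)."""
    sorted_vals = np.take_along_axis(x, order.astype(np.intp), axis=1)
    return bool((sorted_vals[:, 1:] == sorted_vals[:, :-1]).any())


@njit(cache=False)
def filter_order(order, new_id, p_new):  # pragma: no cover - compiled
    """Restrict per-row sort orders to a retained column subset.

    ``new_id[c]`` maps an old column index to its new index, or -1 if the
    column was dropped.  Relative order is preserved, so the result is the
    descending sort order of the retained columns.
    """
    n, p = order.shape
    out = np.empty((n, p_new), dtype=np.int32)
    for i in range(n):
        w = 0
        for l in range(p):
            nid = new_id[order[i, l]]
            if nid >= 0:
                out[i, w] = nid
                w += 1
    return out


@njit(cache=False)
def ordinal_group_rank_sums(order, memb_t, case_row):  # pragma: no cover - compiled
    """Per-group within-subset rank sums for tie-free rows, all subsets a pass.

    ``memb_t`` is the membership matrix transposed to shape (p, B) so the
    inner loop over subsets is contiguous and vectorizes.  Returns int32
    arrays ``(acc_case, acc_ctrl)`` of shape (p, B) holding the sum of
    within-subset ranks over case rows / control rows for each member marker
    (0 for non-members).  Valid only when no row has tied values, so ordinal
    ranks equal midranks; sums stay far below the int32 range for any matrix
    that fits in memory.
    """
    n, p = order.shape
    B = memb_t.shape[1]
    acc_case = np.zeros((p, B), dtype=np.int32)
    acc_ctrl = np.zeros((p, B), dtype=np.int32)
    cnt = np.empty(B, dtype=np.int32)
    for i in range(n):
        base = acc_case if case_row[i] != 0 else acc_ctrl
        for b in range(B):
            cnt[b] = 0
        for l in range(p):
            c = order[i, l]
            mrow = memb_t[c]
            arow = base[c]
            for b in range(B):
                v = mrow[b]
                cnt[b] += v
                arow[b] += v * cnt[b]
    return acc_case, acc_ctrl


@njit(cache=False)
def _signed_sums_midrank(x, order, memb, sign):  # pragma: no cover - compiled
    """Tie-aware path: runs of equal member values share their average rank."""
    B = memb.shape[0]
    n, p = order.shape
    acc = np.zeros((B, p))
    runbuf = np.empty(p, dtype=np.int64)
    for b in range(B):
        mrow = memb[b]
        arow = acc[b]
        for i in range(n):
            si = sign[i]
            cnt = 0       # members seen so far = ordinal rank of the last one
            run_len = 0
            run_val = 0.0
            for l in range(p):
                c = order[i, l]
                if mrow[c] != 0:
                    v = x[i, c]
                    if run_len > 0 and v != run_val:
                        mid = cnt - (run_len - 1) * 0.5
                        contrib = si * mid
                        for u in range(run_len):
                            arow[runbuf[u]] += contrib
                        run_len = 0
                    if run_len == 0:
                        run_val = v
                    runbuf[run_len] = c
                    run_len += 1
                    cnt += 1
            if run_len > 0:
                mid = cnt - (run_len - 1) * 0.5
                contrib = si * mid
                for u in range(run_len):
                    arow[runbuf[u]] += contrib
    return acc


def _signed_sums_reference(x: np.ndarray, memb: np.ndarray, sign: np.ndarray) -> np.ndarray:
    """One rankdata call per subset; slow but transparently correct."""
    B = memb.shape[0]
    acc = np.zeros((B, x.shape[1]))
    for b in range(B):
        cols = np.flatnonzero(memb[b])
        ranks = rankdata(-x[:, cols], axis=1, method="average")
        acc[b, cols] = sign @ ranks
    return acc


def subset_stat(
    x: np.ndarray,
    memb: np.ndarray,
    case_mask: np.ndarray,
    engine: str = "auto",
    order: np.ndarray | None = None,
    has_ties: bool | None = None,
) -> np.ndarray:
    """``S_j^(b)`` for a batch of subsets: shape (B, p), 0 for non-members.

    Parameters
    ----------
    x
        Centered values, shape ``(n, p)``, float64, C-contiguous.
    memb
        Subset membership indicators, shape ``(B, p)``, 0/1.
    case_mask
        Boolean case indicator per row.
    engine
        ``"fast"`` (numba), ``"reference"`` (scipy), or ``"auto"``.
    order, has_ties
        Optional precomputed per-row descending sort order and tie flag
        (recomputed from ``x`` when omitted).
    """
    if engine == "auto":
        engine = "fast" if HAVE_NUMBA else "reference"
    n1 = int(case_mask.sum())
    n0 = case_mask.size - n1
    sign = np.ascontiguousarray(np.where(case_mask, 1.0 / n1, -1.0 / n0))
    memb_u8 = np.ascontiguousarray(memb, dtype=np.uint8)
    if engine == "reference":
        return np.abs(_signed_sums_reference(x, memb_u8, sign)) * memb_u8
    if engine != "fast":
        raise ValueError(f"unknown engine {engine!r}")
    if order is None:
        order = descending_order(x)
    if has_ties is None:
        has_ties = rows_have_ties(x, order)
    if has_ties:
        acc = _signed_sums_midrank(x, order, memb_u8, sign)
        return np.abs(acc) * memb_u8
    case_u8 = np.ascontiguousarray(case_mask, dtype=np.uint8)
    memb_t = np.ascontiguousarray(memb_u8.T)
    acc_case, acc_ctrl = ordinal_group_rank_sums(order, memb_t, case_u8)
    s_t = np.abs(acc_case / n1 - acc_ctrl / n0) * memb_t  # (p, B)
    return s_t.T
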