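"""Partial-permutation selection of the number of relevant markers.

Given a ranking list, how many of its leading markers are actually relevant?
With tiny sample sizes, per-marker permutation p-values and FDR control are
unreliable, so the number is estimated directly from the list.  For each
cutoff m, the class labels are permuted *only on the markers ranked below m*
(a single shared row permutation per replicate, so subject-level structure
among the permuted markers is preserved), the full ensemble score S** is
recomputed on the partially permuted data, and

    nu_m = (1/B) sum_b  1( mean_j S**_j^(b)  >=  mean_j S**_j^(0) ).

If the top m markers contain every relevant marker, permuting the rest is
close to a no-op and nu_m sits near 0.5 (rising to 1 as m -> p); if a
relevant marker is permuted, the mean score collapses and nu_m drops well
below 0.5.  The selected count is the first crossing,

    M1 = min { m : nu_m >= 0.5 }.

Each replicate recomputes S** with a fresh subset-draw stream of its own, so
the comparison integrates over the ensemble's Monte-Carlo variability as
well as the permutation.  The cutoff m = p permutes nothing at all; the
replicate dataset is then identical to the observed one and is counted as
reaching the baseline without recomputation, so nu_p = 1 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import FeatureMatrix, InvalidInputError
from .ensemble import RerankConfig, _child_seq, prescreen, rerank

__all__ = ["NuCurve", "partial_permute", "nu_curve", "select_M1"]


@dataclass(frozen=True)
class NuCurve:
    """The nu_m curve and everything needed to interpret it."""

    m: np.ndarray          # cutoffs at which nu was computed (1-based, increasing)
    nu: np.ndarray         # nu_m values, in [0, 1]
    baseline: float        # mean S** over the active set, unpermuted data
    order: np.ndarray      # active column indices ranked by S** descending
    B_perm: int
    active: np.ndarray     # active set the scores were computed on
    M1: int | None         # min{m : nu_m >= 0.5} among computed m, else None


def partial_permute(
    data: FeatureMatrix,
    permute_set: np.ndarray,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    per_column: bool = False,
) -> FeatureMatrix:
    """Shuffle group assignment of the given marker columns.

    By default one uniform permutation of the row indices is drawn and
    applied to every column in ``permute_set`` — group assignment is a
    subject-level attribute, and the shared permutation preserves the
    correlation structure among the permuted markers.  ``per_column=True``
    instead draws an independent row permutation for each column (which
    destroys inter-marker correlation).  Other columns and the labels are
    untouched; per column, the multiset of values is conserved.
    """
    cols = np.asarray(permute_set, dtype=np.intp)
    if cols.size == 0:
        return data
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = data.values.copy()
    if per_column:
        for c in cols:
            values[:, c] = data.values[rng.permutation(data.n), c]
    else:
        pi = rng.permutation(data.n)
        values[:, cols] = data.values[pi][:, cols]
    return data.with_values(values)


def nu_curve(
    data: FeatureMatrix,
    config: RerankConfig | None = None,
    B_perm: int = 50,
    m_max: int | str = "auto",
    seed: int | None = None,
    confirm_window: int = 5,
    early_stop: bool | None = None,
) -> NuCurve:
    """Compute nu_m for m = 1, 2, ... and locate the 0.5 crossing.

    Parameters
    ----------
    data, config
        The dataset and the rerank configuration (prescreen M0, B, q,
        stop_floor, seed) used both for the baseline run and for every
        permutation replicate.
    B_perm
        Permutation replicates per cutoff m; the Monte-Carlo standard error
        of nu_m is at most ``0.5 / sqrt(B_perm)``.
    m_max
        Largest cutoff to compute, or ``"auto"`` (no cap).
    seed
        Seed for the permutation streams; defaults to ``config.seed``.
    early_stop
        Stop ``confirm_window`` steps after the first crossing of 0.5.
        Defaults to on for ``m_max="auto"`` and off for a numeric cap (set
        explicitly to combine a cap with early stopping).
    """
    cfg = config or RerankConfig()
    if B_perm < 1:
        raise InvalidInputError(f"B_perm must be >= 1, got {B_perm}")
    perm_seed = cfg.seed if seed is None else seed

    if cfg.M0 is not None and cfg.M0 < data.p:
        active = prescreen(data, cfg.M0)
    else:
        active = np.arange(data.p)
    rerank_kwargs = dict(q=cfg.q, B=cfg.B, stop_floor=cfg.stop_floor, engine=cfg.engine)
    base_seed = _child_seq(cfg.seed, 0)

    base = rerank(data, active=active, seed=base_seed, **rerank_kwargs)
    baseline = float(base.s_star_star[active].mean())
    order = active[np.argsort(-base.s_star_star[active], kind="stable")]

    pa = active.size
    limit = pa if m_max == "auto" else min(int(m_max), pa)
    if early_stop is None:
        early_stop = m_max == "auto"
    ms: list[int] = []
    nus: list[float] = []
    crossing: int | None = None
    for m in range(1, limit + 1):
        permute_cols = order[m:]
        hits = 0
        if permute_cols.size == 0:
            # permuting nothing reproduces the dataset, and the same dataset
            # has the same score: count every replicate without recomputing
            hits = B_perm
        else:
            for b in range(1, B_perm + 1):
                rep = _child_seq(perm_seed, m, b)
                perm_rng = np.random.default_rng(_child_seq(rep, 1))
                permuted = partial_permute(data, permute_cols, perm_rng)
                rr = rerank(
                    permuted, active=active, seed=_child_seq(rep, 2), **rerank_kwargs
                )
                if float(rr.s_star_star[active].mean()) >= baseline:
                    hits += 1
        ms.append(m)
        nus.append(hits / B_perm)
        if crossing is None and nus[-1] >= 0.5:
            crossing = m
        if early_stop and crossing is not None and m >= crossing + confirm_window:
            break

    return NuCurve(
        m=np.asarray(ms),
        nu=np.asarray(nus),
        baseline=baseline,
        order=order,
        B_perm=B_perm,
        active=active,
        M1=crossing,
    )


def select_M1(curve: NuCurve) -> int | None:
    """First computed cutoff with nu_m >= 0.5, or None if none qualifies."""
    if curve.m.size == 0:
        raise InvalidInputError("empty nu curve")
    qualifying = curve.m[curve.nu >= 0.5]
    return int(qualifying[0]) if qualifying.size else None
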