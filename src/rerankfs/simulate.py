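"""Synthetic two-group data with known truth.

Two generators mirror the simulation settings the method is evaluated on:

* :func:`gaussian_two_group` — the expression-like design: all markers are
  standard normal in both groups except ``m_star`` markers whose case-group
  mean is shifted by ``delta`` (``N(delta, 1)``).
* :func:`genotype_pools` + :func:`add_pooling_noise` — the DNA-pooling GWA
  design: per marker a base minor-allele frequency is drawn, individual
  genotypes are Binomial(2, f), pools of ``s`` individuals report their mean
  allele frequency, relevant markers carry a case effect on the odds scale
  (f1 = OR*f / (1 - f + OR*f)), and pooling measurement error perturbs each
  observed frequency on the logit scale:

      X = expit( logit(Xtrue) + eps ),   eps ~ N(0, sigma^2),

  with a small fraction of outlier cells using an inflated sigma.

Markers are independent; linkage disequilibrium is deliberately not modeled
(see docs/methods.md for what this does and does not test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .data import FeatureMatrix, InvalidInputError, feature_matrix

__all__ = [
    "SimDesign",
    "TruthSet",
    "gaussian_two_group",
    "genotype_pools",
    "add_pooling_noise",
    "pooling_two_group",
]

#: Noise settings for the three pooling-error scenarios:
#: A = error-free, B = pooling error, C = pooling error plus 1% outliers.
SCENARIOS = {
    "A": dict(sigma=0.0, outlier_rate=0.0, sigma_outlier=0.0),
    "B": dict(sigma=0.05, outlier_rate=0.0, sigma_outlier=0.0),
    "C": dict(sigma=0.05, outlier_rate=0.01, sigma_outlier=5.0),
}


@dataclass(frozen=True)
class SimDesign:
    """Parameters of a synthetic dataset.

    ``delta`` drives the Gaussian design; ``or_effect`` (allelic odds ratio),
    ``s`` (individuals per pool), ``sigma``/``outlier_rate``/``sigma_outlier``
    (logit-normal measurement error) drive the pooling design.
    """

    p: int = 2000
    m_star: int = 10
    n1: int = 100
    n0: int = 100
    delta: float = 2.0
    or_effect: float = 1.8
    s: int = 200
    sigma: float = 0.05
    outlier_rate: float = 0.0
    sigma_outlier: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.m_star <= self.p:
            raise InvalidInputError("need 0 <= m_star <= p")
        if self.s < 1:
            raise InvalidInputError("pool size s must be >= 1")
        if self.sigma < 0 or self.sigma_outlier < 0:
            raise InvalidInputError("noise scales must be >= 0")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise InvalidInputError("outlier_rate must lie in [0, 1]")


@dataclass(frozen=True)
class TruthSet:
    """Which markers carry signal."""

    relevant: np.ndarray     # column indices, sorted ascending
    marker_ids: np.ndarray   # ids of the relevant markers

    @property
    def m_star(self) -> int:
        return self.relevant.size


def _labels(design: SimDesign) -> np.ndarray:
    return np.concatenate([np.ones(design.n1, dtype=np.int8), np.zeros(design.n0, dtype=np.int8)])


def _pick_relevant(design: SimDesign, rng: np.random.Generator) -> np.ndarray:
    return np.sort(rng.choice(design.p, size=design.m_star, replace=False))


def gaussian_two_group(design: SimDesign) -> tuple[FeatureMatrix, TruthSet]:
    """N(0,1) everywhere except relevant markers, N(delta, 1) in cases."""
    rng = np.random.default_rng(np.random.SeedSequence(design.seed))
    relevant = _pick_relevant(design, rng)
    values = rng.standard_normal((design.n1 + design.n0, design.p))
    values[: design.n1, relevant] += design.delta
    fm = feature_matrix(values, _labels(design))
    return fm, TruthSet(relevant=relevant, marker_ids=fm.marker_ids[relevant])


def genotype_pools(
    design: SimDesign,
    base_maf_range: tuple[float, float] = (0.05, 0.5),
    or_range: tuple[float, float] | None = None,
) -> tuple[FeatureMatrix, TruthSet]:
    """Pool-level *true* allele-frequency matrix (no measurement error yet).

    Per marker a base MAF f ~ Uniform(base_maf_range); control individuals'
    minor-allele counts are Binomial(2, f).  At relevant markers cases use
    f1 = OR*f / (1 - f + OR*f); elsewhere f1 = f.  Each pool of s individuals
    reports its mean allele count / 2.

    ``or_range`` draws a per-marker odds ratio uniformly from the given
    interval instead of the shared ``design.or_effect`` — real top
    association hits carry a spread of effect sizes, not one.
    """
    lo, hi = base_maf_range
    if not (0.0 < lo <= hi < 1.0):
        raise InvalidInputError(f"invalid MAF range {base_maf_range}")
    rng = np.random.default_rng(np.random.SeedSequence(design.seed))
    relevant = _pick_relevant(design, rng)
    f = rng.uniform(lo, hi, size=design.p)
    if or_range is None:
        ors = np.full(design.m_star, design.or_effect)
    else:
        ors = rng.uniform(or_range[0], or_range[1], size=design.m_star)
    f_case = f.copy()
    f_case[relevant] = ors * f[relevant] / (1.0 - f[relevant] + ors * f[relevant])
    n1, n0, s = design.n1, design.n0, design.s
    # pool allele frequency = Binomial(2s, f) / (2s): sum of s iid Binomial(2, f)
    case_counts = rng.binomial(2 * s, f_case, size=(n1, design.p))
    ctrl_counts = rng.binomial(2 * s, f, size=(n0, design.p))
    freqs = np.vstack([case_counts, ctrl_counts]) / (2.0 * s)
    fm = feature_matrix(freqs, _labels(design))
    return fm, TruthSet(relevant=relevant, marker_ids=fm.marker_ids[relevant])


def add_pooling_noise(
    freqs: np.ndarray,
    s: int,
    sigma: float,
    outlier_rate: float = 0.0,
    sigma_outlier: float = 5.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Logit-normal pooling measurement error, cellwise.

    True frequencies are clamped to [1/(4s), 1 - 1/(4s)] before the logit
    (the transform is undefined at 0 and 1; the clamp sits below the smallest
    nonzero pool-frequency step 1/(2s)).  With probability ``outlier_rate`` a
    cell's noise scale is ``sigma_outlier`` instead of ``sigma``.
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    if freqs.min() < 0.0 or freqs.max() > 1.0:
        raise InvalidInputError("frequencies must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        np.random.SeedSequence(seed)
    )
    clamp = 1.0 / (4.0 * s)
    clamped = np.clip(freqs, clamp, 1.0 - clamp)
    scale = np.full(freqs.shape, float(sigma))
    if outlier_rate > 0.0:
        scale[rng.random(freqs.shape) < outlier_rate] = sigma_outlier
    eps = rng.standard_normal(freqs.shape) * scale
    # zero noise is the identity exactly (expit/logit round-trip is not)
    return np.where(eps == 0.0, clamped, expit(logit(clamped) + eps))


def pooling_two_group(
    design: SimDesign,
    base_maf_range: tuple[float, float] = (0.05, 0.5),
    or_range: tuple[float, float] | None = None,
) -> tuple[FeatureMatrix, TruthSet]:
    """Pooling design end to end: genotypes -> pools -> logit-normal error."""
    true_fm, truth = genotype_pools(design, base_maf_range, or_range=or_range)
    noise_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=design.seed, spawn_key=(1,))
    )
    values = add_pooling_noise(
        true_fm.values,
        s=design.s,
        sigma=design.sigma,
        outlier_rate=design.outlier_rate,
        sigma_outlier=design.sigma_outlier,
        seed=noise_rng,
    )
    return true_fm.with_values(values), truth
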