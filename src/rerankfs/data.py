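"""Two-group feature-matrix container.

A :class:`FeatureMatrix` holds a subjects-by-markers (or pools-by-markers)
matrix of continuous measurements together with a binary case/control label
per row.  Rows are subjects, columns are markers — the orientation used
throughout the package.  Values must be finite; missing data is rejected
rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FeatureMatrix", "feature_matrix"]


class InvalidInputError(ValueError):
    """Raised when input data violates the container invariants."""


@dataclass(frozen=True)
class FeatureMatrix:
    """An n x p matrix of continuous marker measurements with binary labels.

    Parameters
    ----------
    values
        Float matrix of shape ``(n, p)``; every entry must be finite.
    labels
        Integer vector of length ``n`` with 1 = case, 0 = control.  Both
        groups must be non-empty.
    marker_ids
        Length-``p`` array of unique marker identifiers.
    """

    values: np.ndarray
    labels: np.ndarray
    marker_ids: np.ndarray

    def __post_init__(self) -> None:
        values = np.ascontiguousarray(np.asarray(self.values, dtype=np.float64))
        labels = np.asarray(self.labels)
        ids = np.asarray(self.marker_ids)
        if values.ndim != 2:
            raise InvalidInputError(f"values must be 2-D, got ndim={values.ndim}")
        n, p = values.shape
        if p < 2:
            raise InvalidInputError(f"need at least 2 markers, got p={p}")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise InvalidInputError(
                f"non-finite value at row {bad[0]}, column {bad[1]} "
                f"(marker {ids[bad[1]] if ids.size == p else bad[1]})"
            )
        if labels.shape != (n,):
            raise InvalidInputError(
                f"labels must have shape ({n},), got {labels.shape}"
            )
        lab = labels.astype(np.int8, casting="unsafe")
        if not np.isin(lab, (0, 1)).all():
            raise InvalidInputError("labels must be 0 (control) or 1 (case)")
        if lab.sum() < 1 or (1 - lab).sum() < 1:
            raise InvalidInputError("both case and control groups must be non-empty")
        if ids.shape != (p,):
            raise InvalidInputError(f"marker_ids must have length {p}, got {ids.shape}")
        if len(np.unique(ids)) != p:
            raise InvalidInputError("marker_ids must be unique")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "marker_ids", ids)

    # -- basic shape accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def n1(self) -> int:
        """Number of case rows."""
        return int(self.labels.sum())

    @property
    def n0(self) -> int:
        """Number of control rows."""
        return self.n - self.n1

    @property
    def case_mask(self) -> np.ndarray:
        return self.labels == 1

    @property
    def control_mask(self) -> np.ndarray:
        return self.labels == 0

    # -- derived views ---------------------------------------------------------
    def select_markers(self, indices: np.ndarray) -> "FeatureMatrix":
        """Return a new matrix restricted to the given marker columns."""
        idx = np.asarray(indices, dtype=np.intp)
        return FeatureMatrix(self.values[:, idx], self.labels, self.marker_ids[idx])

    def with_values(self, values: np.ndarray) -> "FeatureMatrix":
        """Return a copy with ``values`` replaced (same labels and ids)."""
        return FeatureMatrix(values, self.labels, self.marker_ids)


def feature_matrix(
    values: np.ndarray,
    labels: np.ndarray,
    marker_ids: np.ndarray | None = None,
) -> FeatureMatrix:
    """Build a :class:`FeatureMatrix`, generating ``M000001``-style ids if absent."""
    values = np.asarray(values, dtype=np.float64)
    if marker_ids is None:
        p = values.shape[1] if values.ndim == 2 else 0
        width = max(6, len(str(p)))
        marker_ids = np.array([f"M{j + 1:0{width}d}" for j in range(p)])
    return FeatureMatrix(values, np.asarray(labels), np.asarray(marker_ids))
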