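"""TSV/CSV readers and writers plus the run manifest.

Matrices are plain delimited text: a header row of marker IDs, one row per
subject/pool.  Labels come either from a named column of the matrix file
(values ``case``/``control`` or ``1``/``0``) or from a separate two-column
file (``sample_id<TAB>label`` or a single label column).  Delimiter is taken
from the extension (``.csv`` -> comma, anything else -> tab).
"""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .data import FeatureMatrix, InvalidInputError
from .selection import NuCurve
from .simulate import TruthSet

__all__ = [
    "read_matrix",
    "write_matrix",
    "write_ranking",
    "write_nu_curve",
    "write_truth",
    "read_truth",
    "write_manifest",
]

_LABEL_MAP = {"case": 1, "control": 0, "1": 1, "0": 0}


def _sep(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _parse_labels(raw: pd.Series, source: str) -> np.ndarray:
    labels = np.empty(len(raw), dtype=np.int8)
    for i, v in enumerate(raw):
        key = str(v).strip().lower()
        if key not in _LABEL_MAP:
            raise InvalidInputError(
                f"unknown label value {v!r} at row {i + 1} of {source} "
                "(expected case/control or 1/0)"
            )
        labels[i] = _LABEL_MAP[key]
    return labels


def read_matrix(
    path: str | Path,
    label_col: str | None = "label",
    labels_path: str | Path | None = None,
) -> FeatureMatrix:
    """Read a feature matrix with labels, validating cell by cell.

    Duplicate marker IDs, missing cells and non-numeric cells are rejected
    with a diagnostic naming the offending row and column.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_sep(path))
    dupes = sorted({h for h in header if header.count(h) > 1})
    if dupes:
        raise InvalidInputError(f"duplicate marker IDs in {path}: {dupes}")
    df = pd.read_csv(path, sep=_sep(path), float_precision="round_trip")
    if labels_path is not None:
        ldf = pd.read_csv(labels_path, sep=_sep(labels_path))
        labels = _parse_labels(ldf.iloc[:, -1], str(labels_path))
        if len(labels) != len(df):
            raise InvalidInputError(
                f"{labels_path} has {len(labels)} labels for {len(df)} rows"
            )
    elif label_col is not None and label_col in df.columns:
        labels = _parse_labels(df[label_col], str(path))
        df = df.drop(columns=[label_col])
    else:
        raise InvalidInputError(
            f"no label column {label_col!r} in {path} and no labels_path given"
        )
    marker_ids = df.columns.to_numpy(dtype=object)
    values = np.empty(df.shape, dtype=np.float64)
    for j, col in enumerate(df.columns):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.index[numeric.isna()]
        if len(bad):
            row = int(bad[0]) + 1
            raise InvalidInputError(
                f"missing or non-numeric cell at data row {row}, column {col!r} in {path}"
            )
        values[:, j] = numeric.to_numpy()
    return FeatureMatrix(values, labels, marker_ids)


def write_matrix(data: FeatureMatrix, path: str | Path, label_col: str = "label") -> None:
    """Write the matrix with labels as the first column; round-trips exactly."""
    df = pd.DataFrame(data.values, columns=data.marker_ids.astype(str))
    df.insert(0, label_col, data.labels.astype(int))
    df.to_csv(path, sep=_sep(path), index=False, float_format="%.17g")


def write_ranking(table: pd.DataFrame, path: str | Path) -> None:
    """Write the per-marker pipeline report.

    Columns: rank, marker_id, s_star_star, t_score, screened, dropped_at.
    ``dropped_at`` is the rerank iteration at which the marker fell out of
    the active set; -1 = survived to the final iteration, -2 = cut by the
    t-test prescreen (never entered the rerank).
    """
    table.to_csv(path, sep=_sep(path), index=False, float_format="%.17g")


def write_nu_curve(curve: NuCurve, path: str | Path) -> None:
    """Write the nu_m table: m, nu_m, B_perm per row."""
    pd.DataFrame(
        {"m": curve.m, "nu_m": curve.nu, "B_perm": curve.B_perm}
    ).to_csv(path, sep=_sep(path), index=False)


def write_truth(truth: TruthSet, data: FeatureMatrix, path: str | Path) -> None:
    """Write marker_id / is_relevant for every marker."""
    flag = np.zeros(data.p, dtype=int)
    flag[truth.relevant] = 1
    pd.DataFrame(
        {"marker_id": data.marker_ids.astype(str), "is_relevant": flag}
    ).to_csv(path, sep=_sep(path), index=False)


def read_truth(path: str | Path) -> np.ndarray:
    """Return the marker IDs flagged as relevant."""
    df = pd.read_csv(path, sep=_sep(path))
    return df.loc[df["is_relevant"] == 1, "marker_id"].to_numpy(dtype=object)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    config: dict,
    inputs: dict[str, str | Path] | None = None,
    outputs: dict[str, str | Path] | None = None,
) -> None:
    """JSON record sufficient to reproduce a run: config, seeds, checksums."""
    from . import __version__

    manifest = {
        "tool": "rerankfs",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "python": platform.python_version(),
        "config": config,
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in (inputs or {}).items()
        },
        "outputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in (outputs or {}).items()
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
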