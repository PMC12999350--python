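"""Reading, validating and writing spot-by-metabolite intensity matrices.

Mass spectrometry imaging (MSI) exports are delimited tables with one row
per spatial spot: two coordinate columns plus one intensity column per
annotated metabolite.  Missing measurements (non-detections) are stored as
``NaN`` internally; the reader can optionally treat stored zeros as missing,
which is the convention used throughout the benchmark because MSI zeros
overwhelmingly reflect technical non-detection rather than true absence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpatialMatrix",
    "FormatSpec",
    "MatrixFormatError",
    "MatrixValidationError",
    "read_matrix",
    "write_matrix",
    "summarize_missingness",
    "fill_missing",
    "zeros_to_missing",
    "save_report",
]


class MatrixFormatError(ValueError):
    """The file does not have the expected column layout."""


class MatrixValidationError(ValueError):
    """The parsed matrix violates a SpatialMatrix invariant."""


@dataclass(frozen=True)
class FormatSpec:
    """Column mapping for delimited MSI exports.

    All numeric columns other than the coordinate (and optional spot-id)
    columns are treated as metabolite intensities.
    """

    x_col: str = "x"
    y_col: str = "y"
    spot_id_col: str | None = "spot_id"
    zeros_as_missing: bool = True


@dataclass
class SpatialMatrix:
    """Non-negative spot x metabolite intensities with 2-D spot coordinates.

    Parameters
    ----------
    intensities
        ``(n_spots, n_metabolites)`` float array; missing measurements are
        ``NaN``.  All non-missing values must be >= 0.
    coords
        ``(n_spots, 2)`` array of (x, y) positions in arbitrary units.
    spot_ids, metabolite_ids
        Unique string identifiers for rows and columns.
    """

    intensities: np.ndarray
    coords: np.ndarray
    spot_ids: list[str] = field(default_factory=list)
    metabolite_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        n, p = self.intensities.shape
        if not self.spot_ids:
            self.spot_ids = [f"spot_{i}" for i in range(n)]
        if not self.metabolite_ids:
            self.metabolite_ids = [f"m_{j}" for j in range(p)]
        self.spot_ids = [str(s) for s in self.spot_ids]
        self.metabolite_ids = [str(s) for s in self.metabolite_ids]
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        n, p = self.intensities.shape
        if self.coords.shape != (n, 2):
            raise MatrixValidationError(
                f"coords shape {self.coords.shape} does not match {n} spots"
            )
        if len(self.spot_ids) != n:
            raise MatrixValidationError("spot_ids length mismatch")
        if len(self.metabolite_ids) != p:
            raise MatrixValidationError("metabolite_ids length mismatch")
        if len(set(self.spot_ids)) != n:
            raise MatrixValidationError("duplicated spot id")
        if len(set(self.metabolite_ids)) != p:
            raise MatrixValidationError("duplicated metabolite id")
        obs = self.intensities[~np.isnan(self.intensities)]
        if obs.size and obs.min() < 0:
            raise MatrixValidationError("negative intensity value")
        if not np.all(np.isfinite(self.coords)):
            raise MatrixValidationError("non-finite coordinate")

    # -- convenience -------------------------------------------------------
    @property
    def n_spots(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.intensities.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean array, True where a measurement is missing."""
        return np.isnan(self.intensities)

    def copy(self) -> "SpatialMatrix":
        return SpatialMatrix(
            self.intensities.copy(),
            self.coords.copy(),
            list(self.spot_ids),
            list(self.metabolite_ids),
        )

    def subset(
        self,
        rows: np.ndarray | Sequence[int] | None = None,
        cols: np.ndarray | Sequence[int] | None = None,
    ) -> "SpatialMatrix":
        rows = np.arange(self.n_spots) if rows is None else np.asarray(rows)
        cols = np.arange(self.n_metabolites) if cols is None else np.asarray(cols)
        return SpatialMatrix(
            self.intensities[np.ix_(rows, cols)],
            self.coords[rows],
            [self.spot_ids[i] for i in rows],
            [self.metabolite_ids[j] for j in cols],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.intensities, columns=self.metabolite_ids)
        df.insert(0, "y", self.coords[:, 1])
        df.insert(0, "x", self.coords[:, 0])
        df.insert(0, "spot_id", self.spot_ids)
        return df


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","


def read_matrix(path: str | Path, format_spec: FormatSpec | None = None) -> SpatialMatrix:
    """Read a delimited spot x metabolite table into a SpatialMatrix.

    Empty fields and the strings ``NA``/``NaN`` become missing values; if
    ``format_spec.zeros_as_missing`` (the default) stored zeros are also
    converted to missing, matching the treatment of MSI zeros as
    non-detections to be imputed.
    """
    fs = format_spec or FormatSpec()
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=_delimiter_for(path),
        na_values=["NA", "NaN"],
        float_precision="round_trip",
    )
    for col in (fs.x_col, fs.y_col):
        if col not in df.columns:
            raise MatrixFormatError(f"missing coordinate column {col!r}")
    spot_ids: list[str] = []
    if fs.spot_id_col and fs.spot_id_col in df.columns:
        spot_ids = df[fs.spot_id_col].astype(str).tolist()
        df = df.drop(columns=[fs.spot_id_col])
    coords = df[[fs.x_col, fs.y_col]].to_numpy(dtype=float)
    value_cols = [c for c in df.columns if c not in (fs.x_col, fs.y_col)]
    if not value_cols:
        raise MatrixFormatError("no metabolite columns found")
    intensities = df[value_cols].to_numpy(dtype=float)
    if fs.zeros_as_missing:
        intensities = intensities.copy()
        intensities[intensities == 0] = np.nan
    return SpatialMatrix(intensities, coords, spot_ids, [str(c) for c in value_cols])


def write_matrix(m: SpatialMatrix, path: str | Path) -> None:
    """Write a SpatialMatrix as delimited text; missing cells become empty fields."""
    path = Path(path)
    m.to_frame().to_csv(path, sep=_delimiter_for(path), index=False, na_rep="")


def fill_missing(m: SpatialMatrix, value: float = 0.0) -> SpatialMatrix:
    """Replace missing entries with a constant (the 'raw' zero-filled baseline)."""
    out = m.copy()
    out.intensities[np.isnan(out.intensities)] = value
    return out


def zeros_to_missing(m: SpatialMatrix) -> SpatialMatrix:
    """Convert stored zeros to missing values (non-detection semantics)."""
    out = m.copy()
    out.intensities[out.intensities == 0] = np.nan
    return out


def summarize_missingness(
    m: SpatialMatrix,
    bins: Sequence[float] = (0.0, 0.2, 0.5, 0.8, 1.0),
) -> dict:
    """Per-metabolite missing fractions plus a histogram over proportion brackets.

    Returns a dict with ``fractions`` (metabolite id -> fraction in [0, 1]),
    ``bin_edges`` and ``bin_counts`` where bracket i counts metabolites with
    fraction in ``(edges[i], edges[i+1]]`` (the first bracket is closed at 0).
    """
    frac = np.isnan(m.intensities).mean(axis=0)
    edges = np.asarray(bins, dtype=float)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for f in frac:
        for i in range(len(edges) - 1):
            lo, hi = edges[i], edges[i + 1]
            if (f > lo or (i == 0 and f == lo)) and f <= hi:
                counts[i] += 1
                break
    return {
        "fractions": dict(zip(m.metabolite_ids, frac.tolist())),
        "bin_edges": edges.tolist(),
        "bin_counts": counts.tolist(),
    }


def save_report(report: Mapping, path: str | Path) -> None:
    """Serialize a metric/rank report to JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
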