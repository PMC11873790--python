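"""Long-format spectral data model.

High-resolution MS data (DIA / MS^E, optionally with ion mobility) are held
as a *long-format* table: one row per detected (m/z, intensity) point, with
columns

    rt        retention time (minutes, >= 0)
    scanid    acquisition-cycle identifier (positive integer; shared by the
              low- and high-energy scans of one duty cycle)
    mslevel   collision-energy function: 1 = low energy, 2 = high energy
    mz        mass-to-charge ratio (Th, > 0)
    intensity detector counts (positive integer; zero-intensity points are
              not stored -- the long format is sparse by construction)
    bin       drift-bin index (1-based; only for ion-mobility samples)
    dt        drift time (milliseconds; present iff ``bin`` is present)

``bin``/``dt`` are either present for every row (an IMS sample) or omitted
entirely (a non-IMS sample); they are never null-filled.  Within a table,
``dt`` is a deterministic, linear function of ``bin`` -- see
:class:`DriftCalibration`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError, SchemaError

#: canonical column order; bin/dt are dropped for non-IMS samples
COLUMNS_IMS = ("rt", "scanid", "mslevel", "mz", "intensity", "bin", "dt")
COLUMNS_NO_IMS = ("rt", "scanid", "mslevel", "mz", "intensity")

#: schema version string embedded in file metadata
SCHEMA_VERSION = "longformat-1"

_DTYPES = {
    "rt": np.float64,
    "scanid": np.int64,
    "mslevel": np.int8,
    "mz": np.float64,
    "intensity": np.uint64,
    "bin": np.int32,
    "dt": np.float64,
}


@dataclass(frozen=True)
class SpectralRecord:
    """A single long-format row."""

    rt: float
    scanid: int
    mslevel: int
    mz: float
    intensity: int
    bin: Optional[int] = None
    dt: Optional[float] = None


@dataclass
class DriftCalibration:
    """Linear bin-index -> drift-time calibration, dt = slope * bin + intercept.

    Parameters
    ----------
    slope
        Milliseconds per bin; must be positive so that predicted drift time
        is strictly increasing in the bin index.
    intercept
        Milliseconds; zero for a through-origin calibration (the default
        fit mode, consistent with typical travelling-wave bin grids).
    n_points
        Number of (bin, dt) pairs the calibration was fitted on.
    max_residual
        Largest absolute fit residual in milliseconds.
    """

    slope: float
    intercept: float = 0.0
    n_points: int = 0
    max_residual: float = 0.0

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise DomainError(f"calibration slope must be positive, got {self.slope}")

    def predict(self, bin: int | np.ndarray) -> float | np.ndarray:
        """Drift time (ms) for a 1-based bin index."""
        b = np.asarray(bin)
        if np.any(b < 1):
            raise DomainError("bin indices are 1-based; got a value < 1")
        out = self.slope * b + self.intercept
        return float(out) if np.isscalar(bin) else out

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DriftCalibration":
        return cls(**d)


@dataclass(frozen=True)
class Violation:
    """One violated table invariant."""

    invariant: str
    where: str
    message: str


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_table`.

    ``ok`` is true iff ``violations`` is empty.  ``warnings`` collects
    tolerated irregularities (e.g. floating-point intensities) that do not
    invalidate the table.
    """

    violations: list[Violation] = field(default_factory=list)
    warnings: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


class LongFormatSpectralTable:
    """Column-oriented long-format spectral table backed by a DataFrame.

    Construct via :meth:`from_dataframe` (checks the column set and
    normalizes dtypes) or :meth:`from_records`.
    """

    def __init__(self, df: pd.DataFrame, *, _checked: bool = False):
        if not _checked:
            df = _check_and_normalize(df)
        self._df = df

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LongFormatSpectralTable":
        """Build a table from a DataFrame with the expected columns.

        Raises
        ------
        SchemaError
            If columns are missing, extra, or out of order.
        """
        return cls(df)

    @classmethod
    def from_records(cls, records: Iterable[SpectralRecord]) -> "LongFormatSpectralTable":
        rows = list(records)
        if not rows:
            return cls.empty(has_ims=False)
        has_ims = rows[0].bin is not None
        cols = COLUMNS_IMS if has_ims else COLUMNS_NO_IMS
        data = {c: [getattr(r, c) for r in rows] for c in cols}
        return cls(pd.DataFrame(data))

    @classmethod
    def empty(cls, has_ims: bool) -> "LongFormatSpectralTable":
        cols = COLUMNS_IMS if has_ims else COLUMNS_NO_IMS
        df = pd.DataFrame({c: pd.Series([], dtype=_DTYPES[c]) for c in cols})
        return cls(df, _checked=True)

    # -- basic properties --------------------------------------------------

    @property
    def df(self) -> pd.DataFrame:
        """The underlying DataFrame (treat as read-only)."""
        return self._df

    @property
    def has_ims(self) -> bool:
        return "bin" in self._df.columns

    @property
    def n_records(self) -> int:
        return len(self._df)

    @property
    def schema_version(self) -> str:
        return SCHEMA_VERSION

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self._df.columns)

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LongFormatSpectralTable):
            return NotImplemented
        if self.columns != other.columns or len(self) != len(other):
            return False
        a = self._df.reset_index(drop=True)
        b = other._df.reset_index(drop=True)
        return all((a[c].to_numpy() == b[c].to_numpy()).all() for c in a.columns)

    def __repr__(self) -> str:
        dims = "rt,scanid,mslevel,mz,intensity" + (",bin,dt" if self.has_ims else "")
        return (
            f"<LongFormatSpectralTable {self.n_records} records "
            f"[{dims}] schema={self.schema_version}>"
        )

    def records(self) -> list[SpectralRecord]:
        """Materialize rows as :class:`SpectralRecord` objects (small tables)."""
        out = []
        for row in self._df.itertuples(index=False):
            d = row._asdict()
            out.append(
                SpectralRecord(
                    rt=float(d["rt"]),
                    scanid=int(d["scanid"]),
                    mslevel=int(d["mslevel"]),
                    mz=float(d["mz"]),
                    intensity=int(d["intensity"]),
                    bin=int(d["bin"]) if "bin" in d else None,
                    dt=float(d["dt"]) if "dt" in d else None,
                )
            )
        return out


def _check_and_normalize(df: pd.DataFrame) -> pd.DataFrame:
    cols = tuple(df.columns)
    if cols not in (COLUMNS_IMS, COLUMNS_NO_IMS):
        expected = f"{COLUMNS_IMS} or {COLUMNS_NO_IMS}"
        missing = [c for c in COLUMNS_IMS if c not in cols and c in COLUMNS_NO_IMS]
        extra = [c for c in cols if c not in COLUMNS_IMS]
        raise SchemaError(
            f"unexpected column set {cols}; expected {expected}"
            + (f"; missing {missing}" if missing else "")
            + (f"; extra {extra}" if extra else "")
        )
    out = df.reset_index(drop=True).copy()
    for c in out.columns:
        want = _DTYPES[c]
        if c == "mslevel" and out[c].dtype == object:
            # tolerate on-disk string encoding ("1"/"2")
            out[c] = out[c].astype(str).astype(np.int8)
        elif c == "intensity":
            vals = out[c]
            if len(vals) and not np.issubdtype(vals.dtype, np.integer):
                arr = vals.to_numpy()
                if np.all(arr >= 0) and np.all(arr == np.floor(arr)):
                    out[c] = arr.astype(np.uint64)
                # non-integral intensities kept as float; flagged by validate_table
            elif vals.dtype != np.uint64 and np.issubdtype(vals.dtype, np.integer):
                if len(vals) == 0 or vals.min() >= 0:
                    out[c] = vals.astype(np.uint64)
        elif out[c].dtype != want:
            out[c] = out[c].astype(want)
    return out


# ---------------------------------------------------------------------------
# operations


def validate_table(table: LongFormatSpectralTable) -> ValidationReport:
    """Check every semantic invariant of the long format.

    The structural column-set check happens at construction time
    (:meth:`LongFormatSpectralTable.from_dataframe` raises
    :class:`~parqms.errors.SchemaError`); this function checks row-level
    and table-wide semantics and never mutates its input:

    * intensity > 0, mz > 0, rt >= 0, mslevel in {1, 2}
    * all records sharing (scanid, mslevel) share exactly one rt
    * dt is a deterministic function of bin (same bin => same dt)
    * scanid, restricted to either MS level, is non-decreasing with rt
    * slope of the implied bin->dt relation is positive

    Floating-point (non-integral) intensities are tolerated but reported
    under ``warnings``.
    """
    df = table.df
    report = ValidationReport()

    def bad(invariant: str, mask: np.ndarray, message: str) -> None:
        idx = np.flatnonzero(mask)
        if idx.size:
            where = f"rows {idx[:5].tolist()}" + ("..." if idx.size > 5 else "")
            report.violations.append(Violation(invariant, where, message))

    if len(df) == 0:
        return report

    inten = df["intensity"].to_numpy()
    if not np.issubdtype(inten.dtype, np.integer):
        nonint = inten != np.floor(inten)
        if nonint.any():
            idx = np.flatnonzero(nonint)
            report.warnings.append(
                Violation(
                    "intensity integral",
                    f"rows {idx[:5].tolist()}",
                    "non-integral intensities present (tolerated)",
                )
            )
    bad("intensity > 0", ~(inten > 0), "zero or negative intensity stored")
    bad("mz > 0", ~(df["mz"].to_numpy() > 0), "non-positive m/z")
    bad("rt >= 0", df["rt"].to_numpy() < 0, "negative retention time")
    lvl = df["mslevel"].to_numpy()
    bad("mslevel in {1,2}", ~np.isin(lvl, (1, 2)), "MS level outside {1, 2}")
    bad("scanid >= 1", df["scanid"].to_numpy() < 1, "non-positive scanid")

    # one rt per (scanid, mslevel)
    nrt = df.groupby(["scanid", "mslevel"], sort=False)["rt"].nunique()
    offenders = nrt[nrt > 1]
    if len(offenders):
        key = offenders.index[0]
        report.violations.append(
            Violation(
                "unique rt per (scanid, mslevel)",
                f"scanid={key[0]}, mslevel={key[1]}",
                f"{len(offenders)} scan group(s) carry more than one rt",
            )
        )

    if table.has_ims:
        bad("bin >= 1", df["bin"].to_numpy() < 1, "bin indices are 1-based")
        bad("dt > 0", ~(df["dt"].to_numpy() > 0), "non-positive drift time")
        ndt = df.groupby("bin", sort=False)["dt"].nunique()
        dt_offenders = ndt[ndt > 1]
        if len(dt_offenders):
            report.violations.append(
                Violation(
                    "dt is a function of bin",
                    f"bin={dt_offenders.index[0]}",
                    "dt not a function of bin: "
                    f"{len(dt_offenders)} bin(s) map to multiple drift times",
                )
            )

    # scanid non-decreasing with rt, per level
    for level in (1, 2):
        sub = df[df["mslevel"] == level]
        if len(sub) < 2:
            continue
        ordered = sub.sort_values("rt", kind="stable")["scanid"].to_numpy()
        if np.any(np.diff(ordered) < 0):
            report.violations.append(
                Violation(
                    "scanid non-decreasing with rt",
                    f"mslevel={level}",
                    "scanid order disagrees with retention-time order",
                )
            )
    return report


def canonical_sort(table: LongFormatSpectralTable) -> LongFormatSpectralTable:
    """Return the table sorted by (mslevel, scanid, bin, mz) ascending.

    The sort is stable (ties keep input order) and idempotent.  For non-IMS
    tables the absent ``bin`` sorts as a constant, i.e. the key degenerates
    to (mslevel, scanid, mz).  This ordering clusters each MS level and
    retention-time run contiguously, which is what makes row-group
    statistics selective when the table is written to Parquet.
    """
    keys = ["mslevel", "scanid", "bin", "mz"] if table.has_ims else ["mslevel", "scanid", "mz"]
    df = table.df.sort_values(keys, kind="stable").reset_index(drop=True)
    return LongFormatSpectralTable(df, _checked=True)


def fit_drift_calibration(
    pairs: Sequence[tuple[int, float]], *, fit_intercept: bool = False
) -> DriftCalibration:
    """Least-squares fit of the linear bin -> drift-time relation.

    By default the intercept is constrained to zero and the slope is the
    through-origin estimator ``sum(bin*dt) / sum(bin^2)``; with
    ``fit_intercept=True`` an ordinary least-squares line is fitted.

    Raises
    ------
    InsufficientDataError
        Fewer than two distinct bin values.
    DomainError
        Any non-positive drift time.
    """
    if len(pairs) == 0:
        raise InsufficientDataError("no (bin, dt) pairs supplied")
    bins = np.asarray([p[0] for p in pairs], dtype=float)
    dts = np.asarray([p[1] for p in pairs], dtype=float)
    if np.unique(bins).size < 2:
        raise InsufficientDataError(
            f"need >= 2 distinct bin values to fit a line, got {np.unique(bins).size}"
        )
    if np.any(dts <= 0):
        raise DomainError("drift times must be positive")
    if fit_intercept:
        slope, intercept = np.polyfit(bins, dts, 1)
    else:
        slope = float(np.sum(bins * dts) / np.sum(bins * bins))
        intercept = 0.0
    resid = dts - (slope * bins + intercept)
    return DriftCalibration(
        slope=float(slope),
        intercept=float(intercept),
        n_points=len(pairs),
        max_residual=float(np.max(np.abs(resid))),
    )


def apply_drift_calibration(cal: DriftCalibration, bin: int) -> float:
    """Drift time (ms) predicted for a 1-based bin index."""
    if bin < 1:
        raise DomainError(f"bin indices are 1-based, got {bin}")
    return cal.predict(bin)
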