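"""Lazy, pushdown-filtered analytics over stored samples.

All operations take a :class:`~parqms.parquet_store.DatasetHandle` and
evaluate in two stages: first row groups whose column statistics cannot
satisfy the predicate are pruned (never read), then the surviving groups
are read with column projection and filtered exactly.  Because samples
are written in canonical (mslevel, scanid, bin, mz) order, the statistics
are selective and narrow queries touch a fraction of the file.

Interval semantics are closed ([lo, hi]) everywhere.  Retention-time
grouping uses exact stored rt values; no binning or tolerance is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .data_model import LongFormatSpectralTable, SpectralRecord, canonical_sort
from .errors import CapabilityError, DomainError, NotFoundError
from .parquet_store import DatasetHandle


@dataclass
class ScanStats:
    """How much of the file a query actually read."""

    row_groups_total: int
    row_groups_read: int
    rows_read: int


def _normalize_level(mslevel) -> int:
    """Accept integer or string MS level ('1'/'2' is the on-disk form)."""
    lvl = int(mslevel)
    if lvl not in (1, 2):
        raise DomainError(f"mslevel must be 1 or 2, got {mslevel!r}")
    return lvl


@dataclass
class RecordPredicate:
    """Conjunction of optional clauses; intervals are closed."""

    mslevel: Optional[int] = None
    rt_range: Optional[tuple[float, float]] = None
    mz_range: Optional[tuple[float, float]] = None
    bin_range: Optional[tuple[int, int]] = None
    scanid_set: Optional[frozenset[int]] = None

    def __post_init__(self) -> None:
        if self.mslevel is not None:
            self.mslevel = _normalize_level(self.mslevel)
        for name in ("rt_range", "mz_range", "bin_range"):
            rng = getattr(self, name)
            if rng is not None and rng[0] > rng[1]:
                raise DomainError(f"{name} lower bound {rng[0]} exceeds upper {rng[1]}")
        if self.scanid_set is not None:
            self.scanid_set = frozenset(int(s) for s in self.scanid_set)


_STAT_COLUMNS = ("mslevel", "rt", "mz", "bin", "scanid")


def _rg_can_match(stats_of, pred: RecordPredicate) -> bool:
    """Decide from row-group statistics whether any row can satisfy pred."""

    def rng_ok(col: str, lo, hi) -> bool:
        st = stats_of(col)
        if st is None or not st.has_min_max:
            return True  # no statistics -> cannot prune
        return not (lo > st.max or hi < st.min)

    if pred.mslevel is not None:
        st = stats_of("mslevel")
        if st is not None and st.has_min_max:
            s = str(pred.mslevel)
            if s < st.min or s > st.max:
                return False
    if pred.rt_range is not None and not rng_ok("rt", *pred.rt_range):
        return False
    if pred.mz_range is not None and not rng_ok("mz", *pred.mz_range):
        return False
    if pred.bin_range is not None and not rng_ok("bin", *pred.bin_range):
        return False
    if pred.scanid_set:
        if not rng_ok("scanid", min(pred.scanid_set), max(pred.scanid_set)):
            return False
    return True


def scan(
    handle: DatasetHandle,
    pred: RecordPredicate,
    columns: Optional[Iterable[str]] = None,
) -> tuple[pd.DataFrame, ScanStats]:
    """Pruned, projected, exactly-filtered scan of a sample.

    Returns the matching rows (as a DataFrame in file order) and the scan
    statistics; the statistics are also stored on
    ``handle.last_scan_stats``.
    """
    pf = handle.parquet_file
    meta = pf.metadata
    names = list(handle.columns)
    if pred.bin_range is not None and not handle.has_ims:
        raise CapabilityError("bin predicate on a sample without ion mobility")
    needed = set(columns) if columns is not None else set(names)
    if pred.mslevel is not None:
        needed.add("mslevel")
    if pred.rt_range is not None:
        needed.add("rt")
    if pred.mz_range is not None:
        needed.add("mz")
    if pred.bin_range is not None:
        needed.add("bin")
    if pred.scanid_set is not None:
        needed.add("scanid")
    proj = [c for c in names if c in needed]

    col_index = {c: i for i, c in enumerate(names)}
    kept = []
    for rg in range(meta.num_row_groups):
        group = meta.row_group(rg)

        def stats_of(col: str, _group=group):
            i = col_index.get(col)
            return None if i is None else _group.column(i).statistics

        if _rg_can_match(stats_of, pred):
            kept.append(rg)

    if kept:
        df = pf.read_row_groups(kept, columns=proj).to_pandas()
    else:
        df = pf.schema_arrow.empty_table().to_pandas()[proj]
    if "mslevel" in df.columns and df["mslevel"].dtype != np.int8:
        df["mslevel"] = df["mslevel"].astype(str).astype(np.int8)

    mask = np.ones(len(df), dtype=bool)
    if pred.mslevel is not None:
        mask &= df["mslevel"].to_numpy() == pred.mslevel
    if pred.rt_range is not None:
        rt = df["rt"].to_numpy()
        mask &= (rt >= pred.rt_range[0]) & (rt <= pred.rt_range[1])
    if pred.mz_range is not None:
        mz = df["mz"].to_numpy()
        mask &= (mz >= pred.mz_range[0]) & (mz <= pred.mz_range[1])
    if pred.bin_range is not None:
        b = df["bin"].to_numpy()
        mask &= (b >= pred.bin_range[0]) & (b <= pred.bin_range[1])
    if pred.scanid_set is not None:
        mask &= df["scanid"].isin(pred.scanid_set).to_numpy()
    out = df.loc[mask, proj].reset_index(drop=True)

    stats = ScanStats(
        row_groups_total=meta.num_row_groups,
        row_groups_read=len(kept),
        rows_read=int(sum(meta.row_group(rg).num_rows for rg in kept)),
    )
    handle.last_scan_stats = stats
    return out, stats


# ---------------------------------------------------------------------------
# result containers


def _format_float(x: float) -> str:
    return repr(float(x))


@dataclass
class ChromatogramSeries:
    """1-D intensity trace over retention time (TIC, BPC or EIC)."""

    kind: str
    mslevel: int
    rt: np.ndarray
    intensity: np.ndarray
    mz_window: Optional[tuple[float, float]] = None
    scan_stats: Optional[ScanStats] = None

    @property
    def points(self) -> list[tuple[float, int]]:
        return [(float(r), int(v)) for r, v in zip(self.rt, self.intensity)]

    def __len__(self) -> int:
        return len(self.rt)

    def to_csv(self, header: bool = False) -> str:
        lines = ["rt,intensity"] if header else []
        lines += [f"{_format_float(r)},{int(v)}" for r, v in zip(self.rt, self.intensity)]
        return "\n".join(lines)


@dataclass
class MassSpectrumSlice:
    """One scan's spectrum, optionally broken down per drift bin."""

    scanid: int
    mslevel: int
    rt: float
    mz: np.ndarray
    intensity: np.ndarray
    per_bin: Optional[dict[int, tuple[np.ndarray, np.ndarray]]] = None
    scan_stats: Optional[ScanStats] = None

    @property
    def points(self) -> list[tuple[float, int]]:
        return [(float(m), int(v)) for m, v in zip(self.mz, self.intensity)]

    def to_csv(self, header: bool = False) -> str:
        lines = ["mz,intensity"] if header else []
        lines += [f"{_format_float(m)},{int(v)}" for m, v in zip(self.mz, self.intensity)]
        return "\n".join(lines)


@dataclass
class MobilitySeries:
    """Summed intensity per drift bin (a mobilogram)."""

    mslevel: int
    bin: np.ndarray
    dt: np.ndarray
    intensity: np.ndarray
    mz_window: Optional[tuple[float, float]] = None
    scan_stats: Optional[ScanStats] = None

    @property
    def points(self) -> list[tuple[int, float, int]]:
        return [
            (int(b), float(d), int(v))
            for b, d, v in zip(self.bin, self.dt, self.intensity)
        ]

    def __len__(self) -> int:
        return len(self.bin)

    def to_csv(self, header: bool = False) -> str:
        lines = ["bin,dt,intensity"] if header else []
        lines += [
            f"{int(b)},{_format_float(d)},{int(v)}"
            for b, d, v in zip(self.bin, self.dt, self.intensity)
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# operations


def _grouped_chromatogram(df: pd.DataFrame, agg: str) -> tuple[np.ndarray, np.ndarray]:
    if len(df) == 0:
        return np.empty(0), np.empty(0, dtype=np.uint64)
    g = df.groupby("rt", sort=True)["intensity"].agg(agg)
    return g.index.to_numpy(), g.to_numpy()


def tic(handle: DatasetHandle, mslevel) -> ChromatogramSeries:
    """Total ion chromatogram: per-rt sum of intensities at one MS level.

    A level absent from the file yields an empty series, not an error.
    """
    lvl = _normalize_level(mslevel)
    df, stats = scan(handle, RecordPredicate(mslevel=lvl), columns=["rt", "intensity"])
    rt, vals = _grouped_chromatogram(df, "sum")
    return ChromatogramSeries("TIC", lvl, rt, vals, scan_stats=stats)


def bpc(handle: DatasetHandle, mslevel) -> ChromatogramSeries:
    """Base peak chromatogram: per-rt maximum intensity at one MS level."""
    lvl = _normalize_level(mslevel)
    df, stats = scan(handle, RecordPredicate(mslevel=lvl), columns=["rt", "intensity"])
    rt, vals = _grouped_chromatogram(df, "max")
    return ChromatogramSeries("BPC", lvl, rt, vals, scan_stats=stats)


def eic(handle: DatasetHandle, mz_lo: float, mz_hi: float, mslevel) -> ChromatogramSeries:
    """Extracted ion chromatogram over the closed m/z window [mz_lo, mz_hi].

    Retention times with no surviving records are omitted.
    """
    if mz_lo > mz_hi:
        raise DomainError(f"inverted m/z window: {mz_lo} > {mz_hi}")
    lvl = _normalize_level(mslevel)
    df, stats = scan(
        handle,
        RecordPredicate(mslevel=lvl, mz_range=(mz_lo, mz_hi)),
        columns=["rt", "intensity"],
    )
    rt, vals = _grouped_chromatogram(df, "sum")
    return ChromatogramSeries("EIC", lvl, rt, vals, mz_window=(mz_lo, mz_hi), scan_stats=stats)


def eic_around(
    handle: DatasetHandle,
    target_mz: float,
    mslevel,
    *,
    tol_da: Optional[float] = None,
    tol_ppm: Optional[float] = None,
) -> ChromatogramSeries:
    """EIC convenience wrapper: target +/- tolerance in Da or ppm."""
    if (tol_da is None) == (tol_ppm is None):
        raise DomainError("specify exactly one of tol_da or tol_ppm")
    if tol_da is not None:
        lo, hi = target_mz - tol_da, target_mz + tol_da
    else:
        lo = target_mz * (1 - tol_ppm * 1e-6)
        hi = target_mz * (1 + tol_ppm * 1e-6)
    return eic(handle, lo, hi, mslevel)


def spectrum_at(
    handle: DatasetHandle, scanid: int, mslevel, collapse_bins: bool = True
) -> MassSpectrumSlice:
    """The mass spectrum of one (scanid, mslevel) scan group.

    With ``collapse_bins`` intensities are summed over drift bins per m/z;
    otherwise the per-bin breakdown is retained alongside the collapsed
    points (their sums agree by construction).
    """
    lvl = _normalize_level(mslevel)
    cols = ["rt", "mz", "intensity"] + (["bin"] if handle.has_ims else [])
    df, stats = scan(
        handle,
        RecordPredicate(mslevel=lvl, scanid_set=frozenset({int(scanid)})),
        columns=cols,
    )
    if len(df) == 0:
        raise NotFoundError(f"no records for scanid={scanid}, mslevel={lvl}")
    rt = float(df["rt"].iloc[0])
    g = df.groupby("mz", sort=True)["intensity"].sum()
    per_bin = None
    if not collapse_bins and handle.has_ims:
        per_bin = {}
        for b, sub in df.groupby("bin", sort=True):
            sub = sub.sort_values("mz", kind="stable")
            per_bin[int(b)] = (sub["mz"].to_numpy(), sub["intensity"].to_numpy())
    return MassSpectrumSlice(
        scanid=int(scanid),
        mslevel=lvl,
        rt=rt,
        mz=g.index.to_numpy(),
        intensity=g.to_numpy(),
        per_bin=per_bin,
        scan_stats=stats,
    )


def mobilogram(
    handle: DatasetHandle, mslevel, mz_window: Optional[tuple[float, float]] = None
) -> MobilitySeries:
    """Summed intensity per drift bin at one MS level.

    Raises :class:`~parqms.errors.CapabilityError` on samples without ion
    mobility (the dimension is structurally absent, not merely empty).
    """
    if not handle.has_ims:
        raise CapabilityError(
            f"{handle.path} is not an ion-mobility sample; no mobilogram exists"
        )
    lvl = _normalize_level(mslevel)
    if mz_window is not None and mz_window[0] > mz_window[1]:
        raise DomainError(f"inverted m/z window: {mz_window[0]} > {mz_window[1]}")
    df, stats = scan(
        handle,
        RecordPredicate(mslevel=lvl, mz_range=mz_window),
        columns=["bin", "dt", "intensity"],
    )
    if len(df) == 0:
        return MobilitySeries(
            lvl,
            np.empty(0, dtype=np.int32),
            np.empty(0),
            np.empty(0, dtype=np.uint64),
            mz_window=mz_window,
            scan_stats=stats,
        )
    g = df.groupby("bin", sort=True).agg(dt=("dt", "first"), intensity=("intensity", "sum"))
    return MobilitySeries(
        mslevel=lvl,
        bin=g.index.to_numpy(),
        dt=g["dt"].to_numpy(),
        intensity=g["intensity"].to_numpy(),
        mz_window=mz_window,
        scan_stats=stats,
    )


def filter_records(handle: DatasetHandle, pred: RecordPredicate) -> LongFormatSpectralTable:
    """Exactly the rows satisfying all supplied clauses, in canonical order."""
    df, _ = scan(handle, pred)
    return canonical_sort(LongFormatSpectralTable.from_dataframe(df[list(handle.columns)]))


def base_peak_record(handle: DatasetHandle, mslevel=None) -> SpectralRecord:
    """The single most intense record in scope.

    Ties are broken by lowest rt, then lowest m/z.
    """
    pred = RecordPredicate(mslevel=mslevel) if mslevel is not None else RecordPredicate()
    df, _ = scan(handle, pred)
    if len(df) == 0:
        raise NotFoundError("no records in scope for base_peak_record")
    inten = df["intensity"].to_numpy()
    best = df[inten == inten.max()].sort_values(["rt", "mz"], kind="stable").iloc[0]
    return SpectralRecord(
        rt=float(best["rt"]),
        scanid=int(best["scanid"]),
        mslevel=int(best["mslevel"]),
        mz=float(best["mz"]),
        intensity=int(best["intensity"]),
        bin=int(best["bin"]) if handle.has_ims else None,
        dt=float(best["dt"]) if handle.has_ims else None,
    )
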