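"""mzML ingestion: assemble a validated long-format table from spectra.

MS^E / HDMS^E acquisitions alternate a low-collision-energy scan (level 1)
and a high-collision-energy scan (level 2) every duty cycle; with ion
mobility each scan is additionally split into drift-resolved sub-spectra,
one per mobility bin.  Converted files disagree on how they mark the
high-energy function, so level attribution is configurable
(:class:`LevelMapConfig`): trust the declared ``msLevel``, threshold on the
collision energy, or assume a strict alternating cycle structure.

Ingestion is lossless: every nonzero (m/z, intensity) point of every
spectrum becomes exactly one table row (zero-intensity profile padding is
dropped by default), and no peak picking or filtering is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._mzml import MzmlSpectrum, iter_spectra, read_file_info
from ._version import __version__
from .data_model import (
    LongFormatSpectralTable,
    canonical_sort,
    fit_drift_calibration,
    validate_table,
)
from .errors import (
    ConfigurationError,
    DomainError,
    IngestError,
    InvalidTableError,
    LevelMappingError,
)
from .parquet_store import SampleMetadata
from .data_model import DriftCalibration

#: drift times are quantized by the instrument; equality across cycles is
#: decided after rounding to this many decimals (milliseconds)
DT_DECIMALS = 6

_MODES = ("declared", "collision_energy_threshold", "alternating")


@dataclass(frozen=True)
class SpectrumHeader:
    """Per-spectrum descriptors needed for cycle/level attribution."""

    index: int
    native_id: str
    ms_level_declared: Optional[int]
    scan_start_time: Optional[float]  # minutes
    drift_time: Optional[float]  # milliseconds
    collision_energy: Optional[float]  # eV
    n_points: int = 0


@dataclass
class LevelMapConfig:
    """How spectra are attributed to MS levels 1 (low CE) and 2 (high CE).

    mode
        ``declared``: trust the file's ``msLevel``, clamped to {1, 2}.
        ``collision_energy_threshold``: level 2 iff collision energy
        exceeds ``ce_threshold`` (default 15 eV, between typical MS^E low
        ~6 eV and high-energy ramps >= 20 eV).
        ``alternating``: ignore annotations; scan groups alternate 1, 2,
        1, 2 ... in file order.
    override_map
        Optional explicit native_id -> level assignments, consulted first.
    """

    mode: str = "declared"
    ce_threshold: float = 15.0
    override_map: Optional[dict[str, int]] = None

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ConfigurationError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.mode == "collision_energy_threshold" and not self.ce_threshold > 0:
            raise ConfigurationError("ce_threshold must be positive")


def map_ms_level(header: SpectrumHeader, level_map: LevelMapConfig) -> int:
    """Deterministically attribute one spectrum to level 1 or 2.

    ``alternating`` mode is positional and handled in
    :func:`assign_cycles`; calling this directly in that mode is an error.
    """
    if level_map.override_map and header.native_id in level_map.override_map:
        lvl = level_map.override_map[header.native_id]
        if lvl not in (1, 2):
            raise LevelMappingError(
                f"override for {header.native_id!r} must be 1 or 2, got {lvl}"
            )
        return lvl
    if level_map.mode == "declared":
        lvl = header.ms_level_declared
        if lvl is None:
            raise LevelMappingError(
                f"spectrum {header.native_id!r} declares no msLevel (declared mode)"
            )
        return 1 if lvl <= 1 else 2
    if level_map.mode == "collision_energy_threshold":
        ce = header.collision_energy
        if ce is None:
            raise LevelMappingError(
                f"spectrum {header.native_id!r} carries no collision energy "
                "(collision_energy_threshold mode)"
            )
        return 2 if ce > level_map.ce_threshold else 1
    raise LevelMappingError(
        "alternating mode attributes levels positionally; use assign_cycles"
    )


def _group_boundaries(
    headers: Sequence[SpectrumHeader], levels: Optional[list[int]]
) -> list[int]:
    """Indices where a new (cycle, level) scan group starts.

    With ion mobility, the drift-resolved sub-spectra of one scan group
    arrive as a run of increasing drift times; a drift-time reset (or a
    level change) starts a new group.  Without ion mobility every spectrum
    is its own group.
    """
    has_dt = [h.drift_time is not None for h in headers]
    if any(has_dt) and not all(has_dt):
        bad = headers[has_dt.index(False)]
        raise IngestError(
            f"inconsistent cycle structure: spectrum {bad.native_id!r} lacks a "
            "drift time while others carry one"
        )
    ims = all(has_dt) and len(headers) > 0
    starts = [0]
    for i in range(1, len(headers)):
        if not ims:
            starts.append(i)
            continue
        level_changed = levels is not None and levels[i] != levels[i - 1]
        dt_reset = headers[i].drift_time <= headers[i - 1].drift_time  # type: ignore[operator]
        if level_changed or dt_reset:
            starts.append(i)
    return starts


def assign_cycles(
    headers: Sequence[SpectrumHeader], level_map: LevelMapConfig
) -> list[tuple[int, int]]:
    """Assign (scanid, mslevel) to each spectrum, in file order.

    scanid starts at 1 and increments whenever a new scan group does not
    move *up* in level — i.e. a level-1 group after a level-2 group opens
    the next duty cycle, and so does any repeated group at the same level.
    All drift-resolved sub-spectra of one (cycle, level) share their
    scanid and level.  Two consecutive level-2 groups raise a structure
    warning (the cycle is still incremented).
    """
    if not headers:
        return []
    if level_map.mode == "alternating":
        starts = _group_boundaries(headers, None)
        group_levels = [1 if g % 2 == 0 else 2 for g in range(len(starts))]
    else:
        levels = [map_ms_level(h, level_map) for h in headers]
        starts = _group_boundaries(headers, levels)
        group_levels = [levels[s] for s in starts]

    out: list[tuple[int, int]] = []
    scanid = 1
    for g, start in enumerate(starts):
        if g > 0:
            if group_levels[g] <= group_levels[g - 1]:
                scanid += 1
                if group_levels[g] == 2 and group_levels[g - 1] == 2:
                    warnings.warn(
                        "two consecutive high-energy scan groups with no "
                        f"low-energy group between them (near spectrum "
                        f"{headers[start].native_id!r}); cycle incremented",
                        stacklevel=2,
                    )
        end = starts[g + 1] if g + 1 < len(starts) else len(headers)
        out.extend([(scanid, group_levels[g])] * (end - start))
    return out


def assign_bins(drift_times: Sequence[float]) -> list[int]:
    """Map drift times to 1-based bin indices by rank.

    Distinct drift times (after rounding to ``DT_DECIMALS`` decimals, the
    instrument quantization) receive ascending 1-based indices; equal
    drift times share a bin, file-wide, so the mapping is invariant to the
    order in which cycles appear.
    """
    if len(drift_times) == 0:
        return []
    dts = np.round(np.asarray(drift_times, dtype=float), DT_DECIMALS)
    if np.any(dts <= 0):
        raise DomainError("drift times must be positive")
    uniq = np.unique(dts)
    rank = {v: i + 1 for i, v in enumerate(uniq)}
    return [rank[v] for v in dts]


def read_mzml(
    path: str | Path,
    level_map: LevelMapConfig | None = None,
    *,
    drop_zeros: bool = True,
) -> tuple[LongFormatSpectralTable, SampleMetadata]:
    """Parse an mzML file into a validated long-format table plus metadata.

    Spectra are streamed one at a time; only per-spectrum scalars (plus
    the growing output columns) are buffered.  Files whose scans carry
    drift-time annotations are ingested as ion-mobility samples with a
    fitted :class:`~parqms.data_model.DriftCalibration`; files without
    them are ingested as plain MS^E samples (no bin/dt columns).

    Parameters
    ----------
    path
        mzML document, plain or gzip-compressed.
    level_map
        MS-level attribution rule; defaults to ``declared`` mode.
    drop_zeros
        Drop zero-intensity profile padding points (the long format is
        sparse by construction).  Set False to keep them, which produces
        a table that fails validation if zeros are present.
    """
    level_map = level_map or LevelMapConfig()
    path = Path(path)

    headers: list[SpectrumHeader] = []
    rts: list[float] = []
    mz_parts: list[np.ndarray] = []
    int_parts: list[np.ndarray] = []
    counts: list[int] = []

    for spec in iter_spectra(path):
        if spec.rt_minutes is None:
            raise IngestError(f"spectrum {spec.native_id!r} has no scan start time")
        headers.append(
            SpectrumHeader(
                index=spec.index,
                native_id=spec.native_id,
                ms_level_declared=spec.ms_level,
                scan_start_time=spec.rt_minutes,
                drift_time=spec.drift_time_ms,
                collision_energy=spec.collision_energy_ev,
                n_points=spec.n_points,
            )
        )
        mz, inten = spec.mz, spec.intensity
        if drop_zeros and len(inten):
            keep = inten != 0
            mz, inten = mz[keep], inten[keep]
        rts.append(spec.rt_minutes)
        mz_parts.append(mz)
        int_parts.append(inten)
        counts.append(len(mz))

    info = read_file_info(path)

    assignment = assign_cycles(headers, level_map)
    has_ims = bool(headers) and headers[0].drift_time is not None
    if has_ims:
        bins = assign_bins([h.drift_time for h in headers])  # type: ignore[misc]

    counts_arr = np.asarray(counts, dtype=np.int64)
    df_cols = {
        "rt": np.repeat(np.asarray(rts, dtype=np.float64), counts_arr),
        "scanid": np.repeat(
            np.asarray([a[0] for a in assignment], dtype=np.int64), counts_arr
        ),
        "mslevel": np.repeat(
            np.asarray([a[1] for a in assignment], dtype=np.int8), counts_arr
        ),
        "mz": np.concatenate(mz_parts) if mz_parts else np.empty(0),
        "intensity": np.concatenate(int_parts) if int_parts else np.empty(0),
    }
    if has_ims:
        df_cols["bin"] = np.repeat(np.asarray(bins, dtype=np.int32), counts_arr)
        df_cols["dt"] = np.repeat(
            np.asarray([h.drift_time for h in headers], dtype=np.float64), counts_arr
        )
    table = canonical_sort(LongFormatSpectralTable.from_dataframe(pd.DataFrame(df_cols)))

    report = validate_table(table)
    if not report.ok:
        raise InvalidTableError(report, f"ingest of {path} produced an invalid table")

    calibration: Optional[DriftCalibration] = None
    if has_ims:
        pairs = sorted({(b, round(h.drift_time, DT_DECIMALS)) for b, h in zip(bins, headers)})  # type: ignore[arg-type]
        if len({b for b, _ in pairs}) >= 2:
            calibration = fit_drift_calibration(pairs)
        else:
            b, d = pairs[0]
            calibration = DriftCalibration(slope=d / b, intercept=0.0, n_points=1)

    metadata = SampleMetadata(
        sample_name=path.name.removesuffix(".gz").removesuffix(".mzML"),
        analysis_name=path.stem,
        acquisition_time=info.start_timestamp,
        instrument_descriptor=info.instrument_descriptor,
        has_ims=has_ims,
        drift_calibration=calibration,
        source_file=str(path),
        converter_name="parqms",
        converter_version=__version__,
        extras={"n_spectra": str(len(headers))},
    )
    return table, metadata
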