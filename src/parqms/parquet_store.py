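"""Parquet persistence for long-format samples.

A sample is a single Parquet file whose rows are the long-format table and
whose metadata travels twice: embedded in the file's key-value metadata
under the key ``"sample_metadata"`` and, by default, mirrored in a JSON
sidecar named ``<stem>-metadata.json`` next to the file.  Both copies hold
the identical JSON document, so the sidecar survives tools that strip
Parquet metadata and the embedded copy survives file moves.

Files are written sorted in canonical order with per-row-group column
statistics, which is what lets the query layer prune row groups instead of
reading whole files.
"""

from __future__ import annotations

import dataclasses
import json
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import pyarrow as pa
import pyarrow.parquet as pq

from . import data_model
from .data_model import (
    COLUMNS_IMS,
    COLUMNS_NO_IMS,
    SCHEMA_VERSION,
    DriftCalibration,
    LongFormatSpectralTable,
    canonical_sort,
    validate_table,
)
from .errors import (
    ConfigurationError,
    InvalidTableError,
    MetadataMismatchError,
    MetadataMissingError,
    SchemaError,
    StorageError,
)

METADATA_KEY = b"sample_metadata"

_CODECS = ("zstd", "snappy", "gzip", "none")


@dataclass
class SampleMetadata:
    """Identity, acquisition descriptors and provenance of one sample.

    ``has_ims`` must agree with the presence of ``drift_calibration``: an
    ion-mobility sample always carries its bin -> drift-time calibration.
    Unanticipated vendor fields go into ``extras`` (string -> string).
    """

    sample_name: str
    analysis_name: str = ""
    acquisition_time: Optional[str] = None
    instrument_descriptor: Optional[str] = None
    polarity: str = "unknown"
    has_ims: bool = False
    drift_calibration: Optional[DriftCalibration] = None
    rt_unit: str = "minute"
    dt_unit: str = "millisecond"
    source_file: str = ""
    converter_name: str = "parqms"
    converter_version: str = ""
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_name:
            raise ConfigurationError("sample_name must be non-empty")
        if self.polarity not in ("positive", "negative", "unknown"):
            raise ConfigurationError(f"unknown polarity {self.polarity!r}")
        if self.has_ims != (self.drift_calibration is not None):
            raise ConfigurationError(
                "has_ims must agree with the presence of drift_calibration"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["drift_calibration"] = (
            self.drift_calibration.to_dict() if self.drift_calibration else None
        )
        d["schema_version"] = SCHEMA_VERSION
        return d

    def to_json_bytes(self) -> bytes:
        """Canonical serialization: UTF-8, sorted keys, 2-space indent."""
        return json.dumps(self.to_dict(), sort_keys=True, indent=2).encode("utf-8")

    @classmethod
    def from_dict(cls, d: dict) -> "SampleMetadata":
        d = dict(d)
        d.pop("schema_version", None)
        cal = d.get("drift_calibration")
        if cal is not None:
            d["drift_calibration"] = DriftCalibration.from_dict(cal)
        return cls(**d)

    @classmethod
    def from_json_bytes(cls, raw: bytes) -> "SampleMetadata":
        return cls.from_dict(json.loads(raw.decode("utf-8")))


@dataclass
class WriteOptions:
    codec: str = "zstd"
    row_group_target_rows: int = 2**20
    sort_before_write: bool = True
    write_json_sidecar: bool = True

    def __post_init__(self) -> None:
        if self.codec not in _CODECS:
            raise ConfigurationError(f"codec must be one of {_CODECS}, got {self.codec!r}")
        if self.row_group_target_rows < 1:
            raise ConfigurationError("row_group_target_rows must be >= 1")


@dataclass
class WriteReport:
    path: str
    n_rows: int
    n_row_groups: int
    file_bytes: int


@dataclass
class RoundtripReport:
    identical: bool
    first_divergence: Optional[str] = None


class DatasetHandle:
    """Lazy reference to an on-disk sample.

    Opening a handle touches only the Parquet footer (schema, row-group
    statistics) and the metadata document; row data are read later, row
    group by row group, by the query layer.  ``last_scan_stats`` records
    how many row groups the most recent query actually read.
    """

    def __init__(self, path: str | Path):
        self.path = str(path)
        try:
            self._pf = pq.ParquetFile(self.path)
        except FileNotFoundError:
            raise
        except Exception as exc:  # pragma: no cover - corrupt file path
            raise StorageError(f"cannot open {path}: {exc}") from exc
        names = tuple(self._pf.schema_arrow.names)
        if names not in (COLUMNS_IMS, COLUMNS_NO_IMS):
            raise SchemaError(
                f"unexpected schema in {path}: found columns {list(names)}, "
                f"expected {list(COLUMNS_IMS)} or {list(COLUMNS_NO_IMS)}"
            )
        self.columns = names
        self.has_ims = "bin" in names
        self.n_rows = self._pf.metadata.num_rows
        self.n_row_groups = self._pf.metadata.num_row_groups
        self.metadata = read_metadata(self.path)
        self.last_scan_stats = None  # set by parqms.query

    @property
    def parquet_file(self) -> pq.ParquetFile:
        return self._pf

    def read_table(self) -> LongFormatSpectralTable:
        """Materialize the full table (escape hatch; queries stay lazy)."""
        df = self._pf.read().to_pandas()
        return LongFormatSpectralTable.from_dataframe(_undictionarize(df))

    def __repr__(self) -> str:
        return (
            f"<DatasetHandle {self.path!r} rows={self.n_rows} "
            f"row_groups={self.n_row_groups} ims={self.has_ims}>"
        )


def _undictionarize(df: pd.DataFrame) -> pd.DataFrame:
    # mslevel is dictionary-encoded string on disk -> semantic small int
    if "mslevel" in df.columns and df["mslevel"].dtype != np.int8:
        df = df.copy()
        df["mslevel"] = df["mslevel"].astype(str).astype(np.int8)
    return df


def _arrow_table(table: LongFormatSpectralTable, kv: dict[bytes, bytes]) -> pa.Table:
    df = table.df
    arrays = {
        "rt": pa.array(df["rt"].to_numpy(), type=pa.float64()),
        "scanid": pa.array(df["scanid"].to_numpy(), type=pa.int64()),
        "mslevel": pa.array(
            df["mslevel"].astype(str), type=pa.dictionary(pa.int32(), pa.string())
        ),
        "mz": pa.array(df["mz"].to_numpy(), type=pa.float64()),
        "intensity": pa.array(df["intensity"].to_numpy(), type=pa.uint64()),
    }
    if table.has_ims:
        arrays["bin"] = pa.array(df["bin"].to_numpy(), type=pa.int32())
        arrays["dt"] = pa.array(df["dt"].to_numpy(), type=pa.float64())
    t = pa.table(arrays)
    return t.replace_schema_metadata(kv)


def sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_name(p.stem + "-metadata.json")


def write_sample(
    table: LongFormatSpectralTable,
    metadata: SampleMetadata,
    path: str | Path,
    options: WriteOptions | None = None,
) -> WriteReport:
    """Write a validated table plus metadata to one Parquet file.

    The table is canonically sorted first (unless disabled), written with
    per-row-group statistics, the metadata document embedded under the
    ``sample_metadata`` key, and mirrored to the JSON sidecar.

    Raises
    ------
    InvalidTableError
        If the table fails :func:`~parqms.data_model.validate_table`; the
        report is attached to the exception and nothing is written.
    """
    options = options or WriteOptions()
    report = validate_table(table)
    if not report.ok:
        raise InvalidTableError(report, "refusing to write invalid table")
    if table.has_ims != metadata.has_ims:
        raise ConfigurationError(
            f"metadata.has_ims={metadata.has_ims} but table has_ims={table.has_ims}"
        )
    if options.sort_before_write:
        table = canonical_sort(table)
    doc = metadata.to_json_bytes()
    at = _arrow_table(table, {METADATA_KEY: doc})
    path = Path(path)
    try:
        pq.write_table(
            at,
            path,
            compression=options.codec,
            row_group_size=options.row_group_target_rows,
            write_statistics=True,
        )
        if options.write_json_sidecar:
            sidecar_path(path).write_bytes(doc)
    except OSError as exc:
        raise StorageError(f"failed writing sample to {path}: {exc}") from exc
    pf = pq.ParquetFile(path)
    return WriteReport(
        path=str(path),
        n_rows=pf.metadata.num_rows,
        n_row_groups=pf.metadata.num_row_groups,
        file_bytes=os.path.getsize(path),
    )


def open_sample(path: str | Path) -> DatasetHandle:
    """Open an on-disk sample lazily (footer and metadata only)."""
    return DatasetHandle(path)


def read_metadata(path: str | Path) -> SampleMetadata:
    """Load the sample metadata document.

    The copy embedded in the Parquet key-value metadata is authoritative;
    the JSON sidecar is a fallback (used with a warning when the embedded
    copy is missing).  If both exist they must mirror each other.
    """
    path = Path(path)
    kv_doc = None
    meta = pq.ParquetFile(path).metadata.metadata
    if meta and METADATA_KEY in meta:
        kv_doc = meta[METADATA_KEY]
    side = sidecar_path(path)
    side_doc = side.read_bytes() if side.exists() else None
    if kv_doc is not None and side_doc is not None:
        if json.loads(kv_doc) != json.loads(side_doc):
            raise MetadataMismatchError(
                f"embedded metadata and sidecar {side} disagree; "
                "the two copies must mirror each other"
            )
        return SampleMetadata.from_json_bytes(kv_doc)
    if kv_doc is not None:
        return SampleMetadata.from_json_bytes(kv_doc)
    if side_doc is not None:
        warnings.warn(
            f"{path}: no embedded sample_metadata; reconstructed from sidecar {side.name}",
            stacklevel=2,
        )
        return SampleMetadata.from_json_bytes(side_doc)
    raise MetadataMissingError(
        f"{path}: no embedded sample_metadata key and no sidecar {side.name}"
    )


def read_sample_table(path: str | Path) -> LongFormatSpectralTable:
    """Read the full table from disk (eager; for round-trip checks/tests)."""
    df = pq.read_table(path).to_pandas()
    return LongFormatSpectralTable.from_dataframe(_undictionarize(df))


def verify_roundtrip(table: LongFormatSpectralTable, path: str | Path) -> RoundtripReport:
    """Compare an in-memory table against its on-disk rendering, cell by cell.

    Both sides are canonically sorted, then every column is compared for
    bit-exact equality (m/z, rt and dt are 64-bit floats on disk, so no
    precision is lost in a write/read cycle).  Divergences are reported,
    not raised.
    """
    a = canonical_sort(table)
    b = canonical_sort(read_sample_table(path))
    if a.columns != b.columns:
        return RoundtripReport(False, f"column sets differ: {a.columns} vs {b.columns}")
    if len(a) != len(b):
        return RoundtripReport(False, f"row counts differ: {len(a)} vs {len(b)}")
    for col in a.columns:
        x = a.df[col].to_numpy()
        y = b.df[col].to_numpy()
        neq = x != y
        if neq.any():
            row = int(np.flatnonzero(neq)[0])
            return RoundtripReport(
                False,
                f"row {row}, column {col!r}: memory={x[row]!r} disk={y[row]!r}",
            )
    return RoundtripReport(True, None)
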