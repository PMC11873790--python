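"""Streaming mzML 1.1 reader and writer.

Covers the subset of mzML this package produces and consumes: plain or
gzip-compressed documents, spectra with 32/64-bit float binary arrays
(zlib-compressed or raw), scan start times in minutes or seconds, per-scan
ion-mobility drift-time annotations and collision energies.  The reader
streams spectrum by spectrum with ``ElementTree.iterparse`` so peak memory
is bounded by a single spectrum, not file size.

Numpress-packed arrays, chromatogram lists and vendor raw access are out
of scope.
"""

from __future__ import annotations

import base64
import gzip
import io
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator, Optional
from xml.etree import ElementTree as ET
from xml.sax.saxutils import escape, quoteattr

import numpy as np

from .errors import MzmlParseError

MZML_NS = "http://psi.hupo.org/ms/mzml"

# CV accessions used for round-tripping
ACC_MS_LEVEL = "MS:1000511"
ACC_SCAN_START_TIME = "MS:1000016"
ACC_DRIFT_TIME = "MS:1002476"
ACC_COLLISION_ENERGY = "MS:1000045"
ACC_MZ_ARRAY = "MS:1000514"
ACC_INTENSITY_ARRAY = "MS:1000515"
ACC_FLOAT64 = "MS:1000523"
ACC_FLOAT32 = "MS:1000521"
ACC_ZLIB = "MS:1000574"
ACC_NO_COMPRESSION = "MS:1000576"

_UNIT_MINUTE = ("UO:0000031", "minute")
_UNIT_SECOND = ("UO:0000010", "second")


@dataclass
class MzmlSpectrum:
    """One decoded mzML spectrum."""

    index: int
    native_id: str
    ms_level: Optional[int]
    rt_minutes: Optional[float]
    drift_time_ms: Optional[float]
    collision_energy_ev: Optional[float]
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_points(self) -> int:
        return len(self.mz)


@dataclass
class MzmlFileInfo:
    """Header-level descriptors harvested before the spectrum list."""

    instrument_descriptor: Optional[str] = None
    start_timestamp: Optional[str] = None
    source_files: list[str] = field(default_factory=list)
    software: list[tuple[str, str]] = field(default_factory=list)


def _open_maybe_gzip(path: str | Path) -> IO[bytes]:
    fh = open(path, "rb")
    magic = fh.read(2)
    fh.seek(0)
    if magic == b"\x1f\x8b":
        return gzip.open(fh, "rb")  # type: ignore[return-value]
    return fh


def _local(tag: str) -> str:
    return tag.rpartition("}")[2]


def _cvparams(elem: ET.Element) -> list[ET.Element]:
    return [c for c in elem if _local(c.tag) == "cvParam"]


def _find_child(elem: ET.Element, local: str) -> Optional[ET.Element]:
    for c in elem:
        if _local(c.tag) == local:
            return c
    return None


def _decode_binary_array(bda: ET.Element, native_id: str) -> tuple[str, np.ndarray]:
    dtype = "<f8"
    compressed = False
    kind = ""
    for cv in _cvparams(bda):
        acc = cv.get("accession", "")
        if acc == ACC_FLOAT64:
            dtype = "<f8"
        elif acc == ACC_FLOAT32:
            dtype = "<f4"
        elif acc == ACC_ZLIB:
            compressed = True
        elif acc == ACC_NO_COMPRESSION:
            compressed = False
        elif acc == ACC_MZ_ARRAY:
            kind = "mz"
        elif acc == ACC_INTENSITY_ARRAY:
            kind = "intensity"
    binary = _find_child(bda, "binary")
    text = (binary.text or "") if binary is not None else ""
    raw = base64.b64decode(text)
    if compressed and raw:
        try:
            raw = zlib.decompress(raw)
        except zlib.error as exc:
            raise MzmlParseError(
                f"spectrum {native_id!r}: corrupt zlib-compressed binary array: {exc}"
            ) from exc
    return kind, np.frombuffer(raw, dtype=dtype).astype(np.float64)


def _float_cv(elem: ET.Element, accession: str) -> Optional[tuple[float, str]]:
    for cv in _cvparams(elem):
        if cv.get("accession") == accession:
            return float(cv.get("value", "nan")), cv.get("unitAccession", "")
    return None


def _parse_spectrum(elem: ET.Element, index: int) -> MzmlSpectrum:
    native_id = elem.get("id", f"index={index}")
    ms_level: Optional[int] = None
    for cv in _cvparams(elem):
        if cv.get("accession") == ACC_MS_LEVEL:
            ms_level = int(cv.get("value", "0"))
    rt = dt = ce = None
    scan_list = _find_child(elem, "scanList")
    if scan_list is not None:
        scan = _find_child(scan_list, "scan")
        if scan is not None:
            got = _float_cv(scan, ACC_SCAN_START_TIME)
            if got is not None:
                value, unit = got
                rt = value / 60.0 if unit == _UNIT_SECOND[0] else value
            got = _float_cv(scan, ACC_DRIFT_TIME)
            if got is not None:
                dt = got[0]
            got = _float_cv(scan, ACC_COLLISION_ENERGY)
            if got is not None:
                ce = got[0]
    if ce is None:
        # ProteoWizard places collision energy inside precursor activation
        for sub in elem.iter():
            if _local(sub.tag) == "activation":
                got = _float_cv(sub, ACC_COLLISION_ENERGY)
                if got is not None:
                    ce = got[0]
                break
    mz = inten = np.empty(0)
    bdal = _find_child(elem, "binaryDataArrayList")
    if bdal is not None:
        for bda in bdal:
            if _local(bda.tag) != "binaryDataArray":
                continue
            kind, arr = _decode_binary_array(bda, native_id)
            if kind == "mz":
                mz = arr
            elif kind == "intensity":
                inten = arr
    if len(mz) != len(inten):
        raise MzmlParseError(
            f"spectrum {native_id!r}: m/z and intensity arrays differ in length "
            f"({len(mz)} vs {len(inten)})"
        )
    return MzmlSpectrum(
        index=index,
        native_id=native_id,
        ms_level=ms_level,
        rt_minutes=rt,
        drift_time_ms=dt,
        collision_energy_ev=ce,
        mz=mz,
        intensity=inten,
    )


def read_file_info(path: str | Path) -> MzmlFileInfo:
    """Harvest header descriptors; stops at the first spectrum."""
    info = MzmlFileInfo()
    with _open_maybe_gzip(path) as fh:
        try:
            for event, elem in ET.iterparse(fh, events=("start", "end")):
                local = _local(elem.tag)
                if event == "start":
                    if local == "run" and elem.get("startTimeStamp"):
                        info.start_timestamp = elem.get("startTimeStamp")
                    elif local == "spectrumList" or local == "spectrum":
                        break
                    continue
                if local == "sourceFile":
                    name = elem.get("name") or elem.get("location") or ""
                    if name:
                        info.source_files.append(name)
                elif local == "software":
                    info.software.append((elem.get("id", ""), elem.get("version", "")))
                elif local == "instrumentConfiguration":
                    for cv in _cvparams(elem):
                        # prefer a concrete model name over the generic term
                        name = cv.get("name", "")
                        if name and name != "instrument model":
                            info.instrument_descriptor = name
                            break
                    else:
                        if info.instrument_descriptor is None and _cvparams(elem):
                            info.instrument_descriptor = _cvparams(elem)[0].get("name")
        except ET.ParseError as exc:
            raise MzmlParseError(_parse_error_message(path, exc)) from exc
    return info


def iter_spectra(path: str | Path) -> Iterator[MzmlSpectrum]:
    """Stream decoded spectra from a (possibly gzipped) mzML document."""
    index = 0
    with _open_maybe_gzip(path) as fh:
        try:
            context = ET.iterparse(fh, events=("end",))
            for _, elem in context:
                if _local(elem.tag) == "spectrum":
                    yield _parse_spectrum(elem, index)
                    index += 1
                    elem.clear()
        except ET.ParseError as exc:
            raise MzmlParseError(_parse_error_message(path, exc)) from exc


def _parse_error_message(path: str | Path, exc: ET.ParseError) -> str:
    line, col = getattr(exc, "position", (None, None))
    where = f" at line {line}, column {col}" if line is not None else ""
    return f"unreadable or truncated mzML {path}{where}: {exc}"


# ---------------------------------------------------------------------------
# writing


def _encode_array(arr: np.ndarray, compress: bool) -> str:
    raw = np.ascontiguousarray(arr, dtype="<f8").tobytes()
    if compress:
        raw = zlib.compress(raw)
    return base64.b64encode(raw).decode("ascii")


def _cv(accession: str, name: str, value: str = "", unit: tuple[str, str] | None = None,
        cv_ref: str = "MS") -> str:
    s = (
        f'<cvParam cvRef="{cv_ref}" accession="{accession}" '
        f"name={quoteattr(name)} value={quoteattr(value)}"
    )
    if unit is not None:
        ucv = "UO" if unit[0].startswith("UO") else "MS"
        s += (
            f' unitCvRef="{ucv}" unitAccession="{unit[0]}"'
            f" unitName={quoteattr(unit[1])}"
        )
    return s + "/>"


def _binary_array_xml(arr: np.ndarray, kind_acc: str, kind_name: str, compress: bool) -> str:
    b64 = _encode_array(arr, compress)
    comp = (
        _cv(ACC_ZLIB, "zlib compression")
        if compress
        else _cv(ACC_NO_COMPRESSION, "no compression")
    )
    return (
        f'<binaryDataArray encodedLength="{len(b64)}">'
        + _cv(ACC_FLOAT64, "64-bit float")
        + comp
        + _cv(kind_acc, kind_name)
        + f"<binary>{b64}</binary></binaryDataArray>"
    )


def render_spectrum_xml(
    spec: MzmlSpectrum, *, profile: bool = True, compress: bool = True
) -> str:
    """Serialize one spectrum element (used by the mzML writer)."""
    parts = [
        f'<spectrum index="{spec.index}" id={quoteattr(spec.native_id)} '
        f'defaultArrayLength="{spec.n_points}">'
    ]
    if spec.ms_level is not None:
        parts.append(_cv(ACC_MS_LEVEL, "ms level", str(spec.ms_level)))
    parts.append(
        _cv("MS:1000128", "profile spectrum")
        if profile
        else _cv("MS:1000127", "centroid spectrum")
    )
    scan_cvs = []
    if spec.rt_minutes is not None:
        scan_cvs.append(
            _cv(ACC_SCAN_START_TIME, "scan start time", repr(spec.rt_minutes), _UNIT_MINUTE)
        )
    if spec.drift_time_ms is not None:
        scan_cvs.append(
            _cv(
                ACC_DRIFT_TIME,
                "ion mobility drift time",
                repr(spec.drift_time_ms),
                ("UO:0000028", "millisecond"),
            )
        )
    if spec.collision_energy_ev is not None:
        scan_cvs.append(
            _cv(
                ACC_COLLISION_ENERGY,
                "collision energy",
                repr(spec.collision_energy_ev),
                ("UO:0000266", "electronvolt"),
            )
        )
    parts.append(
        '<scanList count="1">'
        + _cv("MS:1000795", "no combination")
        + "<scan>"
        + "".join(scan_cvs)
        + "</scan></scanList>"
    )
    parts.append(
        '<binaryDataArrayList count="2">'
        + _binary_array_xml(spec.mz, ACC_MZ_ARRAY, "m/z array", compress)
        + _binary_array_xml(spec.intensity, ACC_INTENSITY_ARRAY, "intensity array", compress)
        + "</binaryDataArrayList>"
    )
    parts.append("</spectrum>")
    return "".join(parts)


def write_mzml(
    spectra: list[MzmlSpectrum],
    path: str | Path,
    *,
    software_version: str = "",
    source_file: str | None = None,
    instrument: str | None = None,
    compress_arrays: bool = True,
    gzip_file: bool = False,
) -> Path:
    """Write a minimal, self-consistent mzML 1.1 document."""
    path = Path(path)
    out: IO[bytes]
    buf = io.StringIO()
    buf.write('<?xml version="1.0" encoding="utf-8"?>\n')
    buf.write(f'<mzML xmlns="{MZML_NS}" version="1.1.0">\n')
    buf.write(
        '<cvList count="2">'
        '<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" '
        'URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
        '<cv id="UO" fullName="Unit Ontology" '
        'URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>'
        "</cvList>\n"
    )
    buf.write("<fileDescription><fileContent>")
    buf.write(_cv("MS:1000579", "MS1 spectrum"))
    buf.write("</fileContent>")
    if source_file:
        name = escape(Path(source_file).name)
        buf.write(
            f'<sourceFileList count="1"><sourceFile id="SF1" name="{name}" '
            f'location="{escape(str(source_file))}"/></sourceFileList>'
        )
    buf.write("</fileDescription>\n")
    buf.write(
        f'<softwareList count="1"><software id="parqms" version="{escape(software_version)}">'
        + _cv("MS:1000799", "custom unreleased software tool", "parqms")
        + "</software></softwareList>\n"
    )
    instr_cv = (
        _cv("MS:1000031", "instrument model", instrument or "")
    )
    buf.write(
        '<instrumentConfigurationList count="1"><instrumentConfiguration id="IC1">'
        + instr_cv
        + "</instrumentConfiguration></instrumentConfigurationList>\n"
    )
    buf.write(
        '<dataProcessingList count="1"><dataProcessing id="DP1">'
        '<processingMethod order="0" softwareRef="parqms">'
        + _cv("MS:1000544", "Conversion to mzML")
        + "</processingMethod></dataProcessing></dataProcessingList>\n"
    )
    buf.write('<run id="R1" defaultInstrumentConfigurationRef="IC1">\n')
    buf.write(f'<spectrumList count="{len(spectra)}" defaultDataProcessingRef="DP1">\n')
    for spec in spectra:
        buf.write(render_spectrum_xml(spec, compress=compress_arrays))
        buf.write("\n")
    buf.write("</spectrumList>\n</run>\n</mzML>\n")
    payload = buf.getvalue().encode("utf-8")
    if gzip_file or str(path).endswith(".gz"):
        with gzip.open(path, "wb") as out:
            out.write(payload)
    else:
        path.write_bytes(payload)
    return path
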