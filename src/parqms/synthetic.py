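"""Ground-truthed synthetic HDMS^E samples.

The generator emulates an alternating-energy DIA acquisition on a
UPLC-IMS-QTOF-like instrument: every duty cycle records a low-energy scan
(level 1) and, slightly later, a high-energy scan (level 2); each scan is
split across ``n_bins`` mobility bins with drift time a linear function of
the bin index.  Each compound contributes a separable Gaussian peak in
retention time and drift, carrying precursor + isotopes at level 1 and
fragments plus an attenuated precursor at level 2 (fragments co-drift with
their precursor, as in HDMS^E).  Uniform chemical noise points and Poisson
counting noise are optional.

A contribution is emitted only when its rounded intensity reaches 1 count,
so generated tables satisfy the no-zero-rows invariant by construction.
Identical configurations (including the seed) produce bit-identical
tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._mzml import MzmlSpectrum, write_mzml
from ._version import __version__
from .data_model import DriftCalibration, LongFormatSpectralTable, canonical_sort
from .errors import ConfigurationError
from .parquet_store import SampleMetadata

#: collision energies written to synthetic mzML scans (eV); typical MS^E
#: low-energy setting and high-energy ramp midpoint
LOW_CE_EV = 6.0
HIGH_CE_EV = 30.0


@dataclass
class CompoundSpec:
    """One simulated compound (separable Gaussian in rt and drift)."""

    precursor_mz: float
    rt_apex: float  # minutes
    rt_sigma: float  # minutes
    dt_apex_bin: float  # real-valued bin units
    dt_sigma_bins: float
    apex_intensity: float  # counts at the rt/dt apex
    isotope_offsets: list[tuple[float, float]] = field(default_factory=list)
    fragments: list[tuple[float, float]] = field(default_factory=list)
    precursor_survival: float = 0.2  # precursor attenuation at level 2

    def __post_init__(self) -> None:
        if self.rt_sigma <= 0 or self.dt_sigma_bins <= 0:
            raise ConfigurationError("peak sigmas must be positive")
        if self.apex_intensity < 1:
            raise ConfigurationError("apex_intensity must be >= 1")
        for _, ab in list(self.isotope_offsets) + list(self.fragments):
            if not 0 < ab <= 1:
                raise ConfigurationError("relative abundances must be in (0, 1]")


@dataclass
class SimulationConfig:
    """Acquisition grid and sample content.

    Defaults describe a short high-resolution run: 600 cycles of 0.005 min
    (3 min gradient, the high-energy scan 0.002 min after the low-energy
    one), 200 mobility bins at 0.071 ms/bin.
    """

    n_cycles: int = 600
    cycle_period: float = 0.005  # minutes
    level2_rt_offset: float = 0.002  # minutes
    n_bins: int = 200
    drift_slope: float = 0.071  # ms per bin
    compounds: list[CompoundSpec] = field(default_factory=list)
    noise_points_per_scan: int = 0
    noise_intensity_max: int = 10
    noise_mz_range: tuple[float, float] = (50.0, 1000.0)
    intensity_noise: str = "none"  # "none" | "poisson"
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_cycles < 1 or self.n_bins < 1:
            raise ConfigurationError("n_cycles and n_bins must be >= 1")
        if self.cycle_period <= 0:
            raise ConfigurationError("cycle_period must be positive")
        if not 0 <= self.level2_rt_offset < self.cycle_period:
            raise ConfigurationError("level2_rt_offset must lie within one cycle")
        if self.drift_slope <= 0:
            raise ConfigurationError("drift_slope must be positive")
        if self.intensity_noise not in ("none", "poisson"):
            raise ConfigurationError("intensity_noise must be 'none' or 'poisson'")
        if self.noise_points_per_scan < 0 or self.noise_intensity_max < 1:
            raise ConfigurationError("invalid noise settings")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["compounds"] = [
            CompoundSpec(
                **{
                    **c,
                    "isotope_offsets": [tuple(t) for t in c.get("isotope_offsets", [])],
                    "fragments": [tuple(t) for t in c.get("fragments", [])],
                }
            )
            for c in d.get("compounds", [])
        ]
        d["noise_mz_range"] = tuple(d.get("noise_mz_range", (50.0, 1000.0)))
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class CompoundTruth:
    precursor_mz: float
    rt_apex: float
    dt_apex_bin: float
    dt_apex_ms: float
    emitted_intensity: dict[int, int]  # per MS level


@dataclass
class GroundTruth:
    compounds: list[CompoundTruth]
    n_records: dict[int, int]  # per MS level, noise included
    total_intensity: dict[int, int]

    def to_json_bytes(self) -> bytes:
        d = {
            "compounds": [dataclasses.asdict(c) for c in self.compounds],
            "n_records": self.n_records,
            "total_intensity": self.total_intensity,
        }
        return json.dumps(d, sort_keys=True, indent=2).encode()


def _species(compound: CompoundSpec, level: int) -> list[tuple[float, float]]:
    if level == 1:
        return [(compound.precursor_mz, 1.0)] + [
            (compound.precursor_mz + dmz, ab) for dmz, ab in compound.isotope_offsets
        ]
    out = list(compound.fragments)
    if compound.precursor_survival > 0:
        out.append((compound.precursor_mz, compound.precursor_survival))
    return out


def simulate_sample(
    config: SimulationConfig,
) -> tuple[LongFormatSpectralTable, GroundTruth, SampleMetadata]:
    """Generate one HDMS^E-like sample with its ground truth.

    The signal model per compound, cycle and bin is
    ``apex_intensity * exp(-(rt-rt_apex)^2 / (2 rt_sigma^2))
    * exp(-(bin-dt_apex_bin)^2 / (2 dt_sigma_bins^2)) * abundance``,
    rounded to integer counts (or Poisson-sampled with that mean), emitted
    when >= 1.  Drift time is ``drift_slope * bin``.
    """
    rng = np.random.default_rng(config.seed)
    cycles = np.arange(1, config.n_cycles + 1, dtype=np.int64)
    rt_level = {
        1: (cycles - 1) * config.cycle_period,
        2: (cycles - 1) * config.cycle_period + config.level2_rt_offset,
    }
    bins = np.arange(1, config.n_bins + 1, dtype=np.int32)
    dt_of_bin = config.drift_slope * bins.astype(np.float64)

    cols: dict[str, list[np.ndarray]] = {
        k: [] for k in ("rt", "scanid", "mslevel", "mz", "intensity", "bin")
    }
    truths: list[CompoundTruth] = []

    for compound in config.compounds:
        emitted = {1: 0, 2: 0}
        g_dt = np.exp(
            -((bins - compound.dt_apex_bin) ** 2) / (2.0 * compound.dt_sigma_bins**2)
        )
        for level in (1, 2):
            g_rt = np.exp(
                -((rt_level[level] - compound.rt_apex) ** 2)
                / (2.0 * compound.rt_sigma**2)
            )
            for mz_value, abundance in _species(compound, level):
                lam = compound.apex_intensity * abundance * np.outer(g_rt, g_dt)
                if config.intensity_noise == "poisson":
                    vals = rng.poisson(lam)
                else:
                    vals = np.rint(lam).astype(np.int64)
                ci, bi = np.nonzero(vals >= 1)
                if ci.size == 0:
                    continue
                v = vals[ci, bi]
                cols["rt"].append(rt_level[level][ci])
                cols["scanid"].append(cycles[ci])
                cols["mslevel"].append(np.full(ci.size, level, dtype=np.int8))
                cols["mz"].append(np.full(ci.size, mz_value))
                cols["intensity"].append(v.astype(np.uint64))
                cols["bin"].append(bins[bi])
                emitted[level] += int(v.sum())
        truths.append(
            CompoundTruth(
                precursor_mz=compound.precursor_mz,
                rt_apex=compound.rt_apex,
                dt_apex_bin=compound.dt_apex_bin,
                dt_apex_ms=config.drift_slope * compound.dt_apex_bin,
                emitted_intensity=emitted,
            )
        )

    if config.noise_points_per_scan > 0:
        k = config.noise_points_per_scan
        for level in (1, 2):
            n = config.n_cycles * k
            cols["rt"].append(np.repeat(rt_level[level], k))
            cols["scanid"].append(np.repeat(cycles, k))
            cols["mslevel"].append(np.full(n, level, dtype=np.int8))
            cols["mz"].append(rng.uniform(*config.noise_mz_range, n))
            cols["intensity"].append(
                rng.integers(1, config.noise_intensity_max + 1, n).astype(np.uint64)
            )
            cols["bin"].append(rng.integers(1, config.n_bins + 1, n).astype(np.int32))

    if not cols["rt"]:
        table = LongFormatSpectralTable.empty(has_ims=True)
    else:
        df = pd.DataFrame({k: np.concatenate(v) for k, v in cols.items()})
        # merge coincident points (noise landing on an existing key)
        df = (
            df.groupby(["mslevel", "scanid", "bin", "mz"], as_index=False, sort=True)
            .agg(rt=("rt", "first"), intensity=("intensity", "sum"))
        )
        df["dt"] = config.drift_slope * df["bin"].astype(np.float64)
        df = df[["rt", "scanid", "mslevel", "mz", "intensity", "bin", "dt"]]
        table = canonical_sort(LongFormatSpectralTable.from_dataframe(df))

    tdf = table.df
    n_records = {
        level: int((tdf["mslevel"] == level).sum()) for level in (1, 2)
    }
    total_intensity = {
        level: int(tdf.loc[tdf["mslevel"] == level, "intensity"].sum())
        for level in (1, 2)
    }
    truth = GroundTruth(truths, n_records, total_intensity)

    metadata = SampleMetadata(
        sample_name=f"synthetic-seed{config.seed}",
        analysis_name="simulated HDMSe acquisition",
        polarity="positive",
        has_ims=True,
        drift_calibration=DriftCalibration(
            slope=config.drift_slope, intercept=0.0, n_points=config.n_bins
        ),
        source_file="simulation",
        converter_name="parqms",
        converter_version=__version__,
        extras={"seed": str(config.seed), "synthetic": "true"},
    )
    return table, truth, metadata


def write_synthetic_mzml(
    table: LongFormatSpectralTable,
    metadata: SampleMetadata,
    path: str | Path,
    pad_zeros: bool = False,
) -> Path:
    """Render a table as mzML, one spectrum per (scanid, mslevel, bin) group.

    Scans carry drift-time annotations (IMS tables), declared MS levels
    and representative collision energies, so ingesting the output with
    :func:`~parqms.ingest_mzml.read_mzml` reproduces the input table under
    any level-attribution mode.  ``pad_zeros`` interleaves zero-intensity
    points around each real point, emulating profile-mode padding; the
    padding is dropped again at ingest.
    """
    df = table.df
    keys = ["scanid", "mslevel", "bin"] if table.has_ims else ["scanid", "mslevel"]
    spectra: list[MzmlSpectrum] = []
    if len(df):
        for i, (key, sub) in enumerate(df.sort_values(keys, kind="stable").groupby(keys, sort=True)):
            sub = sub.sort_values("mz", kind="stable")
            mz = sub["mz"].to_numpy(dtype=np.float64)
            inten = sub["intensity"].to_numpy(dtype=np.float64)
            if pad_zeros:
                mz, inten = _pad_with_zeros(mz, inten)
            level = int(key[1])
            spectra.append(
                MzmlSpectrum(
                    index=i,
                    native_id=f"scan={i + 1}",
                    ms_level=level,
                    rt_minutes=float(sub["rt"].iloc[0]),
                    drift_time_ms=float(sub["dt"].iloc[0]) if table.has_ims else None,
                    collision_energy_ev=LOW_CE_EV if level == 1 else HIGH_CE_EV,
                    mz=mz,
                    intensity=inten,
                )
            )
    return write_mzml(
        spectra,
        path,
        software_version=__version__,
        source_file=metadata.source_file or metadata.sample_name,
        instrument=metadata.instrument_descriptor,
    )


def _pad_with_zeros(mz: np.ndarray, inten: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    delta = 0.003  # Da; narrower than any simulated peak spacing
    pad_mz = np.concatenate([mz - delta, mz + delta])
    pad_mz = pad_mz[(pad_mz > 0) & ~np.isin(pad_mz, mz)]
    all_mz = np.concatenate([mz, pad_mz])
    all_int = np.concatenate([inten, np.zeros(len(pad_mz))])
    order = np.argsort(all_mz, kind="stable")
    return all_mz[order], all_int[order]


@dataclass
class ApexRecovery:
    precursor_mz: float
    true_rt_apex: float
    observed_rt_apex: float
    rt_error: float
    true_dt_apex_bin: float
    observed_apex_bin: int
    bin_error: float


def apex_recovery_check(
    table: LongFormatSpectralTable,
    ground_truth: GroundTruth,
    config: SimulationConfig,
    *,
    mz_tol: float = 0.005,
) -> list[ApexRecovery]:
    """Locate each compound's EIC and mobilogram apex and report errors.

    Works directly on the in-memory table (full scan); the apex is the
    argmax of the per-rt (resp. per-bin) summed intensity within a narrow
    m/z window around the precursor at level 1.
    """
    df = table.df
    out = []
    for truth in ground_truth.compounds:
        sel = df[
            (df["mslevel"] == 1)
            & (df["mz"] >= truth.precursor_mz - mz_tol)
            & (df["mz"] <= truth.precursor_mz + mz_tol)
        ]
        if len(sel) == 0:
            out.append(
                ApexRecovery(
                    truth.precursor_mz, truth.rt_apex, np.nan, np.inf,
                    truth.dt_apex_bin, -1, np.inf,
                )
            )
            continue
        chrom = sel.groupby("rt")["intensity"].sum()
        rt_apex = float(chrom.idxmax())
        mob = sel.groupby("bin")["intensity"].sum()
        bin_apex = int(mob.idxmax())
        out.append(
            ApexRecovery(
                precursor_mz=truth.precursor_mz,
                true_rt_apex=truth.rt_apex,
                observed_rt_apex=rt_apex,
                rt_error=abs(rt_apex - truth.rt_apex),
                true_dt_apex_bin=truth.dt_apex_bin,
                observed_apex_bin=bin_apex,
                bin_error=abs(bin_apex - truth.dt_apex_bin),
            )
        )
    return out


def demo_config(seed: int = 1, *, scale: float = 1.0) -> SimulationConfig:
    """A realistic default sample: five compounds over a 3-min gradient.

    ``scale`` < 1 shrinks the grid proportionally (fewer cycles and bins)
    for quick tests while keeping peak shapes on-grid.
    """
    n_cycles = max(40, int(round(600 * scale)))
    n_bins = max(10, int(round(200 * scale)))
    span = n_cycles * 0.005
    compounds = []
    base = [
        (151.0633, 0.20, 55, (152.0666, 0.11), [(110.0600, 0.6), (93.0335, 0.35)]),
        (230.0248, 0.38, 92, (231.0281, 0.13), [(186.0350, 0.5), (144.0450, 0.3)]),
        (278.1905, 0.55, 120, (279.1938, 0.17), [(233.1300, 0.45), (151.0750, 0.25)]),
        (454.2930, 0.72, 150, (455.2963, 0.28), [(380.2200, 0.5), (196.1130, 0.4)]),
        (609.2812, 0.88, 172, (610.2845, 0.33), [(448.2280, 0.55), (174.0550, 0.3)]),
    ]
    for mz, frac, bin200, iso, frags in base:
        compounds.append(
            CompoundSpec(
                precursor_mz=mz,
                rt_apex=frac * span,
                rt_sigma=0.015 * max(span / 3.0, 0.5),
                dt_apex_bin=bin200 * n_bins / 200.0,
                dt_sigma_bins=max(1.5, 3.0 * n_bins / 200.0),
                apex_intensity=5000.0,
                isotope_offsets=[(iso[0] - mz, iso[1])],
                fragments=frags,
            )
        )
    return SimulationConfig(
        n_cycles=n_cycles,
        n_bins=n_bins,
        compounds=compounds,
        noise_points_per_scan=30,
        noise_intensity_max=150,
        intensity_noise="none",
        seed=seed,
    )
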