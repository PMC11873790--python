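"""Shared fixtures: the worked five-row example table, naive full-scan
query oracles (pure-Python, independent of the library's pruning/groupby
path), and small synthetic sample factories."""

from __future__ import annotations

import pandas as pd
import pytest

import parqms

# The five-row worked example used throughout the docs and tests: two duty
# cycles' low-energy scans plus one high-energy scan, drift grid 0.071 ms/bin.
EXAMPLE_ROWS = [
    (0.0074, 1, 1, 105.9348, 57, 39, 2.769),
    (0.0074, 1, 1, 128.9497, 123, 35, 2.485),
    (0.0116, 1, 2, 172.8606, 19, 60, 4.260),
    (0.0158, 2, 1, 87.9227, 14, 40, 2.840),
    (0.0241, 3, 1, 128.9497, 96, 34, 2.414),
]
COLUMNS = ["rt", "scanid", "mslevel", "mz", "intensity", "bin", "dt"]


def example_df() -> pd.DataFrame:
    return pd.DataFrame(EXAMPLE_ROWS, columns=COLUMNS)


@pytest.fixture
def table1() -> parqms.LongFormatSpectralTable:
    return parqms.LongFormatSpectralTable.from_dataframe(example_df())


@pytest.fixture
def table1_metadata(table1) -> parqms.SampleMetadata:
    cal = parqms.fit_drift_calibration(
        list(zip(table1.df["bin"], table1.df["dt"]))
    )
    return parqms.SampleMetadata(
        sample_name="worked-example", has_ims=True, drift_calibration=cal
    )


@pytest.fixture
def table1_sample(tmp_path, table1, table1_metadata):
    """The five-row example written to Parquet; yields an open handle."""
    path = tmp_path / "worked-example.parquet"
    parqms.write_sample(table1, table1_metadata, path)
    return parqms.open_sample(path)


def small_config(seed: int = 1, **overrides) -> parqms.SimulationConfig:
    """A compact two-compound HDMSe run for fast tests."""
    defaults = dict(
        n_cycles=24,
        cycle_period=0.005,
        level2_rt_offset=0.002,
        n_bins=10,
        drift_slope=0.071,
        compounds=[
            parqms.CompoundSpec(
                precursor_mz=301.1410,
                rt_apex=0.040,
                rt_sigma=0.010,
                dt_apex_bin=4.0,
                dt_sigma_bins=1.2,
                apex_intensity=800.0,
                isotope_offsets=[(1.0033, 0.25)],
                fragments=[(155.0700, 0.5), (97.0290, 0.3)],
            ),
            parqms.CompoundSpec(
                precursor_mz=452.2780,
                rt_apex=0.080,
                rt_sigma=0.012,
                dt_apex_bin=7.0,
                dt_sigma_bins=1.0,
                apex_intensity=500.0,
                fragments=[(210.1120, 0.6)],
            ),
        ],
        noise_points_per_scan=6,
        noise_intensity_max=40,
        intensity_noise="none",
        seed=seed,
    )
    defaults.update(overrides)
    return parqms.SimulationConfig(**defaults)


# ---------------------------------------------------------------------------
# naive full-scan oracles (row-by-row over the raw DataFrame)


def oracle_tic(df: pd.DataFrame, level: int) -> list[tuple[float, int]]:
    acc: dict[float, int] = {}
    for row in df.itertuples(index=False):
        if int(row.mslevel) == level:
            acc[row.rt] = acc.get(row.rt, 0) + int(row.intensity)
    return sorted(acc.items())


def oracle_bpc(df: pd.DataFrame, level: int) -> list[tuple[float, int]]:
    acc: dict[float, int] = {}
    for row in df.itertuples(index=False):
        if int(row.mslevel) == level:
            acc[row.rt] = max(acc.get(row.rt, 0), int(row.intensity))
    return sorted(acc.items())


def oracle_eic(df: pd.DataFrame, lo: float, hi: float, level: int) -> list[tuple[float, int]]:
    acc: dict[float, int] = {}
    for row in df.itertuples(index=False):
        if int(row.mslevel) == level and lo <= row.mz <= hi:
            acc[row.rt] = acc.get(row.rt, 0) + int(row.intensity)
    return sorted(acc.items())


def oracle_mobilogram(
    df: pd.DataFrame, level: int, window=None
) -> list[tuple[int, float, int]]:
    acc: dict[int, int] = {}
    dts: dict[int, float] = {}
    for row in df.itertuples(index=False):
        if int(row.mslevel) != level:
            continue
        if window is not None and not (window[0] <= row.mz <= window[1]):
            continue
        b = int(row.bin)
        acc[b] = acc.get(b, 0) + int(row.intensity)
        dts[b] = row.dt
    return [(b, dts[b], acc[b]) for b in sorted(acc)]


def oracle_filter(df: pd.DataFrame, pred: parqms.RecordPredicate) -> list[tuple]:
    out = []
    for row in df.itertuples(index=False):
        if pred.mslevel is not None and int(row.mslevel) != pred.mslevel:
            continue
        if pred.rt_range is not None and not (pred.rt_range[0] <= row.rt <= pred.rt_range[1]):
            continue
        if pred.mz_range is not None and not (pred.mz_range[0] <= row.mz <= pred.mz_range[1]):
            continue
        if pred.bin_range is not None and not (pred.bin_range[0] <= row.bin <= pred.bin_range[1]):
            continue
        if pred.scanid_set is not None and int(row.scanid) not in pred.scanid_set:
            continue
        out.append(tuple(row))
    return sorted(out)


def table_rows(table: parqms.LongFormatSpectralTable) -> list[tuple]:
    return sorted(tuple(r) for r in table.df.itertuples(index=False))
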