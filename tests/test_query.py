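"""Chromatograms, spectra, mobilograms, filters, and the lazy-access contract."""

import numpy as np
import pandas as pd
import pytest

import parqms
from parqms.errors import CapabilityError, DomainError, NotFoundError

from conftest import (
    COLUMNS,
    example_df,
    oracle_bpc,
    oracle_eic,
    oracle_filter,
    oracle_mobilogram,
    oracle_tic,
    small_config,
    table_rows,
)


def store(tmp_path, table, meta, name="s.parquet", **options):
    report = parqms.write_sample(
        table, meta, tmp_path / name, parqms.WriteOptions(**options) if options else None
    )
    return parqms.open_sample(report.path)


class TestChromatograms:
    def test_tic_level1_hand_summed(self, table1_sample):
        assert parqms.tic(table1_sample, 1).points == [
            (0.0074, 180),
            (0.0158, 14),
            (0.0241, 96),
        ]

    def test_tic_level2_single_point(self, table1_sample):
        assert parqms.tic(table1_sample, 2).points == [(0.0116, 19)]

    def test_tic_accepts_string_level(self, table1_sample):
        assert parqms.tic(table1_sample, "2").points == [(0.0116, 19)]

    def test_empty_file_empty_series(self, tmp_path):
        t = parqms.LongFormatSpectralTable.empty(has_ims=False)
        handle = store(tmp_path, t, parqms.SampleMetadata(sample_name="e"))
        assert parqms.tic(handle, 1).points == []
        assert parqms.bpc(handle, 2).points == []

    def test_bpc_level1_max_per_rt(self, table1_sample):
        assert parqms.bpc(table1_sample, 1).points == [
            (0.0074, 123),
            (0.0158, 14),
            (0.0241, 96),
        ]

    def test_bpc_equals_tic_for_single_record_rts(self, table1_sample):
        # level 2 holds one record, so max == sum
        assert parqms.bpc(table1_sample, 2).points == parqms.tic(table1_sample, 2).points

    def test_eic_narrow_window(self, table1_sample):
        series = parqms.eic(table1_sample, 128.94, 128.95, 1)
        assert series.points == [(0.0074, 123), (0.0241, 96)]

    def test_eic_full_range_equals_tic(self, table1_sample):
        assert (
            parqms.eic(table1_sample, 0.0, 1e6, 1).points
            == parqms.tic(table1_sample, 1).points
        )

    def test_eic_inverted_interval(self, table1_sample):
        with pytest.raises(DomainError, match="inverted"):
            parqms.eic(table1_sample, 200.0, 100.0, 1)

    def test_eic_around_da_and_ppm(self, table1_sample):
        da = parqms.eic_around(table1_sample, 128.9497, 1, tol_da=0.005)
        ppm = parqms.eic_around(table1_sample, 128.9497, 1, tol_ppm=40.0)
        assert da.points == ppm.points == [(0.0074, 123), (0.0241, 96)]
        with pytest.raises(DomainError):
            parqms.eic_around(table1_sample, 128.9497, 1)


class TestSpectrumAt:
    def test_high_energy_scan(self, table1_sample):
        s = parqms.spectrum_at(table1_sample, 1, 2)
        assert s.points == [(172.8606, 19)] and s.rt == 0.0116

    def test_scan3_level1(self, table1_sample):
        s = parqms.spectrum_at(table1_sample, 3, 1)
        assert s.points == [(128.9497, 96)]

    def test_unknown_scan_raises(self, table1_sample):
        with pytest.raises(NotFoundError):
            parqms.spectrum_at(table1_sample, 99, 1)

    def test_per_bin_breakdown_sums_to_collapsed(self, tmp_path):
        table, _, meta = parqms.simulate_sample(small_config(seed=3))
        handle = store(tmp_path, table, meta)
        scanid = int(table.df["scanid"].iloc[0])
        collapsed = parqms.spectrum_at(handle, scanid, 1, collapse_bins=True)
        split = parqms.spectrum_at(handle, scanid, 1, collapse_bins=False)
        total_split = sum(int(v.sum()) for _, v in split.per_bin.values())
        assert total_split == int(collapsed.intensity.sum())


class TestMobilogram:
    def test_grouped_printed_rows(self, table1_sample):
        series = parqms.mobilogram(table1_sample, 1)
        assert [(b, v) for b, _, v in series.points] == [
            (34, 96),
            (35, 123),
            (39, 57),
            (40, 14),
        ]
        for b, d, _ in series.points:
            assert d == pytest.approx(0.071 * b, abs=5e-4)

    def test_window_excluding_all_mz(self, table1_sample):
        assert len(parqms.mobilogram(table1_sample, 1, (5000.0, 6000.0))) == 0

    def test_non_ims_sample_capability_error(self, tmp_path):
        df = example_df().drop(columns=["bin", "dt"])
        t = parqms.LongFormatSpectralTable.from_dataframe(df)
        handle = store(tmp_path, t, parqms.SampleMetadata(sample_name="noims"))
        with pytest.raises(CapabilityError):
            parqms.mobilogram(handle, 1)


class TestFilterRecords:
    def test_level2_single_row(self, table1_sample):
        got = parqms.filter_records(table1_sample, parqms.RecordPredicate(mslevel=2))
        assert [tuple(r) for r in got.df.itertuples(index=False)] == [
            (0.0116, 1, 2, 172.8606, 19, 60, 4.260)
        ]

    def test_empty_predicate_identity(self, table1_sample, table1):
        got = parqms.filter_records(table1_sample, parqms.RecordPredicate())
        assert got == parqms.canonical_sort(table1)

    def test_inverted_range_rejected(self):
        with pytest.raises(DomainError):
            parqms.RecordPredicate(rt_range=(2.0, 1.0))


class TestBasePeak:
    def test_worked_example(self, table1_sample):
        rec = parqms.base_peak_record(table1_sample)
        assert (rec.intensity, rec.mz, rec.rt) == (123, 128.9497, 0.0074)

    def test_single_row_scope(self, table1_sample):
        rec = parqms.base_peak_record(table1_sample, mslevel=2)
        assert rec.intensity == 19 and rec.scanid == 1

    def test_tie_broken_by_lowest_rt_then_mz(self, tmp_path):
        rows = [
            (0.2, 2, 1, 300.0, 50, 1, 0.071),
            (0.1, 1, 1, 400.0, 50, 1, 0.071),
            (0.1, 1, 1, 350.0, 50, 2, 0.142),
        ]
        t = parqms.LongFormatSpectralTable.from_dataframe(pd.DataFrame(rows, columns=COLUMNS))
        meta = parqms.SampleMetadata(
            sample_name="tie", has_ims=True,
            drift_calibration=parqms.DriftCalibration(slope=0.071),
        )
        rec = parqms.base_peak_record(store(tmp_path, t, meta))
        assert (rec.rt, rec.mz) == (0.1, 350.0)

    def test_empty_scope(self, tmp_path):
        t = parqms.LongFormatSpectralTable.empty(has_ims=False)
        handle = store(tmp_path, t, parqms.SampleMetadata(sample_name="e"))
        with pytest.raises(NotFoundError):
            parqms.base_peak_record(handle)


class TestConservation:
    def test_tic_sums_partition_total_intensity(self, tmp_path):
        table, truth, meta = parqms.simulate_sample(small_config(seed=9))
        handle = store(tmp_path, table, meta)
        total = 0
        for level in (1, 2):
            series = parqms.tic(handle, level)
            level_sum = int(series.intensity.sum())
            assert level_sum == truth.total_intensity[level]
            total += level_sum
        assert total == int(table.df["intensity"].sum())

    def test_eic_never_exceeds_tic(self, tmp_path):
        table, _, meta = parqms.simulate_sample(small_config(seed=13))
        handle = store(tmp_path, table, meta)
        full = dict(parqms.tic(handle, 1).points)
        sub = parqms.eic(handle, 150.0, 400.0, 1)
        for rt, v in sub.points:
            assert v <= full[rt]

    def test_bpc_never_exceeds_tic(self, tmp_path):
        table, _, meta = parqms.simulate_sample(small_config(seed=14))
        handle = store(tmp_path, table, meta)
        full = dict(parqms.tic(handle, 2).points)
        for rt, v in parqms.bpc(handle, 2).points:
            assert v <= full[rt]


class TestOracleEquivalence:
    """Every query equals a naive row-by-row full scan (spot check here;
    the broader randomized sweep runs in the acceptance suite)."""

    @pytest.mark.parametrize("seed", [21, 22, 23])
    def test_randomized_sample(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        cfg = small_config(
            seed=seed,
            n_cycles=int(rng.integers(6, 16)),
            n_bins=int(rng.integers(4, 12)),
            noise_points_per_scan=int(rng.integers(0, 8)),
            intensity_noise=["none", "poisson"][int(rng.integers(0, 2))],
        )
        table, _, meta = parqms.simulate_sample(cfg)
        handle = store(tmp_path, table, meta, row_group_target_rows=max(1, table.n_records // 7))
        df = table.df
        for level in (1, 2):
            assert parqms.tic(handle, level).points == oracle_tic(df, level)
            assert parqms.bpc(handle, level).points == oracle_bpc(df, level)
        lo, hi = sorted(rng.uniform(*cfg.noise_mz_range, 2))
        assert parqms.eic(handle, lo, hi, 1).points == oracle_eic(df, lo, hi, 1)
        got = parqms.mobilogram(handle, 2, (lo, hi))
        assert got.points == oracle_mobilogram(df, 2, (lo, hi))
        pred = parqms.RecordPredicate(
            mslevel=1,
            rt_range=(0.0, float(rng.uniform(0, cfg.n_cycles * cfg.cycle_period))),
            mz_range=(lo, hi),
        )
        assert table_rows(parqms.filter_records(handle, pred)) == oracle_filter(df, pred)


class TestLazyAccess:
    def test_narrow_eic_prunes_row_groups(self, tmp_path):
        table, _, meta = parqms.simulate_sample(small_config(seed=31, n_cycles=60))
        handle = store(
            tmp_path, table, meta, row_group_target_rows=max(1, table.n_records // 12)
        )
        assert handle.n_row_groups > 1
        target = small_config().compounds[0].precursor_mz
        series = parqms.eic(handle, target - 0.01, target + 0.01, 1)
        stats = series.scan_stats
        assert stats.row_groups_total == handle.n_row_groups
        assert stats.row_groups_read < stats.row_groups_total

    def test_level_filter_prunes(self, tmp_path):
        table, _, meta = parqms.simulate_sample(small_config(seed=32))
        handle = store(
            tmp_path, table, meta, row_group_target_rows=max(1, table.n_records // 6)
        )
        series = parqms.tic(handle, 1)
        assert series.scan_stats.row_groups_read < series.scan_stats.row_groups_total
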