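"""mzML ingestion: level mapping, cycle/bin assignment, losslessness."""

import numpy as np
import pandas as pd
import pytest

import parqms
from parqms._mzml import MzmlSpectrum, write_mzml
from parqms.errors import DomainError, IngestError, LevelMappingError, MzmlParseError
from parqms.ingest_mzml import SpectrumHeader

from conftest import COLUMNS, small_config


def header(i, level=1, dt=None, ce=None, rt=0.0):
    return SpectrumHeader(
        index=i, native_id=f"scan={i + 1}", ms_level_declared=level,
        scan_start_time=rt, drift_time=dt, collision_energy=ce,
    )


class TestLevelMapping:
    def test_collision_energy_threshold(self):
        cfg = parqms.LevelMapConfig(mode="collision_energy_threshold", ce_threshold=15.0)
        assert parqms.map_ms_level(header(0, ce=6.0), cfg) == 1
        assert parqms.map_ms_level(header(0, ce=30.0), cfg) == 2

    def test_declared_passthrough_and_clamp(self):
        cfg = parqms.LevelMapConfig(mode="declared")
        assert parqms.map_ms_level(header(0, level=1), cfg) == 1
        assert parqms.map_ms_level(header(0, level=2), cfg) == 2
        assert parqms.map_ms_level(header(0, level=3), cfg) == 2

    def test_threshold_without_ce_names_spectrum(self):
        cfg = parqms.LevelMapConfig(mode="collision_energy_threshold")
        with pytest.raises(LevelMappingError, match="scan=1"):
            parqms.map_ms_level(header(0, ce=None), cfg)

    def test_override_map_wins(self):
        cfg = parqms.LevelMapConfig(mode="declared", override_map={"scan=1": 2})
        assert parqms.map_ms_level(header(0, level=1), cfg) == 2


class TestAssignCycles:
    def test_alternating_no_ims(self):
        headers = [header(0, 1), header(1, 2), header(2, 1), header(3, 2)]
        got = parqms.assign_cycles(headers, parqms.LevelMapConfig())
        assert got == [(1, 1), (1, 2), (2, 1), (2, 2)]

    def test_single_scan(self):
        assert parqms.assign_cycles([header(0, 1)], parqms.LevelMapConfig()) == [(1, 1)]

    def test_drift_resolved_subspectra_share_scanid(self):
        dts = [0.5, 1.0, 1.5, 2.0, 2.5]
        headers = (
            [header(i, 1, dt=d) for i, d in enumerate(dts)]
            + [header(5 + i, 2, dt=d) for i, d in enumerate(dts)]
            + [header(10 + i, 1, dt=d) for i, d in enumerate(dts)]
        )
        got = parqms.assign_cycles(headers, parqms.LevelMapConfig())
        assert got[:10] == [(1, 1)] * 5 + [(1, 2)] * 5
        assert got[10:] == [(2, 1)] * 5

    def test_consecutive_high_energy_groups_warn_and_increment(self):
        headers = [header(0, 1), header(1, 2), header(2, 2, rt=0.1)]
        with pytest.warns(UserWarning, match="consecutive high-energy"):
            got = parqms.assign_cycles(headers, parqms.LevelMapConfig())
        assert got == [(1, 1), (1, 2), (2, 2)]

    def test_mixed_ims_presence_rejected(self):
        headers = [header(0, 1, dt=1.0), header(1, 1)]
        with pytest.raises(IngestError, match="scan=2"):
            parqms.assign_cycles(headers, parqms.LevelMapConfig())

    def test_alternating_mode_ignores_declarations(self):
        headers = [header(0, 1), header(1, 1), header(2, 1), header(3, 1)]
        got = parqms.assign_cycles(
            headers, parqms.LevelMapConfig(mode="alternating")
        )
        assert got == [(1, 1), (1, 2), (2, 1), (2, 2)]


class TestAssignBins:
    def test_rank_transform_of_printed_drift_times(self):
        assert parqms.assign_bins([2.485, 2.769, 4.260]) == [1, 2, 3]

    def test_single_bin(self):
        assert parqms.assign_bins([5.0]) == [1]

    def test_full_grid_recovers_slope(self):
        dts = [0.071 * k for k in range(1, 201)]
        bins = parqms.assign_bins(dts)
        assert bins == list(range(1, 201))
        cal = parqms.fit_drift_calibration(list(zip(bins, dts)))
        assert cal.slope == pytest.approx(0.071, rel=1e-12)

    def test_order_invariance(self):
        dts = [2.769, 2.485, 4.260, 2.485]
        assert parqms.assign_bins(dts) == [2, 1, 3, 1]

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(DomainError):
            parqms.assign_bins([1.0, -0.5])


class TestReadMzml:
    def grid_table(self):
        """10 cycles x 2 levels x 5 bins x 3 points, all nonzero."""
        rows = []
        for c in range(1, 11):
            for level in (1, 2):
                rt = (c - 1) * 0.01 + (0.004 if level == 2 else 0.0)
                for b in range(1, 6):
                    for j in range(3):
                        rows.append(
                            (rt, c, level, 100.0 + 10 * j + 0.01 * b, 5 + c + j, b, 0.071 * b)
                        )
        return parqms.LongFormatSpectralTable.from_dataframe(
            pd.DataFrame(rows, columns=COLUMNS)
        )

    def meta(self):
        return parqms.SampleMetadata(
            sample_name="grid", has_ims=True,
            drift_calibration=parqms.DriftCalibration(slope=0.071),
        )

    def test_record_count_matches_generator(self, tmp_path):
        table = self.grid_table()
        path = tmp_path / "grid.mzML"
        parqms.write_synthetic_mzml(table, self.meta(), path)
        got, meta = parqms.read_mzml(path)
        assert got.n_records == 10 * 2 * 5 * 3 == 300
        assert got == parqms.canonical_sort(table)
        assert meta.has_ims and meta.drift_calibration.slope == pytest.approx(0.071)

    def test_losslessness_intensity_sum(self, tmp_path):
        table = self.grid_table()
        path = tmp_path / "grid.mzML"
        parqms.write_synthetic_mzml(table, self.meta(), path)
        got, _ = parqms.read_mzml(path)
        assert int(got.df["intensity"].sum()) == int(table.df["intensity"].sum())

    def test_zero_padding_dropped(self, tmp_path):
        table = self.grid_table()
        p1, p2 = tmp_path / "plain.mzML", tmp_path / "padded.mzML"
        parqms.write_synthetic_mzml(table, self.meta(), p1, pad_zeros=False)
        parqms.write_synthetic_mzml(table, self.meta(), p2, pad_zeros=True)
        t1, _ = parqms.read_mzml(p1)
        t2, _ = parqms.read_mzml(p2)
        assert t1 == t2

    def test_empty_spectrum_contributes_nothing(self, tmp_path):
        spectra = [
            MzmlSpectrum(
                index=0, native_id="scan=1", ms_level=1, rt_minutes=0.01,
                drift_time_ms=None, collision_energy_ev=6.0,
                mz=np.array([100.0]), intensity=np.array([42.0]),
            ),
            MzmlSpectrum(
                index=1, native_id="scan=2", ms_level=1, rt_minutes=0.02,
                drift_time_ms=None, collision_energy_ev=6.0,
            ),
        ]
        path = tmp_path / "empty.mzML"
        write_mzml(spectra, path)
        table, _ = parqms.read_mzml(path)
        assert table.n_records == 1

    def test_gzip_compressed_input(self, tmp_path):
        table = self.grid_table()
        path = tmp_path / "grid.mzML.gz"
        parqms.write_synthetic_mzml(table, self.meta(), path)
        got, _ = parqms.read_mzml(path)
        assert got == parqms.canonical_sort(table)

    def test_level_attribution_modes_agree_on_synthetic(self, tmp_path):
        table, _, meta = parqms.simulate_sample(small_config(seed=7))
        path = tmp_path / "s.mzML"
        parqms.write_synthetic_mzml(table, meta, path)
        declared, _ = parqms.read_mzml(path)
        threshold, _ = parqms.read_mzml(
            path, parqms.LevelMapConfig(mode="collision_energy_threshold")
        )
        alternating, _ = parqms.read_mzml(path, parqms.LevelMapConfig(mode="alternating"))
        assert declared == threshold == alternating

    def test_truncated_document_raises_parse_error(self, tmp_path):
        table = self.grid_table()
        path = tmp_path / "grid.mzML"
        parqms.write_synthetic_mzml(table, self.meta(), path)
        raw = path.read_bytes()
        bad = tmp_path / "trunc.mzML"
        bad.write_bytes(raw[: len(raw) // 2])
        with pytest.raises(MzmlParseError, match="line"):
            parqms.read_mzml(bad)


@pytest.mark.parametrize("seed", [11, 12])
def test_mzr_oracle_agrees_on_tiny_fixture(tmp_path, seed):
    """Cross-check the hand-written mzML layer against Bioconductor mzR."""
    import shutil
    import subprocess

    if shutil.which("Rscript") is None:
        pytest.skip("Rscript unavailable")
    cfg = small_config(seed=seed, n_cycles=6, noise_points_per_scan=2)
    table, _, meta = parqms.simulate_sample(cfg)
    path = tmp_path / "tiny.mzML"
    parqms.write_synthetic_mzml(table, meta, path)
    script = tmp_path / "oracle.R"
    script.write_text(
        'suppressMessages(library(mzR))\n'
        f'f <- openMSfile("{path}")\n'
        "h <- header(f); p <- peaks(f)\n"
        'cat(nrow(h), sum(sapply(p, function(m) sum(m[,2]))), sep="\\n")\n'
    )
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, check=True
    ).stdout.split()
    n_spectra_r, total_intensity_r = int(out[0]), float(out[1])
    keys = ["scanid", "mslevel", "bin"]
    assert n_spectra_r == table.df.groupby(keys).ngroups
    assert total_intensity_r == float(table.df["intensity"].sum())
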