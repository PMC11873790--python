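# parqms

Long-format columnar storage and fast filtered access for
data-independent-acquisition mass spectrometry, with optional ion
mobility.

## The problem

Waters-style MS^E acquisitions fragment *all* ions by alternating a
low-collision-energy scan and a high-collision-energy scan every duty
cycle; with an ion-mobility cell in the path (HDMS^E) each scan is
further split into drift-time-resolved sub-spectra. The resulting runs
are awkward to work with: vendor formats are opaque, and XML-based open
formats (mzML) produce multi-gigabyte files whose parsing dominates any
downstream analysis and whose structure resists random access.

`parqms` stores such data the way analysts actually query it: as a
sparse **long-format table** — one row per detected point — in Apache
Parquet. Each row carries

| column | meaning |
|---|---|
| `rt` | retention time (minutes) |
| `scanid` | duty-cycle number, shared by the low- and high-energy scans of one cycle |
| `mslevel` | collision-energy function: 1 = low energy, 2 = high energy |
| `mz` | mass-to-charge ratio (Th) |
| `intensity` | detector counts (> 0; zero points are not stored) |
| `bin` | drift-bin index (1-based; ion-mobility samples only) |
| `dt` | drift time (ms), a linear function of `bin`: `dt = a·bin + b` |

Because files are written sorted by `(mslevel, scanid, bin, mz)` with
per-row-group column statistics, chromatograms and windowed extractions
become predicate-pushdown scans: row groups that cannot match are never
read, so a narrow EIC on a large run touches a small fraction of the
file. Sample metadata (identity, acquisition descriptors, the fitted
drift calibration, provenance) travels both embedded in the Parquet
key-value metadata and as a JSON sidecar.

The package provides:

- **`parqms.ingest_mzml`** — a streaming mzML 1.1 reader that assembles
  a validated long-format table; MS-level attribution is configurable
  (declared `msLevel`, collision-energy threshold, or strict
  alternation), drift bins are recovered by ranking per-scan drift
  times, and the `bin → dt` calibration is fitted by through-origin
  least squares.
- **`parqms.parquet_store`** — bit-exact round-trip writing/reading with
  mirrored metadata.
- **`parqms.query`** — lazy TIC/BPC/EIC, spectrum slices, mobilograms,
  generic record filters, base-peak lookup; every result records how
  many row groups were actually read.
- **`parqms.synthetic`** — a ground-truthed HDMS^E simulator (Gaussian
  peaks in rt and drift, isotopes, co-drifting fragments, chemical and
  Poisson noise) plus an mzML renderer, so the whole pipeline is
  testable without instrument data.
- **`parqms` CLI** — `convert`, `info`, `validate`, `simulate`, `tic`,
  `bpc`, `eic`, `spectrum`, `mobilogram`.

## Worked example

Five rows spanning three duty cycles (two low-energy scans of cycle 1,
the high-energy scan of cycle 1, and one low-energy scan each of cycles
2 and 3), on a 0.071 ms/bin drift grid:

```python
import pandas as pd
import parqms

rows = [
    (0.0074, 1, 1, 105.9348,  57, 39, 2.769),
    (0.0074, 1, 1, 128.9497, 123, 35, 2.485),
    (0.0116, 1, 2, 172.8606,  19, 60, 4.260),
    (0.0158, 2, 1,  87.9227,  14, 40, 2.840),
    (0.0241, 3, 1, 128.9497,  96, 34, 2.414),
]
cols = ["rt", "scanid", "mslevel", "mz", "intensity", "bin", "dt"]
table = parqms.LongFormatSpectralTable.from_dataframe(pd.DataFrame(rows, columns=cols))

cal = parqms.fit_drift_calibration(list(zip(table.df["bin"], table.df["dt"])))
meta = parqms.SampleMetadata(sample_name="worked-example", has_ims=True,
                             drift_calibration=cal)
parqms.write_sample(table, meta, "worked-example.parquet")

handle = parqms.open_sample("worked-example.parquet")
print("TIC level 1:", parqms.tic(handle, 1).points)
print("BPC level 1:", parqms.bpc(handle, 1).points)
print("EIC 128.94-128.95:", parqms.eic(handle, 128.94, 128.95, 1).points)
print("mobilogram level 1:", parqms.mobilogram(handle, 1).points)
print("base peak:", parqms.base_peak_record(handle))
print(f"drift calibration: dt = {cal.slope:.3f} ms/bin "
      f"(n={cal.n_points}, max residual {cal.max_residual:.1e} ms)")
```

prints

```
TIC level 1: [(0.0074, 180), (0.0158, 14), (0.0241, 96)]
BPC level 1: [(0.0074, 123), (0.0158, 14), (0.0241, 96)]
EIC 128.94-128.95: [(0.0074, 123), (0.0241, 96)]
mobilogram level 1: [(34, 2.414, 96), (35, 2.485, 123), (39, 2.769, 57), (40, 2.84, 14)]
base peak: SpectralRecord(rt=0.0074, scanid=1, mslevel=1, mz=128.9497, intensity=123, bin=35, dt=2.485)
drift calibration: dt = 0.071 ms/bin (n=5, max residual 8.9e-16 ms)
```

Reading: the level-1 TIC at rt 0.0074 sums the two coincident points
(57 + 123 = 180) while the BPC keeps their maximum (123); the EIC
isolates the 128.9497 Th trace across cycles 1 and 3; the mobilogram
redistributes the same intensities over drift bins; and the drift times
sit exactly on a 0.071 ms/bin line through the origin. The same queries
are available from a shell:

```
$ parqms tic worked-example.parquet --mslevel 2
0.0116,19
```

— the lone high-energy record. A realistic synthetic sample for
experimenting comes from `parqms.demo_config()` /
`parqms simulate`.

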