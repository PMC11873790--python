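# Methods

## Data model

A sample is a sparse long-format table: one row per detected nonzero
(m/z, intensity) point, with columns `rt, scanid, mslevel, mz,
intensity` and, for ion-mobility acquisitions, `bin, dt`. The model
encodes MS^E / HDMS^E semantics directly:

- `mslevel` is the collision-energy function (1 = low, 2 = high), not a
  fragmentation hierarchy; both functions of one duty cycle share a
  `scanid` even though their retention times differ by the intra-cycle
  offset.
- `bin`/`dt` are either present everywhere (IMS sample) or absent
  entirely; they are never null-filled. Within a table `dt` is a
  function of `bin`, and the two are related linearly by the drift
  calibration `dt = a·bin + b` with `a > 0`.
- Zero-intensity points are not stored: profile padding carries no
  information in a long format, and sparseness is what makes the
  columnar rendering compact. Ingest can retain zeros
  (`drop_zeros=False`) for forensic comparisons, at the cost of a
  validation failure.

Units: `rt` in minutes, `dt` in milliseconds. These match vendor
convention and the magnitudes of typical UPLC-IMS-QTOF runs; they are
recorded in the sample metadata (`rt_unit`, `dt_unit`) so alternative
conventions remain representable rather than implicit.

Validation distinguishes violations (zero intensities, non-positive
m/z, multiple rt per scan group, `dt` not a function of `bin`, scanid
order disagreeing with rt order) from warnings (non-integral
intensities, which some converters emit after transformation; they are
flagged but tolerated).

Canonical order is `(mslevel, scanid, bin, mz)` ascending, stable in
ties, with the absent `bin` sorting as a constant. The sort is what
makes on-disk statistics selective (below); it is idempotent and
verdict-preserving, so it can be applied defensively.

### Drift calibration

The default fit is through-origin least squares, slope
`Σ(bin·dt)/Σ(bin²)`: observed drift grids are consistent with a zero
intercept, and a one-parameter model extrapolates better from few
distinct bins. A free-intercept ordinary-least-squares mode is
available for instruments with a fixed gate delay. The fit reports its
largest absolute residual so a mis-specified grid is visible rather
than silently averaged away.

## mzML ingestion

The reader is a streaming ElementTree parser covering the subset of
mzML 1.1 this package emits and its tests exercise: plain or gzipped
documents, 32/64-bit float binary arrays with zlib or no compression,
scan start times in minutes or seconds (normalized to minutes),
per-scan drift-time annotations and collision energies (read from the
scan, falling back to precursor activation). Peak memory is bounded by
one spectrum plus the growing output columns. Numpress arrays,
chromatogram lists and vendor raw access are out of scope.

Level attribution is configurable because converted DIA files disagree
on how the high-energy function is marked:

- `declared` (default): trust `msLevel`, clamped to {1, 2};
- `collision_energy_threshold`: level 2 iff CE > threshold (default
  15 eV, between typical low-energy settings around 6 eV and
  high-energy ramps of 20 eV and above);
- `alternating`: ignore annotations; scan groups alternate 1, 2, 1, 2
  in file order.

Cycle assignment groups consecutive spectra into scan groups (a
drift-time reset or a level change opens a new group; without IMS every
spectrum is its own group) and increments `scanid` whenever a new group
does not move up in level. Two consecutive high-energy groups emit a
structure warning but still advance the cycle, so malformed files
ingest with an audit trail instead of failing.

Drift bins are recovered by a rank transform: distinct drift times,
after rounding to 6 decimals (drift times are instrument-quantized;
the rounding prevents spurious bin explosion from float noise), receive
ascending 1-based indices file-wide. This makes bin assignment
invariant to cycle order. One consequence is worth stating plainly:
bin indices are recoverable from an mzML rendering only if every
mobility channel between 1 and the maximum is observed somewhere in the
file. Real acquisitions satisfy this trivially (every frame covers all
bins); synthetic identity tests use configurations whose noise floor
covers the grid, and assert that density before relying on it.

## Parquet storage

Physical schema: `rt`, `mz`, `dt` as 64-bit floats (no lossy
encoding — round trips are bit-exact), `intensity` as unsigned 64-bit,
`bin` as 32-bit integer, `scanid` as 64-bit integer, and `mslevel` as a
dictionary-encoded *string* ("1"/"2"). The string encoding is
deliberate byte-level compatibility with files produced by the R
converter this format originates from, whose own access examples filter
`mslevel == '1'`; in memory the semantic type is a small integer and
the query layer accepts either form.

Writes sort canonically by default, enable per-row-group statistics,
and default to zstd compression with row groups of 2^20 rows. The
metadata document (identity, acquisition descriptors, drift
calibration, provenance, schema version `longformat-1`, plus an open
`extras` map) is serialized once — UTF-8 JSON, sorted keys — and stored
twice: under the Parquet key-value key `sample_metadata` and as a
`<stem>-metadata.json` sidecar. The embedded copy is authoritative; the
sidecar is a fallback (with a warning) and a tamper check: if both
exist and disagree, reading errors rather than guessing.

## Query layer

Opening a sample touches only the footer. Each query then runs a
two-stage scan: row groups whose min/max statistics cannot satisfy the
predicate are skipped, and the survivors are read with column
projection and filtered exactly. Because the file is sorted with
`mslevel` outermost, a level filter alone typically halves the scan,
and rt/scanid/bin statistics are monotone within a level, so
chromatographic and mobility windows prune further. Every result
carries a `ScanStats` (row groups total/read, rows read) making the
lazy-access contract observable and testable rather than assumed.

Semantics chosen where reasonable alternatives existed:

- intervals are closed `[lo, hi]` everywhere — the natural reading of
  "within a range", documented to avoid off-by-one-ulp surprises;
- rt grouping uses exact stored values; the low- and high-energy scans
  of one cycle are *not* merged onto a common rt for display;
- empty results are empty series, not errors — except a mobilogram on a
  non-IMS sample, where the dimension is structurally absent and a
  capability error is raised;
- the base-peak record breaks intensity ties by lowest rt, then lowest
  m/z, so the answer is deterministic on quantized data.

## Synthetic samples

The generator emulates an alternating-energy HDMS^E acquisition on a
regular grid: `n_cycles` duty cycles of `cycle_period` minutes, the
high-energy scan offset by `level2_rt_offset` within the cycle, and
`n_bins` drift bins with `dt = drift_slope·bin`. Defaults — 600 cycles
of 0.005 min (a 3-minute gradient), 200 bins at 0.071 ms/bin — mirror a
short run on the instrument class this format targets.

Each compound contributes a separable Gaussian,

    I(c, b) = A · exp(−(rt_c − rt_apex)² / 2σ_rt²)
                · exp(−(b − b_apex)² / 2σ_b²) · α_s ,

where `α_s` is the relative abundance of the species: at level 1 the
precursor (α = 1) and its isotopologues; at level 2 the fragments plus
the precursor attenuated by a survival factor (default 0.2). Fragments
inherit the precursor's drift profile, as co-drifting fragments do in
HDMS^E. Contributions are rounded to integer counts (or Poisson-sampled
with the model value as mean) and emitted only when ≥ 1 count, which
guarantees the no-zero-rows invariant. Chemical noise adds a fixed
number of uniform (m/z, bin) points per scan. A single seeded NumPy
generator drives all randomness; identical configurations produce
bit-identical tables. Coincident points (noise landing on an occupied
key) are merged by summation so the table has one row per
(scanid, level, bin, m/z).

Ground truth records, per compound, the true apexes and the emitted
intensity per level (accumulated during generation, so conservation
against the table is exact in the noise-free case), and per sample the
record and intensity totals per level.

What the generator does *not* emulate — and therefore what passing
tests cannot show about real data: peak tailing (no exponentially
modified Gaussians), mass-accuracy drift or peak width in m/z (species
are delta functions in m/z), detector saturation, realistic isotope
patterns derived from formulas, and inter-scan rt jitter. The mzML
renderer writes one spectrum per (scanid, level, bin) group with
repr-precision text attributes for rt and dt, so float values survive
the XML round trip bit-exactly; binary arrays are 64-bit floats.

The mzML layer is additionally cross-checked in the test suite against
an independent reader (Bioconductor's mzR, driven through Rscript) on a
tiny fixture, comparing spectrum counts and intensity totals.

## Problem sizes and numerical choices

Unit and acceptance tests run on reduced grids — typically 5–80 cycles
and 3–20 bins with a handful of compounds, and a half-scale (300-cycle,
100-bin) sample for the size comparison — chosen so the full suite
completes in seconds while every code path (multi-row-group files,
both noise models, empty levels, dense and sparse mobility grids) is
still exercised. The randomized query sweep uses 100 samples with
freshly drawn grids, windows and predicates per sample.

Numerical conventions: drift-time equality across cycles is decided at
6 decimals (ms); calibration recovery is asserted to 1e-12 relative
error; table equality everywhere means bit-exact cell equality after
canonical sort, never approximate comparison — the storage path is
designed to make that achievable, so the tests demand it.

## Known limitations

Single-file samples only (no partitioned multi-sample datasets, no
object-store transport, no encryption); no peak picking, centroiding,
alignment or deconvolution (downstream tools own those); no CCS
derivation from drift time; no mz5/mzMLb/numpress support; level
attribution beyond two collision-energy functions (e.g. SONAR or
multi-function methods) is out of scope.
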