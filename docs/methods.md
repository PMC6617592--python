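# Methods

## The measurement model

A nadir line-scanning LiDAR travels along a column of sown row plots at
constant speed, emitting lateral sweeps at a fixed line rate. Each sweep is
stored as one scan line: an odometer position `x` plus a fixed grid of
lateral positions `y` with a rectified height `z` per sample (mm above the
stream's datum). Rectification from the sensor's polar returns
(`lateral = r sin θ`, `height = sensor_height − r cos θ`, θ from nadir) is
provided in `preprocess.polar_to_heights`; storing heights rather than raw
ranges keeps everything downstream sensor-agnostic. Samples with no usable
return are held as NaN in memory and `NA` on disk, and are excluded — never
interpolated — on the per-scan-integral path.

The per-plot LiDAR Volume is

    LV = (Σ per-scan cross-section integrals) × distance / number of scans,

i.e. the mean lateral cross-section area of canopy height above the virtual
cut, multiplied by the along-track distance covered. This reading is chosen
because it is the only one that makes LV invariant to scan rate: rescanning
the same plot with twice the line rate must not change its volume index,
which recurrent growth scanning requires. Internally LV is in mm³
(mm² × mm); it is reported as a unitless index, with an optional
`lv_scale` factor for matching legacy magnitude conventions.

## Pipeline stages and their parameters

| parameter            | default | units | role |
|----------------------|---------|-------|------|
| `scan_length_mm`     | 36 000  | mm    | nominal column length |
| `segments_per_scan`  | 18      | —     | plots per column; segment length must be exact to the mm |
| `row_spacing_mm`     | 550     | mm    | lateral swath / plot pitch |
| `cutting_height_mm`  | 40      | mm    | virtual cut above estimated ground |
| `ground_percentile`  | 0.05    | —     | quantile of valid in-window heights used as ground |
| `ma_window`          | 5       | samples | lateral moving-average width (odd) |
| `grid_res_mm`        | 50      | mm    | raster cell size for the diagnostic surface path |

**Filtering.** The moving average runs along the lateral axis of each scan
line (one sweep = one line, so this is "the direction of the scan"); windows
truncate at the swath edges rather than padding, and invalid samples neither
contribute to nor receive smoothed values. The default window of 5 samples is
the smallest that suppresses single-sample speckle; it is configurable. An
across-line (along-track) average would also be implementable but is not the
default here.

**Segmentation.** Plot windows are half-open along-track intervals
`[start, end)` tiling `[first_odometer, first_odometer + scan_length)`, so no
boundary scan is counted twice; a stream shorter than 95 % of the configured
scan length is refused. Manual per-plot offsets (a CSV of plot_id,
offset_mm) accommodate mis-aligned plots; overlap after shifting is an error
naming the colliding plots. Serpentine passes (decreasing odometer) are
normalised to increasing order at parse time and plot numbering is flipped
for such columns.

**Ground.** The soil elevation is the linearly interpolated 5th-percentile
of the window's valid heights. Inter-row soil, canopy gaps and the profile
tails populate the low tail of the height distribution, making the estimate
robust to canopy dominance. This fails by construction when a canopy covers
the entire swath with no soil visible (the quantile lands on vegetation); the
row-plot geometry this tool targets always exposes inter-row soil. Plots with
no scans or only invalid returns yield a flagged `empty` result rather than
LV = 0 — silent zeros would corrupt downstream regressions. Windows whose
observed odometer span covers less than half the nominal length are flagged
`sparse` (their LV still uses the observed span; a coverage fraction is
reported).

**Integration.** Cross-sections use the trapezoid rule over contiguous valid
runs; gaps from invalid returns contribute no area. Scan lines with no valid
sample are excluded from the scan count entirely (zero evidence, not zero
area). `distance` is the span of odometer positions actually observed in the
window, never the nominal window length, so partially covered plots are not
extrapolated.

**Raster path.** As an independent diagnostic, `h⁺` samples are binned onto
a regular grid fitted to the observed footprint (cell size = span /
round(span / resolution), so the grid tiles the footprint exactly); empty
cells are filled by nearest-neighbour interpolation and flagged. For a
constant canopy the raster volume equals LV exactly; for smooth dense
canopies the two agree to well under 2 %. The per-scan-integral path is the
production path; the raster is an oracle.

## The simulator, and what it does not emulate

`fieldsim.simulate_field` generates heights as
`ground(x) + canopy(y) + ε`, with

- canopies per plot: a **box** (uniform height over a centred band — a dense
  even sward) or a **Gaussian ridge** (`peak·exp(−y²/2σ²)` — a single row's
  bell-shaped cross-section), constant along the row; both have closed-form
  volumes above the cut (the ridge via an erf expression, cross-checked
  against quadrature in the tests);
- **ground**: a slow sinusoid, default period 12 m and amplitude 50 mm —
  realistic cultivated-field undulation — plus an arbitrary datum offset;
- **noise**: Gaussian on height, default SD 5 mm, the scale of leaf flutter
  and ranging error; **dropouts**: Bernoulli per sample (default 2 %)
  standing in for no-return samples;
- **geometry**: 0.5 m/s travel at a 300 Hz line rate (native along-track
  spacing 5/3 mm) and 700 000 points/m² native density. The default density
  is reduced 100× (both spacings widened ~10×) so simulations run at desk
  scale; full density is reachable through `density_pts_m2` up to a
  10⁷-sample guard. `along_spacing_mm` decouples line rate from density so
  scan-rate experiments can vary one axis alone.

Not modelled: beam divergence and footprint, multi-return physics, wind or
curtain artefacts, within-row patchiness along the travel axis, and any
FW/DW-to-volume biology. Passing the recovery checks therefore demonstrates
that the geometry processing is correct and noise-robust, not that LV
predicts yield in a real trial — that link rests on field calibration.

## Validation conditions and observed behaviour

The volume-recovery study uses 100 plots (five 40 m columns of twenty 2 m
plots), alternating box and ridge canopies with total heights drawn uniformly
over 140–540 mm (≈5× span above the 40 mm cut), 5 mm noise, 2 % dropout, and
the undulating ground above, at the default reduced density. Squared
correlation against analytic truth and the median relative error are the
yardsticks. The largest single-plot errors (up to ~±15–20 %) occur on plots
whose window sits on a steep flank of the ground sinusoid: a per-plot
*constant* ground estimate cannot follow within-plot slope, so sloping soil
above the cut leaks into the integral. A sloped-plane ground fit would
remove this and is a natural extension.

Two numerical interactions worth knowing:

- **Smoothing × cut clipping.** The lateral moving average smears sharp
  canopy edges; mass smeared below the virtual cut is clipped, costing
  ~1–2 % on box canopies. Since the moving average exists to suppress
  noise, the noiseless recovery checks run with `ma_window = 1`,
  isolating segmentation + integration accuracy; noisy-condition checks
  keep the default window.
- **Discretisation.** Using the observed odometer span as `distance`
  under-covers a window by up to one line spacing, and lateral sampling
  resolves a box edge to half a sample spacing; both fall linearly with
  density. The noiseless convergence check therefore runs at
  280 000 points/m² (2.5× below the instrument's native density), where
  total discretisation error is ~0.3–0.4 %; at the default 100×-reduced
  density it is ~1 %.

Degenerate inputs are handled explicitly: empty/all-invalid plots are
flagged and excluded from results; fewer than two valid samples in a scan
line give zero area; a cut above the canopy top gives zero volume (not an
error); a zero-variance column in the correlation matrix yields flagged NaN
entries; CV is refused for n < 2 or zero mean; RGR requires positive yields
and increasing times, and contraction intervals are reported as negative
rates rather than suppressed.

## Trait statistics conventions

Standard deviations are sample SDs (n − 1). %DM is returned both as a
fraction and ×100; table-matching output rounds the fraction to two
decimals, matching the bundled trial table, which prints fractions. The
bundled per-cultivar regressions are of LV (response, ~10⁵ per gram) on FW
(grams), so their X-intercepts (~90–106) are in grams; only the algebraic
identity X-intercept = −Y-intercept/slope is recomputable from the summary
parameters, as the underlying per-cultivar observations are not part of the
dataset (the cultivar-8 row carries no readable R² and is stored as NaN).
OLS fitting delegates to `scipy.stats.linregress`; the correlation matrix to
`numpy.corrcoef`.

## Problem sizes

Test-suite and acceptance runs use the reduced default density, 2 m plots
and columns of 1–20 plots (≤ ~1.5 M samples per run), completing in seconds;
these sizes were chosen as the smallest at which the discretisation terms
above are clearly separated from the noise terms.
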