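# Methods

## Generalized polarization

All readouts derive from the ratiometric generalized polarization

GP = (I_blue − I_red) / (I_blue + I_red),

where the two intensities are collected in a short- and a long-wavelength
emission window of an environment-sensitive membrane dye.  GP increases as
the probe's surroundings become less hydrated and more ordered.  The same
definition is applied at two levels: band-integrated spectrofluorometer
spectra (`gp.spectrum_gp`, trapezoidal integration with linear
interpolation at window edges, exact for piecewise-linear spectra) and
per-pixel confocal images (`gp.gp_map`).  Pixels whose summed intensity
does not strictly exceed a threshold are masked invalid; when no numeric
threshold is supplied, Otsu's threshold of the summed-channel image is
used because it is reproducible and parameter-free.  Emission windows
default to 500–580 nm (blue) and 620–750 nm (red), the conventional
di-4-ANEPPDHQ choice; both are configurable because detector windows vary
between instruments.  Optional constant per-channel background subtraction
(negatives clipped to zero) is applied before GP and echoed in the run
report.

## Seeded watershed and membrane extraction

Cells are segmented by flooding the Sobel gradient magnitude of the
Gaussian-smoothed (σ = 2 px default) summed-intensity image from
user-supplied markers, with 8-connectivity; the basin grown from the
background seeds becomes label 0 and each cell seed yields its own label
in seed order.  The priority-flood implementation used is deterministic
(FIFO tie-break), so repeated runs are bit-identical.  A rank-based
variant replaces intensities by their ranks first, making the label map
invariant under any strictly increasing intensity transform.  Two seeds in
one basin still produce two labels — never a silent merge — and a warning
is logged when adjacent cell labels meet across a below-median gradient
boundary, the signature of that situation.

Plasma-membrane pixels are the band within `band_width` (default 3 px,
Euclidean distance) of each cell's boundary on the inner side, refined by
keeping pixels whose summed intensity is at or above the
`refinement_quantile` quantile of the band (default 0.5, closed lower
bound, so a uniform band is retained in full).  Masks are disjoint by
construction because each band lies inside its own label region.  The
per-cell statistic is the median GP over membrane ∩ valid pixels; cells
with fewer than `min_pixels` (default 20) such pixels are dropped and
counted in the run report.  Whether the membrane should instead be taken
from the watershed lines themselves is not decidable from typical usage;
the intensity-band definition was chosen because it is robust to the exact
boundary placement and both band width and quantile are logged.

## Treatment statistics

Per-treatment summaries report mean ± SEM (sample SD/√n; undefined — not
zero — for n = 1) and median with quartiles.  Group comparison is one-way
ANOVA from the standard sums of squares followed by Tukey's HSD: q = |m_i −
m_j| / √(MSE/2·(1/n_i + 1/n_j)) (Tukey–Kramer form for unequal n), with
adjusted p-values from the studentized-range distribution at k groups and
N − k degrees of freedom.

Cross-dye comparison uses Deming errors-in-variables regression, because
both axes (e.g. the GP of one dye and the excitation ratio of another) are
measured with error and ordinary least squares would attenuate the slope.
With δ = σ²_y/σ²_x and s_xx, s_yy, s_xy the sample (co)variances,

slope = [s_yy − δ·s_xx + √((s_yy − δ·s_xx)² + 4δ·s_xy²)] / (2·s_xy),

computed in a cancellation-free form when δ·s_xx dominates; intercept =
ȳ − slope·x̄.  δ defaults to 1 (orthogonal regression), the standard choice
when the error-variance ratio is unknown, and is echoed in all outputs.
Standard errors come from the leave-one-out jackknife and the slope
p-value from t = slope/SE with n − 2 df — distribution-free and standard
for Deming fits.  The jackknife t-test is well calibrated from n ≈ 6
upward and mildly conservative at n = 4 (empirical size ≈ 0.035 at nominal
0.05), which should be kept in mind when regressing four treatment means.
Regressions are run on treatment-level means, as such dye-comparison
figures are conventionally drawn; raw p-values are reported without
multiple-testing correction across the (two) dye pairs, stated in the
output metadata.  Degenerate inputs (constant x, zero covariance) raise
explicit errors rather than returning an arbitrary line.

## Trajectory geometry

The bilayer normal is the laboratory +z axis; no per-frame plane fitting
is done (flat-bilayer convention).  Units are Å, ns and degrees
throughout.  Per frame:

- **Leaflets** — P atoms split by z about their median; an atom exactly at
  the median goes to the bottom leaflet (fixed tie rule).
- **Thickness** — mean z of top-leaflet P atoms minus mean z of
  bottom-leaflet P atoms.
- **Tilt** — angle between the N2→N3 vector and +z, in [0°, 180°]; an
  optional fold maps it to [0°, 90°] (axis convention).  Neither choice is
  silently changed.
- **RMSD** — dye heavy atoms after optimal rigid superposition (Kabsch,
  translation + rotation) onto the first analyzed frame; reference frame
  and fitting group are recorded in the output metadata.
- **Interface distance** — (mean z of the proximal leaflet's P plane) −
  (atom z), with the sign arranged to be positive *toward the bilayer
  center* for either leaflet.  The proximal leaflet is the one whose P
  plane lies nearest the dye's headgroup edge atom, fixed from the first
  frame (the dye is assumed not to flip).
- **Midpoint depth** — mean of the two chromophore edge-atom distances
  (N2-like and C23-like), the quantity used for insertion-depth summaries.

Window averages are taken over frames with t ≥ t_end − window
(inclusive); the default window is the trailing 100 ns, the conventional
"converged tail" of a few-hundred-ns simulation.

Convergence between two trajectories started at different insertion
depths is the earliest time t at which the two midpoint-depth curves —
optionally smoothed by a trailing running mean of width `smooth_ns`
(default 0, i.e. raw) — differ by less than `tolerance` at every time in
[t, t + hold]; if no such t exists the result is "not converged" (None).
Pointwise comparison of trailing means was chosen over a cumulative
running mean because the latter never forgets the initial transient and
would not return the step time even for an exact step-function pair.

## Synthetic data: what it emulates and what it does not

**Images.** Cells are non-overlapping discs with an annular membrane ring,
a dim interior and a dark background.  Defaults: 50 cells of radius 12–18
px in a 512×512 field; ring width 1.5 px (a plasma membrane is ~5 nm, so
its image is the microscope PSF — about 1.5 px at typical confocal
sampling); membrane/interior/background photon means 2000/300/50
(bright-ring confocal midplane conditions); Gaussian read noise SD 5.
Each cell's true GP (default: uniform in 0.1–0.6, the physiological
plasma-membrane range) splits the total intensity as I_blue = I(1+GP)/2,
I_red = I(1−GP)/2, inverting the GP definition exactly; Poisson shot noise
then read noise are applied per channel, and negatives are clipped.  A
separate `noise_seed` lets noise vary while geometry stays fixed.  Real
micrographs differ in every morphological respect (irregular cell shapes,
intracellular organelles, shading, out-of-focus light), so segmentation
scores on these images demonstrate correctness of the algorithmics, not
field performance.

**Spectra.** Two Gaussian emission bands (centers 530/670 nm, SD 15 nm, on
a 480–780 nm grid at 1 nm) whose amplitudes are solved exactly — on the
discrete grid, with the same trapezoidal integrals the analysis uses — so
the band-integrated GP equals the target and the total integral a set
value.  GP = ±1 is the single-band boundary case; targets requiring a
negative amplitude (possible only with heavily overlapping bands) raise.
Real dye spectra are asymmetric and multi-component; the two-band model is
the minimal shape with an exactly known GP.

**Trajectories.** Two phosphate planes at ±thickness/2 (default P–P 39 Å,
the POPC value; 64 lipids per leaflet on an 8 Å grid, ~65 Å² per
headgroup) with per-atom per-frame Gaussian z jitter (SD 2 Å).  The dye is
a rigid rod (10 Å, 12 atoms) in the top leaflet whose midpoint depth below
the plane and whose polar tilt follow exact-discretization
Ornstein–Uhlenbeck processes; OU dynamics were chosen because the
stationary mean and SD are closed-form, giving recovery tests analytic
expectations: the SE of a T-window mean is ≈ SD·√(2τ/T).  Defaults: depth
SD 1.5 Å, relaxation time τ = 10 ns, tilt 30° ± 5°, 300 ns sampled every
0.1 ns.  Atom naming makes the generator round-trip exact: the deep rod
end is N2 with neighbor N3 (so the N2→N3 vector reproduces the generated
tilt directly in [0°, 90°]) and the shallow end C23; the midpoint of the
two edge distances equals the OU depth by symmetry.  An
`initial_depth_offset` (e.g. 5 Å) starts the dye away from its stationary
depth for two-start convergence experiments.  There is no force field, no
lipid–dye interaction and no membrane undulation: these trajectories test
the geometry post-processor, not molecular dynamics.

Packaged depth presets place the chromophore/sensor midpoint at
di-4-ANEPPDHQ 4.4 Å, di-8-ANEPPS 3.7 Å and Laurdan 10.6 Å below the
proximal phosphate plane — the literature insertion depths for these dyes
in POPC — so depth-recovery runs have meaningful targets.

## Numerical conventions

- CSV output: comma-separated, UTF-8, header row, 9 significant digits.
- Medians of even-sized samples are the midpoint of the two central order
  statistics (numpy convention); quantiles use linear interpolation with a
  closed ≥ comparison where a cut is applied.
- XTC stores positions at 0.001 nm precision (0.01 Å); the CSV coordinate
  dump is the lossless portable format.
- All randomness in a generator flows from the single integer seed of its
  spec; identical spec ⇒ bit-identical output.

## Problem sizes

Tests and the reproduction script run at the sizes stated above: 300 ns /
3001-frame trajectories with 64 lipids per leaflet, 512×512 images with 50
cells (one 760×760, 100-cell field for the bias check), 200-replicate
ANOVA simulations and 10⁴-replicate null calibrations — sizes at which the
closed-form OU and sampling expectations are comfortably resolvable.

## Known limitations

- The synthetic imaging noise model (Poisson + Gaussian) is a convention;
  no instrument calibration stands behind the default read noise.
- Membrane extraction assumes ring-shaped, roughly convex cells; deeply
  concave cells would need a geodesic band.
- The trajectory tools assume a flat, non-flipping, single-dye system;
  curvature, undulations and sterol-containing bilayers are out of scope.
- Fluorescence lifetime and anisotropy modalities are not modeled.
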