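"""Synthetic images, spectra and bilayer trajectories with known ground truth.

Every downstream stage of the pipeline (GP maps, seeded watershed, membrane
extraction, trajectory geometry) can be exercised on data generated here,
with the quantities the pipeline should recover recorded exactly.

What is emulated
----------------
* **Images** — fields of non-overlapping disc "cells" with a bright annular
  plasma-membrane ring, a dimmer interior and a dark background, imaged with
  Poisson shot noise plus Gaussian read noise.  Each cell carries a true GP
  that fixes the blue/red channel split: ``I_blue = I (1+GP)/2`` and
  ``I_red = I (1-GP)/2``, which inverts the GP definition exactly.
* **Spectra** — two Gaussian emission bands on a wavelength grid whose
  amplitudes are solved so that the band-integrated GP (same integration
  windows as :mod:`membranegp.gp`) equals a requested target exactly in the
  noiseless case.
* **Trajectories** — a flat bilayer represented by two jittered phosphate
  planes plus a rigid-rod dye whose chromophore-midpoint depth below the
  proximal phosphate plane and whose tilt to the membrane normal follow
  mean-reverting Ornstein–Uhlenbeck (OU) processes.  OU dynamics are used
  because their stationary mean and SD are closed-form, so recovery tests
  have analytic expectations.

The packaged depth presets place the chromophore (or sensor) midpoint of
each dye at its literature insertion depth below the phosphate plane:
di-4-ANEPPDHQ 4.4 Å, di-8-ANEPPS 3.7 Å, Laurdan 10.6 Å; the default tilt
is 30° to the membrane normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .gp import BandPair, DEFAULT_BANDS, EmissionSpectrum, TwoChannelImage, integrate_band
from .mdgeom import BilayerTrajectory

__all__ = [
    "ImageSpec",
    "SpectrumSpec",
    "TrajectorySpec",
    "GroundTruth",
    "DEPTH_PRESETS",
    "DEFAULT_TILT_MEAN",
    "trajectory_spec_for_dye",
    "make_cell_image",
    "make_spectrum",
    "make_trajectory",
]

#: Chromophore/sensor-moiety insertion depths below the proximal phosphate
#: plane (Å) for the three dyes, as determined by all-atom simulations of
#: each dye in a POPC bilayer.
DEPTH_PRESETS: dict[str, float] = {
    "di-4-ANEPPDHQ": 4.4,
    "di-8-ANEPPS": 3.7,
    "Laurdan": 10.6,
}

#: Default dye tilt to the membrane normal (degrees).
DEFAULT_TILT_MEAN = 30.0


@dataclass(frozen=True)
class ImageSpec:
    """Parameters of a synthetic two-channel cell image.

    Intensities are photon means per pixel.  ``membrane_width`` is the
    radial width of the bright plasma-membrane annulus; the default mimics
    a diffraction-limited ring (~1.5 px at typical confocal sampling).
    ``per_cell_gp`` is one true GP per cell in [-1, 1]; if None, values are
    drawn uniformly from [0.1, 0.6] (the physiological plasma-membrane
    range) using ``seed``.
    """

    image_shape: tuple[int, int] = (512, 512)
    n_cells: int = 50
    cell_radius_range: tuple[float, float] = (12.0, 18.0)
    membrane_width: float = 1.5
    membrane_intensity: float = 2000.0
    interior_intensity: float = 300.0
    background_intensity: float = 50.0
    per_cell_gp: tuple[float, ...] | None = None
    read_noise_sd: float = 5.0
    poisson_noise: bool = True
    seed: int = 0
    noise_seed: int | None = None  # vary noise with geometry fixed; default: seed

    def __post_init__(self) -> None:
        if self.membrane_width < 1:
            raise ValueError("membrane_width must be >= 1 pixel")
        if self.per_cell_gp is not None:
            if len(self.per_cell_gp) != self.n_cells:
                raise ValueError("per_cell_gp length must equal n_cells")
            if any(abs(g) > 1 for g in self.per_cell_gp):
                raise ValueError("every per_cell_gp must lie in [-1, 1]")
        if self.cell_radius_range[0] > self.cell_radius_range[1]:
            raise ValueError("cell_radius_range must be (lo, hi) with lo <= hi")
        if self.cell_radius_range[0] <= self.membrane_width:
            raise ValueError("cell radius must exceed membrane_width")


@dataclass(frozen=True)
class SpectrumSpec:
    """Parameters of a synthetic two-band emission spectrum."""

    wavelength_range: tuple[float, float] = (480.0, 780.0)
    step: float = 1.0
    blue_center: float = 530.0
    red_center: float = 670.0
    band_sd: float = 15.0
    total_intensity: float = 1.0e4
    target_gp: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    bands: BandPair = DEFAULT_BANDS
    excitation_wavelength: float = 488.0

    def __post_init__(self) -> None:
        if not self.blue_center < self.red_center:
            raise ValueError("blue_center must be below red_center")
        if abs(self.target_gp) > 1:
            raise ValueError("target_gp must lie in [-1, 1]")
        lo, hi = self.wavelength_range
        if not (lo < self.blue_center < hi and lo < self.red_center < hi):
            raise ValueError("band centers must lie inside wavelength_range")


@dataclass(frozen=True)
class TrajectorySpec:
    """Parameters of a synthetic bilayer + rigid-rod dye trajectory.

    ``dye_depth`` is the stationary mean distance of the chromophore
    midpoint below the proximal (top) phosphate plane; ``depth_sd`` and
    ``depth_relaxation_time`` are the stationary SD and the OU relaxation
    time of its fluctuations.  ``initial_depth_offset`` starts the dye away
    from its stationary depth (two-start convergence experiments); the
    offset decays with the same relaxation time.  Defaults follow typical
    single-dye POPC simulations: a ~39 Å P–P bilayer of 64 lipids per
    leaflet, 300 ns sampled every 0.1 ns, depth fluctuations of 1.5 Å with
    a 10 ns memory, and a 30° mean tilt.
    """

    thickness: float = 39.0
    n_lipids_per_leaflet: int = 64
    p_jitter_sd: float = 2.0
    dye_depth: float = DEPTH_PRESETS["di-4-ANEPPDHQ"]
    depth_sd: float = 1.5
    depth_relaxation_time: float = 10.0
    tilt_mean: float = DEFAULT_TILT_MEAN
    tilt_sd: float = 5.0
    rod_length: float = 10.0
    n_dye_atoms: int = 12
    duration: float = 300.0
    frame_interval: float = 0.1
    initial_depth_offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.duration < self.frame_interval:
            raise ValueError("duration must be at least one frame_interval")
        if self.n_dye_atoms < 2:
            raise ValueError("need at least 2 dye atoms (the two edges)")
        if self.rod_length > self.thickness:
            raise ValueError(
                f"rod_length {self.rod_length} Å exceeds bilayer thickness "
                f"{self.thickness} Å"
            )


def trajectory_spec_for_dye(dye: str, **overrides) -> TrajectorySpec:
    """A :class:`TrajectorySpec` at the packaged depth preset for ``dye``."""
    if dye not in DEPTH_PRESETS:
        raise KeyError(f"unknown dye {dye!r}; presets: {sorted(DEPTH_PRESETS)}")
    return TrajectorySpec(dye_depth=DEPTH_PRESETS[dye], **overrides)


@dataclass
class GroundTruth:
    """Exact quantities a downstream stage should recover.

    Only the fields relevant to the generated artifact are populated.
    """

    cell_label_map: np.ndarray | None = None
    membrane_masks: dict[int, np.ndarray] | None = None
    per_cell_gp: tuple[float, ...] | None = None
    cell_centers: tuple[tuple[int, int], ...] | None = None
    spectrum_gp: float | None = None
    depth_series: np.ndarray | None = None
    tilt_series: np.ndarray | None = None


# ---------------------------------------------------------------------------
# images


def _place_cells(spec: ImageSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping disc centers and radii."""
    h, w = spec.image_shape
    gap = 6.0  # guaranteed clearance between cell rims, px
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    max_tries = 2000 * max(spec.n_cells, 1)
    tries = 0
    while len(centers) < spec.n_cells and tries < max_tries:
        tries += 1
        r = rng.uniform(*spec.cell_radius_range)
        margin = r + 2.0
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        if all(
            math.hypot(cy - oy, cx - ox) >= r + orad + gap
            for (oy, ox), orad in zip(centers, radii)
        ):
            centers.append((cy, cx))
            radii.append(r)
    if len(centers) < spec.n_cells:
        raise ValueError(
            f"could not place {spec.n_cells} non-overlapping cells in "
            f"{spec.image_shape} after {max_tries} tries; placed {len(centers)}"
        )
    return centers, radii


def make_cell_image(spec: ImageSpec) -> tuple[TwoChannelImage, GroundTruth]:
    """Generate a two-channel image of ring-membrane cells plus ground truth.

    The noiseless per-pixel total intensity is split between channels
    according to the owning cell's GP (background splits evenly, GP = 0);
    Poisson shot noise and Gaussian read noise are then applied per channel
    independently.  Ground truth records the exact label map, per-cell
    membrane annuli, true GP values and cell centers (usable as perfect
    watershed seeds).
    """
    rng = np.random.default_rng(spec.seed)
    gp_values = spec.per_cell_gp
    if gp_values is None:
        gp_values = tuple(rng.uniform(0.1, 0.6, size=spec.n_cells))
    centers, radii = _place_cells(spec, rng)

    h, w = spec.image_shape
    yy, xx = np.mgrid[0:h, 0:w]
    total = np.full((h, w), float(spec.background_intensity))
    gp_field = np.zeros((h, w))
    labels = np.zeros((h, w), dtype=np.int32)
    membrane_masks: dict[int, np.ndarray] = {}

    for i, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
        dist = np.hypot(yy - cy, xx - cx)
        disc = dist <= r
        ring = disc & (dist > r - spec.membrane_width)
        interior = disc & ~ring
        labels[disc] = i
        total[interior] = spec.interior_intensity
        total[ring] = spec.membrane_intensity
        gp_field[disc] = gp_values[i - 1]
        membrane_masks[i] = ring

    blue = total * (1.0 + gp_field) / 2.0
    red = total * (1.0 - gp_field) / 2.0
    noise_rng = rng if spec.noise_seed is None else np.random.default_rng(spec.noise_seed)
    if spec.poisson_noise:
        blue = noise_rng.poisson(blue).astype(float)
        red = noise_rng.poisson(red).astype(float)
    if spec.read_noise_sd > 0:
        blue = blue + noise_rng.normal(0.0, spec.read_noise_sd, size=blue.shape)
        red = red + noise_rng.normal(0.0, spec.read_noise_sd, size=red.shape)
    blue = np.clip(blue, 0.0, None)
    red = np.clip(red, 0.0, None)

    truth = GroundTruth(
        cell_label_map=labels,
        membrane_masks=membrane_masks,
        per_cell_gp=tuple(float(g) for g in gp_values),
        cell_centers=tuple((int(round(cy)), int(round(cx))) for cy, cx in centers),
    )
    return TwoChannelImage(blue=blue, red=red), truth


# ---------------------------------------------------------------------------
# spectra


def make_spectrum(spec: SpectrumSpec) -> tuple[EmissionSpectrum, GroundTruth]:
    """Generate a two-Gaussian-band emission spectrum with an exact GP.

    The two band amplitudes are solved (2x2 linear system) so that, on the
    discrete wavelength grid and with the same trapezoidal band integration
    used by :func:`membranegp.gp.spectrum_gp`, the band-integrated GP equals
    ``target_gp`` exactly and the full-range integral equals
    ``total_intensity``.  ``target_gp = ±1`` is the single-band boundary
    (the other amplitude is zero).  Targets that would require a negative
    amplitude, given the spectral cross-talk between windows, raise.
    """
    lo, hi = spec.wavelength_range
    wl = np.arange(lo, hi + spec.step / 2, spec.step)
    shape_b = np.exp(-0.5 * ((wl - spec.blue_center) / spec.band_sd) ** 2)
    shape_r = np.exp(-0.5 * ((wl - spec.red_center) / spec.band_sd) ** 2)

    def _band_integrals(shape: np.ndarray) -> tuple[float, float, float]:
        s = EmissionSpectrum(wl, shape)
        full = (float(wl[0]), float(wl[-1]))
        return (
            integrate_band(s, spec.bands.blue),
            integrate_band(s, spec.bands.red),
            integrate_band(s, full),
        )

    g_bb, g_br, s_b = _band_integrals(shape_b)  # blue basis into blue/red window
    g_rb, g_rr, s_r = _band_integrals(shape_r)
    g = spec.target_gp

    if g == 1.0:
        a, b = spec.total_intensity / s_b, 0.0
    elif g == -1.0:
        a, b = 0.0, spec.total_intensity / s_r
    else:
        # rows: GP constraint (I_blue - I_red) - g (I_blue + I_red) = 0,
        #       total-intensity constraint
        m = np.array(
            [
                [(g_bb - g_br) - g * (g_bb + g_br), (g_rb - g_rr) - g * (g_rb + g_rr)],
                [s_b, s_r],
            ]
        )
        a, b = np.linalg.solve(m, np.array([0.0, spec.total_intensity]))
        tol = 1e-9 * max(abs(a), abs(b))
        if a < -tol or b < -tol:
            raise ValueError(
                f"target_gp={g} infeasible with these bands: requires a "
                "negative band amplitude (band overlap limits attainable GP)"
            )
        a, b = max(a, 0.0), max(b, 0.0)

    intensities = a * shape_b + b * shape_r
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        intensities = intensities + rng.normal(0.0, spec.noise_sd, size=wl.size)
        intensities = np.clip(intensities, 0.0, None)
    spectrum = EmissionSpectrum(
        wl, intensities, excitation_wavelength=spec.excitation_wavelength
    )
    return spectrum, GroundTruth(spectrum_gp=float(g))


# ---------------------------------------------------------------------------
# trajectories


def _ou_path(
    rng: np.random.Generator,
    n: int,
    dt: float,
    mean: float,
    sd: float,
    tau: float,
    x0: float,
) -> np.ndarray:
    """Exact discretization of an OU process (stationary mean/SD, memory tau)."""
    x = np.empty(n)
    x[0] = x0
    if sd == 0:
        # deterministic relaxation of the initial offset
        decay = np.exp(-dt * np.arange(n) / tau)
        return mean + (x0 - mean) * decay
    phi = math.exp(-dt / tau)
    innov_sd = sd * math.sqrt(1.0 - phi * phi)
    noise = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = mean + phi * (x[i - 1] - mean) + noise[i - 1]
    return x


def _dye_atom_names(n: int) -> tuple[str, ...]:
    """Edge atoms are N2 (deep end) and C23; N2's neighbor is N3 (tilt pair)."""
    if n == 2:
        return ("N2", "C23")
    names = ["N2", "N3"] + [f"C{i}" for i in range(3, n)] + ["C23"]
    return tuple(names[:n])


def make_trajectory(spec: TrajectorySpec) -> tuple[BilayerTrajectory, GroundTruth]:
    """Generate a bilayer + rigid-rod dye trajectory with exact ground truth.

    The two phosphate planes sit at ±thickness/2 with per-atom, per-frame
    Gaussian z jitter.  The dye is a rigid rod of equally spaced atoms in
    the top leaflet whose midpoint depth below the ideal top plane follows
    an OU process about ``dye_depth`` (started at
    ``dye_depth + initial_depth_offset``) and whose axis keeps a fixed
    azimuth while its polar tilt follows an OU process about ``tilt_mean``.
    Atom naming: the deep rod end is "N2", its neighbor "N3" (so the
    N2→N3 vector points up the rod axis and reproduces the tilt exactly),
    and the shallow end is "C23".  Ground truth records the midpoint depth
    and tilt series.
    """
    rng = np.random.default_rng(spec.seed)
    dt = spec.frame_interval
    n_frames = int(round(spec.duration / dt)) + 1
    times = np.arange(n_frames) * dt

    n_lip = spec.n_lipids_per_leaflet
    side = math.ceil(math.sqrt(n_lip))
    spacing = 8.0  # Å, ~65 Å² per POPC headgroup
    box_xy = side * spacing
    grid = np.array(
        [(ix * spacing + spacing / 2, iy * spacing + spacing / 2)
         for ix in range(side) for iy in range(side)][:n_lip]
    )

    depth = _ou_path(
        rng, n_frames, dt,
        mean=spec.dye_depth, sd=spec.depth_sd, tau=spec.depth_relaxation_time,
        x0=spec.dye_depth + spec.initial_depth_offset,
    )
    tilt = _ou_path(
        rng, n_frames, dt,
        mean=spec.tilt_mean, sd=spec.tilt_sd, tau=spec.depth_relaxation_time,
        x0=spec.tilt_mean,
    )
    azimuth = rng.uniform(0.0, 2.0 * math.pi)

    n_atoms = 2 * n_lip + spec.n_dye_atoms
    coords = np.empty((n_frames, n_atoms, 3))
    half = spec.thickness / 2.0
    # leaflet P atoms: indices [0, n_lip) top, [n_lip, 2 n_lip) bottom
    coords[:, :n_lip, 0] = grid[:, 0]
    coords[:, :n_lip, 1] = grid[:, 1]
    coords[:, n_lip:2 * n_lip, 0] = grid[:, 0]
    coords[:, n_lip:2 * n_lip, 1] = grid[:, 1]
    if spec.p_jitter_sd > 0:
        jitter = rng.normal(0.0, spec.p_jitter_sd, size=(n_frames, 2 * n_lip))
    else:
        jitter = np.zeros((n_frames, 2 * n_lip))
    coords[:, :n_lip, 2] = half + jitter[:, :n_lip]
    coords[:, n_lip:2 * n_lip, 2] = -half + jitter[:, n_lip:]

    # rigid rod: midpoint at z = half - depth, axis tilted from +z, fixed azimuth
    theta = np.radians(tilt)
    axis = np.stack(
        [
            np.sin(theta) * math.cos(azimuth),
            np.sin(theta) * math.sin(azimuth),
            np.cos(theta),
        ],
        axis=1,
    )  # (n_frames, 3), unit vectors
    offsets = np.linspace(-spec.rod_length / 2.0, spec.rod_length / 2.0,
                          spec.n_dye_atoms)
    center = np.zeros((n_frames, 3))
    center[:, 0] = box_xy / 2.0
    center[:, 1] = box_xy / 2.0
    center[:, 2] = half - depth
    dye = center[:, None, :] + offsets[None, :, None] * axis[:, None, :]
    coords[:, 2 * n_lip:, :] = dye

    p_names = tuple("P" for _ in range(2 * n_lip))
    names = p_names + _dye_atom_names(spec.n_dye_atoms)
    dye_idx = np.arange(2 * n_lip, n_atoms)
    traj = BilayerTrajectory(
        times=times,
        coordinates=coords,
        atom_names=names,
        p_atom_indices=np.arange(2 * n_lip),
        dye_atom_indices=dye_idx,
        dye_heavy_indices=dye_idx,  # the synthetic rod has no hydrogens
        box=(box_xy, box_xy, spec.thickness + 40.0),
    )
    truth = GroundTruth(depth_series=depth, tilt_series=tilt)
    return traj, truth
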