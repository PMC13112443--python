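"""Generalized polarization (GP) from emission spectra and two-channel images.

GP is the ratiometric index

    GP = (I_blue - I_red) / (I_blue + I_red)

of an environment-sensitive membrane dye's emission, where ``I_blue`` and
``I_red`` are intensities collected in a short- and a long-wavelength band.
Higher GP reports a less hydrated, more ordered lipid environment.  The same
formula applies to a spectrofluorometer spectrum (band-integrated intensities)
and to a confocal image (per-pixel channel intensities).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

__all__ = [
    "EmissionSpectrum",
    "BandPair",
    "TwoChannelImage",
    "GPMap",
    "DEFAULT_BANDS",
    "compute_gp",
    "integrate_band",
    "spectrum_gp",
    "gp_map",
    "subtract_background",
]


@dataclass(frozen=True)
class EmissionSpectrum:
    """An emission spectrum at a single excitation wavelength.

    Parameters
    ----------
    wavelengths:
        Strictly increasing wavelength grid in nm, at least two points.
    intensities:
        Intensities (arbitrary units) on the same grid; must be finite.
    excitation_wavelength:
        Excitation wavelength in nm (informational).
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    excitation_wavelength: float | None = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("spectrum needs at least two wavelength points")
        if wl.size != it.size:
            raise ValueError("wavelengths and intensities differ in length")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(it)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])


@dataclass(frozen=True)
class BandPair:
    """Blue/red emission integration windows, each ``(lo, hi)`` in nm."""

    blue: tuple[float, float]
    red: tuple[float, float]

    def __post_init__(self) -> None:
        for name, band in (("blue", self.blue), ("red", self.red)):
            lo, hi = band
            if not lo < hi:
                raise ValueError(f"{name} band must have lo < hi, got {band}")
        if tuple(self.blue) == tuple(self.red):
            raise ValueError("blue and red bands must differ")

    def swapped(self) -> "BandPair":
        return BandPair(blue=self.red, red=self.blue)


#: Default di-4-ANEPPDHQ emission windows (nm).  The blue window sits on the
#: ordered-phase emission, the red window on the disordered-phase emission;
#: both are configurable because detector windows differ between instruments.
DEFAULT_BANDS = BandPair(blue=(500.0, 580.0), red=(620.0, 750.0))


@dataclass(frozen=True)
class TwoChannelImage:
    """Registered blue/red intensity images of identical shape."""

    blue: np.ndarray
    red: np.ndarray
    pixel_size: float | None = None  # µm, optional

    def __post_init__(self) -> None:
        blue = np.asarray(self.blue, dtype=float)
        red = np.asarray(self.red, dtype=float)
        if blue.shape != red.shape:
            raise ValueError(
                f"channel shapes differ: blue {blue.shape} vs red {red.shape}"
            )
        object.__setattr__(self, "blue", blue)
        object.__setattr__(self, "red", red)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.blue.shape

    @property
    def total(self) -> np.ndarray:
        return self.blue + self.red

    def swapped(self) -> "TwoChannelImage":
        return TwoChannelImage(blue=self.red, red=self.blue, pixel_size=self.pixel_size)


@dataclass(frozen=True)
class GPMap:
    """Per-pixel GP with a validity mask.

    ``gp`` is NaN wherever ``valid`` is False; on valid pixels it lies in
    [-1, 1].  ``intensity_threshold`` is the summed-channel threshold that
    defined validity (strict inequality).
    """

    gp: np.ndarray
    valid: np.ndarray
    intensity_threshold: float

    def __post_init__(self) -> None:
        if self.gp.shape != self.valid.shape:
            raise ValueError("gp and valid must share a shape")


def compute_gp(i_blue, i_red):
    """GP = (I_blue - I_red) / (I_blue + I_red), elementwise.

    Accepts scalars or arrays of nonnegative intensities.  Where both
    channels are zero the ratio is undefined and NaN is returned; callers
    that build maps mask those pixels out (see :func:`gp_map`).
    """
    b = np.asarray(i_blue, dtype=float)
    r = np.asarray(i_red, dtype=float)
    if np.any(b < 0) or np.any(r < 0):
        raise ValueError("intensities must be nonnegative")
    total = b + r
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, (b - r) / np.where(total > 0, total, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def integrate_band(spectrum: EmissionSpectrum, band: tuple[float, float]) -> float:
    """Trapezoidal integral of the spectrum over ``band``.

    The band edges need not coincide with grid points: the intensity is
    linearly interpolated at the edges, which makes the integral exact for
    piecewise-linear spectra.
    """
    lo, hi = float(band[0]), float(band[1])
    if not lo < hi:
        raise ValueError(f"band must have lo < hi, got {band}")
    wl_lo, wl_hi = spectrum.span
    if lo < wl_lo or hi > wl_hi:
        raise ValueError(
            f"band [{lo}, {hi}] nm outside the spectrum span [{wl_lo}, {wl_hi}] nm"
        )
    wl = spectrum.wavelengths
    it = spectrum.intensities
    inner = (wl > lo) & (wl < hi)
    xs = np.concatenate(([lo], wl[inner], [hi]))
    ys = np.concatenate(([np.interp(lo, wl, it)], it[inner], [np.interp(hi, wl, it)]))
    return float(np.trapezoid(ys, xs))


def spectrum_gp(spectrum: EmissionSpectrum, bands: BandPair = DEFAULT_BANDS) -> float:
    """Band-integrated GP of a spectrum: GP of the two window integrals."""
    i_blue = integrate_band(spectrum, bands.blue)
    i_red = integrate_band(spectrum, bands.red)
    if i_blue < 0 or i_red < 0:
        # noisy spectra can integrate slightly negative; clip at zero so the
        # ratio stays in range, as one would clip negative counts
        i_blue = max(i_blue, 0.0)
        i_red = max(i_red, 0.0)
    return compute_gp(i_blue, i_red)


def subtract_background(
    image: TwoChannelImage, blue_bg: float = 0.0, red_bg: float = 0.0
) -> TwoChannelImage:
    """Constant per-channel background subtraction, clipping negatives to 0."""
    return TwoChannelImage(
        blue=np.clip(image.blue - blue_bg, 0.0, None),
        red=np.clip(image.red - red_bg, 0.0, None),
        pixel_size=image.pixel_size,
    )


def gp_map(image: TwoChannelImage, intensity_threshold: float | None = None) -> GPMap:
    """Pixel-by-pixel GP of a two-channel image with intensity masking.

    Pixels whose summed intensity exceeds ``intensity_threshold`` (strictly)
    are valid; everywhere else the GP is NaN.  If no threshold is given,
    Otsu's threshold of the summed-channel image is used, which gives a
    reproducible, parameter-free separation of foreground from background.
    """
    total = image.total
    if intensity_threshold is None:
        intensity_threshold = float(threshold_otsu(total))
    valid = total > intensity_threshold
    gp = np.full(total.shape, np.nan)
    gp[valid] = compute_gp(image.blue[valid], image.red[valid])
    return GPMap(gp=gp, valid=valid, intensity_threshold=float(intensity_threshold))
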