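"""Core data model for vibrational hyperspectral data.

A measurement is either a single :class:`Spectrum` (one wavenumber axis, one
intensity vector) or a :class:`HyperspectralCube` (an H x W raster of spectra
sharing one axis).  Wavenumbers are always stored in canonically *increasing*
order in cm^-1; instrument files that store them high-to-low are reversed on
read.  Band quantification is trapezoidal integration over a
:class:`BandWindow`, optionally after subtracting the chord between the window
endpoints (the local-baseline convention used for quantitative band ratios).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "Modality",
    "WavenumberAxis",
    "Spectrum",
    "HyperspectralCube",
    "BandWindow",
    "ValidationError",
    "FormatError",
    "integrate_band",
    "integrate_band_array",
    "band_image",
]


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


class FormatError(ValueError):
    """Raised when a file does not carry the metadata a format requires."""


class Modality(str, enum.Enum):
    RAMAN = "raman"
    FTIR = "ftir"

    @classmethod
    def coerce(cls, value: "Modality | str") -> "Modality":
        if isinstance(value, cls):
            return value
        return cls(str(value).lower())


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing wavenumber grid in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValidationError("axis needs at least two wavenumber values")
        if not np.all(np.isfinite(values)):
            raise ValidationError("axis contains non-finite wavenumbers")
        if np.any(values <= 0):
            raise ValidationError("wavenumbers must be positive")
        if not np.all(np.diff(values) > 0):
            raise ValidationError("axis must be strictly increasing")
        object.__setattr__(self, "values", values)

    @classmethod
    def regular(cls, start: float, stop: float, step: float) -> "WavenumberAxis":
        n = int(round((stop - start) / step)) + 1
        return cls(start + step * np.arange(n))

    @classmethod
    def from_any(cls, values) -> "tuple[WavenumberAxis, bool]":
        """Canonicalize a possibly decreasing axis; returns (axis, flipped)."""
        values = np.asarray(values, dtype=float)
        if values.size >= 2 and values[0] > values[-1]:
            return cls(values[::-1].copy()), True
        return cls(values), False

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:  # value equality, convenient in tests
        return isinstance(other, WavenumberAxis) and np.array_equal(
            self.values, other.values
        )

    @property
    def step(self) -> float:
        """Nominal channel spacing (median of the first differences)."""
        return float(np.median(np.diff(self.values)))

    @property
    def low(self) -> float:
        return float(self.values[0])

    @property
    def high(self) -> float:
        return float(self.values[-1])

    def index_of(self, wavenumber: float) -> int:
        """Nearest channel index for a wavenumber."""
        return int(np.argmin(np.abs(self.values - wavenumber)))

    def window_slice(self, low: float, high: float) -> slice:
        """Channel slice for [low, high], endpoints snapped to nearest channels."""
        if low >= high:
            raise ValidationError(f"window low {low} must be < high {high}")
        half = self.step / 2
        if low < self.low - half or high > self.high + half:
            raise ValidationError(
                f"window [{low}, {high}] outside axis range "
                f"[{self.low}, {self.high}]"
            )
        i0 = self.index_of(low)
        i1 = self.index_of(high)
        if i1 <= i0:
            i1 = i0 + 1
        return slice(i0, i1 + 1)

    def region_mask(self, regions) -> np.ndarray:
        """Boolean channel mask for a list of (low, high) ranges."""
        mask = np.zeros(len(self), dtype=bool)
        for low, high in regions:
            mask |= (self.values >= low) & (self.values <= high)
        return mask


@dataclass(frozen=True)
class BandWindow:
    """An integration window on the wavenumber axis.

    ``baseline_mode='linear_endpoints'`` subtracts the chord between the
    window endpoints before integrating; ``'none'`` integrates the raw signal.
    """

    label: str
    low: float
    high: float
    baseline_mode: str = "none"

    def __post_init__(self) -> None:
        if self.low >= self.high:
            raise ValidationError("BandWindow requires low < high")
        if self.baseline_mode not in ("none", "linear_endpoints"):
            raise ValidationError(f"unknown baseline_mode {self.baseline_mode!r}")

    @classmethod
    def around(
        cls, center: float, half_width: float, label: str = "",
        baseline_mode: str = "none",
    ) -> "BandWindow":
        return cls(label or f"{center:g}", center - half_width,
                   center + half_width, baseline_mode)


@dataclass
class Spectrum:
    """One spectrum: intensities over a shared wavenumber axis."""

    axis: WavenumberAxis
    intensities: np.ndarray
    modality: Modality = Modality.RAMAN

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.modality = Modality.coerce(self.modality)
        if self.intensities.shape != (len(self.axis),):
            raise ValidationError(
                f"intensities length {self.intensities.shape} does not match "
                f"axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("intensities must be finite")

    def copy(self) -> "Spectrum":
        return Spectrum(self.axis, self.intensities.copy(), self.modality)

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        return Spectrum(self.axis, intensities, self.modality)

    def crop(self, low: float, high: float) -> "Spectrum":
        sl = self.axis.window_slice(low, high)
        return Spectrum(WavenumberAxis(self.axis.values[sl]),
                        self.intensities[sl], self.modality)

    def integrate(self, window: BandWindow) -> float:
        return integrate_band(self, window)


@dataclass
class HyperspectralCube:
    """H x W raster of spectra sharing one wavenumber axis.

    ``data`` has shape (height, width, channels); coordinates are (row, col)
    with the origin at the top-left.  ``pixel_size`` is the edge of one pixel
    in micrometres, so an area of ``n`` pixels is ``n * pixel_size**2`` um^2.
    """

    axis: WavenumberAxis
    data: np.ndarray
    pixel_size: float
    modality: Modality = Modality.RAMAN
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.modality = Modality.coerce(self.modality)
        if self.data.ndim != 3:
            raise ValidationError("cube data must be (height, width, channels)")
        if self.data.shape[2] != len(self.axis):
            raise ValidationError("cube channel count does not match axis")
        if not self.pixel_size > 0:
            raise ValidationError("pixel_size must be positive")
        self.metadata = dict(self.metadata)

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.height * self.width

    def flat(self) -> np.ndarray:
        """(n_pixels, channels) view of the data."""
        return self.data.reshape(self.n_pixels, len(self.axis))

    def pixel(self, row: int, col: int) -> Spectrum:
        return Spectrum(self.axis, self.data[row, col].copy(), self.modality)

    def with_data(self, data: np.ndarray) -> "HyperspectralCube":
        return HyperspectralCube(self.axis, data, self.pixel_size,
                                 self.modality, dict(self.metadata))

    def copy(self) -> "HyperspectralCube":
        return self.with_data(self.data.copy())

    def mean_spectrum(self, mask: np.ndarray | None = None) -> Spectrum:
        if mask is None:
            mean = self.data.mean(axis=(0, 1))
        else:
            mean = self.data[mask].mean(axis=0)
        return Spectrum(self.axis, mean, self.modality)


def _integrate(values: np.ndarray, x: np.ndarray, baseline_mode: str) -> np.ndarray:
    if baseline_mode == "linear_endpoints":
        t = (x - x[0]) / (x[-1] - x[0])
        chord = (values[..., :1] * (1 - t) + values[..., -1:] * t)
        values = values - chord
    return np.trapezoid(values, x, axis=-1)


def _integrate_exact(
    data: np.ndarray, axis: WavenumberAxis, low: float, high: float,
    baseline_mode: str,
) -> np.ndarray:
    """Cubic-spline band integral with exact (non-snapped) window bounds.

    Equal-width windows then capture identical fractions of identically
    shaped bands regardless of how the band centers fall on the grid, which
    keeps ratios of equal-shape bands exactly proportional to their areas.
    """
    from scipy.interpolate import CubicSpline

    axis.window_slice(low, high)  # range validation
    xv = axis.values
    i0 = max(0, int(np.searchsorted(xv, low)) - 4)
    i1 = min(len(xv), int(np.searchsorted(xv, high)) + 4)
    spline = CubicSpline(xv[i0:i1], data[..., i0:i1], axis=-1)
    area = spline.integrate(low, high)
    if baseline_mode == "linear_endpoints":
        area = area - 0.5 * (spline(low) + spline(high)) * (high - low)
    return np.asarray(area)


def integrate_band(
    spectrum: Spectrum, window: BandWindow, snap: bool = True
) -> float:
    """Band area (intensity * cm^-1) over a window.

    With ``snap=True`` (the default, used for chemical maps) the window
    endpoints snap to the nearest channels of the native grid and the
    integral is trapezoidal; with ``snap=False`` (used for quantitative band
    ratios) a cubic spline is integrated between the exact bounds.  With
    ``linear_endpoints`` the chord between the window-endpoint intensities
    is subtracted, so any affine spectrum integrates to exactly zero.
    """
    if snap:
        sl = spectrum.axis.window_slice(window.low, window.high)
        x = spectrum.axis.values[sl]
        return float(_integrate(spectrum.intensities[sl], x,
                                window.baseline_mode))
    return float(_integrate_exact(spectrum.intensities, spectrum.axis,
                                  window.low, window.high,
                                  window.baseline_mode))


def integrate_band_array(
    data: np.ndarray, axis: WavenumberAxis, window: BandWindow,
    snap: bool = True,
) -> np.ndarray:
    """Vectorized :func:`integrate_band` over the last array dimension."""
    data = np.asarray(data, dtype=float)
    if snap:
        sl = axis.window_slice(window.low, window.high)
        return _integrate(data[..., sl], axis.values[sl], window.baseline_mode)
    return _integrate_exact(data, axis, window.low, window.high,
                            window.baseline_mode)


def band_image(cube: HyperspectralCube, window: BandWindow) -> np.ndarray:
    """Per-pixel band integral; a (height, width) chemical map."""
    return integrate_band_array(cube.data, cube.axis, window)
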