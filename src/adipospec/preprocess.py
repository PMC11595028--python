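"""Preprocessing chains for Raman and FTIR hyperspectral cubes.

Raman chain (applied per pixel before clustering): cosmic-ray despiking with
a running-median filter, then subtraction of a 3rd-order polynomial baseline
fitted as a lower envelope.  The class mean spectra extracted after
clustering are further treated with a concave rubber-band baseline (10
iterations), Savitzky-Golay smoothing (11 points), cropping to the retained
range and vector normalization.

FTIR chain: an amide-I quality test (absorbance >= 0.2 between 1620 and
1680 cm^-1) masks out empty pixels, PCA noise reduction (13 components)
reconstructs the kept pixels, Savitzky-Golay smoothing (13 points) and
vector normalization follow; Mie-scattering correction (RMieS-EMSC with a
van de Hulst extinction basis, 7 principal components) is applied to the
class mean spectra extracted after clustering, optionally followed by a
second derivative for band-position work.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, signal
from sklearn.decomposition import PCA

from .core import (
    BandWindow,
    HyperspectralCube,
    Modality,
    Spectrum,
    ValidationError,
    WavenumberAxis,
)
from .mie import extinction_database

__all__ = [
    "PreprocessConfig",
    "despike",
    "correct_baseline",
    "savgol",
    "vector_normalize",
    "quality_mask",
    "pca_denoise",
    "rmies_correct",
    "preprocess_raman_cube",
    "preprocess_ftir_cube",
    "postprocess_mean_spectrum",
]


@dataclass
class PreprocessConfig:
    despike_filter_size: int = 3
    despike_dynamic_factor: float = 8.0
    despike_floor: float = 0.05        # scale floor, fraction of spectrum range
    poly_order: int = 3
    poly_iterations: int = 10
    rubberband_iterations: int = 10
    rubberband_bend: float = 1.0
    savgol_points: int = 11
    savgol_polyorder: int = 2
    keep_range: tuple[float, float] | None = (500.0, 3100.0)
    quality_window: BandWindow = BandWindow("amide_I", 1620.0, 1680.0)
    quality_threshold: float = 0.2
    denoise_components: int = 13
    rmies_components: int = 7
    rmies_iterations: int = 1

    def __post_init__(self) -> None:
        if self.despike_filter_size % 2 == 0 or self.despike_filter_size < 3:
            raise ValidationError("despike filter size must be odd and >= 3")
        if self.savgol_points % 2 == 0 or self.savgol_points <= self.savgol_polyorder:
            raise ValidationError("Savitzky-Golay window must be odd and > polyorder")
        if self.quality_threshold < 0:
            raise ValidationError("quality threshold must be nonnegative")

    @classmethod
    def defaults(cls, modality: Modality | str) -> "PreprocessConfig":
        modality = Modality.coerce(modality)
        if modality is Modality.RAMAN:
            return cls()
        return cls(savgol_points=13, keep_range=None)


# ------------------------------------------------------------------ despike

def _despike_array(
    data: np.ndarray, filter_size: int, dynamic_factor: float, floor: float
) -> tuple[np.ndarray, np.ndarray]:
    """Despike over the last axis; returns (cleaned, flagged boolean mask)."""
    med = ndimage.median_filter(
        data, size=(1,) * (data.ndim - 1) + (filter_size,), mode="nearest"
    )
    resid = data - med
    mad = np.median(np.abs(resid), axis=-1, keepdims=True)
    span = np.ptp(data, axis=-1, keepdims=True)
    # Genuine bands never produce running-median residuals near the spectral
    # range, so the robust scale is floored at a fraction of it; this keeps
    # sharp band tops untouched while cosmic spikes (several times the local
    # maximum) remain far above threshold.
    scale = np.maximum(1.4826 * mad, floor * span)
    flagged = np.abs(resid) > dynamic_factor * scale
    cleaned = np.where(flagged, med, data)
    return cleaned, flagged


def despike(
    cube: HyperspectralCube,
    filter_size: int = 3,
    dynamic_factor: float = 8.0,
    floor: float = 0.05,
) -> tuple[HyperspectralCube, np.ndarray]:
    """Remove cosmic-ray spikes; returns (cube, boolean map of replaced channels).

    A channel is replaced by its running median when its residual exceeds
    ``dynamic_factor`` times a robust scale of the spectrum's residuals
    (MAD-based, floored at ``floor`` x the spectrum's peak-to-peak range).
    All other channels are bit-unchanged.
    """
    if filter_size % 2 == 0 or filter_size < 3:
        raise ValidationError("filter_size must be odd and >= 3")
    cleaned, flagged = _despike_array(cube.data, filter_size, dynamic_factor, floor)
    return cube.with_data(cleaned), flagged


def despike_spectrum(
    spectrum: Spectrum, filter_size: int = 3, dynamic_factor: float = 8.0,
    floor: float = 0.05,
) -> Spectrum:
    cleaned, _ = _despike_array(
        spectrum.intensities[None, :], filter_size, dynamic_factor, floor
    )
    return spectrum.with_intensities(cleaned[0])


# ----------------------------------------------------------------- baseline

def _poly_baseline_batch(
    Y: np.ndarray, x: np.ndarray, order: int, iterations: int
) -> np.ndarray:
    """Lower-envelope polynomial baseline for each row of Y.

    Iteratively reweighted least squares: points above the current fit are
    down-weighted so the polynomial settles under the peaks.
    """
    xn = 2.0 * (x - x[0]) / (x[-1] - x[0]) - 1.0
    A = np.polynomial.polynomial.polyvander(xn, order)  # (C, K)
    W = np.ones_like(Y)
    baseline = np.zeros_like(Y)
    for _ in range(iterations):
        M = np.einsum("pc,ck,cl->pkl", W, A, A)
        b = np.einsum("pc,pc,ck->pk", W, Y, A)
        beta = np.linalg.solve(M, b[..., None])[..., 0]
        baseline = beta @ A.T
        W = np.where(Y <= baseline, 1.0, 0.05)
    return baseline


def _lower_hull_indices(x: np.ndarray, y: np.ndarray) -> list[int]:
    """Andrew monotone chain, lower hull of points sorted by x."""
    hull: list[int] = []
    for i in range(len(x)):
        while len(hull) >= 2:
            o, a = hull[-2], hull[-1]
            cross = (x[a] - x[o]) * (y[i] - y[o]) - (y[a] - y[o]) * (x[i] - x[o])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def _rubberband_values(
    x: np.ndarray, y: np.ndarray, iterations: int, bend_scale: float
) -> np.ndarray:
    """Concave rubber-band baseline removal on one intensity vector.

    Each pass bends the working spectrum convex by subtracting a parabolic
    sag (halved every iteration) before taking the lower convex hull; the
    estimated baseline is the hull plus the sag, which lets the support
    curve follow concave baseline regions a plain hull would bridge.  The
    estimate never exceeds the spectrum, so nonnegative input stays
    nonnegative.
    """
    corrected = y.astype(float).copy()
    span = np.ptp(y)
    if span == 0:
        return corrected - corrected[0]
    shape = (x - x[0]) * (x[-1] - x) / ((x[-1] - x[0]) / 2.0) ** 2
    for i in range(max(1, iterations)):
        amp = bend_scale * span / 2.0**i
        z = corrected - amp * shape
        idx = _lower_hull_indices(x, z)
        corrected = z - np.interp(x, x[idx], z[idx])
    return corrected


def correct_baseline(
    spectrum: Spectrum,
    method: str = "poly",
    config: PreprocessConfig | None = None,
) -> Spectrum:
    """Baseline-correct one spectrum with ``'poly'`` or ``'rubberband'``."""
    config = config or PreprocessConfig()
    y = spectrum.intensities
    if method == "poly":
        if len(y) <= config.poly_order + 1:
            raise ValidationError("spectrum too short for polynomial baseline")
        baseline = _poly_baseline_batch(
            y[None, :], spectrum.axis.values, config.poly_order,
            config.poly_iterations,
        )[0]
        return spectrum.with_intensities(y - baseline)
    if method == "rubberband":
        return spectrum.with_intensities(
            _rubberband_values(spectrum.axis.values, y,
                               config.rubberband_iterations,
                               config.rubberband_bend)
        )
    raise ValidationError(f"unknown baseline method {method!r}")


def correct_baseline_cube(
    cube: HyperspectralCube, method: str = "poly",
    config: PreprocessConfig | None = None,
) -> HyperspectralCube:
    config = config or PreprocessConfig()
    flat = cube.flat()
    if method == "poly":
        baseline = _poly_baseline_batch(
            flat, cube.axis.values, config.poly_order, config.poly_iterations
        )
        return cube.with_data((flat - baseline).reshape(cube.data.shape))
    if method == "rubberband":
        out = np.empty_like(flat)
        for i in range(flat.shape[0]):
            out[i] = _rubberband_values(
                cube.axis.values, flat[i], config.rubberband_iterations,
                config.rubberband_bend,
            )
        return cube.with_data(out.reshape(cube.data.shape))
    raise ValidationError(f"unknown baseline method {method!r}")


# -------------------------------------------------------- smoothing & norm

def savgol(
    spectrum: Spectrum, points: int = 11, polyorder: int = 2, deriv: int = 0
) -> Spectrum:
    """Savitzky-Golay smoothing / differentiation with respect to wavenumber.

    With ``deriv=2`` positive bands appear as minima, the usual convention
    for second-derivative FTIR band-position analysis.
    """
    if points % 2 == 0 or points <= polyorder:
        raise ValidationError("points must be odd and > polyorder")
    if points > len(spectrum.axis):
        raise ValidationError("window exceeds spectrum length")
    out = signal.savgol_filter(
        spectrum.intensities, points, polyorder, deriv=deriv,
        delta=spectrum.axis.step, mode="interp",
    )
    return spectrum.with_intensities(out)


def savgol_cube(
    cube: HyperspectralCube, points: int, polyorder: int = 2, deriv: int = 0
) -> HyperspectralCube:
    out = signal.savgol_filter(
        cube.data, points, polyorder, deriv=deriv, delta=cube.axis.step,
        axis=-1, mode="interp",
    )
    return cube.with_data(out)


def vector_normalize(
    spectrum: Spectrum, region: BandWindow | None = None
) -> Spectrum:
    """Scale to unit Euclidean norm (over ``region`` if given)."""
    y = spectrum.intensities
    sl = (
        spectrum.axis.window_slice(region.low, region.high)
        if region is not None
        else slice(None)
    )
    norm = float(np.linalg.norm(y[sl]))
    if norm == 0.0:
        raise ValidationError("cannot vector-normalize a zero spectrum")
    return spectrum.with_intensities(y / norm)


def vector_normalize_array(data: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(data, axis=-1, keepdims=True)
    safe = np.where(norms == 0, 1.0, norms)
    return data / safe


# ----------------------------------------------------- quality and denoise

def quality_mask(
    cube: HyperspectralCube,
    window: BandWindow | None = None,
    threshold: float = 0.2,
) -> np.ndarray:
    """Pixels whose maximum absorbance inside ``window`` reaches ``threshold``."""
    window = window or BandWindow("amide_I", 1620.0, 1680.0)
    sl = cube.axis.window_slice(window.low, window.high)
    return cube.data[:, :, sl].max(axis=-1) >= threshold


def pca_denoise(
    cube: HyperspectralCube,
    n_components: int = 13,
    mask: np.ndarray | None = None,
) -> HyperspectralCube:
    """Project masked pixels onto the leading principal axes and reconstruct."""
    flat = cube.flat().copy()
    if mask is None:
        keep = np.ones(cube.n_pixels, dtype=bool)
    else:
        keep = np.asarray(mask, dtype=bool).reshape(cube.n_pixels)
    X = flat[keep]
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    if n_components < 1:
        raise ValidationError("not enough masked pixels for PCA denoising")
    pca = PCA(n_components=n_components, random_state=0)
    flat[keep] = pca.inverse_transform(pca.fit_transform(X))
    return cube.with_data(flat.reshape(cube.data.shape))


# ------------------------------------------------------------- RMieS-EMSC

def rmies_correct(
    spectra: Sequence[Spectrum] | np.ndarray,
    reference: Spectrum | np.ndarray,
    n_components: int = 7,
    n_iterations: int = 1,
    axis: WavenumberAxis | None = None,
    radius_range: tuple[float, float] = (2.0, 8.0),
    index_range: tuple[float, float] = (1.1, 1.5),
    grid: tuple[int, int] = (10, 10),
) -> list[Spectrum] | np.ndarray:
    """Mie-scattering EMSC correction against a reference spectrum.

    Builds a database of van de Hulst extinction curves over a grid of sphere
    radii and refractive indices, keeps its first ``n_components`` principal
    directions, regresses each spectrum on [constant, linear term, reference,
    components] and returns reference + residual / reference-coefficient.
    The corrected mean replaces the reference between iterations.
    """
    if isinstance(reference, Spectrum):
        if axis is None:
            axis = reference.axis
        ref = reference.intensities.astype(float)
    else:
        ref = np.asarray(reference, dtype=float)
    as_spectra = not isinstance(spectra, np.ndarray)
    if as_spectra:
        spectra = list(spectra)
        if axis is None:
            axis = spectra[0].axis
        Y = np.array([s.intensities for s in spectra], dtype=float)
        modality = spectra[0].modality
    else:
        Y = np.atleast_2d(np.asarray(spectra, dtype=float))
    if axis is None:
        raise ValidationError("axis required when passing raw arrays")
    if n_components < 1:
        raise ValidationError("n_components must be >= 1")

    db = extinction_database(axis.values, radius_range, index_range, *grid)
    db = db - db.mean(axis=0)
    _, _, vt = np.linalg.svd(db, full_matrices=False)
    comps = vt[:n_components]

    x = axis.values
    linear = (x - x.mean()) / np.ptp(x)
    corrected = Y.copy()
    for _ in range(max(1, n_iterations)):
        design = np.column_stack([np.ones_like(x), linear, ref, comps.T])
        beta, _, rank, _ = np.linalg.lstsq(design, corrected.T, rcond=None)
        if rank < design.shape[1]:
            warnings.warn("RMieS design matrix is rank deficient; "
                          "using the minimum-norm solution")
        fitted = design @ beta
        b = beta[2]
        b = np.where(np.abs(b) < 1e-8, np.where(b < 0, -1e-8, 1e-8), b)
        corrected = ref[None, :] + (corrected - fitted.T) / b[:, None]
        ref = corrected.mean(axis=0)
    if as_spectra:
        return [Spectrum(axis, row, modality) for row in corrected]
    return corrected


# ---------------------------------------------------------------- pipelines

def preprocess_raman_cube(
    cube: HyperspectralCube, config: PreprocessConfig | None = None
) -> tuple[HyperspectralCube, dict]:
    """Per-pixel Raman chain: despike, 3rd-order polynomial baseline."""
    config = config or PreprocessConfig.defaults(Modality.RAMAN)
    cube, flagged = despike(
        cube, config.despike_filter_size, config.despike_dynamic_factor,
        config.despike_floor,
    )
    cube = correct_baseline_cube(cube, "poly", config)
    log = {
        "steps": ["despike", "poly_baseline"],
        "spike_channels_replaced": int(flagged.sum()),
        "poly_order": config.poly_order,
    }
    return cube, log


def preprocess_ftir_cube(
    cube: HyperspectralCube, config: PreprocessConfig | None = None
) -> tuple[HyperspectralCube, np.ndarray, dict]:
    """FTIR chain: quality test, PCA denoise, smoothing, vector norm."""
    config = config or PreprocessConfig.defaults(Modality.FTIR)
    mask = quality_mask(cube, config.quality_window, config.quality_threshold)
    cube = pca_denoise(cube, config.denoise_components, mask)
    cube = savgol_cube(cube, config.savgol_points, config.savgol_polyorder)
    flat = cube.flat().copy()
    keep = mask.reshape(-1)
    flat[keep] = vector_normalize_array(flat[keep])
    cube = cube.with_data(flat.reshape(cube.data.shape))
    log = {
        "steps": ["quality_mask", "pca_denoise", "savgol", "vector_normalize"],
        "pixels_kept": int(mask.sum()),
        "pixels_total": int(mask.size),
        "denoise_components": config.denoise_components,
    }
    return cube, mask, log


def postprocess_mean_spectrum(
    spectrum: Spectrum, config: PreprocessConfig | None = None
) -> Spectrum:
    """Raman class-mean chain: rubber band, smoothing, crop, vector norm."""
    config = config or PreprocessConfig.defaults(Modality.RAMAN)
    out = correct_baseline(spectrum, "rubberband", config)
    out = savgol(out, config.savgol_points, config.savgol_polyorder)
    if config.keep_range is not None:
        low = max(config.keep_range[0], out.axis.low)
        high = min(config.keep_range[1], out.axis.high)
        out = out.crop(low, high)
    return vector_normalize(out)
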