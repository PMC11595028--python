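"""Synthetic adipocyte phantoms with ground truth.

A virtual adipocyte is a :class:`CellLayout`: mutually exclusive compartment
masks (lipid droplets, a one-pixel perilipidic shell around each droplet, an
elliptical nucleus, cytoplasm) plus a per-compartment molecular composition
in mole fractions of the component library.  :func:`render_cube` turns a
layout into an ideal hyperspectral cube; :func:`corrupt_cube` then adds the
instrumental artifacts the preprocessing stage is supposed to remove
(fluorescence-like polynomial baselines, Mie scattering extinction for FTIR,
Gaussian noise, cosmic-ray spikes) and returns a registry of everything it
injected so downstream recovery is checkable.

The default layouts model one cell filling the field of view.  The Raman
phantom (0.5 um pixels) resolves micrometre lipid droplets and the nucleus;
the FTIR phantom (5.5 um pixels) models a mature adipocyte with large
coalesced droplets, and every in-cell FTIR pixel additionally receives a
through-thickness cytoplasm overlay because transmission FTIR integrates the
whole cell depth while confocal Raman sections optically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import yaml
from scipy import ndimage

from .core import (
    HyperspectralCube,
    Modality,
    ValidationError,
    WavenumberAxis,
)
from .library import ComponentSpectrum, compartment_spectrum, default_library
from .mie import vandehulst_q

__all__ = [
    "COMPARTMENTS",
    "default_raman_axis",
    "default_ftir_axis",
    "default_composition",
    "LayoutConfig",
    "CellLayout",
    "CorruptionSpec",
    "sample_cell_layout",
    "render_cube",
    "corrupt_cube",
    "droplet_scatter_weight",
    "simulate_cube",
    "save_ground_truth",
]

COMPARTMENTS = (
    "background",
    "lipid_droplet",
    "perilipidic_area",
    "nucleus",
    "cytoplasm",
)

_EIGHT = np.ones((3, 3), dtype=bool)
_FWHM_G = 2.0 * np.sqrt(2.0 * np.log(2.0))


def default_raman_axis() -> WavenumberAxis:
    """550-3100 cm^-1 at a 3 cm^-1 step."""
    return WavenumberAxis.regular(550.0, 3100.0, 3.0)


def default_ftir_axis() -> WavenumberAxis:
    """900-3700 cm^-1 at a 4 cm^-1 step."""
    return WavenumberAxis.regular(900.0, 3700.0, 4.0)


def default_composition() -> dict[str, dict[str, float]]:
    """Per-compartment mole fractions of the default library components.

    The lipid-droplet acyl pool is dominated by stearic, palmitic and oleic
    chains with a mean of 0.42 C=C bonds per chain; the minor TAG, CE and PL
    fractions are fixed so that the pooled unsaturation stays at exactly
    0.42 C=C per chain.
    """
    return {
        "lipid_droplet": {
            "SFA_18_0": 0.28110,
            "SFA_16_0": 0.26236,
            "MUFA_18_1": 0.39354,
            "TAG_48_1": 0.037,
            "CE_14_1": 0.013,
            "PL_34_1": 0.013,
        },
        "perilipidic_area": {
            "PL_34_1": 0.35,
            "MUFA_18_1": 0.10,
            "protein_beta": 0.30,
            "cytochrome": 0.10,
            "sugar": 0.15,
        },
        "nucleus": {
            "nucleic_acid": 0.45,
            "protein_alpha": 0.40,
            "PL_34_1": 0.15,
        },
        "cytoplasm": {
            "protein_alpha": 0.60,
            "cytochrome": 0.08,
            "nucleic_acid": 0.07,
            "sugar": 0.10,
            "PL_34_1": 0.15,
        },
    }


@dataclass
class LayoutConfig:
    """Geometry and composition of one virtual cell."""

    field_um: float = 32.0
    pixel_size: float = 0.5
    nucleus_area_mean: float = 60.0   # um^2
    nucleus_area_sd: float = 8.0
    ld_area_median: float = 3.0       # um^2, log-normal
    ld_area_sigma: float = 0.8        # log-sd; right tail reaches tens of um^2
    n_droplet_attempts: int = 30
    composition: dict[str, dict[str, float]] = field(
        default_factory=default_composition
    )
    composition_jitter: float = 0.0   # log-sd of per-sample fraction jitter

    @classmethod
    def defaults(cls, modality: Modality | str) -> "LayoutConfig":
        modality = Modality.coerce(modality)
        if modality is Modality.RAMAN:
            return cls()
        # FTIR: wide field, coarse pixels, large coalesced droplets of a
        # mature adipocyte (several pixels across at 5.5 um)
        return cls(
            field_um=700.0,
            pixel_size=5.5,
            ld_area_median=700.0,
            ld_area_sigma=0.6,
            n_droplet_attempts=200,
        )


@dataclass
class CellLayout:
    """Ground truth: compartment masks + composition + droplet instances."""

    masks: dict[str, np.ndarray]
    composition: dict[str, dict[str, float]]
    pixel_size: float
    ld_instances: list[tuple[tuple[float, float], float]]  # ((row, col) px, radius px)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) != 1:
            raise ValidationError("compartment masks must share one shape")
        total = np.zeros(next(iter(shapes)), dtype=int)
        for mask in self.masks.values():
            total += mask.astype(int)
        if total.max() > 1:
            raise ValidationError("compartment masks must be mutually exclusive")
        for name, comp in self.composition.items():
            s = sum(comp.values())
            if comp and abs(s - 1.0) > 1e-8:
                raise ValidationError(
                    f"composition of {name!r} sums to {s}, expected 1"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.masks.values())).shape

    def label_map(self) -> np.ndarray:
        """Integer image: index into :data:`COMPARTMENTS`."""
        labels = np.zeros(self.shape, dtype=int)
        for idx, name in enumerate(COMPARTMENTS):
            if name in self.masks:
                labels[self.masks[name]] = idx
        return labels

    def in_cell(self) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        for name, m in self.masks.items():
            if name != "background":
                mask |= m
        return mask


def _jitter_composition(
    composition: dict[str, dict[str, float]], sigma: float, rng: np.random.Generator
) -> dict[str, dict[str, float]]:
    if sigma <= 0:
        return {k: dict(v) for k, v in composition.items()}
    out = {}
    for compartment, fractions in composition.items():
        names = list(fractions)
        values = np.array([fractions[n] for n in names])
        values = values * rng.lognormal(0.0, sigma, len(values))
        values /= values.sum()
        out[compartment] = dict(zip(names, values.tolist()))
    return out


def sample_cell_layout(
    config: LayoutConfig | None = None,
    seed: int = 0,
    modality: Modality | str = Modality.RAMAN,
) -> CellLayout:
    """Draw one random cell layout.

    The nucleus is an ellipse with a normally distributed area placed near
    the field centre; lipid droplets are discs with log-normal areas placed
    by rejection so that droplet + shell footprints never overlap each other
    or the nucleus.  Attempts that no longer fit are discarded, so dense
    configurations saturate gracefully.
    """
    if config is None:
        config = LayoutConfig.defaults(modality)
    rng = np.random.default_rng(seed)
    n = int(round(config.field_um / config.pixel_size))
    if n < 8:
        raise ValidationError("field of view too small for a cell layout")
    rows, cols = np.mgrid[0:n, 0:n].astype(float)

    # nucleus: random ellipse near the field centre
    area = max(10.0, rng.normal(config.nucleus_area_mean, config.nucleus_area_sd))
    ratio = rng.uniform(1.0, 1.8)
    a_px = np.sqrt(area * ratio / np.pi) / config.pixel_size
    b_px = np.sqrt(area / (np.pi * ratio)) / config.pixel_size
    theta = rng.uniform(0.0, np.pi)
    cr = n / 2 + rng.uniform(-n / 6, n / 6)
    cc = n / 2 + rng.uniform(-n / 6, n / 6)
    dr, dc = rows - cr, cols - cc
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    nucleus = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    if not nucleus.any():
        raise ValidationError("nucleus does not fit the field of view")

    ld = np.zeros((n, n), dtype=bool)
    shell = np.zeros((n, n), dtype=bool)
    instances: list[tuple[tuple[float, float], float]] = []
    mu = np.log(config.ld_area_median)
    for _ in range(config.n_droplet_attempts):
        area_ld = rng.lognormal(mu, config.ld_area_sigma)
        radius_px = np.sqrt(area_ld / np.pi) / config.pixel_size
        margin = radius_px + 2
        if 2 * margin >= n:
            continue
        r0 = rng.uniform(margin, n - margin)
        c0 = rng.uniform(margin, n - margin)
        disc = (rows - r0) ** 2 + (cols - c0) ** 2 <= radius_px**2
        if not disc.any():
            continue
        ring = ndimage.binary_dilation(disc, structure=_EIGHT) & ~disc
        footprint = disc | ring
        if (footprint & (nucleus | ld | shell)).any():
            continue
        ld |= disc
        shell |= ring
        instances.append(((r0, c0), radius_px))

    cytoplasm = ~(nucleus | ld | shell)
    masks = {
        "background": np.zeros((n, n), dtype=bool),
        "lipid_droplet": ld,
        "perilipidic_area": shell,
        "nucleus": nucleus,
        "cytoplasm": cytoplasm,
    }
    composition = _jitter_composition(
        config.composition, config.composition_jitter, rng
    )
    return CellLayout(masks, composition, config.pixel_size, instances)


def render_cube(
    layout: CellLayout,
    library: Mapping[str, ComponentSpectrum] | None = None,
    modality: Modality | str = Modality.RAMAN,
    axis: WavenumberAxis | None = None,
    psf_fwhm: float | None = None,
    gain: float | None = None,
    projection_overlay: float | None = None,
    band_scale: Mapping[str, Mapping[str, float]] | None = None,
) -> HyperspectralCube:
    """Render a layout into an ideal (artifact-free) hyperspectral cube.

    Each pixel is the mole-fraction-weighted sum of component spectra of its
    compartment, optionally blurred per channel with a Gaussian PSF of
    full-width-half-maximum ``psf_fwhm`` (um; defaults 0.3 Raman, 6.0 FTIR,
    the lateral resolutions of the two instruments).  ``gain`` scales the
    whole cube (default 4.0 for FTIR so in-cell amide-I absorbance sits in
    the 0.2-1 range probed by the quality test).  ``projection_overlay``
    adds that fraction of the cytoplasm spectrum to every in-cell pixel
    (default 0.5 for FTIR, 0 for Raman: transmission FTIR integrates the
    whole cell depth while confocal Raman sections optically);
    ``band_scale`` maps compartment -> {band role -> factor} for
    perturbation experiments.
    """
    modality = Modality.coerce(modality)
    if library is None:
        library = default_library()
    if axis is None:
        axis = default_raman_axis() if modality is Modality.RAMAN else default_ftir_axis()
    if psf_fwhm is None:
        psf_fwhm = 0.3 if modality is Modality.RAMAN else 6.0
    if gain is None:
        gain = 1.0 if modality is Modality.RAMAN else 4.0
    if projection_overlay is None:
        projection_overlay = 0.0 if modality is Modality.RAMAN else 0.5

    base = np.zeros((len(COMPARTMENTS), len(axis)))
    for idx, name in enumerate(COMPARTMENTS):
        comp = layout.composition.get(name)
        if comp:
            scale = band_scale.get(name) if band_scale else None
            base[idx] = compartment_spectrum(comp, library, axis, modality,
                                             scale).intensities
    labels = layout.label_map()
    data = base[labels]
    if projection_overlay > 0:
        cyto = base[COMPARTMENTS.index("cytoplasm")]
        data = data + projection_overlay * layout.in_cell()[..., None] * cyto
    data *= gain
    if psf_fwhm > 0:
        sigma_px = psf_fwhm / _FWHM_G / layout.pixel_size
        data = ndimage.gaussian_filter(data, sigma=(sigma_px, sigma_px, 0.0),
                                       mode="reflect")
    return HyperspectralCube(
        axis, data, layout.pixel_size, modality,
        {"generator": "adipospec.phantom", "psf_fwhm_um": psf_fwhm,
         "gain": gain, "projection_overlay": projection_overlay},
    )


@dataclass
class CorruptionSpec:
    """Instrumental artifact model; all randomness flows from ``seed``."""

    gaussian_sigma: float = 0.03      # noise sd, fraction of mean signal
    baseline_degree: int = 3
    baseline_scale: float = 0.5       # baseline amplitude, fraction of mean signal
    spike_rate: float = 0.02          # probability of one cosmic spike per pixel
    spike_amplitude: float = 10.0     # multiple of the pixel's max intensity
    spike_width: int = 1              # channels per spike
    mie: bool = False
    mie_radius_range: tuple[float, float] = (2.0, 8.0)   # um
    mie_index_range: tuple[float, float] = (1.1, 1.5)
    mie_amplitude_range: tuple[float, float] = (0.05, 0.15)  # absorbance units
    mie_correlation_px: float = 4.0   # spatial correlation of the Mie fields
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.spike_rate <= 1.0:
            raise ValidationError("spike_rate must be in [0, 1]")
        if self.gaussian_sigma < 0:
            raise ValidationError("gaussian_sigma must be nonnegative")

    @classmethod
    def defaults(cls, modality: Modality | str, seed: int = 0) -> "CorruptionSpec":
        modality = Modality.coerce(modality)
        if modality is Modality.RAMAN:
            return cls(seed=seed)
        return cls(
            gaussian_sigma=0.02,
            baseline_degree=2,
            baseline_scale=0.1,
            spike_rate=0.0,          # FPA detectors: no cosmic-ray spikes
            mie=True,
            seed=seed,
        )

    @classmethod
    def none(cls, seed: int = 0) -> "CorruptionSpec":
        return cls(gaussian_sigma=0.0, baseline_scale=0.0, spike_rate=0.0,
                   mie=False, seed=seed)


def _smooth_uniform_field(
    rng: np.random.Generator, shape: tuple[int, int],
    low: float, high: float, correlation_px: float,
) -> np.ndarray:
    """Spatially correlated field rescaled to [low, high]."""
    f = ndimage.gaussian_filter(rng.normal(size=shape), correlation_px,
                                mode="reflect")
    span = f.max() - f.min()
    if span == 0:
        return np.full(shape, 0.5 * (low + high))
    return low + (high - low) * (f - f.min()) / span


def droplet_scatter_weight(
    layout: CellLayout, floor: float = 0.2, blur_px: float = 1.0
) -> np.ndarray:
    """Per-pixel Mie scattering weight tied to droplet morphology.

    The spherical lipid droplets are the dominant Mie scatterers of an
    adipocyte, so scattering amplitude peaks on and around droplets and
    falls to ``floor`` over plain cytoplasm.
    """
    ld = layout.masks["lipid_droplet"].astype(float)
    return floor + (1.0 - floor) * np.clip(
        ndimage.gaussian_filter(ld, blur_px, mode="reflect"), 0.0, 1.0
    )


def corrupt_cube(
    cube: HyperspectralCube,
    spec: CorruptionSpec,
    scatter_weight: np.ndarray | None = None,
) -> tuple[HyperspectralCube, dict]:
    """Add artifacts in order: baseline, Mie extinction, noise, spikes.

    Mie scattering multiplies the transmitted intensity, which in absorbance
    units adds an extinction curve; it is therefore applied additively on
    the absorbance scale.  The Mie parameter fields are spatially smooth
    (scattering follows cell morphology, not the detector grid) and the
    amplitude is optionally weighted by ``scatter_weight`` (e.g.
    :func:`droplet_scatter_weight`).  Returns the corrupted cube and a
    registry of every injected artifact (baseline coefficients, per-pixel
    Mie parameters, the noise sd, and the list of spike locations).
    """
    rng = np.random.default_rng(spec.seed)
    data = cube.data.copy()
    n_pix = cube.n_pixels
    flat = data.reshape(n_pix, -1)
    mean_signal = float(np.abs(cube.data).mean())
    registry: dict = {"mean_signal": mean_signal, "noise_sigma": 0.0,
                      "spikes": [], "baseline": None, "mie": None}

    if spec.baseline_scale > 0:
        x = np.linspace(0.0, 1.0, flat.shape[1])
        powers = np.vstack([x**k for k in range(spec.baseline_degree + 1)])
        coeffs = np.empty((n_pix, spec.baseline_degree + 1))
        coeffs[:, 0] = rng.uniform(0.5, 1.5, n_pix)
        if spec.baseline_degree > 0:
            coeffs[:, 1:] = rng.normal(0.0, 0.5, (n_pix, spec.baseline_degree))
        baseline = spec.baseline_scale * mean_signal * (coeffs @ powers)
        flat += baseline
        registry["baseline"] = {"coefficients": coeffs,
                                "scale": spec.baseline_scale * mean_signal}

    if spec.mie:
        shape = (cube.height, cube.width)
        corr = spec.mie_correlation_px
        radii = _smooth_uniform_field(rng, shape, *spec.mie_radius_range, corr)
        indices = _smooth_uniform_field(rng, shape, *spec.mie_index_range, corr)
        amps = _smooth_uniform_field(rng, shape, *spec.mie_amplitude_range, corr)
        if scatter_weight is not None:
            amps = amps * np.asarray(scatter_weight, dtype=float)
        rho = (
            4.0 * np.pi * (radii[..., None] * 1e-4)
            * (indices[..., None] - 1.0) * cube.axis.values
        )
        data += amps[..., None] * 0.5 * vandehulst_q(rho)
        registry["mie"] = {"radius_um": radii, "ref_index": indices,
                           "amplitude": amps}

    if spec.gaussian_sigma > 0:
        sigma = spec.gaussian_sigma * mean_signal
        flat += rng.normal(0.0, sigma, flat.shape)
        registry["noise_sigma"] = sigma

    if spec.spike_rate > 0:
        hit = rng.random(n_pix) < spec.spike_rate
        channels = rng.integers(0, flat.shape[1], n_pix)
        for i in np.nonzero(hit)[0]:
            ch = int(channels[i])
            height = spec.spike_amplitude * max(flat[i].max(), mean_signal)
            stop = min(ch + spec.spike_width, flat.shape[1])
            flat[i, ch:stop] += height
            r, c = divmod(i, cube.width)
            registry["spikes"].append((int(r), int(c), ch))

    return cube.with_data(data), registry


def simulate_cube(
    modality: Modality | str = Modality.RAMAN,
    seed: int = 0,
    layout_config: LayoutConfig | None = None,
    corruption: CorruptionSpec | None = None,
    library: Mapping[str, ComponentSpectrum] | None = None,
    band_scale: Mapping[str, Mapping[str, float]] | None = None,
    psf_fwhm: float | None = None,
) -> tuple[HyperspectralCube, CellLayout, dict]:
    """Layout + render + corrupt in one call.

    Sub-stage seeds are split deterministically from ``seed`` (layout uses
    ``seed``, corruption ``seed + 1``), so one integer reproduces the cube.
    Returns (corrupted cube, ground-truth layout, artifact registry).
    """
    modality = Modality.coerce(modality)
    layout = sample_cell_layout(layout_config, seed=seed, modality=modality)
    clean = render_cube(layout, library, modality, psf_fwhm=psf_fwhm,
                        band_scale=band_scale)
    if corruption is None:
        corruption = CorruptionSpec.defaults(modality, seed=seed + 1)
    else:
        corruption = replace(corruption, seed=corruption.seed + seed + 1)
    weight = droplet_scatter_weight(layout) if corruption.mie else None
    corrupted, registry = corrupt_cube(clean, corruption, weight)
    registry["clean"] = clean
    return corrupted, layout, registry


def save_ground_truth(layout: CellLayout, base_path) -> None:
    """Sidecar ground truth: label CSV + composition YAML."""
    from pathlib import Path

    base = Path(base_path)
    np.savetxt(base.with_suffix(".labels.csv"), layout.label_map(),
               fmt="%d", delimiter=",")
    payload = {
        "compartments": list(COMPARTMENTS),
        "pixel_size": layout.pixel_size,
        "composition": layout.composition,
        "ld_instances": [
            {"row": float(r), "col": float(c), "radius_px": float(rad)}
            for (r, c), rad in layout.ld_instances
        ],
    }
    base.with_suffix(".truth.yaml").write_text(yaml.safe_dump(payload))
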