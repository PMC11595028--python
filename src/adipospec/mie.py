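"""Van de Hulst approximation of Mie extinction by a homogeneous sphere.

Q(rho) = 2 - (4/rho) sin(rho) + (4/rho^2)(1 - cos(rho)),
rho = 4 pi r (n - 1) nu, with sphere radius r, relative refractive index n
and wavenumber nu.  These smooth oscillatory curves are the dominant
baseline distortion of transmission FTIR microspectra of single cells and
form the basis set of the scattering correction.
"""

from __future__ import annotations

import numpy as np

__all__ = ["vandehulst_q", "extinction_curve", "extinction_database"]


def vandehulst_q(rho: np.ndarray) -> np.ndarray:
    """Extinction efficiency Q(rho); the rho -> 0 limit is 0."""
    rho = np.asarray(rho, dtype=float)
    out = np.empty_like(rho)
    small = np.abs(rho) < 1e-6
    r = np.where(small, 1.0, rho)
    out = 2.0 - (4.0 / r) * np.sin(r) + (4.0 / r**2) * (1.0 - np.cos(r))
    return np.where(small, 0.0, out)


def extinction_curve(
    wavenumbers: np.ndarray, radius_um: float, ref_index: float
) -> np.ndarray:
    """Q along a wavenumber axis (cm^-1) for one (radius, index) pair."""
    radius_cm = radius_um * 1e-4
    rho = 4.0 * np.pi * radius_cm * (ref_index - 1.0) * np.asarray(wavenumbers)
    return vandehulst_q(rho)


def extinction_database(
    wavenumbers: np.ndarray,
    radius_range: tuple[float, float] = (2.0, 8.0),
    index_range: tuple[float, float] = (1.1, 1.5),
    n_radii: int = 10,
    n_indices: int = 10,
) -> np.ndarray:
    """Grid of extinction curves, shape (n_radii * n_indices, channels)."""
    radii = np.linspace(*radius_range, n_radii)
    indices = np.linspace(*index_range, n_indices)
    curves = [
        extinction_curve(wavenumbers, r, n) for r in radii for n in indices
    ]
    return np.asarray(curves)
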