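"""Confocal point-spread function from the scalar Debye integral.

The focal field of an aplanatic objective of half-angle alpha is

    U(v, u) = (2 pi / lambda) * integral_0^alpha P(theta)
              J0(v sin(theta)/sin(alpha))
              exp(i u sin^2(theta/2) / (2 sin^2(alpha/2))) sin(theta) dtheta

in normalized optical coordinates v = k r sin(alpha), u = 4 k z
sin^2(alpha/2), k = 2 pi n / lambda.  The unit-modulus propagation phase
does not affect |U| and is omitted.  A confocal microscope with an ideal
(point) pinhole has intensity PSF |U_ex|^2 |U_em|^2.

Expansion microscopy is modeled by shrinking the PSF by the expansion
factor rather than enlarging the specimen: :func:`scale_psf` divides the
voxel pitch (here always in pre-expansion sample units) by the factor and
leaves the sampled intensities untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy import ndimage
from scipy.special import j0

__all__ = [
    "PSFKernel",
    "debye_field",
    "confocal_psf",
    "scale_psf",
    "render_confocal_psf",
    "resample_psf",
    "fwhm_of_profile",
    "psf_fwhm_nm",
]

DEFAULT_NA = 1.15
DEFAULT_WAVELENGTH_EX = 561.0  # nm, red membrane channel
DEFAULT_WAVELENGTH_EM = 590.0  # nm
DEFAULT_IMMERSION_INDEX = 1.33  # water-dipped into the expanded hydrogel


@dataclass
class PSFKernel:
    """Sampled 3-D intensity PSF with physical pitch metadata.

    ``intensity`` has axis order (z, y, x) and sums to 1; ``voxel_pitch``
    is (dz, dy, dx) in nm of *pre-expansion* sample space once
    :func:`scale_psf` has been applied.
    """

    intensity: np.ndarray
    voxel_pitch: tuple[float, float, float]
    wavelength_ex: float = DEFAULT_WAVELENGTH_EX
    wavelength_em: float = DEFAULT_WAVELENGTH_EM
    na: float = DEFAULT_NA
    expansion_factor: float = 1.0

    def __post_init__(self) -> None:
        if np.any(self.intensity < 0):
            raise ValueError("PSF intensity must be non-negative")
        if any(p <= 0 for p in self.voxel_pitch):
            raise ValueError("voxel_pitch must be positive")


def _aplanatic(theta: np.ndarray) -> np.ndarray:
    return np.sqrt(np.cos(theta))


def debye_field(
    na: float,
    wavelength: float,
    v_grid: np.ndarray,
    u_grid: np.ndarray,
    n_immersion: float = DEFAULT_IMMERSION_INDEX,
    apodization: Callable[[np.ndarray], np.ndarray] = _aplanatic,
    quad_tol: float = 1e-6,
    max_order: int = 4096,
) -> np.ndarray:
    """Scalar focal field U(v, u) by Gauss-Legendre quadrature over theta.

    ``v_grid`` and ``u_grid`` are broadcastable arrays of normalized radial
    and axial coordinates.  The quadrature order is doubled until the
    max-abs change of U falls below ``quad_tol`` (relative to the on-axis
    amplitude); failure to converge raises a numerical error.
    """
    if not 0 < na < n_immersion:
        raise ValueError("require 0 < NA < immersion index")
    v = np.asarray(v_grid, dtype=float)
    u = np.asarray(u_grid, dtype=float)
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(u))):
        raise ValueError("grids must be finite")
    alpha = float(np.arcsin(na / n_immersion))
    sin_a = np.sin(alpha)
    sin2_ha = np.sin(alpha / 2.0) ** 2

    def evaluate(order: int) -> np.ndarray:
        nodes, weights = np.polynomial.legendre.leggauss(order)
        theta = 0.5 * alpha * (nodes + 1.0)
        w = 0.5 * alpha * weights
        st = np.sin(theta)
        sh = np.sin(theta / 2.0) ** 2
        amp = apodization(theta) * st * w  # (order,)
        bess = j0(np.multiply.outer(v, st / sin_a))  # (..., order)
        phase = np.exp(1j * np.multiply.outer(u, sh / (2.0 * sin2_ha)))
        return (2.0 * np.pi / wavelength) * np.sum(bess * phase * amp, axis=-1)

    order = 32
    prev = evaluate(order)
    scale = max(np.abs(prev).max(), 1e-300)
    while order <= max_order:
        order *= 2
        cur = evaluate(order)
        if np.abs(cur - prev).max() / scale < quad_tol:
            return cur
        prev = cur
    raise ArithmeticError(
        f"Debye quadrature did not converge to {quad_tol} below order {max_order}"
    )


def confocal_psf(
    excitation: np.ndarray,
    emission: np.ndarray,
    voxel_pitch: tuple[float, float, float],
    **meta,
) -> PSFKernel:
    """Ideal-pinhole confocal intensity: |U_ex|^2 |U_em|^2, unit-sum."""
    ex = np.asarray(excitation)
    em = np.asarray(emission)
    if ex.shape != em.shape:
        raise ValueError(f"field grids differ: {ex.shape} vs {em.shape}")
    intensity = (np.abs(ex) ** 2) * (np.abs(em) ** 2)
    s = intensity.sum()
    if s <= 0:
        raise ValueError("zero-intensity PSF")
    return PSFKernel(intensity=intensity / s, voxel_pitch=tuple(voxel_pitch), **meta)


def scale_psf(psf: PSFKernel, expansion_factor: float) -> PSFKernel:
    """Apply expansion-microscopy scaling: pitch /= factor, samples unchanged."""
    if expansion_factor < 1:
        raise ValueError("expansion_factor must be >= 1")
    pitch = tuple(p / expansion_factor for p in psf.voxel_pitch)
    return replace(
        psf,
        intensity=psf.intensity.copy(),
        voxel_pitch=pitch,
        expansion_factor=psf.expansion_factor * expansion_factor,
    )


def fwhm_of_profile(x: np.ndarray, y: np.ndarray) -> float:
    """Full width at half maximum of a sampled unimodal profile.

    Half-max crossings are located by linear interpolation between the
    bracketing samples on each side of the peak.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ipk = int(np.argmax(y))
    half = y[ipk] / 2.0

    def crossing(idx_range) -> float:
        prev = ipk
        for i in idx_range:
            if y[i] < half:
                # interpolate between i and prev
                t = (half - y[i]) / (y[prev] - y[i])
                return x[i] + t * (x[prev] - x[i])
            prev = i
        raise ValueError("profile does not fall below half maximum")

    left = crossing(range(ipk - 1, -1, -1))
    right = crossing(range(ipk + 1, len(y)))
    return float(abs(right - left))


def _fields_on_grid(na, wl_ex, wl_em, n_immersion, r_nm, z_nm):
    """Excitation/emission fields over an (r, z) polar grid (optical units)."""
    alpha = np.arcsin(na / n_immersion)
    out = []
    for wl in (wl_ex, wl_em):
        k = 2.0 * np.pi * n_immersion / wl
        v = k * r_nm * np.sin(alpha)
        u = 4.0 * k * z_nm * np.sin(alpha / 2.0) ** 2
        out.append(debye_field(na, wl, v, u, n_immersion=n_immersion))
    return out


def render_confocal_psf(
    na: float = DEFAULT_NA,
    wavelength_ex: float = DEFAULT_WAVELENGTH_EX,
    wavelength_em: float = DEFAULT_WAVELENGTH_EM,
    voxel_pitch: tuple[float, float, float] = (60.0, 30.0, 30.0),
    n_immersion: float = DEFAULT_IMMERSION_INDEX,
    support_fwhm: float = 4.0,
) -> PSFKernel:
    """Sample the confocal PSF on a Cartesian grid in optical (nm) units.

    The support is truncated at ``support_fwhm`` times the lateral/axial
    FWHM per axis (odd voxel counts, peak at the central voxel) and the
    kernel renormalized to unit sum.  ``voxel_pitch`` is (dz, dy, dx) nm in
    the un-expanded optical space; apply :func:`scale_psf` afterwards for
    expansion microscopy.
    """
    # probe FWHMs on fine 1-D profiles first to size the support
    r_probe = np.linspace(0, 4 * wavelength_em, 2048)
    z_probe = np.linspace(0, 16 * wavelength_em, 2048)
    ex_r, em_r = _fields_on_grid(na, wavelength_ex, wavelength_em, n_immersion, r_probe, 0.0)
    ex_z, em_z = _fields_on_grid(na, wavelength_ex, wavelength_em, n_immersion, 0.0 * z_probe, z_probe)
    lat = np.abs(ex_r) ** 2 * np.abs(em_r) ** 2
    axi = np.abs(ex_z) ** 2 * np.abs(em_z) ** 2
    fwhm_lat = fwhm_of_profile(np.concatenate([-r_probe[::-1], r_probe]),
                               np.concatenate([lat[::-1], lat]))
    fwhm_ax = fwhm_of_profile(np.concatenate([-z_probe[::-1], z_probe]),
                              np.concatenate([axi[::-1], axi]))

    dz, dy, dx = voxel_pitch
    half = [
        max(1, int(np.ceil(support_fwhm * fwhm_ax / 2.0 / dz))),
        max(1, int(np.ceil(support_fwhm * fwhm_lat / 2.0 / dy))),
        max(1, int(np.ceil(support_fwhm * fwhm_lat / 2.0 / dx))),
    ]
    z = np.arange(-half[0], half[0] + 1) * dz
    y = np.arange(-half[1], half[1] + 1) * dy
    x = np.arange(-half[2], half[2] + 1) * dx
    r = np.sqrt(y[:, None] ** 2 + x[None, :] ** 2)
    # radial symmetry: evaluate on unique radii only, then broadcast over z
    r_unique, inv = np.unique(np.round(r, 6), return_inverse=True)
    rr = np.broadcast_to(r_unique[None, :], (z.size, r_unique.size))
    zz = np.broadcast_to(z[:, None], rr.shape)
    ex, em = _fields_on_grid(na, wavelength_ex, wavelength_em, n_immersion, rr, zz)
    intens_rz = np.abs(ex) ** 2 * np.abs(em) ** 2  # (nz, nr)
    intensity = intens_rz[:, inv].reshape(z.size, y.size, x.size)
    kern = confocal_psf(
        np.sqrt(np.sqrt(intensity)),  # re-pack as equal ex/em fields
        np.sqrt(np.sqrt(intensity)),
        (dz, dy, dx),
        wavelength_ex=wavelength_ex,
        wavelength_em=wavelength_em,
        na=na,
    )
    return kern


def resample_psf(psf: PSFKernel, target_pitch: tuple[float, float, float]) -> PSFKernel:
    """Linearly interpolate the PSF onto a new pitch, conserving total mass."""
    zoom = [p / t for p, t in zip(psf.voxel_pitch, target_pitch)]
    out = ndimage.zoom(psf.intensity, zoom, order=1, mode="nearest")
    out = np.clip(out, 0, None)
    # trim to odd extents so the peak stays central
    slc = tuple(slice(0, s - 1 if s % 2 == 0 else s) for s in out.shape)
    out = out[slc]
    s = out.sum()
    if s <= 0:
        raise ValueError("degenerate resampled PSF")
    return replace(psf, intensity=out / s, voxel_pitch=tuple(target_pitch))


def psf_fwhm_nm(psf: PSFKernel) -> tuple[float, float]:
    """(lateral, axial) FWHM in nm at the PSF's current pitch."""
    nz, ny, nx = psf.intensity.shape
    cz, cy, cx = nz // 2, ny // 2, nx // 2
    lat_x = psf.intensity[cz, cy, :]
    ax = psf.intensity[:, cy, cx]
    dz, dy, dx = psf.voxel_pitch
    f_lat = fwhm_of_profile(np.arange(nx) * dx, lat_x)
    f_ax = fwhm_of_profile(np.arange(nz) * dz, ax)
    return f_lat, f_ax
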