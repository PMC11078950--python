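"""Microscope optics model: PSF, depth of field, field of view, resolution.

All object-space lengths are in micrometres.  The camera pixel pitch ``e``
is a physical (sensor-plane) length; dividing by the magnification ``M``
gives the object-space sampling ``e / M``.

The point spread function is modelled either as an isotropic Gaussian with
``sigma = 0.21 * lambda / NA`` (the standard least-squares fit to the Airy
disk) or as the Airy-disk intensity pattern whose first zero falls at the
Rayleigh radius ``0.61 * lambda / NA``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf, j1


class InvalidConfigError(ValueError):
    """Raised when microscope parameters are unphysical."""


@dataclass(frozen=True)
class OpticsConfig:
    """Microscope acquisition parameters.

    Parameters
    ----------
    wavelength_em : float
        Emission wavelength in µm (drives PSF and DOF).
    numerical_aperture : float
        Objective NA; must not exceed the refractive index.
    magnification : float
        Total magnification M (≥ 1).
    refractive_index : float
        Refractive index µ of the imaging medium (1 for air).
    pixel_pitch : float
        Camera pixel size e in µm (sensor plane).
    wavelength_ex : float or None
        Excitation wavelength in µm; metadata only.
    psf_model : {"gaussian", "airy"}
        PSF parameterisation used by :func:`make_psf` and the renderer.
    """

    wavelength_em: float
    numerical_aperture: float
    magnification: float
    refractive_index: float = 1.0
    pixel_pitch: float = 6.45
    wavelength_ex: float | None = None
    psf_model: str = "gaussian"

    def __post_init__(self) -> None:
        for name in ("wavelength_em", "numerical_aperture", "magnification",
                     "refractive_index", "pixel_pitch"):
            if not getattr(self, name) > 0:
                raise InvalidConfigError(f"{name} must be positive")
        if self.numerical_aperture > self.refractive_index:
            # physically NA <= µ; tolerated (warning) because published DOF
            # figures are often quoted with µ = 1 even for immersion lenses
            warnings.warn(
                "numerical aperture exceeds the refractive index; "
                "check the immersion medium", RuntimeWarning)
        if self.magnification < 1:
            raise InvalidConfigError("magnification must be >= 1")
        if self.psf_model not in ("gaussian", "airy"):
            raise InvalidConfigError(f"unknown psf_model {self.psf_model!r}")

    @property
    def pixel_pitch_object(self) -> float:
        """Object-space sampling of one camera pixel, e / M, in µm."""
        return self.pixel_pitch / self.magnification

    @property
    def psf_sigma(self) -> float:
        """Gaussian PSF standard deviation 0.21·λ/NA in µm."""
        return 0.21 * self.wavelength_em / self.numerical_aperture


@dataclass
class PSFKernel:
    """A PSF sampled on a square grid, normalised to unit sum.

    ``values[i, j]`` samples the PSF at object-space position
    ``center + (i - m, j - m) * grid_spacing`` for an odd grid of half-size m.
    """

    values: np.ndarray
    grid_spacing: float
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or np.any(self.values < 0):
            raise ValueError("PSF kernel must be a 2D nonnegative grid")


def depth_of_field(optics: OpticsConfig) -> float:
    """Depth of field λ·µ/NA² + µ·e/(M·NA), in µm.

    The first term is the diffractive (wave-optics) depth; the second is the
    geometric contribution of the finite camera pixel.
    """
    lam, mu = optics.wavelength_em, optics.refractive_index
    na, m, e = optics.numerical_aperture, optics.magnification, optics.pixel_pitch
    return lam * mu / na**2 + mu * e / (m * na)


def field_of_view(optics: OpticsConfig,
                  sensor_pixels: tuple[int, int]) -> tuple[float, float]:
    """Object-space field of view (per axis: n_pixels · e / M), in µm."""
    nx, ny = sensor_pixels
    if nx <= 0 or ny <= 0:
        raise InvalidConfigError("sensor pixel counts must be positive")
    scale = optics.pixel_pitch / optics.magnification
    return (nx * scale, ny * scale)


def rayleigh_limit(optics: OpticsConfig) -> float:
    """Classical lateral resolution bound 0.61·λ/NA, in µm."""
    return 0.61 * optics.wavelength_em / optics.numerical_aperture


def psf_radial(optics: OpticsConfig, r: np.ndarray) -> np.ndarray:
    """Unnormalised PSF intensity at radius ``r`` µm from the emitter.

    Gaussian: exp(-r²/2σ²).  Airy: (2·J1(v)/v)² with v scaled so the first
    zero sits at the Rayleigh radius.
    """
    r = np.asarray(r, dtype=float)
    if optics.psf_model == "gaussian":
        s = optics.psf_sigma
        return np.exp(-0.5 * (r / s) ** 2)
    # First zero of J1 at v = 3.8317...; map it onto 0.61 λ / NA.
    v = r * (3.8317059702075125 / rayleigh_limit(optics))
    out = np.ones_like(v)
    nz = v != 0
    out[nz] = (2.0 * j1(v[nz]) / v[nz]) ** 2
    return out


def make_psf(optics: OpticsConfig, grid_spacing: float,
             support_radius: float) -> PSFKernel:
    """Sample the PSF on a square grid and normalise it to unit sum.

    Parameters
    ----------
    grid_spacing : float
        Sample spacing in object-space µm.
    support_radius : float
        Half-extent of the grid in µm; should cover at least ~3 PSF
        half-widths, otherwise a truncation warning is emitted.
    """
    if grid_spacing <= 0:
        raise InvalidConfigError("grid_spacing must be positive")
    if support_radius <= 0:
        raise InvalidConfigError("support_radius must be positive")
    m = int(np.ceil(support_radius / grid_spacing))
    ax = np.arange(-m, m + 1) * grid_spacing
    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    vals = psf_radial(optics, np.hypot(xx, yy))
    total = vals.sum()
    edge = vals[0, :].sum() + vals[-1, :].sum() + vals[1:-1, 0].sum() + vals[1:-1, -1].sum()
    if total <= 0 or edge / total > 0.01:
        warnings.warn(
            "PSF support radius truncates >1% of the kernel mass; "
            "increase support_radius", RuntimeWarning)
    return PSFKernel(values=vals / total, grid_spacing=grid_spacing)


def _gauss_pixel_integral(centers: np.ndarray, points: np.ndarray,
                          pitch: float, sigma: float) -> np.ndarray:
    """Integral of a unit 2D Gaussian at ``points`` over square pixels.

    centers : (n, 2) pixel-centre coordinates; points : (p, 2) emitter
    positions.  Returns (n, p).  Separable erf closed form.
    """
    h = pitch / 2.0
    root2s = np.sqrt(2.0) * sigma

    def axis(c, p):
        d = c[:, None] - p[None, :]
        return 0.5 * (erf((d + h) / root2s) - erf((d - h) / root2s))

    return axis(centers[:, 0], points[:, 0]) * axis(centers[:, 1], points[:, 1])


def pixel_integrated_psf(optics: OpticsConfig, pixel_centers: np.ndarray,
                         points: np.ndarray, pitch: float,
                         oversample: int = 8) -> np.ndarray:
    """PSF mass collected by each camera pixel from each source point.

    Parameters
    ----------
    pixel_centers : (n, 2) array
        Object-space centres of the camera pixel footprints, µm.
    points : (p, 2) array
        Continuous emitter / test-point positions, µm.
    pitch : float
        Pixel footprint side length in object space, µm.
    oversample : int
        Midpoint-quadrature subdivisions per pixel axis (Airy model only;
        the Gaussian model integrates in closed form).

    Returns
    -------
    (n, p) array of nonnegative pixel integrals, normalised so a fully
    captured PSF sums to 1 over pixels.
    """
    pixel_centers = np.atleast_2d(np.asarray(pixel_centers, dtype=float))
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if optics.psf_model == "gaussian":
        return _gauss_pixel_integral(pixel_centers, points, pitch,
                                     optics.psf_sigma)
    # Airy: midpoint quadrature on an oversampled sub-grid, normalised by
    # the analytic total power of the Airy pattern (pi * (2/k)^2 with the
    # scaling used in psf_radial -> computed numerically once).
    q = (np.arange(oversample) + 0.5) / oversample - 0.5
    offs = np.stack(np.meshgrid(q * pitch, q * pitch, indexing="ij"),
                    axis=-1).reshape(-1, 2)
    n, p = len(pixel_centers), len(points)
    out = np.zeros((n, p))
    for o in offs:
        d = (pixel_centers[:, None, :] + o) - points[None, :, :]
        out += psf_radial(optics, np.hypot(d[..., 0], d[..., 1]))
    cell = (pitch / oversample) ** 2
    # total power of (2 J1(v)/v)^2 over the plane, in object-space units
    k = 3.8317059702075125 / rayleigh_limit(optics)
    total_power = 4.0 * np.pi / k**2
    return out * cell / total_power
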