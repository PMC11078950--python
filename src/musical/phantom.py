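"""Synthetic fibril phantoms: ground truth, photokinetics, camera rendering.

The generator emulates autofluorescent fibrous matrix (collagen-like
curvilinear fibrils) imaged by a widefield fluorescence microscope:

1. smooth random centerlines, optionally crowded into a dense sub-region;
2. point emitters scattered along the fibrils at a Poisson linear density,
   with transverse Gaussian jitter standing in for the fibril cross-section;
3. independent per-emitter intensity fluctuations across frames (two-state
   Markov blinking, or lognormal brightness noise);
4. PSF blur, camera pixel integration, Poisson shot noise, Gaussian read
   noise, offset and bit-depth clipping.

Coordinates are object-space µm, (row-axis, col-axis), with the origin at
the field corner, matching the reconstruction core's conventions.  Every
operation is deterministic given its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter

from .core import ImageStack
from .optics import OpticsConfig, pixel_integrated_psf


@dataclass
class FluctuationModel:
    """Per-emitter temporal fluctuation statistics.

    kind : {"two_state_blinking", "lognormal_brightness"}
        Blinking is a stationary binary Markov chain with on-probability
        ``p_on`` and lag-1 state autocorrelation ``on_off_correlation``;
        lognormal draws i.i.d. per-frame brightness with the given CV.
    brightness_cv : float
        Extra multiplicative lognormal brightness noise (also applied on
        top of blinking when > 0).
    """

    kind: str = "two_state_blinking"
    p_on: float = 0.7
    on_off_correlation: float = 0.3
    brightness_cv: float = 0.2

    def __post_init__(self) -> None:
        if self.kind not in ("two_state_blinking", "lognormal_brightness"):
            raise ValueError(f"unknown fluctuation kind {self.kind!r}")
        if not 0.0 <= self.p_on <= 1.0:
            raise ValueError("p_on must be in [0, 1]")
        if not 0.0 <= self.on_off_correlation <= 1.0:
            raise ValueError("on_off_correlation must be in [0, 1]")
        if self.brightness_cv < 0:
            raise ValueError("brightness_cv must be >= 0")


@dataclass
class CameraModel:
    """Camera gain/noise model: counts = gain·Poisson(photons) + read noise + offset."""

    gain: float = 1.0
    read_noise_sd: float = 2.0
    offset: float = 100.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")


@dataclass
class FibrilPhantom:
    """Ground truth for a simulated fibril field.

    centerlines are densely sampled polylines in µm; ``density_raster`` is
    the emitter-count histogram on a grid of ``raster_pitch`` µm and sums to
    the emitter count.  ``dense_region`` is the (row0, row1, col0, col1)
    bounds in µm of the designated dense sub-region (None if uniform).
    """

    field_size: tuple[float, float]
    centerlines: list = field(default_factory=list)
    fibril_width: float = 0.1
    raster_pitch: float = 0.1
    emitters: np.ndarray | None = None          # (E, 2) µm
    emitter_brightness: np.ndarray | None = None  # (E,) photons/frame
    density_raster: np.ndarray | None = None
    dense_region: tuple[float, float, float, float] | None = None

    @property
    def n_emitters(self) -> int:
        return 0 if self.emitters is None else len(self.emitters)

    def raster_shape(self) -> tuple[int, int]:
        return (int(round(self.field_size[0] / self.raster_pitch)),
                int(round(self.field_size[1] / self.raster_pitch)))

    def region_masks(self, shape: tuple[int, int],
                     pitch: float) -> dict[str, np.ndarray]:
        """Dense / sparse boolean masks on a grid of the given pitch."""
        rows = (np.arange(shape[0]) + 0.5) * pitch
        cols = (np.arange(shape[1]) + 0.5) * pitch
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        if self.dense_region is None:
            dense = np.zeros(shape, dtype=bool)
        else:
            r0, r1, c0, c1 = self.dense_region
            dense = (rr >= r0) & (rr < r1) & (cc >= c0) & (cc < c1)
        return {"dense": dense, "sparse": ~dense}

    def total_length(self, region: str | None = None) -> float:
        """Summed centerline arclength (µm), optionally within one region."""
        total = 0.0
        for line in self.centerlines:
            seg = np.diff(line, axis=0)
            lens = np.hypot(seg[:, 0], seg[:, 1])
            if region is None or self.dense_region is None:
                keep = np.ones(len(lens), dtype=bool)
            else:
                mid = 0.5 * (line[:-1] + line[1:])
                r0, r1, c0, c1 = self.dense_region
                inside = ((mid[:, 0] >= r0) & (mid[:, 0] < r1)
                          & (mid[:, 1] >= c0) & (mid[:, 1] < c1))
                keep = inside if region == "dense" else ~inside
            total += float(lens[keep].sum())
        return total


def _smooth_polyline(rng: np.random.Generator, bounds, waviness: float,
                     n_ctrl: int = 8, samples_per_seg: int = 25) -> np.ndarray:
    """Random-walk control points smoothed by a cubic spline, clipped to bounds."""
    r0, r1, c0, c1 = bounds
    span = max(r1 - r0, c1 - c0)
    step = span / (n_ctrl - 1)
    pos = np.array([rng.uniform(r0, r1), rng.uniform(c0, c1)])
    theta = rng.uniform(0, 2 * np.pi)
    ctrl = [pos.copy()]
    for _ in range(n_ctrl - 1):
        theta += rng.normal(0.0, waviness)
        pos = pos + step * np.array([np.sin(theta), np.cos(theta)])
        # reflect off the region walls to stay inside
        for ax, (lo, hi) in enumerate(((r0, r1), (c0, c1))):
            if pos[ax] < lo:
                pos[ax] = 2 * lo - pos[ax]
                theta = -theta if ax == 0 else np.pi - theta
            elif pos[ax] > hi:
                pos[ax] = 2 * hi - pos[ax]
                theta = -theta if ax == 0 else np.pi - theta
        ctrl.append(pos.copy())
    ctrl = np.asarray(ctrl)
    t = np.arange(n_ctrl, dtype=float)
    cs = CubicSpline(t, ctrl, axis=0)
    tt = np.linspace(0.0, n_ctrl - 1.0, (n_ctrl - 1) * samples_per_seg + 1)
    line = cs(tt)
    line[:, 0] = np.clip(line[:, 0], r0, r1)
    line[:, 1] = np.clip(line[:, 1], c0, c1)
    return line


def generate_fibrils(field_size: tuple[float, float], n_fibrils: int,
                     waviness: float = 0.4, dense_fraction: float = 0.5,
                     seed: int | None = None,
                     dense_region_frac: float = 0.5,
                     fibril_width: float = 0.1,
                     raster_pitch: float = 0.1) -> FibrilPhantom:
    """Generate smooth random fibril centerlines with a dense sub-region.

    ``dense_fraction`` of the fibrils are confined to the dense region
    (the first ``dense_region_frac`` of the field along the column axis);
    the rest roam the remainder.  Deterministic per seed.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible phantoms")
    fr, fc = field_size
    if fr <= 0 or fc <= 0:
        raise ValueError("field_size must be positive")
    if not 0.0 <= dense_fraction <= 1.0:
        raise ValueError("dense_fraction must be in [0, 1]")
    min_span = 4.0 * raster_pitch
    if n_fibrils > 0 and (fr < min_span
                          or fc * dense_region_frac < min_span
                          or fc * (1.0 - dense_region_frac) < min_span):
        raise ValueError("field too small for the requested fibril layout")
    rng = np.random.default_rng(seed)
    split = dense_region_frac * fc
    dense_bounds = (0.0, fr, 0.0, split)
    sparse_bounds = (0.0, fr, split, fc)
    centerlines = []
    for _ in range(n_fibrils):
        in_dense = rng.uniform() < dense_fraction
        bounds = dense_bounds if in_dense else sparse_bounds
        centerlines.append(_smooth_polyline(rng, bounds, waviness))
    phantom = FibrilPhantom(field_size=(fr, fc), centerlines=centerlines,
                            fibril_width=fibril_width,
                            raster_pitch=raster_pitch,
                            dense_region=dense_bounds if n_fibrils else None)
    phantom.density_raster = np.zeros(phantom.raster_shape())
    return phantom


def place_emitters(phantom: FibrilPhantom, linear_density: float,
                   jitter_sd: float = 0.0, seed: int | None = None,
                   brightness: float = 500.0) -> FibrilPhantom:
    """Scatter emitters along the centerlines at a Poisson linear density.

    Spacing along each fibril is a Poisson process (``linear_density``
    emitters/µm); transverse Gaussian jitter of ``jitter_sd`` µm along the
    local normal emulates the fibril cross-section.  Updates the phantom's
    emitter table and density raster in place and returns it.
    """
    if linear_density <= 0:
        raise ValueError("linear_density must be positive")
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)
    positions, bright = [], []
    for line in phantom.centerlines:
        seg = np.diff(line, axis=0)
        seglen = np.hypot(seg[:, 0], seg[:, 1])
        total = seglen.sum()
        if total <= 0:
            continue
        n = rng.poisson(total * linear_density)
        if n == 0:
            continue
        s = np.sort(rng.uniform(0.0, total, size=n))
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0,
                      len(seglen) - 1)
        frac = (s - cum[idx]) / np.maximum(seglen[idx], 1e-300)
        pts = line[idx] + frac[:, None] * seg[idx]
        if jitter_sd > 0:
            tang = seg[idx] / np.maximum(seglen[idx], 1e-300)[:, None]
            normal = np.column_stack([-tang[:, 1], tang[:, 0]])
            pts = pts + rng.normal(0.0, jitter_sd, size=n)[:, None] * normal
        positions.append(pts)
        bright.append(np.full(n, brightness))
    if positions:
        pts = np.vstack(positions)
        fr, fc = phantom.field_size
        pts[:, 0] = np.clip(pts[:, 0], 0.0, np.nextafter(fr, 0.0))
        pts[:, 1] = np.clip(pts[:, 1], 0.0, np.nextafter(fc, 0.0))
        phantom.emitters = pts
        phantom.emitter_brightness = np.concatenate(bright)
    else:
        phantom.emitters = np.zeros((0, 2))
        phantom.emitter_brightness = np.zeros(0)
    phantom.density_raster = _count_raster(phantom)
    return phantom


def _count_raster(phantom: FibrilPhantom) -> np.ndarray:
    shape = phantom.raster_shape()
    fr, fc = phantom.field_size
    hist, _, _ = np.histogram2d(
        phantom.emitters[:, 0], phantom.emitters[:, 1], bins=shape,
        range=[[0.0, fr], [0.0, fc]])
    return hist


def simulate_fluctuations(emitter_brightness: np.ndarray,
                          model: FluctuationModel, n_frames: int,
                          seed: int | None = None) -> np.ndarray:
    """Per-frame brightness matrix (emitters × K), rows independent.

    Blinking: each emitter follows a stationary two-state Markov chain with
    on-probability ``p_on`` and transition persistence chosen so the lag-1
    state autocorrelation equals ``on_off_correlation``.  Lognormal: i.i.d.
    unit-mean multiplicative noise with the configured CV.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)
    b = np.asarray(emitter_brightness, dtype=float)
    e = b.size
    out = np.tile(b[:, None], (1, n_frames))
    if model.kind == "two_state_blinking":
        p, rho = model.p_on, model.on_off_correlation
        # transition probabilities with stationary p and eigenvalue rho
        p_on_on = p + rho * (1.0 - p)
        p_off_on = p * (1.0 - rho)
        state = rng.uniform(size=e) < p
        states = np.empty((e, n_frames), dtype=bool)
        for t in range(n_frames):
            states[:, t] = state
            pr = np.where(state, p_on_on, p_off_on)
            state = rng.uniform(size=e) < pr
        out = out * states
    if model.brightness_cv > 0:
        cv = model.brightness_cv
        sig2 = np.log1p(cv * cv)
        noise = rng.lognormal(-0.5 * sig2, np.sqrt(sig2), size=(e, n_frames))
        out = out * noise
    return out


def render_stack(phantom: FibrilPhantom, brightness_matrix: np.ndarray,
                 optics: OpticsConfig, camera: CameraModel | None = None,
                 seed: int | None = None, oversample: int = 8,
                 psf_cutoff_sigma: float = 5.0) -> ImageStack:
    """Render the phantom into a noisy camera stack.

    Each frame's expected photon image is the emitter field blurred by the
    optics PSF and integrated over the camera pixel footprints (closed-form
    for the Gaussian model, ``oversample``× midpoint quadrature for Airy).
    Counts are then gain-scaled Poisson draws plus Gaussian read noise and
    offset, clipped to the camera bit depth.  Deterministic per seed.
    """
    if seed is None:
        raise ValueError("a seed is required")
    camera = camera or CameraModel()
    rng = np.random.default_rng(seed)
    b = np.asarray(brightness_matrix, dtype=float)
    if b.ndim != 2 or b.shape[0] != phantom.n_emitters:
        raise ValueError("brightness_matrix must be (n_emitters, K)")
    pitch = optics.pixel_pitch_object
    fr, fc = phantom.field_size
    hh, ww = int(round(fr / pitch)), int(round(fc / pitch))
    k = b.shape[1]
    expected = np.zeros((hh * ww, k))
    if phantom.n_emitters:
        centers = _grid_centers(hh, ww, pitch)
        # chunk emitters to bound the (pixels × emitters) footprint matrix
        chunk = max(1, int(2e7 // (hh * ww)))
        for lo in range(0, phantom.n_emitters, chunk):
            hi = min(lo + chunk, phantom.n_emitters)
            a = pixel_integrated_psf(optics, centers, phantom.emitters[lo:hi],
                                     pitch, oversample=oversample)
            expected += a @ b[lo:hi]
    photons = rng.poisson(np.clip(expected, 0.0, None)).astype(np.float64)
    counts = camera.gain * photons + camera.offset
    if camera.read_noise_sd > 0:
        counts += rng.normal(0.0, camera.read_noise_sd, size=counts.shape)
    full_well = 2 ** camera.bit_depth - 1
    sat = np.mean(counts >= full_well)
    if sat > 0.01:
        warnings.warn(f"{100 * sat:.1f}% of pixels saturated", RuntimeWarning)
    counts = np.clip(counts, 0.0, full_well)
    frames = counts.T.reshape(k, hh, ww)
    return ImageStack(frames=frames, pixel_pitch_object=pitch,
                      metadata={"seed": seed, "gain": camera.gain,
                                "offset": camera.offset,
                                "read_noise_sd": camera.read_noise_sd})


def _grid_centers(hh: int, ww: int, pitch: float) -> np.ndarray:
    rows = (np.arange(hh) + 0.5) * pitch
    cols = (np.arange(ww) + 0.5) * pitch
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()])


def blur_density(density_raster: np.ndarray, blur_sigma: float) -> np.ndarray:
    """Gaussian blur of a ground-truth density raster.

    ``blur_sigma`` is in raster pixels; σ = 0 is the identity.  A large blur
    emulates a diffraction-limited rendering of the density, a small blur a
    super-resolved one.  Reflective boundary keeps the total conserved.
    """
    if blur_sigma < 0:
        raise ValueError("blur_sigma must be >= 0")
    if blur_sigma == 0:
        return np.asarray(density_raster, dtype=float).copy()
    return gaussian_filter(np.asarray(density_raster, dtype=float),
                           blur_sigma, mode="reflect", truncate=6.0)


def point_source_phantom(positions_um: np.ndarray,
                         field_size: tuple[float, float],
                         brightness: float = 500.0,
                         raster_pitch: float = 0.1) -> FibrilPhantom:
    """Phantom of isolated point emitters (no fibrils); for calibration."""
    pts = np.atleast_2d(np.asarray(positions_um, dtype=float))
    phantom = FibrilPhantom(field_size=field_size, centerlines=[],
                            raster_pitch=raster_pitch)
    phantom.emitters = pts
    phantom.emitter_brightness = np.full(len(pts), brightness)
    phantom.density_raster = _count_raster(phantom)
    return phantom


def fibrosis_series(field_size: tuple[float, float], n_fibrils: int,
                    heterogeneity_levels, seed: int,
                    linear_density: float = 3.0, jitter_sd: float = 0.05,
                    dense_region_frac: float = 0.25,
                    raster_pitch: float = 0.1) -> list[FibrilPhantom]:
    """Phantom series with programmed decreasing density heterogeneity.

    Each entry confines a decreasing fraction of its fibrils to the dense
    sub-region, emulating progressive homogenisation of the matrix (as in a
    fibrosis time course).  ``heterogeneity_levels`` are the dense fractions,
    given from most to least heterogeneous.
    """
    out = []
    for idx, dense_fraction in enumerate(heterogeneity_levels):
        ph = generate_fibrils(field_size, n_fibrils,
                              dense_fraction=dense_fraction,
                              seed=seed + 1000 * idx,
                              dense_region_frac=dense_region_frac,
                              raster_pitch=raster_pitch)
        place_emitters(ph, linear_density, jitter_sd=jitter_sd,
                       seed=seed + 1000 * idx + 1)
        out.append(ph)
    return out
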