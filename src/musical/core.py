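"""MUSICAL reconstruction core.

The algorithm treats a fluctuation image stack as a collection of sliding
N×N windows.  Each window's pixel-time matrix (N² × K) is factored by a thin
singular value decomposition; the leading ``r`` left singular vectors
("eigenimages") span the signal subspace, the remainder the noise subspace.
A continuous test point ``p`` is scored by projecting the unit-norm,
pixel-integrated PSF centred at ``p`` onto both subspaces:

    indicator(p) = (||P_S g|| / ||P_N g||) ** alpha

Points on true emitters produce PSF vectors nearly orthogonal to the noise
subspace, so the indicator peaks there far more sharply than the
diffraction-limited mean image.  Evaluating the indicator on an s×s sub-pixel
grid of each window's central camera pixel and stitching the blocks yields a
super-resolved map on a grid s times finer than the camera's.

Conventions (fixed package-wide):

* vectorization of an N×N crop is row-major (C order);
* pixel (i, j) covers the object-space square
  [i, i+1) × [j, j+1) · pitch, its centre at (i+0.5, j+0.5) · pitch,
  with the origin at the image corner; axis 0 = image rows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .optics import OpticsConfig, pixel_integrated_psf, rayleigh_limit

logger = logging.getLogger(__name__)

#: relative floor applied to singular values before taking log10 in the
#: knee search, and to the noise norm in the indicator
EPS_FLOOR = 1e-12


class DataError(ValueError):
    """Raised for non-finite or structurally invalid input data."""


class DegenerateSubspaceError(ValueError):
    """Raised when a window has no usable signal or noise subspace."""


@dataclass
class ImageStack:
    """K frames of H×W nonnegative intensities with acquisition metadata.

    ``pixel_pitch_object`` is the object-space size of one camera pixel
    (µm); ``frame_interval`` (s) is metadata only.
    """

    frames: np.ndarray
    pixel_pitch_object: float
    frame_interval: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise DataError("frames must be a K×H×W array")
        if self.frames.shape[0] < 2:
            raise DataError("a fluctuation stack needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise DataError("frames contain non-finite values")
        if np.any(self.frames < 0):
            raise DataError("frames contain negative intensities")
        if not self.pixel_pitch_object > 0:
            raise DataError("pixel_pitch_object must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def mean_frame(self) -> np.ndarray:
        """Temporal mean: the diffraction-limited image."""
        return self.frames.mean(axis=0)


@dataclass
class MusicalParams:
    """Reconstruction parameters.

    window_size : odd int or None
        Sliding-window side N in camera pixels; ``None`` derives the
        default from the optics (see :func:`default_window_size`).
    subpixels : int
        Sub-pixelation s: each camera pixel becomes an s×s block.
    alpha : float
        Contrast exponent of the indicator.
    threshold_mode : {"auto_knee", "manual"}
        Signal-rank selection: knee of the singular-value plot, or a fixed
        absolute singular-value cutoff (``threshold_value``).
    stride : int
        Window step in camera pixels; positions not visited stay invalid.
    mean_subtract : bool
        Subtract each pixel's temporal mean before the SVD (off by default:
        raw intensities are decomposed).
    """

    window_size: int | None = None
    subpixels: int = 10
    alpha: float = 4.0
    threshold_mode: str = "auto_knee"
    threshold_value: float | None = None
    stride: int = 1
    mean_subtract: bool = False

    def __post_init__(self) -> None:
        if self.window_size is not None:
            n = int(self.window_size)
            if n < 3 or n % 2 == 0:
                raise ValueError("window_size must be odd and >= 3")
            self.window_size = n
        if self.subpixels < 1:
            raise ValueError("subpixels must be >= 1")
        if not self.alpha > 0 and self.alpha != 0:
            raise ValueError("alpha must be nonnegative")
        if self.threshold_mode not in ("auto_knee", "manual"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.threshold_mode == "manual" and self.threshold_value is None:
            raise ValueError("manual threshold_mode needs threshold_value")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass
class SubspaceBasis:
    """Thin-SVD factorisation of one window's pixel-time matrix.

    ``eigenimages`` holds the left singular vectors as columns (length N²);
    ``signal_rank`` r marks columns 1..r as the signal subspace.
    """

    eigenimages: np.ndarray
    singular_values: np.ndarray
    signal_rank: int | None = None


@dataclass
class IndicatorMap:
    """Sub-pixelated indicator map with a validity mask.

    ``values`` is (s·H) × (s·W); ``valid_mask`` marks the reconstructed
    interior (window borders and degenerate windows are invalid).
    """

    values: np.ndarray
    valid_mask: np.ndarray
    params: MusicalParams
    pixel_pitch: float  # µm per *map* pixel (camera pitch / s)
    provenance: dict = field(default_factory=dict)

    @property
    def masked(self) -> np.ndarray:
        """values with invalid entries as NaN."""
        out = self.values.astype(float).copy()
        out[~self.valid_mask] = np.nan
        return out


def default_window_size(optics: OpticsConfig) -> int:
    """Smallest odd N covering twice the Rayleigh radius in camera pixels.

    The window must match the spatial spread of the PSF so the subspace
    model sees the whole blur of any emitter inside it.
    """
    span = 2.0 * rayleigh_limit(optics) / optics.pixel_pitch_object
    n = int(np.ceil(span + 1))
    if n % 2 == 0:
        n += 1
    return max(n, 3)


def extract_window(stack: ImageStack, center: tuple[int, int],
                   n: int) -> np.ndarray:
    """The N²×K pixel-time matrix of the N×N window centred at ``center``.

    Column j is the row-major vectorization of frame j's crop.
    """
    i, j = center
    h = (n - 1) // 2
    hh, ww = stack.shape
    if i - h < 0 or j - h < 0 or i + h >= hh or j + h >= ww:
        raise IndexError(f"window {n}x{n} at {center} exceeds image bounds")
    crop = stack.frames[:, i - h:i + h + 1, j - h:j + h + 1]
    return crop.reshape(stack.n_frames, n * n).T.copy()


def decompose_window(window_matrix: np.ndarray) -> SubspaceBasis:
    """Thin SVD of the window matrix; singular values nonincreasing."""
    m = np.asarray(window_matrix, dtype=float)
    if not np.all(np.isfinite(m)):
        raise DataError("window matrix contains non-finite entries")
    u, s, _ = np.linalg.svd(m, full_matrices=False)
    return SubspaceBasis(eigenimages=u, singular_values=s)


def knee_threshold(singular_values: np.ndarray) -> int:
    """Signal rank at the knee of the log10 singular-value plot.

    The knee is the point of maximum perpendicular distance between the
    log10 spectrum and the chord joining its endpoints; the returned rank r
    counts eigenimages 1..r into the signal subspace.  Values are floored at
    1e-12 of the maximum before the log.  A flat or log-linear spectrum has
    no knee; r = 1 is returned with a warning.  Ties go to the smaller rank.
    """
    s = np.asarray(singular_values, dtype=float)
    if s.size < 3:
        raise ValueError("knee detection needs at least 3 singular values")
    smax = s[0]
    if smax <= 0:
        warnings.warn("all-zero spectrum; returning rank 1", RuntimeWarning)
        return 1
    y = np.log10(np.maximum(s, EPS_FLOOR * smax))
    x = np.arange(s.size, dtype=float)
    # perpendicular distance to the chord (endpoints included, distance 0)
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / norm
    dmax = float(np.max(dist))
    if dmax <= 1e-9 * max(1.0, abs(dy)):
        warnings.warn("degenerate singular-value spectrum (no knee); "
                      "returning rank 1", RuntimeWarning)
        return 1
    # ties (to rounding) go to the smaller rank
    return int(np.argmax(dist >= dmax * (1.0 - 1e-9))) + 1


def psf_vector(optics: OpticsConfig, test_point: tuple[float, float],
               n: int, pitch: float, oversample: int = 8) -> np.ndarray:
    """Unit-norm pixel-integrated PSF vector for one test point.

    ``test_point`` is an object-space coordinate (µm) inside the window,
    whose pixel (i, j) occupies [i, i+1)×[j, j+1)·pitch.  The PSF centred at
    the point is integrated over each of the N² pixel footprints and
    vectorized row-major, matching :func:`extract_window`.
    """
    centers = _window_pixel_centers(n, pitch)
    g = pixel_integrated_psf(optics, centers, np.asarray(test_point, float),
                             pitch, oversample=oversample)[:, 0]
    nrm = np.linalg.norm(g)
    if nrm < 1e-300 or not np.isfinite(nrm):
        raise DegenerateSubspaceError(
            "test point outside the PSF support of the window")
    return g / nrm


def _window_pixel_centers(n: int, pitch: float) -> np.ndarray:
    """(N², 2) row-major pixel centres of an N×N window, origin at corner."""
    ax = (np.arange(n) + 0.5) * pitch
    ii, jj = np.meshgrid(ax, ax, indexing="ij")
    return np.column_stack([ii.ravel(), jj.ravel()])


def indicator(test_point: tuple[float, float], basis: SubspaceBasis,
              psf_vec: np.ndarray, alpha: float) -> float:
    """Indicator value (||P_S g|| / ||P_N g||)^alpha at one test point.

    The projections use only the retained thin-SVD eigenimages: signal =
    columns 1..r, noise = the remaining columns.  The noise norm is floored
    at 1e-12 to keep the ratio finite.
    """
    r = basis.signal_rank
    if r is None:
        raise ValueError("basis.signal_rank is not set")
    total = basis.eigenimages.shape[1]
    if r < 1:
        raise DegenerateSubspaceError("empty signal subspace (r = 0)")
    if r >= total:
        raise DegenerateSubspaceError(
            "no noise subspace: signal rank equals the thin-SVD rank")
    coeffs = basis.eigenimages.T @ psf_vec
    sig = float(np.linalg.norm(coeffs[:r]))
    noi = max(float(np.linalg.norm(coeffs[r:])), EPS_FLOOR)
    return (sig / noi) ** alpha


def _signal_rank(s: np.ndarray, params: MusicalParams) -> int:
    if params.threshold_mode == "manual":
        return int(np.sum(s > params.threshold_value))
    return knee_threshold(s)


def image_threshold(stack: ImageStack, window_size: int,
                    n_sample_windows: int = 40, seed: int = 0) -> float:
    """A single per-image singular-value cutoff at the knee.

    Samples window positions across the image, takes the median singular
    value spectrum, and returns the singular value at its knee.  Used with
    ``threshold_mode='manual'`` this reproduces the per-image heuristic
    thresholding practitioners apply when inspecting singular-value plots,
    and keeps windows without structure out of the map instead of forcing a
    spurious signal subspace on them.
    """
    half = (window_size - 1) // 2
    hh, ww = stack.shape
    if hh <= window_size or ww <= window_size:
        raise ValueError("image too small for the window")
    rng = np.random.default_rng(seed)
    spectra = []
    for _ in range(n_sample_windows):
        i = int(rng.integers(half, hh - half))
        j = int(rng.integers(half, ww - half))
        m = extract_window(stack, (i, j), window_size)
        spectra.append(np.linalg.svd(m, compute_uv=False))
    med = np.median(np.asarray(spectra), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = knee_threshold(med)
    return float(med[min(r, med.size - 1)])


def _window_spectrum_coeffs(m: np.ndarray, g: np.ndarray):
    """Singular values and projection coefficients U^T g of one window.

    Equivalent to a thin SVD followed by ``U.T @ g`` but computed through
    the smaller Gram matrix: time-side (K×K) when K < N², else space-side.
    Returns (singular_values, coeffs) with rows ordered by nonincreasing
    singular value.
    """
    n2, k = m.shape
    if k < n2:
        w, v = np.linalg.eigh(m.T @ m)
        w, v = w[::-1], v[:, ::-1]
        sv = np.sqrt(np.clip(w, 0.0, None))
        denom = np.maximum(sv, EPS_FLOOR * max(sv[0], 1.0))
        coeffs = (v.T @ (m.T @ g)) / denom[:, None]
    else:
        w, u = np.linalg.eigh(m @ m.T)
        w, u = w[::-1], u[:, ::-1]
        sv = np.sqrt(np.clip(w, 0.0, None))
        coeffs = u.T @ g
    return sv, coeffs


def reconstruct(stack: ImageStack, params: MusicalParams | None = None,
                optics: OpticsConfig | None = None) -> IndicatorMap:
    """Run the full sliding-window reconstruction.

    For each window position (stride steps of the window centre), the
    window matrix is decomposed, a signal rank chosen per
    ``params.threshold_mode``, and the indicator evaluated on the s×s
    sub-pixel grid of the window's central camera pixel.  A border of
    (N−1)/2 camera pixels and any degenerate windows are left invalid.
    Deterministic given its inputs.

    Returns an :class:`IndicatorMap` on the (s·H)×(s·W) grid.
    """
    if optics is None:
        raise ValueError("reconstruct requires an OpticsConfig")
    params = params or MusicalParams()
    n = params.window_size or default_window_size(optics)
    k, (hh, ww) = stack.n_frames, stack.shape
    if hh <= n or ww <= n:
        raise ValueError(f"image {hh}x{ww} too small for window {n}")
    if k < n * n:
        warnings.warn(
            f"stack has K={k} < N²={n*n} frames; eigenimages are truncated "
            "to the thin-SVD rank", RuntimeWarning)
    s = params.subpixels
    half = (n - 1) // 2
    pitch = stack.pixel_pitch_object

    # Window geometry is translation invariant, so the unit PSF vectors of
    # the s×s test points in the central camera pixel are computed once.
    sub = (half + (np.arange(s) + 0.5) / s) * pitch
    ii, jj = np.meshgrid(sub, sub, indexing="ij")
    pts = np.column_stack([ii.ravel(), jj.ravel()])
    centers = _window_pixel_centers(n, pitch)
    g = pixel_integrated_psf(optics, centers, pts, pitch)  # (N², s²)
    g = g / np.linalg.norm(g, axis=0, keepdims=True)

    values = np.zeros((s * hh, s * ww), dtype=np.float64)
    valid = np.zeros((s * hh, s * ww), dtype=bool)
    n_degenerate = 0
    n_windows = 0

    for i in range(half, hh - half, params.stride):
        for j in range(half, ww - half, params.stride):
            n_windows += 1
            m = extract_window(stack, (i, j), n)
            if params.mean_subtract:
                m = m - m.mean(axis=1, keepdims=True)
            sv, coeffs = _window_spectrum_coeffs(m, g)
            if sv[0] <= 0:
                n_degenerate += 1
                continue
            # numerical rank: noise eigenimages must carry genuine content,
            # not pure round-off (e.g. a noiseless rank-1 window)
            num_rank = int(np.sum(sv > 1e-10 * sv[0]))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                r = _signal_rank(sv, params)
            if r < 1 or r >= num_rank:
                n_degenerate += 1
                continue
            sig = np.linalg.norm(coeffs[:r], axis=0)
            noi = np.maximum(np.linalg.norm(coeffs[r:], axis=0), EPS_FLOOR)
            block = (sig / noi) ** params.alpha
            values[s * i:s * (i + 1), s * j:s * (j + 1)] = block.reshape(s, s)
            valid[s * i:s * (i + 1), s * j:s * (j + 1)] = True

    if n_degenerate:
        warnings.warn(
            f"{n_degenerate}/{n_windows} windows degenerate (no usable "
            "noise subspace); left invalid in the map", RuntimeWarning)
        logger.info("reconstruct: %d/%d degenerate windows",
                    n_degenerate, n_windows)

    prov = {"n_frames": k, "image_shape": (hh, ww), "window_size": n,
            "n_windows": n_windows, "n_degenerate": n_degenerate,
            "psf_model": optics.psf_model, "psf_sigma_um": optics.psf_sigma}
    return IndicatorMap(values=values, valid_mask=valid, params=params,
                        pixel_pitch=pitch / s, provenance=prov)
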