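"""Matrix-protein density quantification on indicator maps or mean frames.

The metrics mirror routine histopathology image analysis: ROI mean
intensities as absolute densities, intensity ratios between tissue layers
(e.g. sub-epithelium over epithelium), within/between-window variance at a
ladder of physical scales, fibril thickness from line-profile FWHM, and
SSIM for colocalization.  Ratios are scale-free, so relative densities are
comparable across acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import map_coordinates
from skimage.metrics import structural_similarity


class GeometryError(ValueError):
    """Raised when an ROI, mask or line falls outside the usable image."""


class InsufficientDataError(ValueError):
    """Raised when too few valid pixels or ROIs support a statistic."""


@dataclass(frozen=True)
class ROISpec:
    """Rectangular ROI: ``origin`` (row, col) and ``size`` (rows, cols).

    ``frame_of_reference`` records whether the coordinates live on the
    camera grid or the sub-pixel (indicator-map) grid; camera-grid ROIs are
    mapped onto an s× finer map by exact integer scaling.
    """

    origin: tuple[int, int]
    size: tuple[int, int]
    frame_of_reference: str = "camera_grid"

    def __post_init__(self) -> None:
        if self.size[0] <= 0 or self.size[1] <= 0:
            raise GeometryError("ROI size must be positive")
        if self.frame_of_reference not in ("camera_grid", "subpixel_grid"):
            raise GeometryError(
                f"unknown frame_of_reference {self.frame_of_reference!r}")

    def scaled(self, s: int) -> "ROISpec":
        """The same ROI on a grid s× finer."""
        return ROISpec(origin=(self.origin[0] * s, self.origin[1] * s),
                       size=(self.size[0] * s, self.size[1] * s),
                       frame_of_reference="subpixel_grid")

    def slices(self) -> tuple[slice, slice]:
        r, c = self.origin
        h, w = self.size
        return slice(r, r + h), slice(c, c + w)


@dataclass
class LayerMask:
    """A labelled boolean mask aligned to an image (e.g. 'E', 'SE', 'UE')."""

    label: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise GeometryError(f"layer mask {self.label!r} is empty")


@dataclass
class MultiScaleReport:
    """Per-scale variance summary.

    For each window size: the list of within-window pixel variances and the
    between-window variance (variance of the window means).
    """

    window_sizes_um: list
    window_sizes_px: list
    within_variances: list   # list of 1D arrays, one per scale
    between_variance: list   # one float per scale
    n_windows: list

    def as_dict(self) -> dict:
        return {
            "window_sizes_um": list(self.window_sizes_um),
            "window_sizes_px": list(self.window_sizes_px),
            "mean_within_variance": [float(np.mean(v))
                                     for v in self.within_variances],
            "between_variance": [float(b) for b in self.between_variance],
            "n_windows": list(self.n_windows),
        }


@dataclass
class WidthHistogram:
    """FWHM fibril widths (µm) with histogram bin edges."""

    widths: np.ndarray
    bin_edges: np.ndarray

    @property
    def n(self) -> int:
        return len(self.widths)


def roi_mean_density(image: np.ndarray, roi: ROISpec,
                     valid_mask: np.ndarray | None = None) -> float:
    """Mean intensity over the ROI: the absolute density for that region.

    At least half the ROI must be valid (unmasked) pixels.
    """
    image = np.asarray(image, dtype=float)
    rs, cs = roi.slices()
    if (rs.start < 0 or cs.start < 0 or rs.stop > image.shape[0]
            or cs.stop > image.shape[1]):
        raise GeometryError("ROI extends outside the image")
    patch = image[rs, cs]
    if valid_mask is not None:
        vm = np.asarray(valid_mask, dtype=bool)[rs, cs]
        if vm.mean() < 0.5:
            raise InsufficientDataError(
                "fewer than 50% of ROI pixels are valid")
        return float(patch[vm].mean())
    return float(patch.mean())


def layer_ratio(image: np.ndarray, numerator: LayerMask,
                denominator: LayerMask,
                valid_mask: np.ndarray | None = None) -> float:
    """Mean intensity of one layer over another (e.g. SE / E density ratio)."""
    image = np.asarray(image, dtype=float)
    vm = (np.ones(image.shape, dtype=bool) if valid_mask is None
          else np.asarray(valid_mask, dtype=bool))
    num_sel = numerator.mask & vm
    den_sel = denominator.mask & vm
    if not num_sel.any() or not den_sel.any():
        raise InsufficientDataError("a layer mask has no valid pixels")
    den = float(image[den_sel].mean())
    if den <= 0:
        raise ZeroDivisionError("denominator layer has nonpositive mean")
    return float(image[num_sel].mean()) / den


def multiscale_variance(image: np.ndarray, window_sizes_um,
                        pixel_size_um: float, sampler: str = "tile",
                        seed: int | None = None,
                        max_windows: int | None = None) -> MultiScaleReport:
    """Within- and between-window variances at a ladder of physical scales.

    Non-overlapping square windows tile the image (or a random
    non-overlapping subset of at most ``max_windows`` tiles when
    ``sampler='random'``).  For each scale the within-window pixel variance
    of every window and the variance of the window means are recorded.
    """
    image = np.asarray(image, dtype=float)
    sizes = sorted(set(float(s) for s in window_sizes_um), reverse=True)
    rng = np.random.default_rng(seed)
    within, between, sizes_px, counts = [], [], [], []
    for size_um in sizes:
        w = int(round(size_um / pixel_size_um))
        if w < 3:
            raise GeometryError(
                f"window {size_um} µm is below 3 px at this resolution")
        if w > min(image.shape):
            raise GeometryError(f"window {size_um} µm exceeds the image")
        nr, nc = image.shape[0] // w, image.shape[1] // w
        tiles = [(i, j) for i in range(nr) for j in range(nc)]
        if sampler == "random" and max_windows is not None \
                and len(tiles) > max_windows:
            idx = rng.choice(len(tiles), size=max_windows, replace=False)
            tiles = [tiles[i] for i in idx]
        means, variances = [], []
        for i, j in tiles:
            patch = image[i * w:(i + 1) * w, j * w:(j + 1) * w]
            means.append(patch.mean())
            variances.append(patch.var())
        within.append(np.asarray(variances))
        between.append(float(np.var(means)) if len(means) > 1 else 0.0)
        sizes_px.append(w)
        counts.append(len(tiles))
    return MultiScaleReport(window_sizes_um=sizes, window_sizes_px=sizes_px,
                            within_variances=within,
                            between_variance=between, n_windows=counts)


def line_profile(image: np.ndarray, start_um, end_um, pixel_size_um: float,
                 n_samples: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear profile along a segment; returns (distance µm, intensity)."""
    start = np.asarray(start_um, dtype=float) / pixel_size_um - 0.5
    end = np.asarray(end_um, dtype=float) / pixel_size_um - 0.5
    t = np.linspace(0.0, 1.0, n_samples)
    coords = start[:, None] * (1 - t) + end[:, None] * t
    vals = map_coordinates(np.asarray(image, dtype=float), coords, order=1,
                           mode="nearest")
    dist = t * float(np.hypot(*(np.asarray(end_um) - np.asarray(start_um))))
    return dist, vals


def fibril_width(image: np.ndarray, start_um, end_um, pixel_size_um: float,
                 n_samples: int = 256) -> float:
    """FWHM (µm) of the single ridge crossed by the given line.

    Background is the profile minimum; the width is the distance between
    the two half-maximum crossings bracketing the profile peak, with linear
    interpolation between samples.
    """
    if n_samples < 32:
        raise ValueError("n_samples must be >= 32")
    dist, vals = line_profile(image, start_um, end_um, pixel_size_um,
                              n_samples)
    lo, hi = vals.min(), vals.max()
    if hi <= lo:
        raise ValueError("flat profile: the line does not cross a ridge")
    half = lo + 0.5 * (hi - lo)
    peak = int(np.argmax(vals))

    def crossing(i0, step):
        i = peak
        while 0 <= i + step < len(vals):
            j = i + step
            if vals[j] < half:
                frac = (vals[i] - half) / (vals[i] - vals[j])
                return dist[i] + frac * (dist[j] - dist[i])
            i = j
        return None

    left = crossing(peak, -1)
    right = crossing(peak, +1)
    if left is None or right is None:
        raise ValueError("profile has no two half-maximum crossings; "
                         "the line must cross exactly one ridge")
    return float(abs(right - left))


def width_histogram(widths, bins: int = 20) -> WidthHistogram:
    widths = np.asarray(widths, dtype=float)
    if np.any(widths <= 0):
        raise ValueError("widths must be positive")
    _, edges = np.histogram(widths, bins=bins)
    return WidthHistogram(widths=widths, bin_edges=edges)


def ssim(image_a: np.ndarray, image_b: np.ndarray,
         data_range: float | None = None) -> float:
    """Mean structural similarity with the standard Gaussian window.

    Gaussian weights with σ = 1.5, C1 = (0.01 L)², C2 = (0.03 L)² where L
    defaults to the joint dynamic range of the two images.
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise GeometryError("SSIM requires equal image shapes")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("SSIM inputs must be finite")
    if data_range is None:
        data_range = float(max(a.max(), b.max()) - min(a.min(), b.min()))
        if data_range == 0:
            return 1.0
    return float(structural_similarity(
        a, b, gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
        data_range=data_range))


def density_fidelity(gt_density: np.ndarray, candidate_images: dict,
                     rois, region_labels: dict) -> dict:
    """Compare candidate images' ROI densities against the ground truth.

    For every candidate image (co-registered with ``gt_density``), ROI mean
    intensities are computed, a single least-squares gain fits them to the
    ground-truth ROI densities, and Pearson correlation plus mean absolute
    error are reported per region class ('dense' / 'sparse', each needing
    at least 3 ROIs).  ROIs are assigned to the region containing their
    centre.
    """
    gt = np.asarray(gt_density, dtype=float)
    rois = list(rois)
    labels = []
    for roi in rois:
        r = roi.origin[0] + roi.size[0] // 2
        c = roi.origin[1] + roi.size[1] // 2
        lab = next((name for name, m in region_labels.items() if m[r, c]),
                   None)
        labels.append(lab)
    labels = np.asarray(labels, dtype=object)
    gt_means = np.asarray([roi_mean_density(gt, roi) for roi in rois])
    report: dict = {}
    for name, img in candidate_images.items():
        img = np.asarray(img, dtype=float)
        if img.shape != gt.shape:
            raise GeometryError(
                f"candidate {name!r} is not co-registered with the truth")
        cand = np.asarray([roi_mean_density(img, roi) for roi in rois])
        denom = float(cand @ cand)
        gain = float(cand @ gt_means) / denom if denom > 0 else 0.0
        scaled = gain * cand
        entry = {"gain": gain}
        for region in sorted(set(region_labels)):
            sel = labels == region
            if sel.sum() < 3:
                raise InsufficientDataError(
                    f"fewer than 3 ROIs in region {region!r}")
            if np.std(gt_means[sel]) == 0 or np.std(scaled[sel]) == 0:
                corr = 0.0
            else:
                corr = float(stats.pearsonr(gt_means[sel], scaled[sel])[0])
            entry[region] = {
                "pearson_r": corr,
                "mae": float(np.mean(np.abs(scaled[sel] - gt_means[sel]))),
                "n_rois": int(sel.sum()),
            }
        report[name] = entry
    return report


def group_comparison(groups: dict) -> dict:
    """Thin wrappers around standard group statistics.

    One-way ANOVA across all groups and Tukey HSD pairwise comparisons;
    provided for staging-style summaries, not re-derived here.
    """
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    f, p = stats.f_oneway(*arrays)
    tukey = stats.tukey_hsd(*arrays)
    pairs = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairs[f"{names[i]} vs {names[j]}"] = float(tukey.pvalue[i, j])
    return {"anova_F": float(f), "anova_p": float(p), "tukey_p": pairs}


def paired_ttest(a, b) -> dict:
    """Paired two-tailed t-test between matched measurements."""
    t, p = stats.ttest_rel(np.asarray(a, float), np.asarray(b, float))
    return {"t": float(t), "p": float(p)}
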