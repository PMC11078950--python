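# Methods

## The reconstruction model

A widefield fluorescence fluctuation stack is a sequence of K frames
I₁,…,I_K of the same field of view in which emitter brightnesses vary
independently from frame to frame (blinking, photophysics, or any other
intensity fluctuation measured by the camera). For every N×N window of
camera pixels the stack defines a pixel–time matrix **M** ∈ ℝ^(N²×K) whose
columns are the vectorized (row-major) window crops. Its thin singular value
decomposition

    M = U Σ Vᵀ,  σ₁ ≥ σ₂ ≥ … ≥ σ_R,  R = min(N², K)

splits the pixel space into a *signal subspace* spanned by the first r left
singular vectors u₁…u_r ("eigenimages") and a *noise subspace* spanned by
the remainder. A continuous test point **p** inside the window is scored by
the unit-norm vector **g**(p) obtained by integrating the microscope PSF
centred at **p** over the N² camera-pixel footprints:

    indicator(p) = ( ‖P_S g‖ / ‖P_N g‖ )^α ,
    ‖P_S g‖² = Σ_{i≤r} (uᵢ·g)²,  ‖P_N g‖² = Σ_{i>r} (uᵢ·g)²

Test points on true emitters are (nearly) orthogonal to the noise subspace,
so the ratio diverges there and decays steeply off-structure; the exponent α
sets the contrast. The indicator is evaluated on an s×s sub-pixel grid of
each window's central camera pixel (s = 10 by default) and the blocks are
stitched into a map s× finer than the camera grid. Because each window
writes only its own central block, stitching is seam-free without blending.

Components of **g** outside the thin-SVD span (possible when K < N²) are
excluded: the decomposition is truncated to rank R and the noise norm uses
the retained eigenimages only. The implementation computes the projection
coefficients uᵢ·g through the smaller Gram matrix (time-side MᵀM when
K < N², else space-side MMᵀ), which is algebraically identical to the SVD
route; the test suite checks the equivalence against an explicit SVD with
naive projections to 1e-8.

### Signal-rank selection

* `auto_knee` (default): per window, the rank at the knee of the log₁₀
  singular-value plot — the point of maximum perpendicular distance to the
  chord joining the spectrum's endpoints. Singular values are floored at
  1e-12·σ₁ before the log; a flat or log-linear spectrum has no knee and
  returns r = 1 with a warning; ties (to 1e-9 relative) go to the smaller
  rank.
* `manual`: a fixed singular-value cutoff, r = #{σᵢ > threshold}. The
  helper `image_threshold` samples windows across the image, takes the knee
  of the *median* spectrum, and returns one per-image cutoff — the
  procedure a practitioner follows when choosing a threshold from
  singular-value plots of an image. A per-image cutoff keeps windows
  without structure from being forced to donate a spurious signal subspace
  (the per-window knee must always return r ≥ 1, which inflates background
  indicators); the density experiments therefore use it.

Windows whose noise subspace carries no genuine content (numerical rank
≤ r, e.g. a noiseless constant window) are masked invalid rather than
scored; the map records them in a validity mask, and a border of (N−1)/2
camera pixels is likewise masked rather than padded — padding would
fabricate structure at tissue edges.

### Optics

The PSF is an isotropic Gaussian with σ = 0.21·λ/NA by default (the
standard least-squares fit to the Airy core); an Airy-disk model with first
zero at 0.61·λ/NA is available. Pixel integrals of the Gaussian use the
separable erf closed form; the Airy model uses 8× midpoint quadrature per
pixel axis (configurable). Depth of field follows
DOF = λµ/NA² + µe/(M·NA); note that for the 20×/0.80 configuration
(λ = 0.460 µm, µ = 1, e = 6.45 µm) this evaluates to 1.12 µm, which the
applications literature tends to quote loosely as "~1.2 µm". The NA ≤ µ
physical constraint is enforced as a warning, not an error, because
published DOF figures are routinely quoted with µ = 1 even for immersion
objectives. The default window size is the smallest odd N covering twice
the Rayleigh radius, N ≥ 2·(0.61λ/NA)/(e/M) + 1.

### Units and conventions

All object-space lengths are µm; camera pixel pitch e is divided by the
magnification M for object-space sampling. Vectorization is row-major;
pixel (i, j) covers [i, i+1)×[j, j+1)·pitch with its centre at
(i+0.5, j+0.5)·pitch and the origin at the image corner. The pipeline
promotes integer input to float; the noise norm is floored at 1e-12 to
keep indicators finite.

## The synthetic phantom

The generator emulates autofluorescent fibrous matrix imaged in widefield:

1. **Geometry** — smooth random centerlines (random-walk control points,
   cubic-spline smoothed, reflected off region walls); a configurable
   fraction of fibrils is confined to a designated dense sub-region.
2. **Emitters** — a Poisson process along each centerline (default linear
   densities 1–25 /µm depending on the experiment) with transverse Gaussian
   jitter standing in for the fibril cross-section. The ground-truth
   density raster is the emitter-count histogram and sums exactly to the
   emitter count.
3. **Photokinetics** — per-emitter two-state Markov blinking with
   stationary on-probability p_on = 0.7 and lag-1 persistence 0.3, plus
   multiplicative lognormal brightness noise with CV 0.2 (temporal
   fluctuation CV ≈ 0.2–0.6 overall). Fixed-tissue autofluorescence
   fluctuates for reasons that are not mechanistically settled, so the
   model is deliberately generic and every statistic is configurable.
4. **Camera** — PSF blur and pixel integration (erf closed form), Poisson
   shot noise on expected photons, gain, Gaussian read noise (default
   2 counts), offset (default 100) and bit-depth clipping.

Everything is reproducible: identical seeds give bit-identical outputs.

What the phantom does *not* emulate: out-of-focus background from 3-D
tissue (it is planar), scattering, detector saturation in dense bundles,
calibrated photophysics, and stain/label chemistry. Passing tests therefore
demonstrate the algorithmic properties (resolution, localization, density
fidelity relative to a diffraction-limited rendering of the *same* planar
scene), not clinical performance on tissue.

## Canned experiments and the problem sizes used

`musical.experiments` freezes the protocols used by the test suite and the
reproduction script:

* **Localization** — one blinking emitter at a random sub-pixel position in
  a 9×9-pixel field (20×/0.80), 200 frames, brightness 120 photons/frame
  (peak-pixel SNR ≈ 6, above the ≥3 regime where fluctuation nanoscopy is
  expected to work), window 7, s = 10; 100 trials; a hit is an argmax
  within one sub-pixel.
* **Two-emitter resolution** — a pair 0.6× the Rayleigh radius apart,
  500 frames; local-maximum counts along the joining row in the map versus
  the temporal mean.
* **Density fidelity** — twenty 64×64-pixel fields at 100×/0.80 (pixel
  64.5 nm in object space, PSF σ ≈ 1.9 px, a regime where diffraction
  genuinely erases sub-ROI density variation), 16 fibrils with 65% in the
  dense half, 25 emitters/µm at 400 photons/frame, 200 frames; N = 13,
  s = 10, α = 4, per-image pooled threshold; 3×3-camera-pixel ROIs tile
  the interior; Pearson correlation of ROI means against the ground-truth
  count raster after a single least-squares gain, per region class,
  reconstruction versus offset-subtracted mean frame.
* **Fibrosis-series ordering** — five stages confining 90/75/60/45/30% of
  120 fibrils to one quarter of a 270×270 µm field; each stage averages
  four phantom replicates (as stage statistics average animals in tissue
  studies); between-window variance of a 1 µm-blurred density rendering at
  0.5 µm/px, windows of 90/45/25 µm.

These sizes are the package's desk-scale defaults; they are deliberately
smaller than a full 1388×1040 acquisition while preserving each effect
(sub-Rayleigh separations, blur-to-ROI ratios, window counts per scale).

## Density metrics

ROI mean intensity is the absolute density of the ROI; layer ratios
(e.g. sub-epithelium / epithelium) are scale-free, so relative densities
compare across acquisitions. Camera-grid ROIs map onto the s× finer map by
exact integer scaling; reports record both interpretations of printed ROI
sizes (camera pixels and map pixels) via the ROI's frame-of-reference
field. Multi-scale analysis tiles non-overlapping windows at a ladder of
physical sizes (default 90/45/25/10/5 µm) and reports within-window
variances and the between-window variance of window means. Fibril width is
the FWHM of a bilinear line profile with the background taken as the
profile minimum (robust to shading, unlike a global minimum). SSIM uses
the standard Gaussian window (σ = 1.5, C₁ = (0.01L)², C₂ = (0.03L)²) via
scikit-image; the suite cross-checks it against an independent
from-the-definition implementation. Group statistics (one-way ANOVA, Tukey
HSD, paired t) are thin wrappers over SciPy and are not re-derived.

A caveat that shapes two tests: with α = 4 the indicator is heavy-tailed,
so mask-mean statistics of a *single* map scatter substantially even when
the underlying density ratio is exact; the layer-ratio validation therefore
asserts the median over seeds rather than each seed. Likewise scale
invariance of the reconstruction is mathematically exact, but scaling the
input by a non-power-of-two rounds the floating-point inputs before the
SVD, so equality is asserted to 1e-9 relative rather than bitwise.

## Known limitations

* The indicator is not calibrated in physical units; density comparisons
  are relative (ratios, correlations), matching how such maps are used.
* Very dense bundles saturate the signal subspace (r bounded by N² and K),
  so individual fibrils inside highly condensed regions are not resolved.
* The per-window knee heuristic is robust for structured windows but
  inflates background; prefer the per-image pooled threshold for
  quantitative density work.
* No drift correction, no 3-D (volumetric) rendering, no GPU path.
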