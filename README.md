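# musical-nanoscopy

Computational super-resolution and density quantification for
autofluorescence fluctuation microscopy.

Dense fibrous matrix proteins — collagen in connective tissue, keratin in
epithelium — autofluoresce, so their spatial density can be imaged without
labels on an ordinary widefield microscope. At low magnification the
diffraction-limited image blurs fibrils together and misrepresents the very
density variations a histopathologist needs. This package reconstructs a
super-resolved *indicator map* from a short stack of frames (the emitters'
intensities fluctuate frame to frame) using multiple signal classification
(MUSICAL): each sliding N×N window's pixel–time matrix **M** ∈ ℝ^(N²×K) is
factored by SVD into signal and noise subspaces, and every sub-pixel test
point *p* is scored against the expected point spread function **g**(p):

    indicator(p) = ( ‖P_S g(p)‖ / ‖P_N g(p)‖ )^α

with α = 4 and 10×10 sub-pixels per camera pixel by default. On top of the
maps it implements the quantification used for staging fibrous pathology:
ROI mean densities, layer intensity ratios (e.g. sub-epithelium /
epithelium), multi-scale within/between-window variance (90…5 µm ladders),
fibril FWHM from line profiles, and SSIM. A fully ground-truthed fibril
phantom simulator (curvilinear fibrils, blinking emitters, PSF blur,
Poisson + read noise) generates all test data.

See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

Two blinking emitters separated by 0.6× the Rayleigh limit, imaged at
20×/0.80 NA (λ_em = 460 nm, 6.45 µm camera pixels), 500 frames:

```python
import numpy as np
from musical import (OpticsConfig, MusicalParams, depth_of_field,
                     field_of_view, rayleigh_limit, point_source_phantom,
                     FluctuationModel, simulate_fluctuations, render_stack,
                     reconstruct, CameraModel)

optics = OpticsConfig(wavelength_em=0.460, numerical_aperture=0.80,
                      magnification=20, pixel_pitch=6.45)
print(f"DOF  = {depth_of_field(optics):.3f} um")
print(f"Rayleigh limit = {rayleigh_limit(optics):.3f} um")

pitch = optics.pixel_pitch_object
sep = 0.6 * rayleigh_limit(optics)
c = 16 / 2 * pitch
pos = np.array([[c, c - sep / 2], [c, c + sep / 2]])
phantom = point_source_phantom(pos, (16 * pitch, 16 * pitch),
                               brightness=2000)
blink = simulate_fluctuations(phantom.emitter_brightness,
                              FluctuationModel(), 500, seed=11)
stack = render_stack(phantom, blink, optics, CameraModel(offset=100.0),
                     seed=12)
imap = reconstruct(stack, MusicalParams(subpixels=10), optics)
```

Output (peak positions found along the row through the emitters, in map
pixels = camera pixels × 10):

```
DOF  = 1.122 um
Rayleigh limit = 0.351 um
map peaks at columns: [76 83] (true: 76.7, 83.3)
mean-frame peaks at columns: [7]
```

The 1.122 µm depth of field is the λµ/NA² + µe/(M·NA) closed form; a
448 × 335 µm² field of view follows from the 1388×1040 sensor. The
diffraction-limited mean frame shows a single blob (one peak, camera
column 7) where the indicator map resolves both emitters within a
sub-pixel of their true positions — the pair is 0.21 µm apart, well below
the 0.35 µm Rayleigh limit.

## Command line

```sh
musical optics   --config config.yaml              # DOF / FOV / window size
musical simulate --config config.yaml --out sim/   # phantom + ground truth
musical run      --stack sim/stack.ome.tif --config config.yaml --out map.tif
musical analyze  --map map.tif --scales 90,45,25,10,5 --out report/
```

Every run writes a manifest (config snapshot, checksums, timings) that
reproduces its outputs bit for bit.

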