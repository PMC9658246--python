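# Methods

`octfp` extracts two stacked anatomical surfaces from a volumetric OCT
fingertip scan — the epidermal skin surface (*outer fingerprint*) and the
dermal–epidermal junction (*inner fingerprint*) — and converts both to
conventional 2D grayscale fingerprint images.  This note documents the
model behind each stage, the parameters that matter, the numerical
choices, what the synthetic phantom does and does not emulate, and the
known limitations.

Conventions: volumes are indexed `(x, y, z)` with `z = 0` at the scan top
(nearest the scan head) and one A-scan contiguous in memory.  Surfaces
are heightmaps of fractional axial voxel positions; NaN marks a hole.

## 1. Edge detection along A-scans

Skin-layer boundaries appear along each A-scan as a dark→bright step or a
thin bright band.  Both are located with a size-`L` antisymmetric ramp
kernel

```
kernel0(L) = [1, 2, …, L/2, −L/2, …, −2, −1]
```

whose low-pass ramp shape suppresses speckle.  `L` is adjustable because
the optimal size tracks the thickness of the layer being probed and can
reach a significant fraction of the scan-line length, which would make
direct convolution O(L) per sample.  Differentiating the kernel twice
under zero padding leaves exactly four non-zero taps,
`{+1, −(L+1), +(L+1), −1}`; convolving with this sparse kernel and
integrating twice (two cumulative sums, with the zero- and first-order
kernels contributing the two integration constants at the start index)
reproduces the dense result in one O(n) pass, independent of `L`.  Note
the final tap is −1, not +1: the second difference of an antisymmetric
kernel is antisymmetric, and only this sign reconstructs the dense
convolution — the equivalence against a brute-force dense oracle is
asserted in the tests to 10⁻⁶ of the dynamic range.

All kernels are used in normalized form, scaled by `(2/L)/(L/2+1)`, which
makes the unit-step peak response exactly 0.5 for every even `L` so that
responses of different kernel sizes are directly comparable.

Response alignment places the positive peak at the step transition / band
position.  A candidate peak is accepted only if the response declines to
"zero" within one kernel length on both sides of the maximum (mismatched
kernels fail this); two numerical choices make the gate robust:

* "zero" is `≤ 1%` of the peak (`GATE_REL`), because float-valued volumes
  (see §3) retain sub-quantum background residue that never reaches
  exactly zero;
* a maximum at the very first or last sample is rejected outright — under
  zero padding any positive line start produces a spurious step response
  at the boundary, which on no-finger (background) lines is the global
  maximum.  Without this rejection, background lines report a "surface"
  at `z = 0` and the masking probe (§5) degenerates.

Accepted peaks are refined to sub-voxel precision by a parabola through
the three response samples around the maximum.  One systematic effect is
worth knowing: on a band-type boundary (a Gaussian band of width σ over a
tissue step) the response is antisymmetric about the band center, so its
peak sits roughly σ voxels *above* the center, for every kernel size
(measured −0.55 to −1.3 voxels for σ = 0.8–1.5).  This is a property of
the estimator, not a bug; it cancels entirely in the 2D fingerprints
(which only use heights relative to the envelopes) and appears as a
near-constant bias in absolute-height comparisons.

## 2. Intensity roll-off compensation

OCT sensitivity decays with depth, so far parts of a curved fingertip are
dimmer.  The per-depth mean intensity `A(z)` is fitted by ordinary least
squares; the fitted deviation from the global mean is subtracted from
every voxel, amplifying deep layers without changing overall brightness.
The compensated volume stays float32 (clamped to the 8-bit value range):
the subtracted trend is fractional, and requantizing to uint8 would
inject ±1 LSB noise whose pattern depends on the data-dependent fit,
measurably degrading the run-to-run reproducibility of sub-voxel
detection.

## 3. Volume pyramid and contrast enhancement

Edge detection on raw scan lines yields a rough, hole-ridden surface; a
multi-resolution pyramid provides noise reduction.  Each level halves all
three dimensions (preserving the finger's aspect ratio) by 2×2×2 block
averaging, which equals center-aligned trilinear reduction.  Upsampling
is separable trilinear at positions offset half a voxel from the coarse
centers; both resamplers map constant fields to constant fields, so they
cannot manufacture block edges ("clusters").

Contrast enhancement cascades coarse structure down the pyramid: from the
coarsest level, each level is upsampled and multiplied voxelwise into the
next finer one, and the product is affinely rescaled to [0, 255] to bound
its range.  The macrostructure of the fingerprint is represented more
reliably by coarse voxels, so the product boosts the true boundary in
low-contrast lines.  Pyramid levels stay float32; because the edge
kernels sum to zero and peak location and parabolic refinement are
invariant under positive affine maps, detection is then exactly invariant
to the (data-dependent) rescale factors.

Enhancement is configurable per pass (`DetectionConfig.contrast_enhancement`).
The outer pass uses it; the inner pass disables it, for a reproducibility
reason: the upsampled coarse field is not shift-equivariant, so on a
flattened volume (whose per-line integer shifts depend on the previously
computed envelope) the enhanced intensities — and through them the
sub-voxel surface — would inherit irrelevant details of the flattening
offsets.  Measured on a phantom, a pure 9-voxel constant shift moved the
detected junction by 0.27 voxels RMS with enhancement and 0.008 without.
The flattened volume also no longer needs rescue: the dominant confound
(the bright air–skin boundary) has been truncated away.

## 4. Coarse-to-fine surface segmentation

At each pyramid level, every scan line is probed with a set of kernel
sizes inside an axial search *region*; per line and kernel the best valid
peak and its response are stored.  The kernel used at a line is chosen by
lateral consistency: for each kernel, the response-weighted standard
deviation of its candidate positions over a (2r+1)² neighbourhood
(default r = 2) is computed, and the kernel with the smallest deviation
wins, ties toward the smaller size.  This rests on two assumptions —
layer thickness varies slowly across the fingertip, and curvature is
negligible within the neighbourhood.

When the volume under analysis has been shifted per line (the flattened
inner pass), the variance vote is taken on *unshifted* positions
(`line_offset`, fed with the recorded flatten shifts): the smoothness
assumption holds for the physical junction, not for the deliberately
jagged flattened frame.  Without this, ±1-voxel rounding differences in
the shifts inflate every kernel's apparent variance and near-tied votes
flip unpredictably.

Lines where no kernel produced a valid peak remain holes and are
collapsed by repeated interpolation at their perimeter (each sweep gives
every hole with a defined 8-neighbour the mean of those neighbours;
double-buffered, so sweep order cannot bias the result).

The region for the next finer level is centered on the upscaled (×2
bilinear, heights doubled) hole-free surface; its half-width is
`f_w × (weighted-median kernel size of the previous run) × 2`, the median
weighted by peak response.  Kernel size tracks layer thickness, so this
band is wide enough for the layer without reaching the neighbouring one.
The kernel set shrinks with the level: sizes are halved per level,
floored to even, minimum 2.

Defaults (all "hardware dependent" in the original setup, all logged at
run start): `f_w = 1.5`; initial region = full depth at the coarsest
level; kernel sizes {4, 6, 8, 12, 16} at full resolution; r = 2; pyramid
depth 3 (4 for gigavoxel scans), reduced so the coarsest level keeps ≥ 32
voxels per axis — coarser levels merge the two skin-layer bands into
adjacent voxels and the initial full-depth search can lock onto the
junction instead of the surface.

## 5. Fingertip masking

The detected outer surface covers the whole scan area; the mask recovers
the part actually covered by the fingertip.  Per line, the maximum voxel
value in a band of depth `w_n` (default 20 voxels) just below the surface
is compared with the maximum just above: below the true air–skin boundary
lies bright tissue, above it only air, so fingertip lines classify True
almost always while background lines (where the "surface" is
interpolated noise) come out True about half the time (ties go to False).
The probe runs on the *uncompensated* cast volume — roll-off compensation
brightens deep air as well as deep tissue and would tilt the comparison
toward True everywhere.

Refinement: box blur at the friction-ridge scale (`ridge_px`, default
25 px ≈ 500 µm at 20 µm pitch), Otsu re-binarization, keep the largest
4-connected component, fill enclosed background, then one more
blur+re-binarize smoothing pass and a final component/hole cleanup.  The
result is a single 4-connected component without interior holes,
independent of finger shape, position, or orientation.

## 6. Ridge envelopes

Flattening the volume against the fingerprint surface itself would press
the ridge pattern into the deeper layers (a "hybrid fingerprint"), so
flattening uses the *upper envelope*: a smooth surface touching only the
ridge tops.  Per scan row, a horizon search seeds at the global top
(minimum z) and hops outward: the next top is the sample within the
expected ridge spacing `l` (default 50 px) that maximizes the elevation
angle toward the scan top — an upper-convex-hull step with bounded edge
length, which equals the convex hull on convex fingertips while the
window bound keeps concave tips from being bridged too far.  Ties go to
the farthest sample, so flat stretches are crossed in one hop.  Adjacent
tops are joined linearly; each segment, having minimal slope, never
undercuts the profile.  A single direction can dip into valleys where
ridges are crossed at a shallow angle, so the search runs along rows and
along columns and keeps, per pixel, the value closer to the scan top.

A box filter then removes line-to-line roughness.  Its size
(`smooth_px`, default 9 px) targets the roughness scale, *not* the ridge
period: smoothing at the ridge period drags the envelope up to ~2.3
voxels off the tops and the envelope property fails at a quarter of the
pixels.  After smoothing the envelope is projected back onto the correct
side of the surface (z-wise minimum with the surface), so "upper envelope
at or above every sample" holds exactly; the clamp in the 2D conversion
(§8) remains for degenerate pixels.  The lower envelope reuses the same
search on the surface mirrored about the upper envelope (`2·Eup − S`),
flipped back.

The envelopes are deliberately information-destroying: on phantoms the
spectral power of the upper envelope near the ridge frequency is below 1%
of the surface's.

## 7. Flattening and the inner pass

With `E` the outer upper envelope (nearest-masked-value extrapolated
outside the mask) and `ΔS = max over mask of (S − E)` the outer-layer
thickness, every A-scan is shifted up by `round(E + ΔS)` voxels; content
shifted past the top is discarded, vacated bottom samples are zero-filled.
For every masked line the flattened content at z = 0 then lies at or below
the original surface — the outer fingerprint layer is entirely removed,
and the dermal–epidermal junction sits near the top where signal quality
is best.  Shifts are integer (no axial resampling) and recorded exactly,
so unflattening the detected inner surface is a lossless inverse.  The
API accepts only an envelope as the flatten reference, never a raw
surface — the hybrid-fingerprint hazard is excluded structurally.

The inner pass is the same segmentation code with a different
configuration: no contrast enhancement (§3), variance vote in true space
(§4), and an initial region starting a few voxels below the top
(`inner_margin`, default 4) so the Gaussian tail of the truncated outer
band cannot win the search.  The outer mask is reused for the inner
fingerprint; a separate inner mask is not computed.

## 8. 3D-to-2D conversion

Each fingerprint image is a parallel projection of its surface:
`(S − Eup) / (Elow − Eup)`, clamped to [0, 1].  Normalizing by the local
envelope distance compensates natural ridge-height variation; ridge tops
map to 0 (dark), valleys to 1 (light), background outside the mask to 1.
Pixels with envelope distance below 10⁻⁶ voxel carry no relief and map to
0.5.  The image keeps the native lateral grid; the ppi follows from the
lateral pitch (20 µm → 1270 ppi), with optional resampling to the 500 ppi
interchange standard in the CLI.

## 9. The synthetic phantom

Human OCT fingertip data are not publicly available, so the package ships
a generator whose defaults define the study conditions used by the tests
and the acceptance script.  At native resolution (20 µm lateral, 5.5 µm
axial) a 256³ patch models:

* a spherical fingertip (radius 8 mm) suspended in air, apex 40 voxels
  below the scan top, lateral contact radius 110 px (2.2 mm);
* a cosine ridge pattern, period 25 px (500 µm), outer peak-to-peak
  relief 8 axial voxels (44 µm), orientation 0.3 rad;
* a bright thin air–skin boundary band (Gaussian cross-section, σ = 1.0
  voxel, peak 240) — the brightest feature of the scan, as an air–tissue
  specular interface should be;
* the junction at epidermis depth 70 voxels (385 µm) carrying the same
  ridge pattern at amplitude 6, rendered dimmer and slightly wider
  (peak 100, σ = 1.5);
* tissue (peak 60) with exponential attenuation 0.008 per voxel of depth
  below the surface;
* multiplicative speckle `I·max(0, 1 + σ_s·N(0,1))` with σ_s = 0.3
  (0.5 in the noisy preset) and a linear sensitivity roll-off
  `I·(1 − a·z)` with a = 0.001 (0.0015 noisy);
* presets: `flat-slab` (64³, noiseless, for unit tests),
  `clean-finger-256`, `noisy-finger-256`, `scarred-finger` (a Gaussian
  groove, depth 15 voxels, width ~12 px, crossing the ridges of the outer
  surface only — the junction underneath is untouched), and
  `off-center-tilted`.

What the phantom does **not** emulate: fully developed coherent speckle
statistics (the clipped-Gaussian model is a simplification sufficient to
stress the edge filter), the double-row microstructure of the junction,
sweat ducts, motion artifacts, and real detector noise floors.  Passing
tests therefore demonstrate the signal-processing chain's correctness and
robustness under controlled optics, not clinical performance on human
skin; the original study's biometric error rates require non-public human
data and are out of reach here.

## 10. Problem sizes and measured behaviour

The reference conditions are 256³ voxel phantoms (a 5 mm native-
resolution patch); a full pipeline run takes ~20 s on one CPU core.  At
these conditions the chain achieves (fixed seeds; recomputed from scratch
by `scripts/acceptance.py` and the acceptance tests): outer surface RMSE
≈ 0.9 axial voxels and inner ≈ 1.85 against ground truth inside the mask
(bias-dominated, §1), mask Dice ≈ 0.98 on the centered, off-center/tilted
and heavy-speckle presets, exact envelope ordering and top contact,
lossless flatten/unflatten, inner-fingerprint invariance to the scar
(mean absolute 2D difference < 0.01 vs > 0.25 for the outer inside the
scar), and identical dominant ridge frequency in the outer and inner
outputs.  1024³ volumes are supported by the same code path (the
detection sweep is chunked to bound the working set), but the test suite
does not exercise them.

## 11. Known limitations

* The absolute surface height carries the estimator bias of §1; consumers
  needing calibrated absolute depths must correct for the boundary-band
  width of their scanner.
* The envelope horizon search is a 1D×2 separable reconstruction; a truly
  2D envelope (e.g. rolling ball) might behave better on strongly
  diagonal ridge flow, at higher cost.
* The 2D projection is a parallel projection of the curved surface; it
  does not emulate the contact deformation of touch-based scanners, so
  geometric distortion grows toward the fingertip silhouette.
* Error handling treats an all-background scan as a processing failure
  ("no fingertip found") rather than returning an empty result.
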