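# Methods

## Geometric model

Two views of a planar scene are related by a homography `x' ∝ H x`,
`H ∈ R^{3×3}` defined up to scale and normalized here to `h33 = 1`
(eight degrees of freedom). For fetoscopic video we additionally assume:

* **piecewise planarity** of the placental surface within a frame pair;
* **rigidity over time** — the chorionic plate does not deform
  perceptibly during imaging;
* **constrained scope motion** — the scope pivots about the incision
  point at a roughly fixed working distance, so consecutive frames are
  related by a rotation plus translation, with scale and shear
  negligible.

Coordinates are pixels, origin at the top-left corner, x right, y down,
pixel centers at integer coordinates. A pairwise homography for frames
`(k, k+1)` maps frame `k+1` coordinates into frame `k` coordinates;
relative homographies into the reference frame (index 0 by default) are
left products of the pairwise matrices. All in-plane rotation matrices
use the convention `R(β) = [[cos β, sin β], [−sin β, cos β]]` — the
transpose of the usual counter-clockwise matrix — kept consistent across
the pair generator, the decomposition and the recomposition so that
recovered angles compare directly with generator inputs.

## 4-point parameterization and DLT

A homography is equivalently represented by the displacements of four
non-collinear source corners (fixed order TL, TR, BR, BL; corners on the
outermost pixel centers, e.g. `(127, 0)` for a 128-wide patch). The
matrix is recovered from the four correspondences by the Hartley-
normalized direct linear transform (via scikit-image's
`ProjectiveTransform`), preceded by an explicit collinearity check that
raises a degenerate-geometry error rather than returning a garbage fit.
Round trips between the two forms reproduce corner positions to well
below 1e-8 px over the near-affine domain (verified over 1000 seeded
random matrices in the test suite).

## Rotation–scale–rotation decomposition

The 2×2 linear block of an (affine) estimate is factored by SVD as
`A = R(θ) diag(s_g, s_h) R(γ)`; the translation is read directly from
`h13, h23`, and the projective row is ignored (a warning is emitted if
`|h31|` or `|h32|` exceeds 1e-3). Canonicalization makes the
decomposition a true function:

* reflections are folded into the angles so `s_g ≥ s_h > 0`;
* orientation-reversing blocks (negative determinant) are rejected —
  they cannot be written as rotation·positive-scale·rotation, and video
  homographies are orientation-preserving;
* if `s_g = s_h` within 1e-10 (isotropic block) the full rotation is
  assigned to `θ` and `γ = 0`;
* otherwise `θ` is folded into `(−π/2, π/2]` using the
  `(θ, γ) → (θ+π, γ+π)` gauge freedom.

**Conditioning.** When the two scales are nearly equal — exactly the
regime of near-rigid scope motion — the split of the total rotation
between `θ` and `γ` is ill-conditioned: only the sum `θ + γ` (the polar
rotation angle) is a stable function of the matrix. Two consequences are
drawn throughout the package:

1. rotation *comparisons* (tests, metrics, recovery experiments) use the
   polar angle, exposed as `rotation_angle()`;
2. the consistent-estimation medians (below) are taken on the stable
   parameterization `(θ+γ, γ, s_g, s_h, t_x, t_y)`, with
   `θ = median(θ+γ) − median(γ)` recovered afterwards. With raw
   per-component angle medians the rotation error of the filtered
   estimate was measured to *increase* over a single estimate (about
   1.6× at 0.5 px displacement noise); on the stable parameterization it
   contracts by the expected ~1/√N. For majority-identical estimates and
   for well-separated scales the two readings coincide.

## Controlled and perturbed pair generation

Training/evaluation pairs are minted from a single grayscale image
(≥ 256×256, intensities in [0, 1]): a 128×128 patch `P_A` is sampled at
a random integer origin, the corners of `P_B` are the rigid map
`x' = R(β) x + d` of `P_A`'s corners, and `P_B` is the source image
resampled (bilinear) under the corresponding matrix. The rotation is
about the image coordinate origin, exactly as the corner formula is
written; a patch-center option exists but is off by default. Defaults:
`β` uniform in (−5°, +5°), `d_x, d_y` uniform in (−16, 16) px — the
controlled regime of the constrained scope. Placements whose displaced
corners leave the image are resampled (bounded retries, then a placement
error). The ground truth is exact corner algebra; nothing is estimated.

The *perturbed* alternative displaces each corner independently and
uniformly (integer by default, up to 32 px for the generic data model,
16 px in the training comparison), producing a general projective ground
truth — the unconstrained regime that generic deep homography training
uses.

## Synthetic sequences

Frame `k` of a simulated sequence is a texture resampled under a pose
`W_k` (frame → texture); the ground-truth pairwise homography is
`W_k^{-1} W_{k+1}`, exact up to floating-point products. Trajectories:

* **circular** — the frame center orbits at constant radius while the
  frame rotates with the orbit angle; the angular step is
  `360°/(n_frames−1)` so the final frame's pose coincides with the
  first and the loop closes *by construction* (the loop-closure scenario
  used to expose drift);
* **spiral** — linearly growing radius over a configurable number of
  turns;
* **exploratory** — a seeded random walk of rigid increments about the
  frame center (per-frame translation and rotation bounds), emulating
  freehand scanning.

Default per-frame step 6 px and rotation bound 2° at the 256×256 working
resolution, inside the controlled training ranges. Photometric artifacts
(specular Gaussian blobs, Gaussian blur, occlusion discs) and the
circular scope mask perturb intensities only — highlights move with the
camera, not the scene — so the geometric ground truth is untouched.
Textures are smooth low-contrast backgrounds (large-scale mottle plus
fine grain) darkened along random curvilinear vessel-like tracks;
defaults: ~6 vessels per 256² tile, contrast amplitude 0.35, chosen so
the texture is registrable by the feature baseline (a known shift is
recovered to < 0.5 px) while remaining low-contrast like placental
imagery.

What the simulator does **not** emulate: photorealistic placental
appearance, non-planar geometry, fluid refraction, honeycomb fiber
artifacts. Passing synthetic experiments therefore demonstrates the
correctness and robustness of the estimation/filtering machinery under
the stated motion model, not clinical performance on real fetoscopy.

## Estimation backends

All backends implement `estimate(patch_a, patch_b, corners)` returning a
4-point homography whose matrix maps patch-B coordinates onto patch-A
coordinates. Displacements are measured at the patch grid corners; under
co-located patch sampling the displacement of a frame-coordinate corner
under the frame-level homography equals the displacement of the
patch-local corner under the patch-level one (the translation conjugation
cancels in the displacements), so attaching the same displacements to
frame-coordinate corners makes the DLT yield the frame-level transform
with no shift correction.

* **Feature baseline.** SIFT keypoints/descriptors (ORB selectable),
  brute-force matching with cross-check and ratio test (0.8), RANSAC
  projective fit (3 px reprojection threshold, 2000 trials, fixed seed).
  The DoG contrast threshold is lowered to 0.004 from scikit-image's
  natural-image default because placental imagery is low-contrast.
  Fewer than 4 usable matches raises an estimation-failure signal; at
  sequence level a failed pair is substituted with the identity and
  logged.
* **Regression network.** A compact convolutional regressor implemented
  in numpy (im2col convolutions, ReLU, two fully connected layers,
  Euclidean loss `½‖·‖²`, Adam): input a 2-channel stack of the two
  patches scaled to [−1, 1], output the 8 corner displacements
  (normalized by 32 px). The desk-scale preset downsamples patches to
  32×32 (block mean) and uses 4 convolutions (16, 16, 32, 32 channels),
  a 128-unit hidden layer, Adam lr 1e-3, batch 32 — sized to train in
  minutes on one CPU; a full-scale preset (128×128 input, 8
  convolutions, 1024 hidden units, lr 1e-4) mirrors the published
  regressor layout and remains available in config. The output head is
  near-zero initialized so an untrained network predicts approximately
  no displacement. Pairs are minted at run time each step; training is
  bit-reproducible per seed.
* **Oracle.** Returns ground truth read off the true homography at the
  requested corners, optionally corrupted by seeded Gaussian
  displacement noise and/or outliers (ground truth composed with a large
  rigid offset), either i.i.d. or as an exact count per block of calls.
  Testing backend only.

## Consistent estimation

Per frame pair, `N = 99` (odd, so the median is an order statistic)
co-located random patches are drawn uniformly over the valid origin
range; each estimate is decomposed, failures are dropped (warning if
fewer than half survive, pair-failure signal if none do), and the
parameter-wise medians — on the stabilized parameterization above — are
recomposed. Angle medians are computed after rebasing around the
circular mean, so samples straddling ±π keep their central value. A
`median_theta_only` flag reproduces the literal single-angle variant:
the iteration whose `θ` attains the median is selected and its whole
parameter tuple used.

## Pipeline

Raw frames with a bright circular field on a dark surround are
preprocessed by Otsu thresholding + morphological opening/closing,
largest-component centroid and area-equivalent radius (foreground
covering > 95% of the frame is treated as full-field, "no mask"); the
inscribed square of side `⌊r√2⌋` (optional safety margin) is cropped and
resized to the 256×256 grayscale working resolution. The mosaic canvas
is the bounding box of all projected frame corners (with a configurable
pixel budget); frames are inverse-warped bilinearly, pixels outside the
circular mask excluded, and blended either latest-on-top (default, the
layered look of sequential mosaics) or by coverage-weighted averaging.

## Metrics

* **Residual error**: mean over all `W×H` integer pixel coordinates of
  `‖Ĥ⁻¹x − H⁻¹x‖²` (inverse maps, squared norm — implemented literally
  as specified; the forward variant would be conventional but is not
  silently substituted). Units px².
* **4-point RMSE**: `√(Σᵢ[(Δuᵢ−Δûᵢ)² + (Δvᵢ−Δv̂ᵢ)²]/4)`. Units px.
* **Photometric error**: the first patch is warped by the estimate into
  the second patch's coordinates; the mean *absolute* intensity
  difference is taken over pixels whose source sample stays in view
  (excluded from numerator and denominator alike; intensities in [0, 1]).
  L1 is the documented reading of the norm; a squared-difference variant
  is available by flag.

Summaries report median, linearly interpolated quartiles, and mean (the
box-plot convention).

## Problem sizes and numerical choices

The package's own experiments (test suite and `scripts/acceptance.py`)
use: 1000 random matrices for algebra round trips; 500 draws for rigid
pair exactness; 50 trials of 99-iteration median filtering with a 40/99
outlier minority; a 36-frame circular loop for zero-drift verification;
200 controlled pairs and a 100-frame translation-only sequence for the
feature baseline; and 2 × 2000 training steps (batch 32) for the
controlled-vs-perturbed comparison, evaluated on 100 held-out
rotation+translation pairs from unseen textures. These sizes are chosen
so the full suite runs on a single CPU in well under half an hour while
keeping every comparison statistically unambiguous.

Other numerical choices: bilinear interpolation for all image warps
(nearest-neighbor for masks); float32 network arithmetic; tie-breaks in
the median via the order statistic of odd-length samples; degenerate
inputs (collinear corners, singular blocks, points at infinity, empty
valid regions) raise typed errors naming the offending entity rather
than propagating NaNs.

## Known limitations

* The affine assumption discards `h31, h32`; strongly projective motion
  (heavily non-planar views) is outside the model and will show as
  drift, as it does on real non-planar sequences.
* Median filtering assumes a majority of patch estimates are sound; on
  frames where most patches are occluded or textureless the pair fails
  and the identity substitution introduces a local error.
* The desk-scale network demonstrates the *ordering* of training regimes
  (controlled < perturbed < untrained held-out error); its absolute
  accuracy is far from a fully trained full-scale regressor and it is
  not the default sequence backend (the feature baseline is more
  accurate at this scale).
* Loop closure is diagnosed, never enforced: no global refinement.
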