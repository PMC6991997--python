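# Methods

`odseg` implements an unsupervised optic-disc (OD) localization and
segmentation pipeline for color fundus photographs, together with a
synthetic fundus generator that supplies exact ground truth for every
stage. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic experiments do and do not show.

## Pipeline

The stages run in a fixed order on an RGB image normalized to [0, 1]:

1. **De-hazing** (whole image). Non-uniform illumination is modeled as
   haze: `I = t·J + (1−t)·A` with global airlight `A` and per-pixel
   transmission `t`. Pixels of one true scene color trace a straight
   *haze-line* through `A` in RGB space as `t` varies.
2. **Localization.** On the green channel (vessels are most prominent
   there): vessels are suppressed by the maximum over 15 grey dilations
   with a length-12 line structuring element at uniform orientations in
   [0°, 180°); bright distractors smaller than the disc are removed by a
   grey erosion (disc radius 15) followed by dilation (disc radius 20);
   the in-FOV result is Otsu-thresholded; the centroid of the connected
   component with minimum eccentricity is the disc center. A 300 × 300
   crop is cut around it, with a circular region of interest of radius
   `R = R_a·(1 + 0.3)` (`R_a` = dataset-average disc radius).
3. **Vessel detection** in the crop: multi-scale line detector on the
   inverted green channel. Scale `L` responds with
   `max_orientations(mean along a length-L line) − mean of the W×W window`
   (W = 15, 12 orientations, odd L from 1 to 15); per-scale responses are
   standardized within the FOV and averaged together with the
   standardized image. The mask is `response > 0.5`, dilated 1 px.
4. **Vessel removal** by harmonic inpainting of the HSV V and S
   channels: each masked pixel is reconstructed to equal the average of
   its four axial neighbors (discrete Laplace equation, Dirichlet data on
   the known pixels, reflected neighbors at borders).
5. **Binarization** of the vessel-free V channel, two independent ways:
   (a) *adaptive thresholding* — sign of `V − gaussian(V, σ=7)`, cleaned
   by binary erosion (disc diameter 13) then dilation (disc diameter 12);
   (b) *seeded region growing* from the localized center — the
   8-connected frontier pixel whose intensity is closest to the running
   region mean is admitted until that closest difference exceeds 0.05
   (on the [0, 1] V scale).
6. **Selection.** Candidates from both binarizations are pooled; those
   with area in `A_a·(1 ∓ 0.35)` are kept, and the one with smallest
   eccentricity `E = sqrt(Mj² − Mn²)/Mj` (moment-ellipse axis lengths) is
   the disc. Ties break to larger area. If the range is empty, the
   candidate with `E < 0.95` closest in area to `A_a` is returned with a
   low-confidence flag.
7. **Ellipse fitting.** Direct least-squares conic fit with the ellipse
   constraint (Fitzgibbon; Halir–Flusser stabilized block form) to the
   selected component's sub-pixel outer contour; the rasterized fit,
   mapped back to full-image coordinates, is the final mask.

Evaluation uses pixel-wise SN = TP/(TP+FN), SP = TN/(TN+FP),
Acc = (TP+TN)/total and the Jaccard overlap AOL = TP/(TP+FP+FN), computed
over the full image; localization is a hit when the predicted center
falls inside the true disc mask (boundary inclusive).

## De-hazing details and a design departure

Airlight is the mean color of the brightest 0.1% of in-FOV pixels — in a
fundus image, haze is an additive illumination error, so the brightest
pixels are the most airlight-like. Haze-line membership assigns each
pixel to the nearest of 500 Fibonacci-sphere directions of
`color − A` (exhaustive nearest-direction search, chunked). The raw
transmission is `t = r/r_max(line)` with `r = ‖color − A‖`, clamped to
[0.1, 1].

The raw estimate is uninformative exactly where it does the most damage:
pixels whose color is near the airlight — in practice the bright disc
itself — have near-zero radius, and inverting with their raw `t`
collapses all within-line structure onto the line's maximum radius. The
regularizer is therefore a *reliability-weighted normalized convolution*:
a Gaussian average of `t` with per-pixel weights `t²`, at spatial scale
`σ = λ·min(image shape)` (λ = 0.1 by default, so ~50 px at the working
scale). Low-radius pixels inherit the transmission of their reliable
surroundings; since illumination error varies slowly across the retina,
the large smoothing scale loses nothing. An edge-aware smoother guided by
image gradients was deliberately *not* used: image edges (the disc rim)
are precisely where reliable background transmission must propagate into
the unreliable disc interior, and gradient-based conductance would block
that. `λ = 0` disables smoothing; a constant map is a fixed point at any
λ. Pixels exactly at the airlight clamp to the floor `t = 0.1` — their
transmission is moot for the inversion since `I − A = 0` there.

## Parameters

| Parameter | Default | Units | Role |
|---|---|---|---|
| `dehaze.n_directions` | 500 | – | haze-line directions on the sphere |
| `dehaze.lam` | 0.1 | fraction of image size | transmission smoothing scale |
| `dehaze.t_floor` | 0.1 | – | transmission clamp (division guard) |
| `localize.line_se_length` | 12 | px | vessel-suppressing line SE |
| `localize.n_angles` | 15 | – | angular dilations over [0°, 180°) |
| `localize.erosion_disc` / `dilation_disc` | 15 / 20 | px radius | distractor-removing opening |
| `localize.crop_size` | 300 | px | working crop |
| `localize.avg_radius` (`R_a`) | 40 | px | dataset prior; ROI radius = 1.3·R_a |
| `vessels.window` (`W`) | 15 | px | line-detector window |
| `vessels.n_orientations` | 12 | – | 15° steps |
| `vessels.vessel_threshold` | 0.5 | standardized response | favors recall: over-inpainting smooth retina is harmless |
| `segment.sigma` | 7 | px | background blur (≪ disc radius 30–50 px) |
| `segment.erosion_diameter` / `dilation_diameter` | 13 / 12 | px diameter | speckle cleanup |
| `segment.grow_tolerance` | 0.05 | V units | region-growing stop |
| `segment.avg_area` (`A_a`) | π·40² | px² | area prior; admissible range ±35% |

Disc structuring-element "sizes" 15/20 at localization are read as radii
(the usual SE parameter); the segmentation-stage discs are explicit
diameters 13/12, built on an even-sized grid with a half-integer center
for the 12 px disc. All priors are defined at a working scale where the
image short side is ~605 px; much larger images are rescaled to it first,
and named dataset profiles (`drions`, `messidor`, …) ship a nominal
40 px prior that users should replace with values measured from their
ground truth.

## Synthetic scenes

The generator renders, deterministically per seed: a circular FOV on
black; a reddish retina with low-frequency texture and mild vignetting; a
bright elliptical disc (semi-axes 36–46 px, brightness 0.78–0.92) drawn
as a plateau with a 5% radial pallor gradient and a ~2 px soft rim — the
V-channel disc is nearly uniform, which is the premise that makes
V-channel thresholding with a 0.05 growing tolerance meaningful; dark
quadratic-Bezier vessels radiating from the disc (darkest in green);
bright Gaussian lesions of exudate scale (~12–25 px across) outside the
disc; optional haze from a smooth transmission field; additive Gaussian
noise (σ = 0.01), clipped. Ground truth (disc mask, vessel mask and
centerlines, center, area) is the exact rasterized geometry.

Study conditions: *easy* scenes have no haze and at most 2 lesions;
*hard* scenes have haze (airlight (0.9, 0.85, 0.8), transmission
0.5–0.9) plus 5 lesions.

What this does not show: real fundus photographs have parapapillary
atrophy, peripapillary rings, choroidal texture, camera-specific color
calibration and compression artifacts, none of which are modeled.
Passing the synthetic suite demonstrates that every stage implements its
specification and that the assembled pipeline is accurate when its
assumptions (bright near-circular disc, vessels darkest in green, smooth
illumination error) hold — not that the same accuracy transfers to any
particular clinical dataset without re-measured `R_a`/`A_a` priors.

## Numerical choices

- Laplace inpainting solves one sparse SPD system (exact, residual
  ≤ 1e-6 at the mean-value condition); a Jacobi fixed-point iteration is
  kept as an independent second route and agrees to ≤ 1e-5.
- Region growing breaks frontier ties (equal absolute difference to the
  region mean) by lowest (row, col); growth is bounded by the circular
  ROI. The similarity reference is the running mean by default (stabler
  than the seed value; seed mode is available in config).
- Otsu thresholding uses an exact histogram over occupied intensity
  levels (≤ 4096 distinct values; 256 bins otherwise) so the
  between-class-variance maximum matches exhaustive search; the reported
  threshold is the midpoint between the separating levels.
- Line sampling in the vessel detector uses nearest-pixel rasterization
  of the oriented segment (duplicates keep their weight), which keeps the
  operator integer-reproducible and identical to a direct per-pixel
  oracle; borders are reflected.
- Ellipse fitting centers and scales the points before building the
  scatter matrices; boundary points come from a marching-squares contour
  at level 0.5, which sits halfway between inside and outside pixels and
  so is unbiased with respect to rasterization (a pixel-level boundary
  would bias fits ~0.5 px small).
- 8-connectivity throughout labeling and growth; constant-image Otsu
  returns an all-false mask with a warning; an all-black image raises a
  localization failure with a machine-readable code.

## Problem sizes

Synthetic scenes are 512 × 512 px (FOV radius 240), chosen so that the
disc (semi-axes ~36–46 px) sits in the 30–50 px radius range typical of
fundus photography at the 605 px working scale while keeping a full
pipeline run at ~2 s. The shipped evaluation runs 50 easy and 20 hard
scenes.

## Known limitations

- The simplified haze-line de-hazer assumes the airlight is the
  brightest image color; colored flash artifacts violate this.
- Airlight estimation is only well-posed when some region is strongly
  hazed; on a haze-free image the estimate is disc-colored, which the
  reliability weighting then renders harmless (transmission ≈ 1).
- The adaptive-threshold branch contributes little on discs that are
  internally uniform (its erosion removes speckle-dominated interiors);
  the region-growing branch carries such cases, which is the point of
  pooling both.
- Very elongated discs (axis ratio < 0.65) leave the eccentricity
  selection rule less discriminative against vessel fragments.
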