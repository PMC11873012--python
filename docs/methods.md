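# Methods

This note documents the models, defaults and numerical choices behind
`ratvision`, in the package's own terms.

## Viewing model and augmentation

The viewing geometry defaults describe a rig with a 48×27 cm display at
d = 30 cm, rendered at 224×224 px, using the convention that the full
display spans ≈96° of visual angle (ppd = 224/96 ≈ 2.33 px/°). Note that
2·atan(24/30) ≈ 77°, not 96°; the 96° convention is adopted deliberately
because it is the one under which all pixel↔degree constants in the rest of
the pipeline are defined, and it is flagged here as an internal convention
rather than exact trigonometry of the rig.

Head-pose variability is modelled by three angular spans — 60° pitch,
35° roll, 20° yaw — sampled uniformly about zero. Roll maps one-to-one to
an in-plane image rotation (so α ∈ [−17.5°, +17.5°]); pitch and yaw map to
vertical/horizontal displacements on the screen plane via
Δ = 2·d·tan(θ/2), expressed as image fractions Δ/(2·S) where S is the
screen extent along that axis. The affine warp rotates about the geometric
image center, uses bilinear interpolation and zero fill.

The acuity front end applies Gaussian blur (σ_blur, px) then i.i.d.
additive Gaussian noise (σ_noise, intensity units on [0,1]) then clips.
Blur-before-noise reflects the reading of blur as optics and noise as
photoreceptor/neural variability; the alternative order would blur the
noise field and change its spectrum.

## CSF calibration

The simulated detection observer divides the display into non-overlapping
p×p patches (anchored on the largest centered multiple of p), measures the
pixel-intensity SD in each patch, and feeds the resulting feature vector to
a linear SVM (C = 1, tol = 1e-4) trained on 5,000 samples per class at full
scale (500 at the desk scale used by the test suite) — gratings with random
orientation and phase and contrast drawn uniformly from the 12-point
log-spaced test grid [0.005, 1], versus uniform mid-gray fields, both
degraded by the same blur and noise.

Two implementation details matter for honest thresholds:

* **Decision criterion.** The SVM fixes the linear direction; the decision
  threshold is then re-anchored on fresh gray images so the false-alarm
  rate is 10%. Without this, frequencies at which *no* contrast is
  detectable leave the SVM's criterion unconstrained and the psychometric
  can latch at p = 1 (spurious infinite sensitivity); with it, an
  uninformative detector sits at the false-alarm floor and the threshold is
  correctly infinite (zero sensitivity).
* **Frozen noise.** Noise fields are drawn once into a pool of 256 and
  reused under random circular shifts — a standard frozen-noise device that
  preserves i.i.d. marginals while cutting bulk generation cost by an order
  of magnitude.

The psychometric p(detection | c) per spatial frequency is the fraction of
fresh grating trials reported as gratings; the contrast threshold ξ is the
first upward 50% crossing, interpolated linearly in log contrast (boundary
rules: ξ = lowest tested contrast if the curve starts above 0.5; ξ = ∞,
sensitivity 0, if it never reaches 0.5). Sensitivity is σ(ν) = 1/ξ(ν) over
a 7-point log-spaced frequency grid spanning 0.04–1.0 cycles/deg that
includes 0.1 (two log-spaced segments, 0.04→0.1 and 0.1→1.0).

The calibration grid search minimizes the L1 distance (sum over the shared
frequency grid) between simulated and target CSFs over σ_blur ∈
{0.5, 1, 2, 4, 8} px, σ_noise ∈ {0.05, 0.1, 0.2, 0.3, 0.45} and patch size
(28 by default) — log-ish coverage from near-veridical to heavily degraded
viewing. The rodent CSF stand-in is a piecewise log-parabola with peak at
0.1 cycles/deg, zeros at 0.04 and 1.0 cycles/deg and configurable peak
sensitivity (default 20; only the shape descriptors are published, not
absolute sensitivities).

**Peak frequency** is reported as the vertex of a sensitivity-weighted
quadratic fit in log10(ν) to the positive part of the CSF (the standard
log-parabola peak estimator for contrast-sensitivity data), falling back to
the grid argmax for degenerate fits. At patch size 28 the simulated curve
has a broad plateau across 0.063–0.178 cycles/deg, so the raw argmax on a
7-point grid is decided by sampling noise between grid points 37% apart,
while the fitted vertex is stable (≈0.105–0.11 across seeds at desk scale).
Where a single final curve is needed, three independently trained replicate
CSFs are averaged before peak estimation.

## Stimuli and responders

Objects are unions of thick 3-D segments ("lobes") sharing a center; the
canonical pair is a three-lobed tripod and a four-lobed cross. Azimuth is a
true 3-D rotation about the vertical axis followed by orthographic
projection — not a 2-D shear — which produces the horizontal foreshortening
the alignment analysis later inverts. Scale and centering are fixed by the
azimuth-projected, pre-in-plane-rotation bounding box (so the bounding
extent of each azimuth view spans `size_deg` of visual angle, and an
in-plane-rotated view is exactly the rotation of the unrotated one, making
alignment well-posed). The renderer fills pixels within half-thickness of a
projected segment; fill level 1.0 on background 0.0 (the actual display
gray levels in behavioural rigs are not published; these defaults maximize
contrast). Outlines keep a 2-px boundary (thickness configurable — not a
published value) at the original intensity.

Structural variants rotate each lobe's direction about the viewing axis by
an angle uniform in ±angle_jitter and scale its length uniformly within
±length_jitter, seeded. Restricting the angular jitter to the image plane
keeps the perturbation distribution simple and exactly testable
(signed in-plane deviations are uniform) while still deforming the
projected shape.

Simulated responders produce binary choices: a template matcher (argmax dot
product over two stored templates), a planted-feature detector (correct iff
the mean occlusion-mask transparency over a planted pixel set exceeds a
visibility threshold), and the ideal observer (argmax dot product over the
full template store; ties to the lowest index; dot products unnormalized —
template norms are part of the stored knowledge). Lapses are modelled as a
fair coin with probability λ, the common psychophysics convention.

## Networks and readout

The convolutional reference is the classic 16-weight-layer stack
(64,64 | 128,128 | 256×3 | 512×3 | 512×3 conv with 2×2 max-pool between
blocks, then 4096-4096-1000 fully connected; 138,357,544 parameters at
224×224×3 input). The parameter-matched MLP is 16 affine stages
50176→2150→2048→2048→2048→2048→1024→(1024×9)→1000 with ReLU between stages
(137,444,430 parameters; per-layer counts in rounded millions:
108, 4, 4, 4, 4, 2, 1×10, summing to 136). Both run on a small numpy engine
(im2col convolution, fan-in uniform initialization, seeded); grayscale
stimuli are replicated across the three conv-net input channels. "Layer l"
always means the l-th weight layer and activations are taken before the
ReLU. Pretrained weights are an optional plug-in loaded from an `.npz`
archive; nothing in the test suite requires them. The conv architecture
accepts any input size divisible by 32, which the tests use to run full
13-layer stacks at 64×64 cheaply.

Readout: per-unit z-scoring with training-set statistics (zero-variance
units dropped and logged), linear SVM (C = 1, tol = 1e-4, fixed seed),
accuracy tabulated per condition cell. The L1 pattern distance is the
*mean* absolute cell difference, so values are comparable across stimulus
sets of different cell counts. Pearson comparisons require ≥3 cells and
non-constant patterns; pipelines record NaN (and exclude the curve from
extremum histograms) when a saturated classifier yields a constant pattern.
Extremum histograms break ties toward the shallower layer.

The synthetic depth-indexed network used in tests responds at layer l with
snr_l · (Mx) + n(x), where M is a fixed random mixing and n(x) is
unit-variance pseudo-noise seeded from a checksum of the input — responses
are deterministic per stimulus, but decodability of any stimulus property
grows with depth by construction.

## Classification images

Bubbles masks sprinkle N_b = 40 Gaussian apertures (σ from a 2° full width
at half maximum: σ = 2°·ppd/2.355 ≈ 1.98 px; the "size = 2°" convention is
configurable since FWHM vs σ is a modelling choice) with centers uniform in
the centered square spanning 70% of each image dimension; overlapping
apertures are clipped at full transparency. Masking multiplies the image
(black background). The saliency map divides the outcome-weighted mask sum
by the total mask sum per pixel; never-covered pixels are NaN and excluded
from all statistics.

Significance for bubbles maps uses 1,000 label permutations and one-tailed
empirical-quantile tests at p < 0.05 per tail, uncorrected. Note the
direct consequence: under a true effect confined to a small region, ~5% of
the remaining covered pixels are still flagged per tail, so the
fixed-threshold salient region is never a tight localizer of a compact
feature. For region-size-sensitive analyses the package therefore provides
area-matched thresholding (bisection on p until the salient area hits a
target within ±1 px) and a size-matched region (`top_area_region`: the k
pixels with the largest null-standardized saliency), and the planted-
feature validation checks localization with the size-matched region while
verifying that the fixed-threshold region contains the feature.

The structural-variant estimator subtracts the mean image of rejected
variants from the mean image of chosen variants; its null uses 100 choice
permutations with a per-pixel Gaussian fit (mean, SD) for smooth one-tailed
p-values at p < 0.01 per tail; zero-variance pixels are non-significant and
counted in a log message.

## Invariance

Salient-region overlap is intersection-over-union (both-empty defined as
0). Aligned overlap first inverse-transforms each boolean map to the
default view: inverse horizontal shift, inverse in-plane rotation and
inverse scaling about the image center, and azimuth undone by horizontal
re-expansion by 1/cos(azimuth) about the object's vertical axis. The
azimuth inverse is an affine approximation to the true inverse of an
orthographic 3-D rotation — exact for object features on the rotation
axis, increasingly approximate off-axis and at depth — and can be disabled
(`azimuth_correction=False`); |azimuth| ≥ 90° has no inverse and raises.
Boolean masks are resampled nearest-neighbour to avoid fractional
membership; round-trips lose a few boundary pixels (measured IoU ≥ 0.95
for 30° in-plane rotations).

## Experiments and profiles

The three pipelines (`transform_matrix`, `occlusion`, `variants`) draw
train and test augmentations from independent seeded streams per run. The
`paper` profile uses the published counts — 5,000 training images, test
sets of 5,000 (or 2,500 per condition type), 3,000 occlusion masks per
view, five classification runs, unit-population scales
{10³, 5·10³, 10⁴, 5·10⁴, 10⁵} (capped at layer size) — and the `desk`
profile shrinks them (1,000 / 500 / 500 masks / 2 runs / {10³, 10⁴}) for
quick runs; the test suite additionally uses a 48–64 px geometry, chosen so
every pipeline stage runs end to end in seconds to minutes while leaving
all statistical machinery identical. The occlusion study renders 8 views
per object (default, two sizes, ±30° azimuth, ±9° shift, 30° in-plane) and
the ideal observer stores all 16 templates. Training for the occlusion
readout mixes unoccluded and bubble-masked images 50/50; a degeneracy
detector flags the failure mode where one object's occluded views are
~always correct (>90%) and the other's ~always wrong (<10%).

## What the synthetic data do and do not show

The generators emulate the *structure* of the behavioural studies —
transformation axes, occlusion statistics, variant sampling, lapse-limited
choice behaviour — not the photometric detail of real stimuli or the
idiosyncrasies of animal strategy. Green tests certify that the estimators
recover planted structure under the study's sampling conditions and that
the statistics are calibrated; they do not certify any claim about real
animals, for which the deposited stimuli, behaviour and pretrained weights
would have to be supplied through the I/O module.

## Known limitations

* The numpy conv forward pass is single-threaded BLAS; full 224-px
  16-layer runs over thousands of stimuli are minutes-scale, so large
  studies should cache activations (`io` writes lossless `.npz`).
* The azimuth alignment approximation degrades beyond ~60°.
* Pixel-level CSF calibration assumes stationary Gaussian noise; it does
  not model retinal nonuniformity or temporal integration.
* The bubbles permutation test is intentionally uncorrected for multiple
  comparisons (matching field practice); treat fixed-threshold region
  sizes accordingly.
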