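# Methods

This note documents the models and procedures implemented in
`glottalmidline`, the choices made where the design was genuinely open,
and what the synthetic benchmark does and does not show about real
endoscopy data.

## The six-mass vocal-fold model

The glottis is modelled in the image plane as two vocal folds of unit
posterior-anterior length. Each fold carries three point masses at the
stations y = 1/4, 1/2, 3/4 along the midline, moving only laterally;
the posterior point **p** (optionally split into p1/p2 by a posterior
gap) and the anterior point **a** are fixed. The line p–a is the
glottal midline and is therefore known exactly for every rendered
frame — the property that makes the model a ground-truth generator for
midline detection.

The state variable is the half-width `xi[s, i]` of fold *s* at station
*i* (positive = open). Each mass obeys

    m xi'' = F_anchor + F_vertical + F_longitudinal + F_collision + F_drive

with the concrete force terms:

* **Anchor spring** `-k_a (dx + eta dx^3) - d xi'` where
  `dx = xi - xi_rest`. The cubic stiffening (`eta = 800` per squared
  length unit, roughly doubling the effective stiffness at a typical
  amplitude of 0.05) represents tissue nonlinearity and limits the
  limit-cycle amplitude. Damping acts on velocity only.
* **Vertical coupling** — linear springs to the neighbouring masses of
  the same fold; the chain ends attach to the fixed anchors (half-gap
  at p, zero at a).
* **Longitudinal tension** — a restoring force toward the straight
  chord from p to a (string tension of the fold).
* **Collision** — a stiff linear spring engaged while the folds
  overlap at a station (`xi_L + xi_R < 0`), pushing both outward.
* **Driving pressure** `q5 P0 (c0 + beta tanh((xi_L' + xi_R') / v0))`.
  The modulation by the *shared* opening velocity is a lumped stand-in
  for the glottal airflow common to both folds: it injects energy into
  the common mode (Hopf instability guaranteed across the whole
  pressure range since `q5 P0 beta / v0` far exceeds the damping),
  phase-locks the two folds, and — because the static component `c0`
  is small — keeps each fold oscillating around the midline instead of
  displacing it statically. A large static pressure component would
  move the oscillation center off the p–a axis and silently invalidate
  the ground truth.

Six dimensionless factors randomise the model per the study protocol:
Q1 (mass), Q2 (anchor stiffness), Q3 (vertical coupling), Q4
(longitudinal tension) drawn per side from U[0.5, 2], and the shared
Q5 (subglottal pressure) from U[1, 4] and Q6 (collision) from
U[0.5, 6]. Independent per-side draws of Q1–Q4 produce the asymmetric
oscillation patterns, up to one-sided insufficiency (a stiff, light
fold responds weakly off-resonance and never closes). Base constants
were chosen once so that the Q = 1 model oscillates near 140 Hz and
the Q sweep covers roughly 100–220 Hz, matching the adult speaking
range; half-width amplitudes are a few percent of the fold length
(glottal width ≈ 10–25 % of its length).

Integration is classical fixed-step RK4 at `dt = 1e-5 s` (≥ 400 steps
per cycle at 250 Hz), 150 ms total with the first 85 ms discarded as
start-up transient. Initial conditions are rest positions with zero
velocity; transient removal makes their details irrelevant. The
integrator shows clean 4th-order step-size convergence while the drive
modulation is well resolved; with the sharp default modulation
(`v0 = 0.5`) and collisions the observed order degrades gracefully, as
expected for forces with fast transitions at fixed step. Divergent
parameter draws raise an error carrying the config; draws whose
glottal area waveform has fewer than 3 prominent maxima or
peak-to-peak amplitude below 5 % of a reference opening
(half-width 0.2) are discarded and resampled, mirroring the
discard-non-oscillating-models rule.

## Mask synthesis

Outlines (p1 → left masses → a → right masses → p2, half-widths
clipped at contact) are smoothed with two iterations of Chaikin corner
cutting applied directly to the 8-vertex mass polygon, rasterized
onto a 256×256 canvas with the p–a axis spanning 60 % of the image
height and centered on the pixel-grid center, and roughened by setting
each 8-connected boundary pixel to background with probability
p = 0.5 (independently per frame). Frames are sampled at 4000 frames/s
(typical high-speed videoendoscopy), giving ≈ 260 frames per retained
65 ms window.

Two deliberate rendering consequences:

* Chaikin cutting recedes the mask from the sharp glottal tips by
  roughly a quarter of the adjacent polygon edge (~10 px at the
  default geometry). The rendered glottis therefore systematically
  under-covers the anatomical p–a axis — the familiar
  "segmentation underestimates glottis length" effect — and this,
  not detector noise, dominates the absolute keypoint errors of *all*
  detectors. A midpoint-refinement variant that halves this recession
  was evaluated and rejected: plain corner cutting on the mass polygon
  is the stated construction and its error statistics match the
  published benchmark closely.
* The axis is horizontally centered at (W−1)/2 = 127.5, *between*
  pixel columns. Placing it exactly on a pixel-center column makes
  every on-axis pixel an exact tie in the left/right split and biases
  the split by a full column.

Examination motion is modelled as a static per-sequence rotation drawn
from U[−30°, 30°] plus a slow sinusoidal translation (amplitude
U[0, 5] px per axis, frequency U[0, 10] Hz), applied to masks by
nearest-neighbour resampling and to the ground-truth midline by the
same rigid map.

## Detectors

All six detectors consume a non-negative weighted image (a binary mask
is the weight-1 case) and return the midline as posterior/anterior
points — for the line-fitting methods, the first and last intersection
of the fitted line with the support, found by a sub-pixel walk along
the line. Weighted pixels are treated as multiplicities for LR, ODR,
PCA and image moments; TB works on the support extrema with per-row
centers of mass; ellipse fitting uses the outer contour of the
support. Only the largest 8-connected support component is used by
default (contour noise fragments the area). ODR, PCA and image moments
are mathematically the same principal axis; they are implemented by
three independent routes (ODRPACK's iterative optimizer, a 2×2
eigendecomposition, the closed-form `0.5 atan2(2 mu11, mu20 - mu02)`
angle) and cross-checked to 1e-6 rad in the tests. Near-vertical lines
are handled by fitting in the transposed frame (x as a function of y);
internal line representation is point + unit direction so vertical
axes are unexceptional.

## Evaluation

* **MAPE** — the paper-style point error is the relative Euclidean
  distance `|pred − gt| / |gt|` in pixel coordinates (origin top-left),
  reported as a fraction. The coordinate-wise mean of `|Δx/x|, |Δy/y|`
  is computed alongside; it differs materially only in how it weights
  the posterior point, whose y-coordinate is small in this canvas.
* **mIoU** — the peak-frame mask is split into left/right areas by the
  ground-truth and the predicted midline (infinite extensions; pixels
  exactly on the line go left; empty-vs-empty sides count IoU 1,
  empty-vs-non-empty 0) and the two side IoUs are averaged. At summed
  ranges the *peak frame* remains the evaluation mask.

Both metrics are needed: translating a prediction along the true axis
inflates MAPE while leaving the split intact, and a small endpoint
error can still tilt the split badly.

## Benchmark protocol

For every sequence the glottal area waveform (foreground pixel count
per frame) is computed, local maxima are detected (prominence ≥ 10 %
of the waveform range; minimum separation of half the median
inter-peak distance of a greedy first pass), and each detector runs on
the single peak frame and on pixel-wise sums of 2r+1 frames for
r ∈ {0, 1, 3, 5, 10}; peaks whose window would cross the sequence
bounds are dropped for that r. Medians pool all peaks of all
sequences. A master seed fans out to per-sequence seeds through a
counter-based hash, so any subset of the dataset is reproducible
independently.

Problem sizes: the statistics in the acceptance script and test suite
use 250 freshly generated sequences (the original benchmark used
2500); at 250 the medians carry a bootstrap spread of roughly ±0.005
except where noted below. The neural experiments are run at smoke
scale (tens of sequences, 32×32 inputs, narrow filters) — they
exercise the training machinery and the direction of effects, not
published-scale scores.

## Known limitations and open points

* The posterior-point error of the TB detector is the least stable
  statistic: with a posterior gap (present in half the sequences) the
  mask's top edge sits exactly at the true posterior point and the
  error is ~0.01–0.02, without it the tip recession applies (~0.06),
  and the pooled median falls at the boundary between these two
  populations.
* Whether image moments strictly overtake TB at ≥ 7 summed frames
  depends on asymmetry statistics: temporal summation lifts the
  principal-axis methods strongly (≈ 0.81 → 0.90 median mIoU) while
  TB also gains a little from the union's stabilized tips; at n = 250
  the two are statistically tied.
* The synthetic masks have no camera optics, illumination, specular
  reflections or segmentation-model errors beyond boundary-pixel
  dropout; passing the benchmark demonstrates correctness of the
  detectors and harness on idealized segmentations, not clinical
  performance.
* The neural keypoint targets are normalized to [0, 1] image
  fractions; weighted-sum inputs are divided by 2r+1. The multi-task
  network weighs its Dice and MSE heads 1:1. All three choices are
  config-exposed.

## Neural reference models

The networks are implemented on a small in-repo reverse-mode autodiff
(numpy; conv via im2col, verified against central differences) with
RMSprop (rho 0.9, learning rate 1e-4 with 0.5e-6 decay at full scale;
smoke runs use a larger rate). The published MidlineNet layout — four
blocks of two 3×3/32-filter convolutions with max pooling, global
average pooling, dense 4-output head — has 65,188 parameters by closed
form. Data splits are 75/25 train/test then 90/10 train/validation,
and evaluation uses the best-validation epoch. The recurrent variant
replaces each block's convolutions with a ConvLSTM2D cell (per-step
spatial pooling between blocks, regression from the final step); the
multi-task encoder–decoder reads its keypoint head from the bottleneck
through global average pooling and trains with MSE + Dice.
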