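# Methods

## The measurement model

The pipeline estimates LVEF from a single imaging plane (A4C) with the
ellipsoid single-plane, or area-length, model. Treating the LV as a
prolate spheroid seen along its long axis, the volume follows from the
planar area A (px²) and the long-axis length L (px):

    V = 8 A² / (3 π L)

For a true ellipse with axes L and D, A = πLD/4 and the expression
reduces exactly to the spheroid volume πLD²/6; this identity is tested
symbolically and numerically and anchors the simulator's ground truth.
Per cardiac cycle i, EF_i = (EDV_i − ESV_i)/EDV_i × 100, and the
video-level LVEF is the arithmetic mean of EF_i over all N detected
cycles. (The per-cycle EF numerator is written EDV − ESV throughout:
the ejected fraction of a contracting ventricle is positive.) Phenotype
cut-points are strict at the lower edge: HFrEF < 40 ≤ HFmrEF < 50 ≤
HFpEF.

Everything runs in pixel units. EF is a ratio of volumes, so the
px→cm calibration cancels; EDV/ESV are reported in px³ and are not
clinical volumes.

## ED/ES detection

ED and ES frames are the local maxima and minima of the per-frame LV
area curve. Candidate extrema must have topographic prominence strictly
greater than half the curve's global range (so the rule is invariant
under affine rescaling of the areas), and retained extrema must be at
least `min_distance` frames apart (default 20, the "horizontal
stepsize"; higher peaks win when two are closer). Troughs are found by
negating the curve and reusing the peak rule. Each ED is paired with
the first ES that follows it before the next ED; unpaired EDs are
dropped. A constant curve, or one shorter than two stepsizes, yields an
empty cycle set with a warning — never an exception — and the pipeline
reports an "insufficient cycles" status.

## Area refinement (improved Jeffrey's method)

Raw single-frame ED/ES areas inherit any segmentation error on that one
frame. The refinement pools, for the ED of cycle i: (1) the area at the
ED frame, (2) the top ⌈0.1·n⌉ areas of the whole curve, and (3) the top
⌈0.1·m⌉ areas between the cycle's ED and ES frames inclusive, and takes
the mean of the pooled multiset (ES analogously with ascending sorts).
Top-k counts are ceilings with a minimum of one element so short curves
still select. A `pooling="three_part"` switch averages the three part
means instead of the pooled multiset — the two readings the source
material permits — with pooled the default. The global top-10% part is
taken over the whole video rather than restricted to peri-ED frames;
that is the plainer reading and makes the refinement a deliberate
smoother across beats. If refinement ever produces a_ed ≤ a_es the
cycle is reported as degenerate rather than silently clipped. A
90th/10th-percentile baseline (linear interpolation between order
statistics) is kept for ablation.

Consequence worth knowing: because parts (2) share frames across
cycles, Jeffrey-refined per-cycle EFs are pulled toward the video mean.
That is the intended robustness on noisy segmentations, but analyses
that need each beat's own EF (the beat-to-beat display, the
single-cycle-versus-all-cycle comparison) use `refinement="raw"`.

## LV length

The length is the Euclidean apex-to-mid-annulus distance. At inference
no trace is available, so a regression ensemble predicts it from mask
shape features: pixel-count area, the extent along the mask's principal
axis (second-moment eigenvector, direction canonicalised by the third
moment of the projections), and a five-level width profile measured
perpendicular to the axis at 10/30/50/70/90% of the height. Four base
learners — Extra Trees, AdaBoost, Lasso, and a stacking regressor
(Ridge, 5-NN, gradient-boosted trees combined by a ridge meta-learner
on out-of-fold predictions) — are combined by an unweighted mean, the
simplest voting rule consistent with the ensemble's description.
Defaults: 100 trees per tree ensemble, k = 5 neighbours, regularisation
1.0, 5-fold internal CV for the stack, 5-fold external CV for
evaluation. The comparison harness reuses one seeded fold partition for
every candidate model and runs a one-way ANOVA over the per-fold R²
groups (F capped at 1e12 when within-group variance vanishes with
separated means; F = 0, p = 1 for identical constant groups).

When no ensemble is supplied, `run_pipeline` falls back to the
principal-axis height as the length. For an apex-to-base aligned
ventricle the height *is* the long axis, so this geometric route is
exact on the simulator and a reasonable default on clean masks; the
ensemble route exists because real masks are ragged and a learned
mapping from several features is more stable.

## Segmentation network

The network follows the DeepLab lineage: a ResNet-style encoder (3×3
stem at stride 2; a projected residual block to stride 4; a second
residual block with dilation 2 replacing further striding) feeding an
ASPP head — parallel 1×1, three dilated 3×3 branches (rates 2, 4, 8)
and a global-average-pooling branch, concatenated, projected, reduced
to one logit channel and bilinearly upsampled ×4 to the input grid.
Channel widths scale with `width_scale` (default 1/8 of the 64-channel
full stem) so the default model has ~12k parameters and trains on a CPU
in under a minute; `width_scale=1` recovers full-width stages. Input
sizes must be divisible by the total stride (4).

Layers are implemented in-repo on numpy (im2col convolution with stride
and dilation, ReLU, global pooling, bilinear upsampling) with
hand-wired backpropagation, verified against scipy correlation and
finite differences. Training minimises pixel-wise binary cross-entropy
with Adam (default lr 1e-2), full-batch by default, deterministic for a
fixed seed. The shipped configuration is a capacity and correctness
check (overfit ten synthetic frames to Dice ≥ 0.95), not a clinical
model; no augmentation or regularisation is applied. Dice of two empty
masks is defined as 1.

## Synthetic data

The simulator emulates exactly the statistical structure the pipeline
consumes: a filled ellipse whose axes follow a raised-cosine ED→ES→ED
profile, end-systole at 40% of each cycle (systole shorter than
diastole), isotropic shrink s = (1 − EF/100)^(1/3) so each cycle's EF
is exact by construction, cycle lengths either fixed (sinus) or drawn
from a log-normal with a given coefficient of variation and clipped at
4 frames (AF-like), a rising lead-in and falling tail so every truth
extremum is interior, speckle as a dark blood pool / bright rim / mid
far-field template under multiplicative uniform noise of amplitude
1/SNR, and a frame-level area corruptor for outlier experiments. All
generators are deterministic under a fixed seed.

Defaults used in the shipped experiments: 112×112 canvas, ED axes
80×40 px, mean period 40–60 frames, period CV 0.2–0.3 for irregular
rhythm, 3% multiplicative area noise as the segmentation-error proxy,
corruption factor 0.7 for a single bad frame — values chosen once as
representative of resized A4C loops and held fixed. What the simulator
does **not** model: ultrasound physics (point-spread function,
shadowing, dropout), valve/atrial anatomy, probe motion, or observer
trace variability; passing on synthetic data therefore demonstrates the
measurement chain's correctness, not clinical accuracy.

## Experiment designs shipped with the package

- **Ellipse oracle.** Volume identity to 1e-9 relative error on five
  (L, D) pairs; rasterised end-to-end EF within 3 EF points of truth
  for short axes ≥ 20 px (pixel-centre rasterisation keeps mask counts
  within 2% of πLD/4 in that regime).
- **Peak detection.** Detected (ED, ES) pairs equal simulator truth ±1
  frame for 1–6 cycles at periods 40–80; sub-half-range spikes never
  add cycles. Irregular-rhythm draws whose realised periods fall below
  twice the stepsize are outside the detector's contract and skipped.
- **Jeffrey robustness.** 100 seeded irregular curves with 2% area
  noise; cycles detected, then one detected ED frame corrupted ×0.7.
  Mean |refined − true peak| is compared between Jeffrey and raw on the
  same cycles. Corrupting after detection is deliberate: re-detection
  would sidestep the outlier and measure the detector instead.
- **All-cycle vs first-cycle.** 200 seeded videos, 3–5 cycles each,
  beat-to-beat EF scatter of 6 points around a per-video level, 3% area
  noise; Pearson r of all-cycle mean EF vs truth against r of the
  first cycle's EF vs truth, both with raw per-cycle areas so each
  beat's EF is its own (see the Jeffrey consequence above).
- **Length recovery.** 500 rasterised ellipses, label = height + 1 px
  Gaussian noise, 400/100 split, held-out R² ≥ 0.9.
- **Segmentation overfit.** 10 speckled frames, 200 epochs, mean Dice
  ≥ 0.95 against the generating masks.

Problem sizes were fixed once to keep the full suite within a desk-
scale single-CPU run (~1 minute for the acceptance script, ~1 minute
for the heaviest test).

## Numerical conventions

Coordinates are 0-based (x = column, y = row) with pixel-centre
semantics; a pixel belongs to a rasterised shape when its centre is
inside. Frame indices are 0-based half-open. 8-bit intensities are
normalised by the dtype maximum (exactly reversible). Intensities are
resized bilinearly, masks by nearest neighbour. Percentiles use linear
interpolation between order statistics. Reported EFs round to 2
decimals in reports; internal values are unrounded. Multi-component
masks use the largest connected component with a logged warning.

## Known limitations

Single-plane volumes are biased for non-ellipsoidal ventricles
(Simpson's biplane needs a second view and is out of scope). The
annotation reader assumes the EchoNet VolumeTracings convention that a
frame's first chord spans the long axis; this is overridable. AVI/MP4
decoding depends on an imageio ffmpeg backend being present; TIFF
stacks are the self-contained path. The ensemble extrapolates poorly
outside the feature range it was fitted on, as tree methods do.
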