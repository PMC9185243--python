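# Methods note

## Scope

`gaitpose` measures gait from monocular 2D lower-limb keypoint trajectories
(hips, knees, ankles; e.g. OpenPose BODY_25) and classifies six gait
phenotypes. This note records the model, its assumptions, all tunable
parameters, what the synthetic validation does and does not establish, and
the numerical choices made.

## Geometric model and assumptions

The camera is treated as orthographic over the capture volume; the subject
walks a straight route whose sagittal plane is rotated by an angle θ1 about
the vertical axis relative to the image plane. Under these assumptions:

1. **Standing calibration.** A vertical segment is not foreshortened by a
   rotation about the vertical axis, so during the standing segment the
   projected thigh/calf lengths equal the real lengths L3, L4. The
   calibration takes the per-frame hip–knee and knee–ankle pixel distances
   over the standing window, restricted to frames where all six joints are
   detected, and uses the **median** (robust to isolated detector glitches).
   A window with no complete frame raises a calibration error.

2. **3D knee angle.** From one frame's projected distances L1 (hip–knee),
   L2 (knee–ankle), L5 (hip–ankle):

   cos θ2 = (L1² + L2² − L5² + 2·√(L3²−L1²)·√(L4²−L2²)) / (2·L3·L4)

   The out-of-plane offsets of hip and ankle relative to the knee are
   d1 = √(L3²−L1²) and d2 = √(L4²−L2²) up to sign; the formula assumes both
   lie on the **same depth side** of the knee (the `+2·d1·d2` term). For
   normal leg configurations during walking — thigh and calf both trailing
   or leading within the tilted sagittal plane — this holds; the test suite
   verifies exactness to 1e-6° over 1000 random same-side configurations.
   Opposite-side configurations (e.g. extreme hyperextension out of plane)
   would be biased. Projected lengths exceeding real lengths by ≤ 5%
   (`PROJECTION_TOLERANCE`) are clamped and flagged (detector noise);
   larger excess raises a calibration error. |cos θ2| marginally above 1 is
   clamped and flagged. Frames with missing joints yield NaN rather than
   aborting the series.

3. **Step length.** At each cycle's knee-angle minimum αmin (valid domain
   90–180°), with the calf tilted βmin from the image vertical (folded into
   [0°, 90°] via atan2(|Δx|, |Δy|)):

   lα1 = Γ1·sin(αmin − 90°),  lα2 = lα1 − Γ2·sin(βmin), clamped at 0
   (flagged when clamped),

   with Γ1 = L3, Γ2 = L4 from calibration. lα1 models the step as the
   horizontal reach of the flexed thigh; lα2 subtracts the backward
   horizontal offset of the trailing calf. Step lengths inherit the unit of
   the keypoints (pixels); divide by a pixels-per-metre scale for metric
   output.

## Cycle segmentation and features

The per-leg 3D knee-angle series is NaN-interpolated, smoothed with a
0.15 s moving average, and minima are found with `scipy.signal.find_peaks`
on the negated series using a 5° prominence threshold and a 0.4 s minimum
separation. A gait cycle is the interval between **successive minima of the
same leg** (n troughs delimit n−1 cycles); αmin and βmin are re-read from
the unsmoothed data within each cycle. Cadence is counted in steps per
second pooled over both feet, so each leg completes one flexion cycle per
two steps.

The 11 features, in fixed order:

| name | definition |
|------|------------|
| LSS, RSS | mean per-cycle lα2, left / right |
| LLK, LRK | mean per-cycle αmin, left / right |
| AS | LSS + RSS (stride length) |
| APT | mean single-step time: mean gap between the pooled, interleaved cycle boundaries of both legs ≈ 1/cadence |
| AST | mean full-stride time (per-leg cycle duration) ≈ 2/cadence |
| VOR, VOL | variance of the right / left 3D knee-angle series over the walk |
| KAV, KAA | mean absolute angular velocity / acceleration (central differences via `np.gradient`), pooled over both legs |

Fewer than two cycles on either side raises an insufficient-data error
naming the side. The `2d` feature mode recomputes LSS/RSS/LLK/LRK from the
planar angle over the same cycle spans (segmentation always uses the 3D
series), leaving the other seven features identical; it exists to quantify
the benefit of the 3D reconstruction.

## Parameters

| parameter | default | rationale |
|-----------|---------|-----------|
| smoothing window | 0.15 s | shorter than a half-step at any plausible cadence; suppresses pixel noise |
| trough prominence | 5° | well below the smallest archetype flexion amplitude (24°) |
| minimum trough separation | 0.4 s | below the shortest per-leg cycle considered (fast 2.5 steps/s gait) |
| settle time after standing | 0.2 s | skips the stand-to-walk transition frame(s) |
| projection tolerance | 5% | pixel noise occasionally pushes projected length past the calibrated length |
| screening booster | gbtree, η = 0.3, depth 6, 100 rounds | fixed screening configuration |
| acceptance split | stratified 70/30 | held-out accuracy per retained feature count k = 11…1 |
| classifiers | GB(10 stages, log-loss), KNN(k=4, distance, p=1), MLP(50×50, ReLU, Adam, ≤800 iter), RF(57 trees), linear SVM | fixed benchmark configurations; the MLP may report a convergence warning at the iteration cap, by design |

All smoothing/segmentation constants are exposed in `PipelineConfig` and as
function arguments; classifier and booster settings are deliberately fixed.

## Simulator scope

The simulator drives a 3D two-segment leg chain: knee angle
θ(t) = baseline − A·sin²(πu + φ) with stride phase u advancing at
cadence/2 cycles/s, legs half a stride apart; the calf trails the vertical
by (A/3)·sin²(·) so that peak flexion is a landing-like configuration; the
hip advances one nominal step per step, where the nominal step is the
skeleton's horizontal hip→ankle reach at peak flexion. Class archetypes:
standard (1.8 steps/s, 60° amplitude), mop (left amplitude halved), drunk
(large smoothed angle jitter + lateral sway), intermittent (random 0.7 s
pauses that freeze the pose), magnetic (amplitude 24°, cadence 1.1,
shortened advance), scissor (reduced amplitude + 10° inward calf
adduction). Recordings are orthographically projected at a tilt θ1,
converted at 500 px/m, and given Gaussian pixel noise; a 1 s standing
segment is prepended. The default dataset is 8 synthetic subjects × 5
trials × 6 classes = 240 recordings with per-subject size/cadence/amplitude
variation and per-recording tilt drawn from 5–25°.

**What passing the synthetic tests shows:** the geometry is exact under its
stated assumptions; the feature definitions recover the programmed gait
parameters (trough angle within 1°, step time within one frame); the
calf-corrected step estimate is structurally closer to the skeleton's true
per-step displacement than the thigh-only estimate; and the full pipeline
separates the six archetypes (random-forest macro precision ≥ 0.85 on a
stratified 70/30 split). **What it does not show:** performance on real
video — real keypoint noise is not i.i.d. Gaussian, real gaits are not
sinusoidal, perspective is not orthographic, and the archetypes are
caricatures of the clinical phenotypes. Synthetic classification scores
should not be quoted as clinical accuracy.

## Numerical choices

- Angles are computed via `arccos` of a clipped cosine; series
  reconstruction is vectorised and per-frame failures degrade to NaN.
- The per-recording dataset and all stochastic stages take explicit integer
  seeds (`numpy.random.default_rng`); there is no hidden global state.
- Importance = normalized total gain; zero-importance ties (e.g. constant
  features) are broken by feature name for determinism.
- "Acceptance score" = held-out accuracy of the screening booster retrained
  on the top-k features, one fixed stratified 70/30 split, so scores are
  exact multiples of 1/test-fold-size.
- Macro precision/recall are hand-counted from the confusion matrix; a
  class never predicted contributes precision 0 and is flagged
  (`undefined_precision`) rather than silently dropped.
- The depthwise-separable cost ratio 1/N + 1/D_K² is an exact rational
  identity, independent of input channels and output size; `audit_layers`
  additionally reports the honest aggregate over an explicit layer list,
  which differs from the single-layer identity when channel counts vary.
- Feature CSVs are written with 17 significant digits so write/read
  round-trips to 1e-12.

## Known limitations

- Orthographic-camera and straight-route assumptions; no per-frame tilt
  estimation (θ1 may drift in real footage).
- The same-depth-side assumption of the knee-angle formula can fail for
  configurations outside normal gait.
- Step lengths are reported in pixels unless a scale is supplied; no
  absolute metric calibration is attempted.
- Occlusion handling is limited to linear interpolation of short gaps
  (longer gaps are flagged, not filled) and NaN propagation.
- Classifier scores on synthetic data are an internal-consistency check,
  not a clinical validation.
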