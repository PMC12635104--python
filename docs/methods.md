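# Methods

## The estimation problem

Gestational age (GA) is the clinical clock of pregnancy, measured in days
from the last menstrual period. The reference methods — crown–rump length
(CRL) dating before 14 weeks, multi-measurement biometry afterwards —
require trained sonographers acquiring specific imaging planes. `fetalga`
implements an alternative: a regression model that reads GA (with an
uncertainty) off *any* fetal ultrasound frame, fused over the frames of an
undirected scan video by a one-dimensional Bayesian filter. The package
also implements the reference formulas and the agreement statistics needed
to compare the two routes.

## Per-frame model

GA is positive and its measurement error grows roughly multiplicatively
with gestation, so the model works in natural-log space: the label is
`y = ln(GA_days)`. A trunk network maps a canonical 384×576 greyscale frame
to a d-dimensional representation; a **mean head** outputs `mu` (log-days)
and a **variance head** outputs `sigma > 0` (log-days), together a Gaussian
predictive distribution over log-GA. `exp(mu)` is the point estimate in
days and `exp(mu ± 1.96 sigma)` the 95% interval.

Training minimises, summed over the batch,

    L = |y − mu(f(x))|² / 2  −  ln N(y | sg[mu(f(x))], sigma(sg[f(x)]))

where `sg[·]` is a stop-gradient. The squared-error term trains the trunk
and mean head. The Gaussian negative log-likelihood term sees only
gradient-stopped inputs upstream of the variance head, so it trains the
variance head alone: `sigma` learns the conditional error scale
`sigma*(z) ≈ sqrt(E[r² | z])` without ever dragging the trunk toward
variance-friendly features. The analytic gradients implement this contract
exactly and are verified against finite differences in the tests.

Training is phased: **phase 1** freezes the variance head (trunk + mean
head learn the regression); **phase 2** fine-tunes everything, letting
`sigma` calibrate to the phase-1 residual structure. Each phase runs under
Adam (eps 1e-8, betas 0.9/0.999) with a linear learning-rate warmup from 0
followed by cosine annealing back to 0.

### Variance link and floors

The variance head is a single linear layer producing log-sigma; `sigma =
exp(log-sigma)` floored at 1e-4 log-days. The exponential link guarantees
strict positivity; the floor prevents the NLL from diverging if a residual
ever hits zero exactly. When the floor binds, the variance-head gradient
for that sample is zeroed rather than extrapolated.

### The surrogate trunk

The production-scale counterpart of this model is a ConvNeXt-small trunk
(d = 768) trained on millions of archived frames on a GPU cluster — out of
scope for this package, whose purpose is the method, not the clinical
checkpoint. The runnable trunk is a compact NumPy convolutional encoder
with explicit analytic gradients:

* input: canonical frame block-averaged by an integer factor (default 3 →
  128×192); the factor is configurable. 3 was chosen because at 4× the
  phantom structure's boundary blurs into speckle and held-out recovery
  degrades noticeably, while 3× keeps a two-phase training run on ~500
  images around five minutes on one CPU;
* three stride-2 conv layers (5×5 then 3×3, ReLU, default 8/16/32
  channels), global average pooling, and a dense+ReLU projection to the
  d = 32 representation;
* both heads are single linear layers, the minimal reading of "prediction
  head".

All downstream logic (loss, phasing, fusion, evaluation) is trunk-agnostic.

### Surrogate training settings

The demonstration settings (`surrogate_demo_settings`) are 30 epochs in
phase 1 and 60 in phase 2, warmup 3, max learning rate 1e-2, batch 32.
1e-2 was chosen by the learning-rate range-test route (`lr_range_test`);
the `ScheduleConfig` defaults (100 epochs/phase, warmup 10, 3e-4) describe
the full-scale recipe, which uses equal phases. The asymmetric demo split
reflects that the variance head trains only in phase 2: it has to travel
from its prior-scale initialisation (sigma ≈ 0.35) down to the residual
scale (≈ 0.06), and a longer second phase lets it calibrate fully without
lengthening phase 1, where extra epochs mainly overfit the mean head at
this data scale. Batch size and weight decay are not pinned down by the
full-scale recipe; 32 and 0 are used and recorded in the run config. The
loss is summed (not averaged) over the batch; the scaling is absorbed by
the learning rate.

### Junk frames in training

Every stored image in a routine archive carries the patient-record GA even
when the frame shows no fetus. The cohort generator mirrors this: manifest
rows always carry the scan-level `ga_days`, junk frames flagged by
`is_fetal=False` (the rendered `PhantomImage` object itself has no GA when
junk). Training on junk frames with the scan GA as label is what teaches
the variance head that uninformative content means large sigma: the mean
head cannot fit those labels, the residuals stay near the population
spread (~0.3 log-days), and sigma follows. Held-out *accuracy* is always
evaluated on fetal frames only, since no image-level truth exists for junk
frames.

## Video fusion

Over a ≤3-minute video the fetus's GA is constant, so the per-frame
predictions are observations of a single scalar state. A static 1D Kalman
filter tracks state mean `p` and state standard deviation `q` in log-GA
space, initialised at `p0 = 4.94` (exp ≈ 140 days, mid-gestation) and
`q0 = 0.35` (95% prior interval ≈ 70–278 days):

    K_i = q_{i-1}² / (q_{i-1}² + sigma_i²)
    p_i = p_{i-1} + K_i (mu_i − p_{i-1})
    q_i = sqrt((1 − K_i) q_{i-1}² + eps),   eps = 0.001

Three operational rules:

* **Screening.** Frames with `sigma_i > Σ = 0.1` are excluded (strict
  inequality); the model's own uncertainty is the junk-frame detector.
* **Subsampling.** Successive video frames are correlated, violating the
  filter's independent-noise assumption; frames are subsampled at 1 fps.
* **Stopping.** The filter halts and emits as soon as `q_i < τ`, ignoring
  the rest of the video; the confidence criterion "sufficiently confident"
  is realised as a threshold on the state spread. The choice of τ is
  constrained by the process noise: with ε > 0 the spread converges to
  `q_inf(sigma) = sqrt((ε + sqrt(ε² + 4 ε sigma²))/2)` and can never fall
  below `sqrt(ε) ≈ 0.032`, so any τ under that floor would never fire.
  At the screening boundary (sigma = Σ = 0.1), `q_inf ≈ 0.061`; the default
  τ = 0.065 log-days sits just above it, so every stream of accepted frames
  eventually stops (±6.5% GA ≈ ±9 days at 140 days); configurable. If the
  video ends first, the final state is emitted flagged "not reached"; if
  nothing is ever accepted, the prior is emitted flagged `prior_only`.

A published statement of the gain writes `p_{i-1}²` where this package uses
`q_{i-1}²`. With `p ≈ 5` and `sigma ≤ 0.1` the mean-squared form pins
`K > 0.99` for every frame, contradicting the companion `q` update and the
variable roles in the process diagram; it is treated as a typographical
slip for the prior variance. The printed form remains available behind
`FilterConfig.gain_from_state_mean` for audit, and a test documents its
degenerate behaviour.

With `eps = 0` the filter is algebraically the conjugate normal-normal
posterior — precision `1/q0² + Σ 1/sigma_i²`, precision-weighted mean —
hence invariant to the order of accepted observations up to floating-point
rounding (~1e-15 per step; verified to 1e-12). This is the mechanism behind
the method's robustness to the order in which anatomy is scanned. With
`eps > 0` the state spread is floored at `sqrt(eps)`, keeping the filter
responsive; order-invariance then holds only approximately.

## Reference GA

* **Biometry** (mm in, days out):
  `GA = 7·(10.85 + 0.0006·HC·FL + 0.067·BPD + 0.0168·AC)`. Coefficient
  magnitudes only make sense for millimetre inputs. Monotone
  non-decreasing in every measurement (asserted over a grid).
* **CRL dating**: the dating curve is a pluggable strategy; the default is
  the Robinson–Fleming form `GA = 8.052·sqrt(CRL_mm) + 23.73`. The default
  is labelled, not asserted, as any particular chart's parameters.
* **Gold standard**: the dating-scan GA must fall in the 9+0 to 13+6 week
  window (63–97 days); the days elapsed between dating scan and
  examination are added. Propagation is exactly linear in elapsed days.
* Before 14 weeks CRL-based GA is definitionally correct, so biometry
  comparison is disabled there (`comparison_mode` returns
  `"crl_benchmark"`) and accuracy is judged against a literature benchmark
  instead.

## Evaluation battery

* **MAE by GA band**: bands are half-open `[lo, hi)` in weeks of reference
  GA, default breakpoints 10, 14, 18, 24, 30, 36; overall MAE equals the
  count-weighted band mean by construction.
* **Paired Wilcoxon signed-rank** on absolute errors, two-sided (the
  sidedness is a choice; one-sided would halve the p-values). Zero
  differences dropped (Wilcoxon's original rule); exact null for n ≤ 25,
  normal approximation with continuity correction above. The
  implementation (a scipy wrapper) is tested against exhaustive sign-flip
  enumeration for all n ≤ 8.
* **Bland–Altman**: differences predicted − reference, mean ± 1.96 SD
  limits of agreement; limits undefined below 3 pairs.
* **Time-to-prediction CDF**: videos that never reach confidence are
  right-censored — counted in the denominator, never as reached; the
  median is where the CDF first reaches 0.5.
* **Shuffle consistency**: fraction of re-shuffled clip pairs whose
  estimates differ by strictly less than 3 days (threshold configurable).
* The unit of analysis is the scan; aggregate to one record per scan
  before testing.

## Synthetic phantoms

Real archives are access-restricted, so the package ships a generator
whose frames encode GA the way biometry does — through size:

* a bright ellipse (intensity 0.75 over background 0.15) whose
  *equivalent diameter* follows `D(ga) = c · ga^e` pixels, default
  `c = 2.0`, `e = 0.6` (≈ 25–55 px over 9–36 weeks, strictly monotone,
  fits the frame); position, orientation and axis ratio are randomized,
  with semi-axes chosen so the equivalent diameter is exact;
* multiplicative log-normal speckle (default sigma 0.25 of intensity,
  mildly smoothed for spatial correlation) over a slowly varying
  background gain;
* **junk frames**: structured blob noise, no ellipse — the probe-off /
  non-2D-mode analogue that exercises the sigma screen;
* full scans synthesized at 5 fps (so 1-fps subsampling is observable),
  junk arriving in contiguous 5-s blocks; frames render lazily from
  per-frame seeds, so clip splicing and early stopping never pay for
  unrendered frames;
* the 3-minute test clip: 36 non-overlapping 5-s subsegments drawn on a
  5-s grid without replacement, shuffled, concatenated — 180 s exactly;
  a new seed re-selects and re-shuffles (the re-shuffle consistency
  protocol). Grid alignment is a choice; it guarantees non-overlap by
  construction.

What the phantom does *not* emulate: fetal anatomy, probe physics,
shadowing, multiple pregnancies, anomalies, or any realistic appearance
statistics. Passing tests demonstrate that the estimation machinery —
loss, phasing, calibration direction, fusion, statistics — behaves as
specified on data whose generative truth is known; they say nothing about
accuracy on clinical images.

## Cohort and split conventions

Stratified sampling balances (source × 4-week GA band × probe type) cells,
bands anchored at week 8; within a cell, subjects are visited in random
order contributing varying numbers of images, and under-full cells return
all members — no record category is excluded. Train/validation splitting
randomizes at the subject level (all images of one woman on one side),
assigning `floor(n_subjects × fraction)` subjects to training.

## Augmentation

A RandAugment-style policy: per image, N drawn uniformly from a range
(default [1, 3]), N distinct transforms sampled from {rotation, re-scaling,
horizontal flip, blur, brightness–contrast jitter, pixel-wise
multiplicative noise, grid distortion}, each with a magnitude drawn from
its range. Defaults are mild (rotation ±20°, rescale ×[0.9, 1.1], blur
sigma ≤ 1.5 px, jitter ±15%, noise sigma 0.05, grid displacement ≤ 5%) and
geometric fills are black, matching the ultrasound background. Re-scaling
perturbs apparent structure size — the very cue that predicts GA — which
is why its default range is narrow; the tension is inherent and flagged
rather than resolved.

## Numerical and I/O choices

* Resize: bilinear, direct stretch to 384×576 (no letterboxing); colour
  collapsed by Rec. 601 luminance; preprocessing is idempotent.
* Videos: a directory of numbered PNG frames (with `scan.json` metadata)
  is the first-class format; standard containers are read through imageio
  when an ffmpeg plugin is present.
* Checkpoints: a single `.npz` with the config embedded as JSON.
* All randomness flows from explicit integer seeds; fixed seeds reproduce
  runs bit-for-bit.

## Problem sizes used in tests and the acceptance script

The recovery demonstration trains on a 100-subject cohort (~500 images,
GA uniform over 70–250 days, 20% junk), split 90:10 by subject; the video
protocol runs 12 scans × 2 re-shuffled clips. These sizes were chosen so a
full from-scratch run of the suite and the acceptance script completes in
minutes on a single CPU while leaving the recovery margins (baseline/MAE
ratio, slope window, sigma separation) comfortably wide.

### What process noise implies for consistency

ε > 0 gives the filter a finite memory: at steady state the gain tends to
`K∞ = q∞²/(q∞² + σ²)`, so the state effectively averages only the last
~1/K∞ accepted frames and the fused estimate retains a sampling spread of
order `sqrt(K σ²/(2−K))` log-days no matter how long the video is. The
re-shuffle consistency fraction at a fixed day threshold therefore scales
with per-frame accuracy: at the surrogate's σ ≈ 0.06 the 3-day threshold
yields a fraction near 0.5, whereas a per-frame σ an order of magnitude
smaller (the regime of an archive-scale model whose static-image MAE is
~2 days) pushes the same statistic above 0.9. The acceptance script
reports the fraction the pipeline actually achieves.

## Known limitations

* The surrogate trunk is a demonstration vehicle; its absolute MAE on
  phantoms (≈5–7 days held-out, seed-dependent) has no clinical meaning,
  and occasional training runs land noticeably worse — small-sample
  optimisation variance the demo makes no attempt to hide.
* The phantom growth law is one monotone curve, not a biometric chart;
  parameter recovery shows identifiability of the mechanism, not dating
  accuracy.
* The stopping threshold τ is a design choice; the source method states
  only a confidence criterion.
* Exact bitwise order-invariance of the filter is impossible in floating
  point; invariance holds to ~1e-12.
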