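# fetalga

Gestational-age (GA) estimation from non-targeted fetal ultrasound:
per-frame heteroscedastic regression in log-GA space, fused over video by a
static 1D Kalman filter, with the clinical reference formulas and the
agreement statistics to compare against them — all runnable end to end on
synthetic ultrasound phantoms.

## The problem

Accurate GA underpins prenatal care, but the standard ultrasound methods
(crown–rump length dating before 14 weeks, BPD/HC/AC/FL biometry after)
require skilled sonographers acquiring specific planes. An alternative is a
model that estimates GA from *any* fetal frame, together with an
uncertainty that flags unusable frames, so that an undirected sweep of the
probe — even by a novice — yields a usable estimate. This package
implements that method for researchers studying it: the model and its
composite loss, the video fusion filter, the reference dating formulas, the
evaluation battery, and a phantom generator that stands in for restricted
clinical archives.

## The method

**Per-frame model.** A trunk network maps a 384×576 greyscale frame to a
representation `z`; a mean head predicts `μ = E[ln GA]` and a variance head
predicts `σ > 0`, so each frame yields a Gaussian over log-GA. Training
minimises, with `⌊·⌋` a stop-gradient,

    Σ_(x,y)  |y − μ(f(x))|²/2  −  ln 𝒩(y | ⌊μ(f(x))⌋, σ(⌊f(x)⌋))

The squared-error term trains trunk + mean head; the likelihood term trains
only the variance head, which therefore learns the conditional error scale
without distorting the features. Training is two-phase (variance head
frozen, then everything), Adam with linear warmup and cosine annealing.
The runnable trunk is a compact NumPy convolutional surrogate with analytic
gradients; the loss, phasing, and fusion are trunk-agnostic.

**Video fusion.** Per-frame predictions (1 fps subsampled) feed a static 1D
Kalman filter on state (p, q), initialised p₀ = 4.94 (≈140 days),
q₀ = 0.35:

    K = q²/(q² + σᵢ²),   p ← p + K(μᵢ − p),   q ← sqrt((1−K)q² + ε)

Frames with σᵢ > Σ = 0.1 are screened out; the filter stops as soon as q
falls below a confidence threshold and reports the elapsed time.

**References and statistics.** Biometry dating
`GA = 7(10.85 + 0.0006·HC·FL + 0.067·BPD + 0.0168·AC)` (mm → days), CRL
dating with a pluggable curve plus elapsed-day propagation, banded MAE,
paired Wilcoxon signed-rank, Bland–Altman limits of agreement,
time-to-prediction CDF with right-censoring, and re-shuffle consistency.

## Worked example

```python
import numpy as np
import fetalga as fg
from fetalga.model import surrogate_demo_settings, train

# 1. a labelled phantom cohort, split by subject
manifest, images = fg.generate_cohort(
    100, ga_range=(70, 250), junk_fraction=0.2, seed=20,
    images_per_subject=(4, 6),
)
manifest = fg.split_by_subject(manifest, 0.9, seed=20)

# 2. train the surrogate (two phases, ~5 min on one CPU)
config, schedule = surrogate_demo_settings(seed=20)
model, log = train(manifest, config, schedule, images=images)

# 3. fuse a shuffled 3-minute clip of a 160-day scan
scan = fg.generate_scan("demo", ga_days=160.0, duration_s=200.0, seed=7)
clip = fg.splice_shuffled_clip(scan, seed=8)
est = fg.predict_video(clip, model)
print(round(est.ga_days, 1), est.time_to_prediction_s, est.frames_used)
```

This prints `166.7 2.0 3`: the filter accepted 3 confident frames, stopped
2 s into the clip, and the fused estimate is within about a week of the
true 160-day GA — the per-frame σ of ≈0.07 log-days makes a 3-frame fusion
accurate to a few percent, and junk segments are screened out by their
large σ rather than corrupting the state. On held-out
phantoms this training run reaches ≈6 days mean absolute error versus
≈47 days for a constant predictor, with a predicted-vs-true slope of ≈1.0
and junk-frame σ roughly three times fetal-frame σ.

The same pipeline is scriptable from the shell:

```bash
fetalga simulate --n-subjects 100 --seed 20 --out runs/cohort
fetalga train --manifest runs/cohort/manifest.csv --out runs/model
fetalga predict-video --checkpoint runs/model/checkpoint.npz --video scan_frames/
fetalga evaluate --records records.csv --out runs/eval
```

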