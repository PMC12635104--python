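"""Shared fixtures.

The expensive fixture is ``recovery``: a full two-phase training run of the
surrogate model on a ~500-image phantom cohort, shared (session-scoped) by
the parameter-recovery, uncertainty-calibration, and pipeline smoke tests.
"""

import numpy as np
import pandas as pd
import pytest

import fetalga as fg
from fetalga.model import surrogate_demo_settings, train

RECOVERY_SEED = 20


@pytest.fixture(scope="session")
def recovery():
    """Train the surrogate on ~500 phantoms; return model + held-out metrics."""
    manifest, images = fg.generate_cohort(
        100,
        ga_range=(70, 250),
        junk_fraction=0.2,
        seed=RECOVERY_SEED,
        images_per_subject=(4, 6),
    )
    manifest = fg.split_by_subject(manifest, 0.9, seed=RECOVERY_SEED)
    config, schedule = surrogate_demo_settings(seed=RECOVERY_SEED)
    model, log = train(manifest, config, schedule, images=images)

    val = manifest[manifest["split"] == "val"]
    val_fetal = val[val["is_fetal"]]
    val_junk = val[~val["is_fetal"]]
    if len(val_junk) < 3:  # junk draw is Bernoulli; fall back to held-in junk
        val_junk = manifest[~manifest["is_fetal"]]
    x_f = np.stack([images[p].pixels for p in val_fetal["path"]])
    ga_true = val_fetal["ga_days"].to_numpy()
    mu_f, sigma_f = model.predict_batch(x_f)
    ga_pred = np.exp(mu_f)
    x_j = np.stack([images[p].pixels for p in val_junk["path"]])
    _, sigma_j = model.predict_batch(x_j)

    train_rows = manifest[manifest["split"] == "train"]
    baseline_ga = float(np.exp(np.log(train_rows["ga_days"].to_numpy()).mean()))

    return {
        "model": model,
        "log": log,
        "manifest": manifest,
        "images": images,
        "ga_true": ga_true,
        "ga_pred": ga_pred,
        "sigma_fetal": sigma_f,
        "sigma_junk": sigma_j,
        "mae_days": float(np.abs(ga_pred - ga_true).mean()),
        "baseline_mae_days": float(np.abs(baseline_ga - ga_true).mean()),
        "slope": float(np.polyfit(ga_true, ga_pred, 1)[0]),
    }
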