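"""The heteroscedastic model: loss closed forms, stop-gradient contract,
schedule shape, phased training, and parameter recovery on phantoms."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import fetalga as fg
from fetalga.model import (
    LOG_2PI,
    GAModel,
    ModelConfig,
    ScheduleConfig,
    _downscale_batch,
    learning_rate,
    surrogate_demo_settings,
)

TINY = ModelConfig(seed=0, channels=(4, 6, 8), representation_dim=8)


@pytest.fixture(scope="module")
def rng_images():
    rng = np.random.default_rng(0)
    return rng.random((3, 384, 576)).astype(np.float32)


class TestForward:
    def test_sigma_strictly_positive(self, rng_images):
        model = GAModel(TINY)
        _, sigma = model.predict_batch(rng_images)
        assert (sigma > 0).all()

    def test_identical_input_identical_output(self, rng_images):
        model = GAModel(TINY)
        a = model.forward(rng_images[0])
        b = model.forward(rng_images[0])
        assert a == b

    def test_non_canonical_input_rejected(self):
        model = GAModel(TINY)
        with pytest.raises(ValueError):
            model.forward(np.zeros((100, 100)))

    def test_convnext_trunk_not_available(self):
        with pytest.raises(NotImplementedError):
            GAModel(ModelConfig(trunk_kind="convnext-small-equivalent"))


class TestLoss:
    def test_zero_residual_unit_sigma_gives_half_log_2pi(self, rng_images):
        """With y = mu and sigma = 1 the loss is the Gaussian normaliser."""
        model = GAModel(TINY)
        model.var_head.W[:] = 0.0
        model.var_head.b[:] = 0.0  # sigma = exp(0) = 1
        mu, sigma = model.predict_batch(rng_images[:1])
        assert sigma[0] == 1.0
        loss = model.loss_and_grads(rng_images[:1], np.array([mu[0]]))
        assert abs(loss - 0.5 * LOG_2PI) < 1e-10
        assert abs(loss - 0.9189) < 1e-3

    def test_nll_minimised_at_sigma_equal_abs_residual(self):
        """d/dsigma of the Gaussian NLL vanishes at sigma* = |r|."""
        r = 0.2

        def nll(sigma):
            return 0.5 * LOG_2PI + np.log(sigma) + r**2 / (2 * sigma**2)

        res = optimize.minimize_scalar(nll, bounds=(1e-4, 5.0), method="bounded")
        assert abs(res.x - abs(r)) < 1e-6
        # our gradient formula 1 - r^2/sigma^2 vanishes there too
        assert abs(1.0 - r**2 / res.x**2) < 1e-4

    def test_nll_term_contributes_zero_trunk_gradient(self, rng_images):
        """Finite differences: the implemented trunk gradient equals the
        gradient of the squared-error term alone — the NLL term is fully
        gradient-stopped upstream of the variance head."""
        model = GAModel(TINY)
        y = np.array([4.5, 5.0, 5.3])
        model.loss_and_grads(rng_images, y)

        def sq_term():
            x = _downscale_batch(
                rng_images.astype(np.float64), model.config.downscale
            )
            z = model._features(x)
            mu = model.mean_head.forward(z)[:, 0]
            return float(np.sum(0.5 * (y - mu) ** 2))

        W, G = model.trunk[0].W, model.trunk[0].dW
        checked = 0
        for i, j in [(0, 0), (1, 5), (3, 20)]:
            eps = 1e-6
            old = W[i, j]
            W[i, j] = old + eps
            lp = sq_term()
            W[i, j] = old - eps
            lm = sq_term()
            W[i, j] = old
            fd = (lp - lm) / (2 * eps)
            if abs(fd) > 1e-8:
                assert abs(fd - G[i, j]) / abs(fd) < 1e-5
                checked += 1
        assert checked >= 2

    def test_variance_head_gradient_matches_nll_finite_difference(self, rng_images):
        model = GAModel(TINY)
        y = np.array([4.5, 5.0, 5.3])
        model.loss_and_grads(rng_images, y)

        def nll_term():
            x = _downscale_batch(
                rng_images.astype(np.float64), model.config.downscale
            )
            z = model._features(x)
            mu = model.mean_head.forward(z)[:, 0]
            s = np.maximum(model.var_head.forward(z)[:, 0], model._log_floor)
            return float(
                np.sum(0.5 * LOG_2PI + s + 0.5 * (y - mu) ** 2 / np.exp(2 * s))
            )

        b, gb = model.var_head.b, model.var_head.db
        eps = 1e-6
        old = b[0]
        b[0] = old + eps
        lp = nll_term()
        b[0] = old - eps
        lm = nll_term()
        b[0] = old
        fd = (lp - lm) / (2 * eps)
        assert abs(fd - gb[0]) / abs(fd) < 1e-6

    def test_empty_batch_rejected(self, rng_images):
        model = GAModel(TINY)
        with pytest.raises(ValueError):
            model.loss_and_grads(rng_images[:0], np.array([]))


class TestToGaDays:
    def test_log_inverse(self):
        pred = fg.FramePrediction(mu=np.log(140.0), sigma=0.1)
        assert fg.to_ga_days(pred) == pytest.approx(140.0)

    def test_printed_initialisation_constant_rounds_to_140(self):
        assert round(fg.to_ga_days(fg.FramePrediction(mu=4.94, sigma=0.1))) == 140

    def test_95pct_interval_at_prior_spread(self):
        pred = fg.FramePrediction(mu=4.94, sigma=0.35)
        ga, (lo, hi) = fg.to_ga_days(pred, interval=True)
        assert round(ga) == 140
        assert (round(lo), round(hi)) == (70, 278)


class TestSchedule:
    def test_warmup_and_cosine_endpoints(self):
        sched = ScheduleConfig()
        assert learning_rate(0, sched) == 0.0
        assert learning_rate(10, sched) == sched.max_learning_rate
        assert learning_rate(99, sched) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_decay_after_warmup(self):
        sched = ScheduleConfig(epochs_per_phase=50, warmup_epochs=5)
        lrs = [learning_rate(e, sched) for e in range(5, 50)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))

    def test_warmup_must_fit_phase(self):
        with pytest.raises(ValueError):
            ScheduleConfig(epochs_per_phase=5, warmup_epochs=5)


def _tiny_training_setup(n_subjects=12, seed=3):
    manifest, images = fg.generate_cohort(
        n_subjects, ga_range=(70, 250), junk_fraction=0.0, seed=seed,
        images_per_subject=(2, 3),
    )
    manifest = fg.split_by_subject(manifest, 0.8, seed=seed)
    return manifest, images


class TestTraining:
    def test_phase1_leaves_variance_head_bit_identical(self):
        manifest, images = _tiny_training_setup()
        snapshots = {}

        def grab(phase, model):
            snapshots[phase] = [p.copy() for p, _ in model.var_params()]

        config = ModelConfig(seed=1, channels=(4, 6, 8), representation_dim=8)
        schedule = ScheduleConfig(
            epochs_per_phase=2, warmup_epochs=1, max_learning_rate=1e-3,
            batch_size=16,
        )
        model, _ = fg.train(
            manifest, config, schedule, images=images, on_phase_end=grab
        )
        fresh = GAModel(config)
        for before, after in zip(
            [p for p, _ in fresh.var_params()], snapshots[1]
        ):
            assert np.array_equal(before, after)
        # phase 2 then moves it
        assert any(
            not np.array_equal(a, b)
            for a, b in zip(snapshots[1], snapshots[2])
        )

    def test_loss_decreases_over_phase1(self):
        manifest, images = _tiny_training_setup(n_subjects=25, seed=4)
        config = ModelConfig(seed=2)
        schedule = ScheduleConfig(
            epochs_per_phase=20, warmup_epochs=2, max_learning_rate=1e-2,
            batch_size=16, epochs_phase2=3,
        )
        _, log = fg.train(manifest, config, schedule, images=images)
        phase1 = log[log["phase"] == 1]["train_loss"].to_numpy()
        assert phase1[-1] < phase1[0] - 0.01

    def test_seeded_run_reproducible(self):
        manifest, images = _tiny_training_setup()
        config = ModelConfig(seed=5, channels=(4, 6, 8), representation_dim=8)
        schedule = ScheduleConfig(
            epochs_per_phase=2, warmup_epochs=1, max_learning_rate=1e-3,
            batch_size=16,
        )
        m1, log1 = fg.train(manifest, config, schedule, images=images)
        m2, log2 = fg.train(manifest, config, schedule, images=images)
        pd.testing.assert_frame_equal(log1, log2)
        for (a, _), (b, _) in zip(m1.all_params(), m2.all_params()):
            assert np.array_equal(a, b)

    def test_missing_split_rejected(self):
        manifest, images = fg.generate_cohort(4, seed=6)
        with pytest.raises(ValueError):
            fg.train(manifest, TINY, images=images)


class TestCheckpoint:
    def test_round_trip(self, tmp_path, rng_images):
        model = GAModel(TINY)
        path = tmp_path / "ck.npz"
        model.save(str(path))
        loaded = GAModel.load(str(path))
        assert loaded.config == model.config
        assert model.forward(rng_images[0]) == loaded.forward(rng_images[0])


class TestParameterRecovery:
    """Integration: the trained surrogate recovers GA from phantom geometry."""

    def test_heldout_mae_beats_constant_baseline_5x(self, recovery):
        assert recovery["mae_days"] * 5 <= recovery["baseline_mae_days"]

    def test_predicted_vs_true_slope_near_unity(self, recovery):
        assert 0.8 <= recovery["slope"] <= 1.2

    def test_junk_sigma_exceeds_fetal_sigma(self, recovery):
        """The variance head flags uninformative frames with larger sigma."""
        assert recovery["sigma_junk"].mean() > recovery["sigma_fetal"].mean()
        assert (
            recovery["sigma_junk"] > np.median(recovery["sigma_fetal"])
        ).mean() > 0.9

    def test_sigma_screen_separates_junk_from_fetal(self, recovery):
        """At the 0.1 screening threshold, most junk frames are rejected
        and most fetal frames accepted."""
        assert (recovery["sigma_junk"] > 0.1).mean() >= 0.9
        assert (recovery["sigma_fetal"] <= 0.1).mean() >= 0.9
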