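"""Heteroscedastic gestational-age regression from a single frame.

The model maps a canonical ultrasound frame to a Gaussian over log-GA: a
trunk network produces a d-dimensional representation, a mean head outputs
mu (log-days) and a variance head outputs sigma (log-days, strictly
positive).  GA is modelled in natural-log space because it is positive and
its error scales multiplicatively.

Training minimises, summed over the batch,

    |y - mu(f(x))|^2 / 2  -  ln N(y | sg[mu(f(x))], sigma(sg[f(x)]))

where sg[.] is a stop-gradient: the squared-error term trains the trunk and
mean head; the Gaussian negative log-likelihood term trains only the
variance head (both its mu argument and its feature input are detached).
Training is phased: phase 1 freezes the variance head, phase 2 finetunes
everything, each phase under Adam with a linear warmup followed by cosine
annealing to zero.

The network here is a compact convolutional surrogate trunk implemented
directly in NumPy with analytic gradients, operating on 3x-downscaled
(128x192) frames; the loss, stop-gradient semantics, phased schedule and all
downstream fusion logic are trunk-agnostic.  A ConvNeXt-small trunk
(d = 768) is the production-scale counterpart and is out of scope here: it
needs a GPU deep-learning stack and archive-scale data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .phantom import CANONICAL_SHAPE, PhantomImage


LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ModelConfig:
    trunk_kind: str = "small-surrogate"
    representation_dim: int = 32
    channels: tuple = (8, 16, 32)
    downscale: int = 3
    sigma_floor: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trunk_kind not in ("small-surrogate", "convnext-small-equivalent"):
            raise ValueError(f"unknown trunk_kind {self.trunk_kind!r}")
        if self.representation_dim < 1:
            raise ValueError("representation_dim must be >= 1")
        if self.sigma_floor <= 0:
            raise ValueError("sigma_floor must be positive")
        if CANONICAL_SHAPE[0] % self.downscale or CANONICAL_SHAPE[1] % self.downscale:
            raise ValueError("downscale must divide the canonical dimensions")


@dataclass(frozen=True)
class ScheduleConfig:
    """Per-phase optimisation schedule (defaults follow the full-scale recipe)."""

    epochs_per_phase: int = 100
    warmup_epochs: int = 10
    max_learning_rate: float = 3e-4
    batch_size: int = 32
    adam_eps: float = 1e-8
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    #: optional phase-2 override; None reuses epochs_per_phase for both phases
    epochs_phase2: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 <= self.warmup_epochs < self.epochs_per_phase):
            raise ValueError("warmup_epochs must be < epochs_per_phase")
        if self.epochs_phase2 is not None and self.epochs_phase2 <= self.warmup_epochs:
            raise ValueError("epochs_phase2 must exceed warmup_epochs")

    def phase_epochs(self, phase: int) -> int:
        if phase == 2 and self.epochs_phase2 is not None:
            return self.epochs_phase2
        return self.epochs_per_phase


@dataclass(frozen=True)
class FramePrediction:
    """Per-frame prediction: mean and sigma of log-GA (natural log of days)."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError("sigma must be strictly positive")
        if not np.isfinite(np.exp(self.mu)):
            raise ValueError("exp(mu) must be finite")


def to_ga_days(
    prediction: FramePrediction, interval: bool = False
) -> Union[float, Tuple[float, Tuple[float, float]]]:
    """Map a log-space prediction back to days; optionally its 95% interval."""
    ga = float(np.exp(prediction.mu))
    if not interval:
        return ga
    half = 1.96 * prediction.sigma
    return ga, (float(np.exp(prediction.mu - half)), float(np.exp(prediction.mu + half)))


def learning_rate(epoch: int, schedule: ScheduleConfig, phase: int = 1) -> float:
    """Linear warmup from 0 over warmup_epochs, then cosine annealing to 0.

    lr(0) = 0 (when warmup is on), lr(warmup_epochs) = max, lr(last) = 0.
    """
    E, W, M = schedule.phase_epochs(phase), schedule.warmup_epochs, schedule.max_learning_rate
    if epoch < W:
        return M * epoch / W
    span = max(1, E - 1 - W)
    t = (epoch - W) / span
    return M * 0.5 * (1.0 + np.cos(np.pi * t))


# ---------------------------------------------------------------------------
# Layers (NumPy, explicit gradients)
# ---------------------------------------------------------------------------


class _Conv2d:
    def __init__(self, cin: int, cout: int, k: int, stride: int, rng) -> None:
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = rng.normal(0.0, scale, (cout, cin * k * k))
        self.b = np.zeros(cout)
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        k, s = self.k, self.stride
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]
        oh, ow = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            B * oh * ow, C * k * k
        )
        y = cols @ self.W.T + self.b
        self._cache = (x.shape, cols, oh, ow)
        return y.reshape(B, oh, ow, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        (B, C, H, W), cols, oh, ow = self._cache
        k, s = self.k, self.stride
        dy_m = dy.transpose(0, 2, 3, 1).reshape(B * oh * ow, self.cout)
        self.dW += dy_m.T @ cols
        self.db += dy_m.sum(axis=0)
        dcols = (dy_m @ self.W).reshape(B, oh, ow, C, k, k)
        dx = np.zeros((B, C, H, W))
        for i in range(k):
            for j in range(k):
                dx[:, :, i : i + oh * s : s, j : j + ow * s : s] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        return dx

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)

    def params(self):
        return []


class _GlobalAvgPool:
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        B, C, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)

    def params(self):
        return []


class _Dense:
    def __init__(self, nin: int, nout: int, rng) -> None:
        self.W = rng.normal(0.0, np.sqrt(2.0 / nin), (nin, nout))
        self.b = np.zeros(nout)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW += self._x.T @ dy
        self.db += dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _Adam:
    def __init__(self, params, schedule: ScheduleConfig) -> None:
        self.params = params
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0
        self.b1, self.b2, self.eps = (
            schedule.adam_beta1,
            schedule.adam_beta2,
            schedule.adam_eps,
        )

    def step(self, lr: float) -> None:
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------


def _downscale_batch(images: np.ndarray, factor: int = 4) -> np.ndarray:
    """Block-average canonical (B, 384, 576) frames by an integer factor."""
    B = images.shape[0]
    h, w = CANONICAL_SHAPE[0] // factor, CANONICAL_SHAPE[1] // factor
    x = images.reshape(B, h, factor, w, factor).mean(axis=(2, 4))
    return x[:, None, :, :].astype(np.float64)


class GAModel:
    """Trunk + mean head + variance head with an exponential variance link.

    The variance head outputs log-sigma through a single linear layer; sigma
    is exp(log-sigma) floored at ``config.sigma_floor`` for numerical
    safety.  Both heads are single linear maps on the d-vector.
    """

    def __init__(self, config: ModelConfig = ModelConfig()) -> None:
        if config.trunk_kind != "small-surrogate":
            raise NotImplementedError(
                "only the 'small-surrogate' trunk is runnable here; the "
                "ConvNeXt-small trunk requires a GPU deep-learning stack"
            )
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.representation_dim
        c1, c2, c3 = config.channels
        self.trunk: List = [
            _Conv2d(1, c1, 5, 2, rng),
            _ReLU(),
            _Conv2d(c1, c2, 3, 2, rng),
            _ReLU(),
            _Conv2d(c2, c3, 3, 2, rng),
            _ReLU(),
            _GlobalAvgPool(),
            _Dense(c3, d, rng),
            _ReLU(),
        ]
        self.mean_head = _Dense(d, 1, rng)
        self.mean_head.b[:] = np.log(140.0)  # mid-gestation prior
        self.var_head = _Dense(d, 1, rng)
        self.var_head.b[:] = np.log(0.35)  # prior log-GA spread
        self._log_floor = np.log(config.sigma_floor)

    # -- parameter bookkeeping ------------------------------------------------

    def trunk_and_mean_params(self):
        out = []
        for layer in self.trunk:
            out.extend(layer.params())
        out.extend(self.mean_head.params())
        return out

    def var_params(self):
        return self.var_head.params()

    def all_params(self):
        return self.trunk_and_mean_params() + self.var_params()

    def zero_grads(self) -> None:
        for _, g in self.all_params():
            g[:] = 0.0

    # -- forward --------------------------------------------------------------

    def _features(self, x: np.ndarray) -> np.ndarray:
        h = x
        for layer in self.trunk:
            h = layer.forward(h)
        return h

    def _heads(self, z: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        mu = self.mean_head.forward(z)[:, 0]
        s = self.var_head.forward(z)[:, 0]
        s = np.maximum(s, self._log_floor)
        return mu, s, np.exp(s)

    def predict_batch(self, images: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """(mu, sigma) arrays for a (B, 384, 576) stack of canonical frames."""
        x = _downscale_batch(np.asarray(images, dtype=np.float64), self.config.downscale)
        z = self._features(x)
        mu, _, sigma = self._heads(z)
        return mu, sigma

    def forward(self, image: Union[np.ndarray, PhantomImage]) -> FramePrediction:
        """Predict (mu, sigma) for a single canonical frame."""
        pixels = image.pixels if isinstance(image, PhantomImage) else image
        if pixels.shape != CANONICAL_SHAPE:
            raise ValueError(f"expected canonical {CANONICAL_SHAPE} frame")
        mu, sigma = self.predict_batch(pixels[None])
        return FramePrediction(mu=float(mu[0]), sigma=float(sigma[0]))

    # -- loss -----------------------------------------------------------------

    def loss_and_grads(
        self,
        images: np.ndarray,
        y: np.ndarray,
        accumulate: bool = True,
    ) -> float:
        """Composite loss summed over the batch; gradients per the
        stop-gradient contract (squared error -> trunk + mean head; Gaussian
        NLL -> variance head only).
        """
        if len(y) == 0:
            raise ValueError("empty batch")
        if accumulate:
            self.zero_grads()
        x = _downscale_batch(np.asarray(images, dtype=np.float64), self.config.downscale)
        z = self._features(x)
        mu, s, sigma = self._heads(z)
        r = y - mu
        loss = float(
            np.sum(0.5 * r**2 + 0.5 * LOG_2PI + s + 0.5 * r**2 / sigma**2)
        )
        # Squared-error term: d/dmu = -(y - mu); flows through mean head and trunk.
        dmu = -r
        dz = self.mean_head.backward(dmu[:, None])
        # NLL term: d/d(log sigma) = 1 - r^2/sigma^2; the residual uses the
        # gradient-stopped mu and the head input z is detached, so this term
        # contributes nothing to the trunk.
        ds = 1.0 - r**2 / sigma**2
        ds = np.where(s > self._log_floor, ds, 0.0)  # clamped at the floor
        self.var_head.backward(ds[:, None])  # returned dz intentionally dropped
        for layer in reversed(self.trunk):
            dz = layer.backward(dz)
        if not np.isfinite(loss):
            raise RuntimeError("non-finite loss: training diverged")
        return loss

    def loss_value(self, images: np.ndarray, y: np.ndarray) -> float:
        """Loss without touching gradients (validation)."""
        x = _downscale_batch(np.asarray(images, dtype=np.float64), self.config.downscale)
        z = self._features(x)
        mu, s, sigma = self._heads(z)
        r = y - mu
        return float(np.sum(0.5 * r**2 + 0.5 * LOG_2PI + s + 0.5 * r**2 / sigma**2))

    # -- serialization --------------------------------------------------------

    def state_arrays(self) -> List[np.ndarray]:
        return [p for p, _ in self.all_params()]

    def save(self, path: str) -> None:
        arrays = {f"param_{i}": p for i, (p, _) in enumerate(self.all_params())}
        arrays["config_json"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "GAModel":
        data = np.load(path, allow_pickle=False)
        cfg = json.loads(bytes(data["config_json"]).decode())
        cfg["channels"] = tuple(cfg["channels"])
        config = ModelConfig(**cfg)
        model = cls(config)
        for i, (p, _) in enumerate(model.all_params()):
            p[:] = data[f"param_{i}"]
        return model


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _gather_arrays(
    manifest: pd.DataFrame,
    images: Optional[dict] = None,
    image_root: Optional[str] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Stack canonical frames and log-day labels for the given manifest rows."""
    from . import data_io

    frames = []
    for path in manifest["path"]:
        if images is not None:
            img = images[path]
            frames.append(img.pixels if isinstance(img, PhantomImage) else img)
        else:
            from pathlib import Path

            root = Path(image_root) if image_root else Path(".")
            frames.append(data_io.load_image(root / path))
    y = np.log(manifest["ga_days"].to_numpy(dtype=float))
    return np.stack(frames).astype(np.float32), y


def train(
    manifest: pd.DataFrame,
    config: ModelConfig = ModelConfig(),
    schedule: ScheduleConfig = ScheduleConfig(),
    images: Optional[dict] = None,
    image_root: Optional[str] = None,
    augment_policy=None,
    verbose: bool = False,
    on_phase_end: Optional[Callable[[int, "GAModel"], None]] = None,
) -> Tuple[GAModel, pd.DataFrame]:
    """Two-phase training on a split manifest.

    Phase 1 optimises trunk + mean head with the variance head frozen;
    phase 2 finetunes all parameters under a fresh warmup+cosine schedule.
    Every image with a manifest GA participates (junk frames carry the
    scan-level GA and teach the variance head what uninformative content
    looks like).  Returns the model and a per-epoch log
    (epoch, phase, lr, train_loss, val_loss), losses per sample.
    """
    if "split" not in manifest.columns:
        raise ValueError("manifest must carry a 'split' column (train/val)")
    tr = manifest[manifest["split"] == "train"]
    va = manifest[manifest["split"] == "val"]
    if tr.empty or va.empty:
        raise ValueError("manifest must contain both train and val rows")
    x_tr, y_tr = _gather_arrays(tr, images, image_root)
    x_va, y_va = _gather_arrays(va, images, image_root)

    model = GAModel(config)
    rng = np.random.default_rng(config.seed + 1)
    log_rows = []
    from .augment import apply_augment

    for phase in (1, 2):
        params = model.trunk_and_mean_params() if phase == 1 else model.all_params()
        opt = _Adam(params, schedule)
        for epoch in range(schedule.phase_epochs(phase)):
            lr = learning_rate(epoch, schedule, phase)
            order = rng.permutation(len(y_tr))
            total = 0.0
            for start in range(0, len(order), schedule.batch_size):
                idx = order[start : start + schedule.batch_size]
                xb = x_tr[idx]
                if augment_policy is not None:
                    xb = np.stack(
                        [
                            apply_augment(
                                xb[k], augment_policy, int(rng.integers(2**31 - 1))
                            )
                            for k in range(len(idx))
                        ]
                    )
                total += model.loss_and_grads(xb, y_tr[idx])
                opt.step(lr)
            train_loss = total / len(y_tr)
            val_loss = model.loss_value(x_va, y_va) / len(y_va)
            log_rows.append(
                {
                    "epoch": epoch,
                    "phase": phase,
                    "lr": lr,
                    "train_loss": train_loss,
                    "val_loss": val_loss,
                }
            )
            if verbose:
                print(
                    f"phase {phase} epoch {epoch:3d} lr {lr:.2e} "
                    f"train {train_loss:.4f} val {val_loss:.4f}"
                )
        if on_phase_end is not None:
            on_phase_end(phase, model)
    return model, pd.DataFrame(log_rows)


def surrogate_demo_settings(seed: int = 0):
    """Configuration pair for the desk-scale surrogate demonstration.

    A compact trunk on 3x-downscaled (128x192) frames — enough resolution to
    resolve the structure boundary against speckle — trained 30 epochs in
    phase 1 and 60 in phase 2 at a max rate of 1e-2 (picked by LR range test
    for this small network), batch 32, warmup 3.  The longer second phase
    gives the variance head, which only trains in phase 2, room to calibrate
    sigma down from its prior-scale initialisation to the residual scale.
    Used by the recovery tests and the acceptance script.
    """
    return (
        ModelConfig(seed=seed),
        ScheduleConfig(
            epochs_per_phase=30,
            warmup_epochs=3,
            max_learning_rate=1e-2,
            batch_size=32,
            epochs_phase2=60,
        ),
    )


def lr_range_test(
    manifest: pd.DataFrame,
    config: ModelConfig = ModelConfig(),
    schedule: ScheduleConfig = ScheduleConfig(),
    images: Optional[dict] = None,
    lr_grid: Sequence[float] = (1e-5, 1e-4, 1e-3, 1e-2),
    steps: int = 20,
) -> pd.DataFrame:
    """Short LR sweep: train a fresh model a few steps at each rate and
    report the final batch loss, for picking max_learning_rate."""
    tr = manifest[manifest.get("split", "train") == "train"]
    x, y = _gather_arrays(tr, images)
    rows = []
    for lr in lr_grid:
        model = GAModel(config)
        opt = _Adam(model.all_params(), schedule)
        rng = np.random.default_rng(config.seed)
        loss = np.nan
        try:
            for _ in range(steps):
                idx = rng.integers(0, len(y), size=min(schedule.batch_size, len(y)))
                loss = model.loss_and_grads(x[idx], y[idx]) / len(idx)
                opt.step(lr)
        except RuntimeError:
            loss = np.inf
        rows.append({"lr": lr, "final_loss": loss})
    return pd.DataFrame(rows)
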