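"""Static 1D Kalman fusion of per-frame log-GA predictions.

A scan video yields a stream of per-frame predictions (mu_i, sigma_i) in
log-GA space.  Because the fetus's GA is effectively constant over a
<=3-minute video, the state is a single scalar tracked by a static Kalman
filter: state mean p and state standard deviation q, initialised at
p0 = 4.94 (exp(p0) ~ 140 days, mid-gestation) and q0 = 0.35 (a 95% prior
interval of roughly 70-278 days).  Each accepted frame updates

    K_i = q_{i-1}^2 / (q_{i-1}^2 + sigma_i^2)
    p_i = p_{i-1} + K_i (mu_i - p_{i-1})
    q_i = sqrt((1 - K_i) q_{i-1}^2 + eps)

with process noise eps = 0.001.  Frames with sigma_i > SIGMA (0.1) are
screened out — the model's high uncertainty marks them as uninformative
(probe off the fetus, non-2D modes).  The filter stops and emits as soon as
q_i drops below a confidence threshold tau, ignoring the rest of the video.
Process noise bounds the reachable confidence: the steady-state spread at
observation noise sigma is q_inf = sqrt((eps + sqrt(eps^2 + 4 eps sigma^2))/2),
about 0.061 at the screening boundary, so tau defaults to 0.065 — just above
the worst spread any stream of accepted frames converges to, ensuring the
stopping rule can always fire (~ +/-6.5% GA, +/-9 days at 140 days).

Note the gain uses the prior *variance* q_{i-1}^2.  A published statement
of this recurrence writes the gain with the state mean p_{i-1}^2, which
with p ~ 5 would pin K ~ 1 and contradict the companion update for q; the
mean-based form is kept behind ``FilterConfig.gain_from_state_mean`` for
audit but is off by default.

With eps = 0 the filter is algebraically the conjugate-normal Bayesian
posterior, hence invariant (up to float rounding) to the order of accepted
observations — the mechanism behind the method's robustness to shuffling
scan content.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

import numpy as np

from .model import FramePrediction


@dataclass(frozen=True)
class FilterConfig:
    p0: float = 4.94
    q0: float = 0.35
    process_noise: float = 0.001
    screen_threshold: float = 0.1
    stop_threshold: float = 0.065
    frame_rate: float = 1.0
    gain_from_state_mean: bool = False  # printed-form audit switch

    def __post_init__(self) -> None:
        if self.q0 <= 0:
            raise ValueError("q0 must be positive")
        if self.process_noise < 0:
            raise ValueError("process noise must be non-negative")
        if self.screen_threshold <= 0 or self.stop_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class FilterState:
    """Scalar Kalman state in log-GA space with bookkeeping."""

    p: float
    q: float
    n_used: int = 0
    elapsed: float = 0.0

    def __post_init__(self) -> None:
        if self.q <= 0:
            raise ValueError("q must be strictly positive")


@dataclass(frozen=True)
class FusedEstimate:
    """The filter's output for one video."""

    ga_days: float
    interval95: Tuple[float, float]
    time_to_prediction_s: Optional[float]  # None = confidence never reached
    frames_used: int
    frames_rejected: int
    stopped: bool
    prior_only: bool
    p: float
    q: float


def initial_state(config: FilterConfig = FilterConfig()) -> FilterState:
    return FilterState(p=config.p0, q=config.q0)


def kalman_gain(
    state: FilterState, sigma_i: float, config: FilterConfig = FilterConfig()
) -> float:
    """Observation weight K in (0, 1): prior variance over total variance."""
    if sigma_i <= 0:
        raise ValueError("sigma_i must be strictly positive")
    prior_var = state.p**2 if config.gain_from_state_mean else state.q**2
    return prior_var / (prior_var + sigma_i**2)


def screen_frame(obs: FramePrediction, config: FilterConfig = FilterConfig()) -> bool:
    """True = accept.  Rejects iff sigma_i > screen threshold (strict)."""
    return not (obs.sigma > config.screen_threshold)


def kalman_update(
    state: FilterState, obs: FramePrediction, config: FilterConfig = FilterConfig()
) -> FilterState:
    """One accepted-frame update of (p, q); process noise added each step."""
    K = kalman_gain(state, obs.sigma, config)
    p = state.p + K * (obs.mu - state.p)
    q = float(np.sqrt((1.0 - K) * state.q**2 + config.process_noise))
    return FilterState(p=p, q=q, n_used=state.n_used + 1, elapsed=state.elapsed)


def _estimate(state: FilterState, config, rejected, stopped, t_pred) -> FusedEstimate:
    half = 1.96 * state.q
    return FusedEstimate(
        ga_days=float(np.exp(state.p)),
        interval95=(float(np.exp(state.p - half)), float(np.exp(state.p + half))),
        time_to_prediction_s=t_pred,
        frames_used=state.n_used,
        frames_rejected=rejected,
        stopped=stopped,
        prior_only=state.n_used == 0,
        p=state.p,
        q=state.q,
    )


def run_filter(
    predictions: Iterable[Tuple[float, FramePrediction]],
    config: FilterConfig = FilterConfig(),
) -> FusedEstimate:
    """Fuse a timestamp-ordered stream of per-frame predictions.

    Each element is (timestamp_s, FramePrediction).  Frames failing the
    sigma screen leave the state untouched.  The filter halts as soon as
    q < stop_threshold and reports the current timestamp as the time to
    prediction; if the stream ends first, the final state is emitted with
    ``time_to_prediction_s=None``.  An empty (or fully rejected) stream
    returns the prior, flagged ``prior_only``.
    """
    state = initial_state(config)
    rejected = 0
    for t, obs in predictions:
        state.elapsed = t
        if not screen_frame(obs, config):
            rejected += 1
            continue
        state = kalman_update(state, obs, config)
        state.elapsed = t
        if state.q < config.stop_threshold:
            return _estimate(state, config, rejected, stopped=True, t_pred=t)
    return _estimate(state, config, rejected, stopped=False, t_pred=None)


def conjugate_posterior(
    mus: np.ndarray,
    sigmas: np.ndarray,
    config: FilterConfig = FilterConfig(),
) -> Tuple[float, float]:
    """Closed-form normal-normal posterior over the accepted observations.

    With eps = 0 the sequential filter equals this exactly (up to float
    rounding): posterior precision = 1/q0^2 + sum 1/sigma_i^2, posterior
    mean the precision-weighted average.  Used as the independent oracle.
    """
    mus = np.asarray(mus, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    lam = 1.0 / config.q0**2 + np.sum(1.0 / sigmas**2)
    mean = (config.p0 / config.q0**2 + np.sum(mus / sigmas**2)) / lam
    return float(mean), float(1.0 / np.sqrt(lam))


def predict_video(
    video,
    model,
    filter_config: FilterConfig = FilterConfig(),
) -> FusedEstimate:
    """Full video pipeline: subsample at the filter's frame rate, predict
    each frame with the model, screen and fuse.  ``video`` may be a
    SyntheticScan or a data_io.FrameStream."""
    from .data_io import sample_frames

    def stream():
        for t, frame in sample_frames(video, rate=filter_config.frame_rate):
            yield t, model.forward(frame)

    return run_filter(stream(), filter_config)
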