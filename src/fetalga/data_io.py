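"""Canonical preprocessing, video subsampling, manifests, and splits.

Every image entering the model passes through :func:`preprocess_image`,
which enforces the 384x576 greyscale [0, 1] contract.  Video streams are
subsampled (default 1 frame per second) to decorrelate successive
observations before Kalman fusion.  Cohort manifests are plain CSV; the
randomization unit for train/validation splitting is the subject, so all
images of one woman land on the same side of the split.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from skimage.transform import resize

from .phantom import CANONICAL_SHAPE, SyntheticScan

# Rec. 601 luminance weights for colour inputs.
_LUMA = np.array([0.299, 0.587, 0.114])

#: 4-week stratification bands anchored at week 8 (day 56).
BAND_ANCHOR_DAYS = 56.0
BAND_WIDTH_DAYS = 28.0


def preprocess_image(raw: np.ndarray) -> np.ndarray:
    """Convert an arbitrary-size image to the canonical 384x576 frame.

    Colour inputs are collapsed by Rec. 601 luminance, integer inputs scaled
    by their dtype range, and the result resized (bilinear, stretched — no
    letterboxing) to 384x576 with values in [0, 1].  Idempotent: an
    already-canonical frame passes through unchanged.
    """
    arr = np.asarray(raw)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            arr = arr[:, :, :3] @ _LUMA
    elif arr.ndim != 2:
        raise ValueError(f"expected 2-D or 3-D image, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(raw.dtype).max
    else:
        arr = arr.astype(np.float64)
    arr = np.clip(arr, 0.0, 1.0)
    if arr.shape != CANONICAL_SHAPE:
        arr = resize(
            arr, CANONICAL_SHAPE, order=1, mode="edge", anti_aliasing=arr.shape[0] > CANONICAL_SHAPE[0]
        )
        arr = np.clip(arr, 0.0, 1.0)
    return arr.astype(np.float32)


def load_image(path: Union[str, Path]) -> np.ndarray:
    """Read an image file and return the canonical frame."""
    import imageio.v3 as iio

    try:
        raw = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the offending path
        raise IOError(f"could not read image {path!r}: {exc}") from exc
    return preprocess_image(raw)


# ---------------------------------------------------------------------------
# Video handling
# ---------------------------------------------------------------------------


@dataclass
class FrameStream:
    """An ordered frame source with a native frame rate."""

    frames: Sequence[np.ndarray]
    frame_rate: float

    @property
    def duration_s(self) -> float:
        return len(self.frames) / self.frame_rate


def read_video(path: Union[str, Path]) -> FrameStream:
    """Read a video as a FrameStream.

    Two dialects: a directory of numbered PNG frames with a ``scan.json``
    metadata file (preferred for tests and offline use), or a standard
    container via imageio if an ffmpeg plugin is installed.
    """
    import json

    p = Path(path)
    if p.is_dir():
        meta_path = p / "scan.json"
        rate = 5.0
        if meta_path.exists():
            rate = float(json.loads(meta_path.read_text()).get("frame_rate", rate))
        frame_files = sorted(p.glob("frame*.png"))
        if not frame_files:
            raise IOError(f"no frame*.png files in {p}")
        return FrameStream([load_image(f) for f in frame_files], rate)
    import imageio.v3 as iio

    try:
        meta = iio.immeta(p)
        frames = [preprocess_image(f) for f in iio.imiter(p)]
    except Exception as exc:  # noqa: BLE001
        raise IOError(
            f"could not read video {p} (container decoding needs an ffmpeg "
            f"plugin; a directory of numbered PNG frames is always supported): {exc}"
        ) from exc
    rate = float(meta.get("fps", 5.0))
    return FrameStream(frames, rate)


def sample_frames(
    video: Union[SyntheticScan, FrameStream],
    rate: float = 1.0,
) -> Iterator[Tuple[float, np.ndarray]]:
    """Yield (timestamp_s, frame) pairs at ``rate`` frames per second.

    One frame is taken per 1/rate seconds of video time, starting at t = 0;
    a 180-s clip at 1 fps yields 180 frames.  Frames are produced lazily so
    a downstream consumer that stops early never touches the rest.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    native = video.frame_rate
    if isinstance(video, SyntheticScan):
        n_frames = video.n_frames
        get = video.frame
    else:
        n_frames = len(video.frames)
        get = lambda i: video.frames[i]  # noqa: E731
    n_out = int(np.floor(n_frames / native * rate))
    for k in range(n_out):
        t = k / rate
        i = min(int(round(t * native)), n_frames - 1)
        yield t, get(i)


# ---------------------------------------------------------------------------
# Manifests, stratification, splitting
# ---------------------------------------------------------------------------


def read_manifest(path: Union[str, Path]) -> pd.DataFrame:
    m = pd.read_csv(path)
    required = {"subject_id", "path", "ga_days"}
    missing = required - set(m.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return m


def ga_band_index(ga_days) -> np.ndarray:
    """4-week band index of a GA, bands anchored at week 8 (day 56)."""
    return np.floor((np.asarray(ga_days, dtype=float) - BAND_ANCHOR_DAYS) / BAND_WIDTH_DAYS).astype(int)


def stratified_sample(
    manifest: pd.DataFrame,
    per_stratum_target: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Balanced sample over (source x 4-week GA band x probe type) cells.

    Within each cell, subjects are visited in random order and a random
    number of each subject's remaining images is drawn, until the target is
    reached — so per-subject contributions vary, and no record category is
    excluded.  Under-full cells return all their members.
    """
    if manifest.empty:
        raise ValueError("manifest is empty")
    if per_stratum_target < 1:
        raise ValueError("per_stratum_target must be >= 1")
    rng = np.random.default_rng(seed)
    m = manifest.copy()
    m["_band"] = ga_band_index(m["ga_days"])
    picked = []
    for _, cell in m.groupby(["source", "_band", "probe_type"], sort=True):
        if len(cell) <= per_stratum_target:
            picked.append(cell)
            continue
        subjects = cell["subject_id"].unique()
        rng.shuffle(subjects)
        remaining = {s: list(rng.permutation(cell.index[cell["subject_id"] == s])) for s in subjects}
        chosen: list = []
        while len(chosen) < per_stratum_target:
            for s in subjects:
                if len(chosen) >= per_stratum_target:
                    break
                pool = remaining[s]
                if not pool:
                    continue
                take = int(rng.integers(1, min(3, len(pool)) + 1))
                take = min(take, per_stratum_target - len(chosen))
                chosen.extend(pool[:take])
                del pool[:take]
        picked.append(cell.loc[chosen])
    out = pd.concat(picked).drop(columns="_band")
    return out.sort_index().reset_index(drop=True)


def split_by_subject(
    manifest: pd.DataFrame,
    train_fraction: float = 0.9,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign train/val splits with the subject as randomization unit.

    floor(n_subjects * train_fraction) subjects go to training; every image
    of a subject shares that subject's split.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    subjects = np.sort(manifest["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(subjects)
    n_train = int(np.floor(len(subjects) * train_fraction))
    train_set = set(perm[:n_train])
    out = manifest.copy()
    out["split"] = np.where(out["subject_id"].isin(train_set), "train", "val")
    assert not (
        set(out.loc[out["split"] == "train", "subject_id"])
        & set(out.loc[out["split"] == "val", "subject_id"])
    )
    return out
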