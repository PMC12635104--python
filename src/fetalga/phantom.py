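"""Synthetic ultrasound phantoms with a known gestational-age growth law.

Real fetal ultrasound archives are access-restricted, so every downstream
stage of the pipeline (preprocessing, model training, Kalman fusion over
video, evaluation statistics) is exercised on phantoms: greyscale frames in
which a bright ellipse-like structure stands in for the fetus.  The size of
the structure encodes gestational age through a strictly monotone power-law
growth curve, the way real biometric dimensions grow with GA.  Frames are
textured with multiplicative log-normal speckle, and a configurable fraction
of "junk" frames contain structured noise but no fetal structure — the
analogue of video periods where the probe is off the abdomen.

The phantom is a stand-in for exercising the method, not a claim of
anatomical realism.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

#: Canonical frame geometry shared by the whole pipeline (rows, columns).
CANONICAL_SHAPE = (384, 576)

#: Operating GA range in days (9 to 36 completed weeks).
GA_MIN_DAYS = 63.0
GA_MAX_DAYS = 252.0

DEFAULT_GROWTH_COEFFICIENT = 2.0
DEFAULT_GROWTH_EXPONENT = 0.6
DEFAULT_SPECKLE_SIGMA = 0.25

BACKGROUND_LEVEL = 0.15
STRUCTURE_LEVEL = 0.75

#: Internal synthesis frame rate for full scans (frames per second).  The
#: downstream video pipeline subsamples to 1 fps, so synthesising at 5 fps
#: keeps the subsampling stage observable.
SCAN_FRAME_RATE = 5.0

SUBSEGMENT_SECONDS = 5.0
N_SUBSEGMENTS = 36
CLIP_SECONDS = SUBSEGMENT_SECONDS * N_SUBSEGMENTS  # 180 s = 3 minutes


def structure_diameter_px(
    ga_days: float,
    coefficient: float = DEFAULT_GROWTH_COEFFICIENT,
    exponent: float = DEFAULT_GROWTH_EXPONENT,
) -> float:
    """Equivalent diameter (px) of the fetal structure at a given GA.

    D(ga) = coefficient * ga_days ** exponent, strictly increasing in GA.
    The default (2.0, 0.6) spans roughly 25-55 px over 9-36 weeks.
    """
    return coefficient * float(ga_days) ** exponent


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom frame.

    ga_days may be omitted for junk frames (a junk frame has no image-level
    GA); fetal frames require it within the [63, 252]-day operating range.
    """

    ga_days: Optional[float] = None
    growth_coefficient: float = DEFAULT_GROWTH_COEFFICIENT
    growth_exponent: float = DEFAULT_GROWTH_EXPONENT
    speckle_sigma: float = DEFAULT_SPECKLE_SIGMA
    junk: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.growth_coefficient <= 0:
            raise ValueError("growth_coefficient must be positive")
        if self.growth_exponent <= 0:
            raise ValueError("growth_exponent must be positive")
        if self.speckle_sigma < 0:
            raise ValueError("speckle_sigma must be non-negative")
        if not self.junk:
            if self.ga_days is None:
                raise ValueError("fetal phantom requires ga_days")
            if not (GA_MIN_DAYS <= self.ga_days <= GA_MAX_DAYS):
                raise ValueError(
                    f"ga_days={self.ga_days} outside operating range "
                    f"[{GA_MIN_DAYS}, {GA_MAX_DAYS}] days"
                )


@dataclass
class PhantomImage:
    """A rendered phantom frame: 384x576 greyscale intensities in [0, 1]."""

    pixels: np.ndarray
    ga_days: Optional[float]
    is_fetal: bool

    def __post_init__(self) -> None:
        if self.pixels.shape != CANONICAL_SHAPE:
            raise ValueError(f"phantom frame must be {CANONICAL_SHAPE}")
        if not self.is_fetal and self.ga_days is not None:
            raise ValueError("junk frames carry no GA label")


def _background(rng: np.random.Generator, shape: tuple) -> np.ndarray:
    """Smooth large-scale gain variation around the background level."""
    coarse = rng.normal(0.0, 1.0, (shape[0] // 32, shape[1] // 32))
    smooth = ndimage.zoom(coarse, 32, order=1)[: shape[0], : shape[1]]
    return BACKGROUND_LEVEL * (1.0 + 0.3 * np.tanh(smooth))


def _speckle(rng: np.random.Generator, shape: tuple, sigma: float) -> np.ndarray:
    """Multiplicative log-normal speckle field with unit mean."""
    if sigma == 0.0:
        return np.ones(shape)
    logfield = rng.normal(-0.5 * sigma**2, sigma, shape)
    # Mild smoothing mimics the spatial correlation of speckle texture.
    logfield = ndimage.gaussian_filter(logfield, 0.7)
    return np.exp(logfield)


def _ellipse_mask(
    rng: np.random.Generator, shape: tuple, diameter_px: float
) -> np.ndarray:
    """Boolean mask of a randomly placed/oriented ellipse.

    Semi-axes are chosen so the equivalent diameter (2*sqrt(area/pi)) equals
    diameter_px exactly: with axis ratio r, A = (D/2)/sqrt(r), B = (D/2)*sqrt(r).
    """
    ratio = rng.uniform(0.6, 1.0)
    a = 0.5 * diameter_px / np.sqrt(ratio)
    b = 0.5 * diameter_px * np.sqrt(ratio)
    theta = rng.uniform(0.0, np.pi)
    margin = a + 4.0
    cy = rng.uniform(margin, shape[0] - margin)
    cx = rng.uniform(margin, shape[1] - margin)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = yy - cy
    dx = xx - cx
    u = np.cos(theta) * dx + np.sin(theta) * dy
    v = -np.sin(theta) * dx + np.cos(theta) * dy
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _junk_structure(rng: np.random.Generator, shape: tuple) -> np.ndarray:
    """Structured blobs (no ellipse) for frames with no fetal content."""
    coarse = rng.normal(0.0, 1.0, (shape[0] // 16, shape[1] // 16))
    blobs = ndimage.zoom(coarse, 16, order=1)[: shape[0], : shape[1]]
    blobs = ndimage.gaussian_filter(blobs, 4.0)
    return 0.25 * np.clip(blobs, 0.0, None)


def generate_phantom_image(spec: PhantomSpec) -> PhantomImage:
    """Render one phantom frame, deterministically for a given spec.

    Fetal frames contain a bright ellipse whose equivalent diameter follows
    the growth law; junk frames contain only structured noise.
    """
    rng = np.random.default_rng(spec.seed)
    shape = CANONICAL_SHAPE
    img = _background(rng, shape)
    if spec.junk:
        img = img + _junk_structure(rng, shape)
    else:
        d = structure_diameter_px(
            spec.ga_days, spec.growth_coefficient, spec.growth_exponent
        )
        mask = _ellipse_mask(rng, shape, d)
        img = np.where(mask, STRUCTURE_LEVEL, img)
    img = img * _speckle(rng, shape, spec.speckle_sigma)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return PhantomImage(
        pixels=img,
        ga_days=None if spec.junk else float(spec.ga_days),
        is_fetal=not spec.junk,
    )


def measure_equivalent_diameter(pixels: np.ndarray, threshold: float = 0.45) -> float:
    """Pixel-counting estimate of the bright structure's equivalent diameter."""
    area = float(np.count_nonzero(pixels > threshold))
    return 2.0 * np.sqrt(area / np.pi)


# ---------------------------------------------------------------------------
# Cohorts of labelled still images
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["subject_id", "path", "ga_days", "is_fetal", "probe_type", "source"]

_SOURCES = ("site_a", "site_b", "site_c")


def _stratified_gas(
    rng: np.random.Generator, n: int, lo: float, hi: float
) -> np.ndarray:
    """GAs covering [lo, hi]: one uniform draw per equal-width slice, shuffled."""
    edges = np.linspace(lo, hi, n + 1)
    gas = rng.uniform(edges[:-1], edges[1:])
    rng.shuffle(gas)
    return gas


def generate_cohort(
    n_subjects: int,
    ga_range: tuple = (GA_MIN_DAYS, GA_MAX_DAYS),
    junk_fraction: float = 0.2,
    seed: int = 0,
    images_per_subject: tuple = (3, 8),
    growth_coefficient: float = DEFAULT_GROWTH_COEFFICIENT,
    growth_exponent: float = DEFAULT_GROWTH_EXPONENT,
    speckle_sigma: float = DEFAULT_SPECKLE_SIGMA,
    out_dir: Optional[str] = None,
):
    """Generate a labelled phantom cohort.

    Returns ``(manifest, images)`` where ``manifest`` is a DataFrame with
    columns ``subject_id, path, ga_days, is_fetal, probe_type, source`` and
    ``images`` maps each path to its :class:`PhantomImage`.  ``ga_days`` is
    the scan-level truth (known for every stored image, as in a routine
    archive); junk frames are flagged by ``is_fetal`` and the image object
    itself carries no GA.  Per-subject image counts vary uniformly within
    ``images_per_subject``.  If ``out_dir`` is given the frames are also
    written as 8-bit greyscale PNGs and paths point at real files.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not (0.0 <= junk_fraction < 1.0):
        raise ValueError("junk_fraction must be in [0, 1)")
    lo, hi = float(ga_range[0]), float(ga_range[1])
    if not (lo < hi):
        raise ValueError("empty GA range")

    rng = np.random.default_rng(seed)
    gas = _stratified_gas(rng, n_subjects, lo, hi)
    rows = []
    images: dict[str, PhantomImage] = {}
    for s in range(n_subjects):
        subject = f"subj{s:04d}"
        ga = float(gas[s])
        probe = "TV" if (ga < 84.0 and rng.random() < 0.6) else "TA"
        source = _SOURCES[int(rng.integers(len(_SOURCES)))]
        n_images = int(rng.integers(images_per_subject[0], images_per_subject[1] + 1))
        for k in range(n_images):
            junk = bool(rng.random() < junk_fraction)
            frame_seed = int(rng.integers(0, 2**31 - 1))
            spec = PhantomSpec(
                ga_days=None if junk else ga,
                growth_coefficient=growth_coefficient,
                growth_exponent=growth_exponent,
                speckle_sigma=speckle_sigma,
                junk=junk,
                seed=frame_seed,
            )
            path = f"{subject}/im{k:03d}.png"
            images[path] = generate_phantom_image(spec)
            rows.append(
                {
                    "subject_id": subject,
                    "path": path,
                    "ga_days": ga,
                    "is_fetal": not junk,
                    "probe_type": probe,
                    "source": source,
                }
            )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if out_dir is not None:
        _write_cohort(manifest, images, out_dir)
    return manifest, images


def _write_cohort(manifest: pd.DataFrame, images: dict, out_dir: str) -> None:
    import imageio.v3 as iio
    from pathlib import Path

    root = Path(out_dir)
    for path, img in images.items():
        target = root / path
        target.parent.mkdir(parents=True, exist_ok=True)
        iio.imwrite(target, (img.pixels * 255).round().astype(np.uint8))
    manifest.to_csv(root / "manifest.csv", index=False)


# ---------------------------------------------------------------------------
# Full-scan videos and shuffled 3-minute test clips
# ---------------------------------------------------------------------------


@dataclass
class SyntheticScan:
    """A synthetic scan video rendered lazily, frame by frame.

    Each frame is identified by a render seed; pixels are a pure function of
    (seed, junk flag, render parameters), so frame identity — and hence the
    multiset-preservation property of clip splicing — can be checked on the
    seed sequence without rendering.  All fetal frames share one true GA
    (scan duration is negligible against gestation).
    """

    subject_id: str
    true_ga_days: float
    frame_rate: float
    frame_seeds: np.ndarray
    is_fetal: np.ndarray
    render_params: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frame_seeds)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def frame(self, i: int) -> np.ndarray:
        junk = not bool(self.is_fetal[i])
        spec = PhantomSpec(
            ga_days=None if junk else self.true_ga_days,
            junk=junk,
            seed=int(self.frame_seeds[i]),
            **self.render_params,
        )
        return generate_phantom_image(spec).pixels

    def frames(self):
        """Iterate over (timestamp_s, pixels) pairs at the native rate."""
        for i in range(self.n_frames):
            yield i / self.frame_rate, self.frame(i)

    def checksum(self) -> str:
        """Order-insensitive digest of the frame multiset (by identity)."""
        ids = sorted(zip(self.frame_seeds.tolist(), self.is_fetal.tolist()))
        return hashlib.sha256(repr(ids).encode()).hexdigest()


def generate_scan(
    subject_id: str,
    ga_days: float,
    duration_s: float = 200.0,
    frame_rate: float = SCAN_FRAME_RATE,
    junk_block_fraction: float = 0.2,
    seed: int = 0,
    **render_params,
) -> SyntheticScan:
    """Synthesize a full-length scan.

    Junk content arrives in contiguous 5-second blocks (probe repositioning,
    non-2D modes), each block independently junk with the given probability.
    """
    if duration_s <= 0 or frame_rate <= 0:
        raise ValueError("duration and frame rate must be positive")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * frame_rate))
    frames_per_block = max(1, int(round(SUBSEGMENT_SECONDS * frame_rate)))
    n_blocks = int(np.ceil(n_frames / frames_per_block))
    block_junk = rng.random(n_blocks) < junk_block_fraction
    is_fetal = ~np.repeat(block_junk, frames_per_block)[:n_frames]
    frame_seeds = rng.integers(0, 2**31 - 1, size=n_frames)
    return SyntheticScan(
        subject_id=subject_id,
        true_ga_days=float(ga_days),
        frame_rate=float(frame_rate),
        frame_seeds=frame_seeds,
        is_fetal=is_fetal,
        render_params=dict(render_params),
    )


def splice_shuffled_clip(scan: SyntheticScan, seed: int) -> SyntheticScan:
    """Build the 3-minute shuffled test clip from a full-length scan.

    Selects 36 non-overlapping 5-s subsegments (on a 5-s grid, sampled
    without replacement), shuffles their order, and concatenates them into a
    clip of exactly 180 s.  A different seed re-selects and re-shuffles,
    which is the re-shuffle consistency protocol: same scan, possibly
    different frames, different order.
    """
    if scan.duration_s < CLIP_SECONDS:
        raise ValueError(
            f"source scan must be at least {CLIP_SECONDS:.0f} s "
            f"(got {scan.duration_s:.1f} s)"
        )
    rng = np.random.default_rng(seed)
    frames_per_seg = int(round(SUBSEGMENT_SECONDS * scan.frame_rate))
    n_slots = scan.n_frames // frames_per_seg
    slots = rng.choice(n_slots, size=N_SUBSEGMENTS, replace=False)
    rng.shuffle(slots)
    idx = np.concatenate(
        [np.arange(s * frames_per_seg, (s + 1) * frames_per_seg) for s in slots]
    )
    return SyntheticScan(
        subject_id=scan.subject_id,
        true_ga_days=scan.true_ga_days,
        frame_rate=scan.frame_rate,
        frame_seeds=scan.frame_seeds[idx],
        is_fetal=scan.is_fetal[idx],
        render_params=dict(scan.render_params),
    )


def write_scan_frames(scan: SyntheticScan, out_dir: str) -> None:
    """Write a scan as a directory of numbered PNG frames plus metadata."""
    import json
    from pathlib import Path

    import imageio.v3 as iio

    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    for i in range(scan.n_frames):
        iio.imwrite(
            root / f"frame{i:05d}.png",
            (scan.frame(i) * 255).round().astype(np.uint8),
        )
    meta = {
        "subject_id": scan.subject_id,
        "frame_rate": scan.frame_rate,
        "n_frames": scan.n_frames,
        "true_ga_days": scan.true_ga_days,
    }
    (root / "scan.json").write_text(json.dumps(meta, indent=2))
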