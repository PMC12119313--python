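"""Synthetic B-mode-like plaque video generator.

Emulates the statistical structure of carotid-plaque ultrasound clips at
desk scale: grayscale speckle texture, a small plaque-like blob that is
brighter than background (hyperechoic-like, class 0), darker
(hypoechoic-like, class 1) or half-bright/half-dark (mixed-echoic-like,
class 2), slow per-frame drift of the blob, and optional probe-jump
discontinuities in which the blob is abruptly displaced and then drifts
back — so that distant frames can be more similar than adjacent ones.

Speckle is modelled as multiplicative Rayleigh-like noise clipped to
[0, 1]; this is a first-order texture model, not a physical simulator
(no beamforming, no attenuation).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SynthParams",
    "VideoClip",
    "CLASS_NAMES",
    "generate_clip",
    "inject_probe_jump",
    "generate_dataset",
    "write_dataset",
    "load_dataset",
    "load_manifest",
]

CLASS_NAMES = ("hyperechoic", "hypoechoic", "mixed-echoic")

_BACKGROUND = 0.40
_BRIGHT = 0.78
_DARK = 0.10
_EDGE_SOFTNESS = 1.5  # px, sigmoid edge width of the blob profile


@dataclass(frozen=True)
class SynthParams:
    """Generator settings.

    drift_step bounds the per-frame Euclidean displacement of the blob
    centre; jump_rate is the per-clip probability of one probe-jump
    event.  The default clip length (24 frames) is a desk-scale stand-in
    for full-length 120-frame studies, which remain available via
    ``n_frames=120``.
    """

    n_frames: int = 24
    height: int = 64
    width: int = 64
    n_classes: int = 3  # fixed semantics: bright / dark / mixed blob
    speckle_sigma: float = 0.30
    blob_radius_range: tuple[float, float] = (6.0, 12.0)
    drift_step: float = 1.0
    jump_rate: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.height < 16 or self.width < 16:
            raise ValueError("height and width must be >= 16")
        if self.n_classes != 3:
            raise ValueError("the generator defines exactly 3 echogenicity classes")
        if self.speckle_sigma < 0:
            raise ValueError("speckle_sigma must be >= 0")
        if not (0.0 <= self.jump_rate <= 1.0):
            raise ValueError("jump_rate must lie in [0, 1]")
        if self.drift_step < 0:
            raise ValueError("drift_step must be >= 0")
        lo, hi = self.blob_radius_range
        if not (0 < lo <= hi):
            raise ValueError("blob_radius_range must be a positive interval")


@dataclass
class VideoClip:
    """One clip: pixels (channel, time, height, width) in [0, 1]."""

    pixels: np.ndarray
    label: int
    clip_id: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 4:
            raise ValueError("pixels must be rank-4 (channel, time, height, width)")
        if self.pixels.shape[1] < 2:
            raise ValueError("a clip needs at least 2 frames")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("pixel values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[1]

    def to_rgb(self) -> "VideoClip":
        """Replicate a grayscale channel to 3 for RGB-pretrained backbones."""
        if self.pixels.shape[0] == 3:
            return self
        return dataclasses.replace(self, pixels=np.repeat(self.pixels, 3, axis=0))


# ---------------------------------------------------------------------------
# rendering internals
# ---------------------------------------------------------------------------


def _speckle(shape, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative Rayleigh-like field with unit mean, strength sigma."""
    if sigma == 0:
        return np.ones(shape)
    ray = rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=shape)  # mean 1
    return 1.0 + sigma * (ray - 1.0)


def _render_frame(
    center: np.ndarray,
    radius: float,
    label: int,
    params: SynthParams,
    noise_rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (frame, blob_mask) for one time step."""
    yy, xx = np.mgrid[0 : params.height, 0 : params.width]
    dist = np.hypot(yy - center[0], xx - center[1])
    w = 1.0 / (1.0 + np.exp((dist - radius) / _EDGE_SOFTNESS))
    if label == 0:
        blob_val = np.full(w.shape, _BRIGHT)
    elif label == 1:
        blob_val = np.full(w.shape, _DARK)
    else:  # mixed: bright on the left half of the blob, dark on the right
        blob_val = np.where(xx < center[1], _BRIGHT, _DARK)
    frame = _BACKGROUND * (1.0 - w) + blob_val * w
    frame = frame * _speckle(frame.shape, params.speckle_sigma, noise_rng)
    return np.clip(frame, 0.0, 1.0), dist <= radius


def _blob_path(params: SynthParams, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Random-walk centres (T, 2); each step has Euclidean length <= drift_step."""
    margin = radius + 2.0
    lo = np.array([margin, margin])
    hi = np.array([params.height - margin, params.width - margin])
    if np.any(hi <= lo):  # blob almost fills the frame; pin to the centre
        lo = hi = np.array([params.height / 2.0, params.width / 2.0])
    centers = np.empty((params.n_frames, 2))
    centers[0] = rng.uniform(lo, hi)
    for t in range(1, params.n_frames):
        angle = rng.uniform(0, 2 * np.pi)
        step = rng.uniform(0, params.drift_step)
        centers[t] = np.clip(centers[t - 1] + step * np.array([np.sin(angle), np.cos(angle)]), lo, hi)
    return centers


def _jump_offsets(n_frames: int, jump_time: int, d_vec: np.ndarray) -> np.ndarray:
    """Offsets (T, 2): zero before the jump, full displacement at the jump,
    then linear return to zero by the last frame."""
    offsets = np.zeros((n_frames, 2))
    span = max(n_frames - 1 - jump_time, 1)
    for t in range(jump_time, n_frames):
        offsets[t] = d_vec * max(1.0 - (t - jump_time) / span, 0.0)
    return offsets


def _render_clip(
    centers: np.ndarray,
    radius: float,
    label: int,
    params: SynthParams,
    noise_seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    frames, masks = [], []
    for t in range(params.n_frames):
        rng = np.random.default_rng([noise_seed, t])
        frame, mask = _render_frame(centers[t], radius, label, params, rng)
        frames.append(frame)
        masks.append(mask)
    return np.stack(frames)[None, ...], np.stack(masks)


def _noise_seed(seed: int, label: int) -> int:
    return int(np.random.SeedSequence([seed, label, 1]).generate_state(1)[0])


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def generate_clip(label: int, params: SynthParams, seed: int) -> VideoClip:
    """Render one labelled clip; deterministic for fixed (label, params, seed).

    With probability ``params.jump_rate`` the clip contains one probe-jump
    event: the blob is abruptly displaced mid-clip and drifts back, so a
    late frame resembles a pre-jump frame more than the two frames
    straddling the jump resemble each other.
    """
    if label not in (0, 1, 2):
        raise ValueError(f"label must be one of 0, 1, 2 (got {label!r})")
    geom_rng = np.random.default_rng(np.random.SeedSequence([seed, label, 0]))
    radius = geom_rng.uniform(*params.blob_radius_range)
    centers = _blob_path(params, radius, geom_rng)

    jump_time = None
    if geom_rng.uniform() < params.jump_rate and params.n_frames >= 6:
        jump_time = int(geom_rng.integers(params.n_frames // 3, 2 * params.n_frames // 3 + 1))
        magnitude = min(params.height, params.width) / 3.0
        direction = _toward_center(centers[jump_time], params)
        centers = centers + _jump_offsets(params.n_frames, jump_time, magnitude * direction)

    noise_seed = _noise_seed(seed, label)
    pixels, masks = _render_clip(centers, radius, label, params, noise_seed)
    return VideoClip(
        pixels=pixels,
        label=label,
        clip_id=f"synthetic-{label}-{seed}",
        meta={
            "params": params,
            "seed": seed,
            "noise_seed": noise_seed,
            "centers": centers,
            "radius": radius,
            "mask": masks,
            "jump_time": jump_time,
        },
    )


def _toward_center(point: np.ndarray, params: SynthParams) -> np.ndarray:
    target = np.array([params.height / 2.0, params.width / 2.0])
    v = target - point
    n = np.linalg.norm(v)
    return v / n if n > 1e-9 else np.array([0.0, 1.0])


def inject_probe_jump(
    clip: VideoClip, jump_time: int, displacement: float, seed: int
) -> VideoClip:
    """Re-render frames >= ``jump_time`` with the blob displaced by
    ``displacement`` pixels (fresh speckle drawn from ``seed``), drifting
    back to the original path by the last frame.

    With ``displacement=0`` and ``seed`` equal to the clip's own noise
    seed the output is identical to the input.
    """
    if clip.meta.get("centers") is None or "radius" not in clip.meta:
        raise ValueError("clip lacks rendering metadata; only generated clips can be re-rendered")
    params: SynthParams = clip.meta["params"]
    if not (0 < jump_time < params.n_frames):
        raise ValueError(
            f"jump_time must lie in (0, {params.n_frames}) exclusive (got {jump_time})"
        )
    centers = np.array(clip.meta["centers"])
    direction = _toward_center(centers[jump_time], params)
    new_centers = centers + _jump_offsets(params.n_frames, jump_time, displacement * direction)

    pixels = clip.pixels.copy()
    masks = clip.meta["mask"].copy()
    radius = clip.meta["radius"]
    for t in range(jump_time, params.n_frames):
        rng = np.random.default_rng([seed, t])
        frame, mask = _render_frame(new_centers[t], radius, clip.label, params, rng)
        pixels[0, t] = frame
        masks[t] = mask
    meta = dict(clip.meta)
    meta.update(centers=new_centers, mask=masks, jump_time=jump_time)
    return VideoClip(pixels=pixels, label=clip.label, clip_id=clip.clip_id, meta=meta)


def generate_dataset(
    n_per_class: tuple[int, int, int], params: SynthParams, seed: int
) -> tuple[list[VideoClip], pd.DataFrame]:
    """Generate ``sum(n_per_class)`` clips plus a manifest table.

    The manifest has columns (clip_id, path, label, n_frames); ``path``
    is filled in by :func:`write_dataset` and empty for in-memory use.
    """
    if any(n < 0 for n in n_per_class):
        raise ValueError("clip counts must be >= 0")
    clips: list[VideoClip] = []
    for label, count in enumerate(n_per_class):
        for j in range(count):
            clip = generate_clip(label, params, seed=seed * 100_003 + label * 1009 + j)
            clip.clip_id = f"clip_{label}_{j:03d}"
            clips.append(clip)
    manifest = pd.DataFrame(
        {
            "clip_id": [c.clip_id for c in clips],
            "path": ["" for _ in clips],
            "label": [c.label for c in clips],
            "n_frames": [c.n_frames for c in clips],
        }
    )
    return clips, manifest


def write_dataset(clips: list[VideoClip], out_dir: str | Path) -> Path:
    """Write each clip as a folder of 8-bit PNG frames plus manifest.csv."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for clip in clips:
        clip_dir = out_dir / clip.clip_id
        clip_dir.mkdir(exist_ok=True)
        gray = (np.clip(clip.pixels[0], 0, 1) * 255).round().astype(np.uint8)
        for t in range(clip.n_frames):
            iio.imwrite(clip_dir / f"frame_{t:04d}.png", gray[t])
        rows.append(
            {
                "clip_id": clip.clip_id,
                "path": clip.clip_id,
                "label": clip.label,
                "n_frames": clip.n_frames,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return out_dir / "manifest.csv"


def load_manifest(manifest_csv: str | Path) -> pd.DataFrame:
    df = pd.read_csv(manifest_csv)
    if "path" not in df or "label" not in df:
        raise ValueError("manifest must have at least (path, label) columns")
    if "clip_id" not in df:
        df["clip_id"] = [Path(p).stem for p in df["path"]]
    return df


def load_dataset(manifest_csv: str | Path) -> list[VideoClip]:
    """Read clips back from a frame-folder dataset written by write_dataset,
    or any manifest whose ``path`` column points at PNG/JPEG frame folders."""
    import imageio.v3 as iio

    manifest_csv = Path(manifest_csv)
    df = load_manifest(manifest_csv)
    root = manifest_csv.parent
    clips = []
    for row in df.itertuples():
        clip_dir = root / row.path
        frame_files = sorted(clip_dir.glob("frame_*.png")) or sorted(
            p for p in clip_dir.iterdir() if p.suffix.lower() in (".png", ".jpg", ".jpeg")
        )
        if not frame_files:
            raise FileNotFoundError(f"no frames found under {clip_dir}")
        frames = np.stack([np.asarray(iio.imread(f), dtype=np.float64) / 255.0 for f in frame_files])
        if frames.ndim == 4:  # RGB frames -> (C, T, H, W)
            pixels = frames.transpose(3, 0, 1, 2)
        else:
            pixels = frames[None, ...]
        clips.append(VideoClip(pixels=pixels, label=int(row.label), clip_id=str(row.clip_id)))
    return clips
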