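"""Training protocol: preprocessing and augmentation, SGD with linear
warmup and step decay, gradient clipping, and stratified k-fold
cross-validation.

The reference protocol trains with SGD (momentum 0.9, weight decay
1e-4), warms the learning rate linearly to ``base_lr`` over the first
``warmup_epochs`` epochs, then applies tenfold reductions at the decay
milestones.  Frames are resized to ``input_size`` squares; training
applies a clip-consistent random resized crop and a 50% horizontal
flip; pixels are standardised with Kinetics400 statistics by default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .adapter import DistillableModel, ToyVideoNet, attach_aux_heads, register_stages
from .metrics import MetricReport, classification_metrics, confusion_counts, roc_auc_ovr, summarize_folds
from .nn import SGD, Tensor, clip_grad_norm, softmax
from .objective import LossBreakdown, ObjectiveConfig, model_loss
from .relation import linear_resample_matrix
from .synthetic import VideoClip

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "KINETICS400_MEAN",
    "KINETICS400_STD",
    "lr_at",
    "preprocess",
    "train",
    "evaluate",
    "crossvalidate",
    "stratified_fold_indices",
    "stratified_split",
    "smoke_config",
    "default_model_factory",
]

# Published channel statistics of the Kinetics400 video dataset (RGB).
KINETICS400_MEAN = (0.43216, 0.394666, 0.37645)
KINETICS400_STD = (0.22803, 0.22145, 0.216989)


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol settings (defaults follow the reference recipe)."""

    epochs: int = 100
    batch_size: int = 8
    base_lr: float = 0.001
    warmup_epochs: int = 10
    milestones: tuple[int, ...] | None = None  # None -> 50% and 75% of epochs
    decay_factor: float = 0.1
    momentum: float = 0.9
    weight_decay: float = 0.0001
    clip_norm: float = 1.0
    frames_per_clip: int = 16
    input_size: int = 224
    mean: tuple[float, ...] = KINETICS400_MEAN
    std: tuple[float, ...] = KINETICS400_STD
    crop_area: tuple[float, float] = (0.5, 1.0)
    crop_aspect: tuple[float, float] = (0.75, 4.0 / 3.0)
    flip_prob: float = 0.5
    folds: int = 5
    split_ratio: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.warmup_epochs > self.epochs:
            raise ValueError("warmup_epochs must not exceed epochs")
        if not (0.0 < self.decay_factor < 1.0):
            raise ValueError("decay factor must lie in (0, 1)")
        if self.clip_norm <= 0:
            raise ValueError("clip_norm must be positive")
        if not (0.0 < self.split_ratio < 1.0):
            raise ValueError("split_ratio must lie in (0, 1)")
        if self.base_lr <= 0:
            raise ValueError("base_lr must be positive")

    def resolved_milestones(self) -> tuple[int, ...]:
        if self.milestones is not None:
            return tuple(self.milestones)
        return (self.epochs // 2, (3 * self.epochs) // 4)


def smoke_config(**overrides) -> TrainConfig:
    """Desk-scale profile: 15 epochs, 8 frames at 32 px, short warmup."""
    defaults = dict(
        epochs=15,
        batch_size=8,
        warmup_epochs=3,
        frames_per_clip=8,
        input_size=32,
    )
    defaults.update(overrides)
    if "warmup_epochs" not in overrides:
        defaults["warmup_epochs"] = min(defaults["warmup_epochs"], defaults["epochs"])
    return TrainConfig(**defaults)


@dataclass
class TrainHistory:
    """Per-epoch loss aggregates, learning rates, and validation metrics."""

    losses: list[dict] = field(default_factory=list)
    lrs: list[float] = field(default_factory=list)
    val_metrics: list[dict | None] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.losses)


def lr_at(epoch: int, config: TrainConfig) -> float:
    """Learning rate of the warmup + step-decay schedule at ``epoch``."""
    if not (0 <= epoch < config.epochs):
        raise ValueError(f"epoch must lie in [0, {config.epochs - 1}]")
    if epoch < config.warmup_epochs:
        return config.base_lr * (epoch + 1) / config.warmup_epochs
    passed = sum(1 for m in config.resolved_milestones() if epoch >= m)
    return config.base_lr * config.decay_factor**passed


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def _resize_frames(frames: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Separable bilinear resize of (..., H, W) arrays."""
    h, w = frames.shape[-2:]
    if (h, w) == (out_h, out_w):
        return frames
    A = linear_resample_matrix(h, out_h)
    B = linear_resample_matrix(w, out_w)
    out = np.tensordot(frames, A, axes=([-2], [1]))  # (..., W, out_h)
    out = np.tensordot(out, B, axes=([-2], [1]))  # (..., out_h, out_w)
    return out


def _sample_frame_indices(n_available: int, n_wanted: int) -> np.ndarray:
    """Uniform-stride temporal sampling; short clips are looped."""
    if n_available >= n_wanted:
        return np.round(np.linspace(0, n_available - 1, n_wanted)).astype(int)
    return np.arange(n_wanted) % n_available


def _random_resized_crop_box(
    h: int, w: int, area: tuple[float, float], aspect: tuple[float, float], rng
) -> tuple[int, int, int, int]:
    for _ in range(10):
        target_area = rng.uniform(*area) * h * w
        log_ratio = rng.uniform(np.log(aspect[0]), np.log(aspect[1]))
        ratio = np.exp(log_ratio)
        cw = int(round(np.sqrt(target_area * ratio)))
        ch = int(round(np.sqrt(target_area / ratio)))
        if 0 < cw <= w and 0 < ch <= h:
            top = int(rng.integers(0, h - ch + 1))
            left = int(rng.integers(0, w - cw + 1))
            return top, left, ch, cw
    side = min(h, w)
    return (h - side) // 2, (w - side) // 2, side, side


def preprocess(
    clip: VideoClip | np.ndarray,
    config: TrainConfig,
    train_mode: bool,
    seed: int = 0,
) -> np.ndarray:
    """Turn a clip into a model-ready (C, frames_per_clip, S, S) array.

    Train mode: clip-consistent random resized crop (area and aspect
    jittered) and horizontal flip; eval mode: deterministic center crop.
    Channel-wise standardisation always applies.
    """
    pixels = clip.pixels if isinstance(clip, VideoClip) else np.asarray(clip)
    if pixels.ndim != 4 or pixels.shape[1] < 1:
        raise ValueError("clip must be a nonempty (C, T, H, W) array")
    c, t, h, w = pixels.shape
    idx = _sample_frame_indices(t, config.frames_per_clip)
    x = pixels[:, idx]

    rng = np.random.default_rng(seed)
    if train_mode:
        top, left, ch, cw = _random_resized_crop_box(h, w, config.crop_area, config.crop_aspect, rng)
        x = x[:, :, top : top + ch, left : left + cw]
        if rng.uniform() < config.flip_prob:
            x = x[..., ::-1]
    else:
        side = min(h, w)
        top, left = (h - side) // 2, (w - side) // 2
        x = x[:, :, top : top + side, left : left + side]
    x = _resize_frames(x, config.input_size, config.input_size)

    mean = np.asarray(config.mean, dtype=float)
    std = np.asarray(config.std, dtype=float)
    if c == 1 and mean.size != 1:  # grayscale: collapse RGB statistics
        mean = np.array([mean.mean()])
        std = np.array([std.mean()])
    if mean.size != c or std.size != c:
        raise ValueError(f"normalisation statistics have {mean.size} channels, clip has {c}")
    return (x - mean.reshape(c, 1, 1, 1)) / std.reshape(c, 1, 1, 1)


# ---------------------------------------------------------------------------
# training and evaluation
# ---------------------------------------------------------------------------


def _check_breakdown_finite(b: LossBreakdown) -> None:
    for name, value in b.as_dict().items():
        if not np.isfinite(value):
            raise RuntimeError(f"training diverged: loss component {name!r} is non-finite")


def train(
    dataset: Sequence[VideoClip],
    model: DistillableModel,
    config: TrainConfig,
    objective: ObjectiveConfig | None = None,
    eval_data: Sequence[VideoClip] | None = None,
) -> tuple[dict, TrainHistory]:
    """Run the training loop; returns final weights and the history.

    Deterministic for a fixed config seed on a single device: shuffling,
    augmentation draws and initial weights all derive from it.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    objective = objective or ObjectiveConfig()
    params = model.parameters()
    opt = SGD(params, lr=config.base_lr, momentum=config.momentum, weight_decay=config.weight_decay)
    history = TrainHistory()
    n = len(dataset)
    for epoch in range(config.epochs):
        opt.lr = lr_at(epoch, config)
        order = np.random.default_rng([config.seed, epoch]).permutation(n)
        sums: dict[str, float] = {}
        n_batches = 0
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            arrays = [
                preprocess(
                    dataset[i],
                    config,
                    train_mode=True,
                    seed=(config.seed * 1_000_003 + epoch * 10_007 + int(i)) % (2**31),
                )
                for i in sel
            ]
            batch = Tensor(np.stack(arrays).astype(np.float32))
            labels = np.array([dataset[i].label for i in sel])
            breakdown = model_loss(model, batch, labels, objective)
            _check_breakdown_finite(breakdown)
            opt.zero_grad()
            breakdown.total_tensor.backward()
            clip_grad_norm(params, config.clip_norm)
            opt.step()
            for k, v in breakdown.as_dict().items():
                sums[k] = sums.get(k, 0.0) + v
            n_batches += 1
        history.losses.append({k: v / n_batches for k, v in sums.items()})
        history.lrs.append(opt.lr)
        if eval_data is not None:
            report, _, _ = evaluate(model, eval_data, config)
            history.val_metrics.append(report.as_dict())
        else:
            history.val_metrics.append(None)
    return model.state_dict(), history


def evaluate(
    model,
    dataset: Sequence[VideoClip],
    config: TrainConfig,
    batch_size: int | None = None,
) -> tuple[MetricReport, np.ndarray, np.ndarray]:
    """Deterministic evaluation; returns (report, class scores, predictions).

    ``model`` may be a DistillableModel, StagedModel or plain backbone —
    only the teacher/backbone output is used.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    batch_size = batch_size or config.batch_size
    all_scores = []
    for start in range(0, len(dataset), batch_size):
        chunk = dataset[start : start + batch_size]
        batch = Tensor(
            np.stack([preprocess(c, config, train_mode=False) for c in chunk]).astype(np.float32)
        )
        logits = model(batch)
        all_scores.append(softmax(logits, axis=1).data)
    scores = np.concatenate(all_scores)
    preds = scores.argmax(axis=1)
    actual = np.array([c.label for c in dataset])
    n_classes = scores.shape[1]
    report = classification_metrics(confusion_counts(preds, actual, n_classes))
    report.auc_per_class = roc_auc_ovr(scores, actual)
    return report, scores, preds


# ---------------------------------------------------------------------------
# data splitting and cross-validation
# ---------------------------------------------------------------------------


def stratified_fold_indices(labels, k: int, seed: int = 0) -> list[np.ndarray]:
    """Stratified k-fold test indices; every item lands in exactly one fold."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(labels)
    if counts[counts > 0].min() < k:
        raise ValueError(
            f"smallest class has {counts[counts > 0].min()} members, fewer than "
            f"k={k}; use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def stratified_split(labels, train_fraction: float, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Per-class split into train/test index arrays at ``train_fraction``."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        members = rng.permutation(members)
        cut = int(round(train_fraction * len(members)))
        if len(members) >= 2:  # keep at least one test member per class
            cut = min(cut, len(members) - 1)
        train_idx.extend(members[:cut])
        test_idx.extend(members[cut:])
    return np.sort(np.array(train_idx, dtype=int)), np.sort(np.array(test_idx, dtype=int))


def default_model_factory(num_classes: int = 3, in_channels: int = 1, widths=(4, 8, 16, 32)):
    """Factory of toy distillable models for tests and cross-validation."""

    def make(seed: int) -> DistillableModel:
        backbone = ToyVideoNet(in_channels=in_channels, num_classes=num_classes, widths=widths, seed=seed)
        staged = register_stages(backbone, backbone.stage_ids, num_classes)
        return attach_aux_heads(staged, student_stages=(1, 2, 3), seed=seed)

    return make


def crossvalidate(
    dataset: Sequence[VideoClip],
    config: TrainConfig,
    objective: ObjectiveConfig | None = None,
    model_factory: Callable[[int], DistillableModel] | None = None,
) -> tuple[list[MetricReport], dict]:
    """Stratified k-fold cross-validation: train on k-1 folds, test on the
    held-out fold; aggregate mean ± sample std per metric."""
    labels = [c.label for c in dataset]
    folds = stratified_fold_indices(labels, config.folds, seed=config.seed)
    model_factory = model_factory or default_model_factory(num_classes=int(max(labels)) + 1)
    reports: list[MetricReport] = []
    for fold_no, test_idx in enumerate(folds):
        test_set = set(test_idx.tolist())
        train_clips = [c for i, c in enumerate(dataset) if i not in test_set]
        test_clips = [dataset[i] for i in test_idx]
        model = model_factory(config.seed * 97 + fold_no)
        fold_config = dataclasses.replace(config, seed=config.seed * 131 + fold_no)
        train(train_clips, model, fold_config, objective)
        report, _, _ = evaluate(model, test_clips, config)
        reports.append(report)
    return reports, summarize_folds(reports)
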