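"""Post-hoc analysis: frame-to-frame relation coefficients and 3-D
Grad-CAM localisation volumes.

Relation coefficients are the cosine-mode frame-similarity matrix at a
chosen stage (values in [-1, 1], unit diagonal): the same computation
as the relation-distillation module, exposed for inspection of how a
trained model relates temporally distant frames.  Grad-CAM weights each
channel of a tapped layer by the global average of the target-class
score's gradient and rectifies the weighted sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .adapter import DistillableModel, StagedModel
from .nn import Tensor
from .relation import flatten_spatial, linear_resample_matrix, relation_matrix
from .trainer import TrainConfig, preprocess

__all__ = ["RelationReport", "CamVolume", "frame_relation_coefficients", "gradcam_3d"]


@dataclass
class RelationReport:
    """Cosine frame-relation matrix at one stage, plus requested pairs."""

    stage: int
    matrix: np.ndarray
    pairs: list[tuple[tuple[int, int], float]]


@dataclass
class CamVolume:
    """Non-negative class-activation volume at input resolution (max 1)."""

    volume: np.ndarray
    target_class: int
    all_zero: bool = False


def _staged_of(model) -> StagedModel:
    if isinstance(model, DistillableModel):
        return model.staged
    if isinstance(model, StagedModel):
        return model
    raise TypeError("expected a StagedModel or DistillableModel")


def _as_batch(clip, config: TrainConfig | None) -> np.ndarray:
    pixels = clip.pixels if hasattr(clip, "pixels") else np.asarray(clip)
    if config is not None:
        pixels = preprocess(pixels, config, train_mode=False)
    return pixels[None, ...]


def frame_relation_coefficients(
    model,
    clip,
    stage: int,
    pairs: list[tuple[int, int]] | None = None,
    config: TrainConfig | None = None,
) -> RelationReport:
    """Cosine-mode relation matrix of the features at ``stage`` (1-based)."""
    staged = _staged_of(model)
    if not (1 <= stage <= staged.n_stages):
        raise ValueError(f"stage must lie in 1..{staged.n_stages} (got {stage})")
    feats = staged.forward_features(Tensor(_as_batch(clip, config)))
    F = feats[stage - 1][0]  # drop batch axis
    R = relation_matrix(flatten_spatial(F), mode="cosine").values
    chosen = []
    for i, j in pairs or []:
        if not (0 <= i < R.shape[0] and 0 <= j < R.shape[0]):
            raise ValueError(f"frame pair ({i}, {j}) outside 0..{R.shape[0] - 1}")
        chosen.append(((i, j), float(R[i, j])))
    return RelationReport(stage=stage, matrix=R, pairs=chosen)


def _upsample_volume(vol: np.ndarray, target_shape: tuple[int, int, int]) -> np.ndarray:
    out = vol
    for axis, (n_in, n_out) in enumerate(zip(out.shape, target_shape)):
        if n_in != n_out:
            A = linear_resample_matrix(n_in, n_out)
            out = np.moveaxis(np.tensordot(A, np.moveaxis(out, axis, 0), axes=([1], [0])), 0, axis)
    return out


def gradcam_3d(
    model,
    clip,
    target_class: int,
    layer: int,
    config: TrainConfig | None = None,
) -> CamVolume:
    """Gradient-weighted class activation volume at ``layer`` (1-based),
    trilinearly upsampled to the clip's (time, height, width) and
    normalised to a maximum of 1 (all-zero volumes are flagged)."""
    staged = _staged_of(model)
    if not (1 <= layer <= staged.n_stages):
        raise ValueError(f"layer must lie in 1..{staged.n_stages} (got {layer})")
    batch = _as_batch(clip, config)
    # grad on the input guarantees every tapped feature carries a gradient,
    # even through parameter-free stages
    x = Tensor(batch, requires_grad=True)
    feats = staged.forward_features(x)
    logits = staged.backbone.classify(feats.teacher)
    if not (0 <= target_class < logits.shape[1]):
        raise ValueError(f"target_class must lie in 0..{logits.shape[1] - 1}")
    staged.zero_grad()
    score = logits[0, target_class]
    score.backward()
    feature = feats[layer - 1]
    if feature.grad is None or not np.any(feature.grad):
        warnings.warn("Grad-CAM: gradient is zero everywhere; returning an all-zero volume")
        t, h, w = batch.shape[2:]
        return CamVolume(volume=np.zeros((t, h, w)), target_class=target_class, all_zero=True)
    grad = feature.grad[0]  # (C, T', H', W')
    act = feature.data[0]
    channel_weights = grad.mean(axis=(1, 2, 3))
    cam = np.maximum(np.tensordot(channel_weights, act, axes=([0], [0])), 0.0)
    cam = _upsample_volume(cam, tuple(batch.shape[2:]))
    peak = cam.max()
    if peak <= 0:
        warnings.warn("Grad-CAM: rectified activation is zero everywhere")
        return CamVolume(volume=np.zeros_like(cam), target_class=target_class, all_zero=True)
    return CamVolume(volume=cam / peak, target_class=target_class)
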