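"""Attention Module (AM) and attention-guided self-distillation.

The AM compresses a stage feature to two 1-channel maps (mean and max
over channels), concatenates them, and convolves with a 7x7 spatial
kernel (applied per frame by default) to produce a spatial-temporal
attention map M (time, height, width).  The attention-guided
self-distillation (AGSD) loss pulls each student stage's map toward the
teacher's, after resampling all maps to the teacher's resolution.

Because the AM kernel's only gradient source is the AGSD loss, the
teacher map is *not* detached by default (unlike the relation loss);
per-map normalisation (on by default) prevents the trivial collapse of
scaling all maps toward zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv3d, Module, Tensor, as_tensor, concat, interp_axis
from .relation import linear_resample_matrix

__all__ = [
    "PooledPair",
    "AttentionMap",
    "AttentionModule",
    "channel_pool",
    "attention_map",
    "align_attention",
    "agsd_loss",
]


@dataclass
class PooledPair:
    """Channel-pooled maps, each (1, T, H, W) (batched: (N, 1, T, H, W))."""

    avg_map: Tensor
    max_map: Tensor


@dataclass
class AttentionMap:
    """Spatial-temporal attention map (T, H, W) (batched: (N, T, H, W))."""

    map: Tensor
    stage: int | None = None

    @property
    def values(self) -> np.ndarray:
        return self.map.data

    @property
    def shape(self):
        return self.map.shape


def channel_pool(F) -> PooledPair:
    """Mean and max over the channel axis; time/height/width preserved."""
    F = as_tensor(F)
    if F.ndim == 4:
        axis = 0
    elif F.ndim == 5:
        axis = 1
    else:
        raise ValueError("expected (C,T,H,W) or (N,C,T,H,W) features")
    if F.shape[axis] < 1:
        raise ValueError("channel extent must be >= 1")
    avg = F.mean(axis=axis, keepdims=True)
    mx = F.max(axis=axis, keepdims=True)
    return PooledPair(avg_map=avg, max_map=mx)


class AttentionModule(Module):
    """The 2-in/1-out convolution producing attention maps.

    By default a single kernel of spatial size 7x7 and temporal extent 1
    is shared across all stages (it is resolution-agnostic).  A
    spatio-temporal (3,7,7) kernel and a sigmoid squashing are optional.
    """

    def __init__(
        self,
        kernel: tuple[int, int, int] = (1, 7, 7),
        sigmoid: bool = False,
        rng: np.random.Generator | None = None,
    ):
        kt, kh, kw = kernel
        if kt % 2 == 0 or kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("kernel extents must be odd so output size matches input")
        self.conv = Conv3d(
            2, 1, kernel, stride=1, padding=(kt // 2, kh // 2, kw // 2), rng=rng
        )
        self.sigmoid = sigmoid

    def forward(self, F, stage: int | None = None) -> AttentionMap:
        return attention_map(F, self, stage=stage)


def attention_map(F, am: AttentionModule, stage: int | None = None) -> AttentionMap:
    """M = conv([avg-pool(F); max-pool(F)]); shape follows the input's
    (time, height, width) exactly."""
    F = as_tensor(F)
    batched = F.ndim == 5
    pair = channel_pool(F)
    cat_axis = 1 if batched else 0
    stacked = concat([pair.avg_map, pair.max_map], axis=cat_axis)
    if not batched:
        stacked = stacked.reshape(1, *stacked.shape)
    out = am.conv(stacked)  # (N, 1, T, H, W)
    if am.sigmoid:
        out = out.sigmoid()
    n, _, t, h, w = out.shape
    out = out.reshape(n, t, h, w)
    if not batched:
        out = out.reshape(t, h, w)
    return AttentionMap(map=out, stage=stage)


def align_attention(M: AttentionMap, teacher_shape: tuple[int, int, int]) -> AttentionMap:
    """Trilinear (separable half-pixel linear) resampling of an attention map
    to the teacher's (time, height, width); identity when shapes match."""
    x = M.map
    batched = x.ndim == 4
    current = x.shape[1:] if batched else x.shape
    if tuple(current) == tuple(teacher_shape):
        return M
    offset = 1 if batched else 0
    for axis, (n_in, n_out) in enumerate(zip(current, teacher_shape)):
        if n_in != n_out:
            x = interp_axis(x, linear_resample_matrix(n_in, n_out), axis=axis + offset)
    return AttentionMap(map=x, stage=M.stage)


def _map_of(x) -> Tensor:
    return x.map if isinstance(x, AttentionMap) else as_tensor(x)


def _normalized(m: Tensor) -> Tensor:
    if m.ndim == 4:  # batched: per-sample norm
        sq = (m * m).sum(axis=(1, 2, 3), keepdims=True)
    else:
        sq = (m * m).sum(keepdims=True).reshape(1, 1, 1)
    norm = sq.sqrt(eps=1e-12) + Tensor((sq.data <= 1e-24).astype(m.dtype))
    return m / norm


def agsd_loss(
    student_Ms,
    M_K,
    normalize: bool = True,
    detach_teacher: bool = False,
) -> Tensor:
    """Sum over student stages of the Euclidean distance between (optionally
    per-map-normalised) student and teacher attention maps."""
    teacher = _map_of(M_K)
    if detach_teacher:
        teacher = teacher.detach()
    if normalize:
        teacher = _normalized(teacher)
    total: Tensor | None = None
    for idx, M_i in enumerate(student_Ms):
        S = _map_of(M_i)
        if S.shape != teacher.shape:
            raise ValueError(
                f"student stage {idx}: attention map shape {S.shape} does not "
                f"match teacher shape {teacher.shape}; align first"
            )
        if normalize:
            S = _normalized(S)
        diff = S - teacher
        if diff.ndim == 4:
            per = (diff * diff).sum(axis=(1, 2, 3)).sqrt(eps=1e-12)
            term = per.mean()
        else:
            term = diff.frobenius_norm()
        total = term if total is None else total + term
    return total if total is not None else Tensor(0.0)
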