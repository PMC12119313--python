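"""Temporal Relationship Module (TRM) and relationship-guided distillation.

A stage feature F (channel, time, height, width) is flattened across its
spatial dimensions into G (time, width*height*channel); the frame-frame
relation matrix is the normalised Gram matrix of G.  Two normalisations
are exposed:

* ``frobenius`` — R = G.G^t / ||G||_F^2 (the literal definition; its
  entries are not confined to [-1, 1] and its trace is 1),
* ``cosine`` — row-pairwise cosine similarities (unit diagonal, entries
  in [-1, 1], the convention used for frame-relation coefficients).

The relationship-guided self-distillation (RGSD) loss pulls each student
stage's relation matrix toward the teacher's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nn import Tensor, as_tensor, interp_axis

__all__ = [
    "RelationMatrix",
    "flatten_spatial",
    "unflatten_spatial",
    "relation_matrix",
    "align_relation",
    "rgsd_loss",
    "linear_resample_matrix",
]

_ZERO_TOL = 1e-24


@dataclass
class RelationMatrix:
    """T x T symmetric frame-similarity matrix plus its normalisation mode."""

    matrix: Tensor
    mode: str

    @property
    def values(self) -> np.ndarray:
        return self.matrix.data

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[-1]


def flatten_spatial(F) -> Tensor:
    """(C, T, H, W) -> (T, H*W*C), or batched (N, C, T, H, W) -> (N, T, H*W*C).

    Within a row the channel index varies fastest, then width, then height.
    """
    F = as_tensor(F)
    if F.ndim == 4:
        c, t, h, w = F.shape
        return F.transpose(1, 2, 3, 0).reshape(t, h * w * c)
    if F.ndim == 5:
        n, c, t, h, w = F.shape
        return F.transpose(0, 2, 3, 4, 1).reshape(n, t, h * w * c)
    raise ValueError("expected a rank-4 (C,T,H,W) or rank-5 (N,C,T,H,W) feature array")


def unflatten_spatial(G, shape: tuple[int, int, int, int]) -> Tensor:
    """Inverse of :func:`flatten_spatial` for rank-4 shapes."""
    c, t, h, w = shape
    G = as_tensor(G)
    return G.reshape(t, h, w, c).transpose(3, 0, 1, 2)


def relation_matrix(G, mode: str = "frobenius") -> RelationMatrix:
    """Frame-frame relation matrix of ``G`` (T, D) or batched (N, T, D)."""
    G = as_tensor(G)
    if G.ndim not in (2, 3):
        raise ValueError("G must be (T, D) or (N, T, D)")
    if G.size == 0:
        raise ValueError("G must be nonempty")
    Gt = G.transpose(1, 0) if G.ndim == 2 else G.transpose(0, 2, 1)

    if mode == "frobenius":
        axes = tuple(range(G.ndim - 2, G.ndim))
        sq = (G * G).sum(axis=axes, keepdims=True)
        if np.any(sq.data <= _ZERO_TOL):
            raise ValueError("all-zero G: Frobenius normalisation undefined")
        # note ||G|| = ||G^t||, so the denominator is ||G||_F^2
        denom = sq.reshape(*sq.shape[:-2], 1, 1) if sq.ndim > 2 else sq
        R = (G @ Gt) / denom
        return RelationMatrix(R, "frobenius")

    if mode == "cosine":
        sq = (G * G).sum(axis=-1, keepdims=True)
        zero_rows = sq.data <= _ZERO_TOL
        if np.any(zero_rows):
            warnings.warn(
                "cosine relation matrix: zero-feature frames present; their "
                "rows and columns (including the diagonal) are set to 0",
                stacklevel=2,
            )
        denom = sq.sqrt(eps=1e-12) + Tensor(zero_rows.astype(G.dtype))
        Gn = G / denom
        Gnt = Gn.transpose(1, 0) if G.ndim == 2 else Gn.transpose(0, 2, 1)
        R = Gn @ Gnt
        if np.any(zero_rows):
            keep = Tensor((~zero_rows).astype(G.dtype))
            keep_t = keep.transpose(1, 0) if G.ndim == 2 else keep.transpose(0, 2, 1)
            R = R * keep * keep_t
        return RelationMatrix(R, "cosine")

    raise ValueError(f"unknown mode {mode!r}; use 'frobenius' or 'cosine'")


def linear_resample_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1-D linear (half-pixel-centre) resampling matrix of shape (n_out, n_in)."""
    if n_in < 1 or n_out < 1:
        raise ValueError("sizes must be >= 1")
    W = np.zeros((n_out, n_in))
    if n_in == 1:
        W[:, 0] = 1.0
        return W
    for i in range(n_out):
        src = (i + 0.5) * n_in / n_out - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        frac = src - lo
        W[i, lo] += 1.0 - frac
        W[i, hi] += frac
    return W


def align_relation(R: RelationMatrix, teacher_T: int) -> RelationMatrix:
    """Bilinearly resample a relation matrix to the teacher's temporal extent
    and re-symmetrise.  Identity when extents already match."""
    if teacher_T < 1:
        raise ValueError("teacher temporal extent must be >= 1")
    M = R.matrix
    if M.shape[-1] != M.shape[-2]:
        raise ValueError("relation matrix must be square")
    t_i = M.shape[-1]
    if t_i == teacher_T:
        return R
    A = linear_resample_matrix(t_i, teacher_T)
    row_axis = M.ndim - 2
    col_axis = M.ndim - 1
    out = interp_axis(interp_axis(M, A, axis=row_axis), A, axis=col_axis)
    out_t = out.transpose(1, 0) if out.ndim == 2 else out.transpose(0, 2, 1)
    return RelationMatrix((out + out_t) * 0.5, R.mode)


def _matrix_of(x) -> Tensor:
    return x.matrix if isinstance(x, RelationMatrix) else as_tensor(x)


def rgsd_loss(
    student_Rs,
    R_K,
    reduction: str = "frobenius",
    detach_teacher: bool = True,
) -> Tensor:
    """Sum over student stages of the distance between each student's
    relation matrix and the teacher's.

    ``reduction``: 'frobenius' (root of summed squared differences, the
    default), 'squared', or 'mean' (mean squared difference).  Matrices
    with a leading batch axis are averaged over the batch.
    """
    teacher = _matrix_of(R_K)
    if detach_teacher:
        teacher = teacher.detach()
    total: Tensor | None = None
    for idx, R_i in enumerate(student_Rs):
        S = _matrix_of(R_i)
        if S.shape != teacher.shape:
            raise ValueError(
                f"student stage {idx}: relation matrix shape {S.shape} does not "
                f"match teacher shape {teacher.shape}; align first"
            )
        diff = S - teacher
        if diff.ndim == 3:  # batched: per-sample distance, then batch mean
            per = (diff * diff).sum(axis=(1, 2))
            if reduction == "frobenius":
                per = per.sqrt(eps=1e-12)
            elif reduction == "mean":
                per = per * (1.0 / (diff.shape[1] * diff.shape[2]))
            elif reduction != "squared":
                raise ValueError(f"unknown reduction {reduction!r}")
            term = per.mean()
        else:
            if reduction == "frobenius":
                term = diff.frobenius_norm()
            elif reduction == "squared":
                term = (diff * diff).sum()
            elif reduction == "mean":
                term = (diff * diff).mean()
            else:
                raise ValueError(f"unknown reduction {reduction!r}")
        total = term if total is None else total + term
    if total is None:
        return Tensor(0.0)
    return total
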