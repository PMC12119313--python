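"""Staged-backbone adapter: tap intermediate features, attach auxiliary
classifier heads for self-distillation, and strip them for inference.

A *backbone* is any :class:`~dualdistill.nn.Module` that

* exposes its convolutional stages as attributes (e.g. ``stage1`` ...
  ``stage4``), executed in order, each mapping (N, C, T, H, W) to
  (N, C', T', H', W'); and
* implements ``classify(feature) -> logits`` applying its own
  classification head to the last stage's features.

The adapter never copies or re-creates backbone parameters, so a model
trained with auxiliary heads strips back to *exactly* the original
parameter set — distillation adds no inference-time cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attention import AttentionModule
from .nn import Conv3d, Linear, Module, ReLU, Sequential, Tensor, as_tensor

__all__ = [
    "ToyVideoNet",
    "StagedModel",
    "DistillableModel",
    "StageFeatureSet",
    "register_stages",
    "attach_aux_heads",
    "strip_auxiliaries",
]


def _gap(x: Tensor) -> Tensor:
    """Global average pool (N, C, T, H, W) -> (N, C)."""
    return x.mean(axis=(2, 3, 4))


class ToyVideoNet(Module):
    """Reference 4-stage 3D CNN for desk-scale experiments and tests.

    Stage 1 keeps resolution; stages 2-4 halve time, height and width
    (stride 2).  The head is global average pooling plus one affine map.
    """

    def __init__(
        self,
        in_channels: int = 1,
        num_classes: int = 3,
        widths: tuple[int, ...] = (4, 8, 16, 32),
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        if len(widths) != 4:
            raise ValueError("ToyVideoNet has exactly 4 stages")
        chans = (in_channels,) + tuple(widths)
        for i in range(4):
            stride = 1 if i == 0 else 2
            setattr(
                self,
                f"stage{i + 1}",
                Sequential(
                    Conv3d(chans[i], chans[i + 1], 3, stride=stride, padding=1, rng=rng),
                    ReLU(),
                ),
            )
        self.head = Linear(widths[-1], num_classes, rng=rng)
        self.num_classes = num_classes
        self.stage_ids = tuple(f"stage{i + 1}" for i in range(4))

    def classify(self, feature: Tensor) -> Tensor:
        return self.head(_gap(feature))

    def forward(self, x) -> Tensor:
        h = as_tensor(x)
        for sid in self.stage_ids:
            h = getattr(self, sid)(h)
        return self.classify(h)


@dataclass
class StageFeatureSet:
    """Per-stage feature tensors in execution order, teacher last."""

    features: list[Tensor]

    def __len__(self) -> int:
        return len(self.features)

    def __getitem__(self, i) -> Tensor:
        return self.features[i]

    @property
    def teacher(self) -> Tensor:
        return self.features[-1]


def _stage_module_candidates(backbone: Module) -> list[str]:
    return [name for name, v in vars(backbone).items() if isinstance(v, Module)]


class StagedModel(Module):
    """A backbone with its stages registered for feature tapping."""

    def __init__(self, backbone: Module, stage_ids: tuple[str, ...], num_classes: int):
        self.backbone = backbone
        self.stage_ids = tuple(stage_ids)
        self.num_classes = num_classes

    @property
    def n_stages(self) -> int:
        return len(self.stage_ids)

    def forward_features(self, x) -> StageFeatureSet:
        """One forward pass surfacing every stage's features (no recompute)."""
        h = as_tensor(x)
        feats = []
        for sid in self.stage_ids:
            try:
                h = getattr(self.backbone, sid)(h)
            except ValueError as exc:
                raise ValueError(f"stage {sid!r}: {exc}") from exc
            feats.append(h)
        return StageFeatureSet(feats)

    def forward(self, x) -> Tensor:
        return self.backbone.classify(self.forward_features(x).teacher)


def register_stages(backbone: Module, stage_ids, num_classes: int) -> StagedModel:
    """Register the ordered stage attributes of ``backbone`` (shallow to
    deep; the last one is the teacher stage)."""
    stage_ids = tuple(stage_ids)
    if len(stage_ids) < 2:
        raise ValueError("at least 2 stages are required (K >= 2)")
    if len(set(stage_ids)) != len(stage_ids):
        raise ValueError(f"duplicate stage identifiers in {stage_ids}")
    for sid in stage_ids:
        if not isinstance(getattr(backbone, sid, None), Module):
            raise ValueError(
                f"unknown stage {sid!r}; discoverable candidates: "
                f"{_stage_module_candidates(backbone)}"
            )
    if not callable(getattr(backbone, "classify", None)):
        raise ValueError("backbone must implement classify(feature) -> logits")
    return StagedModel(backbone, stage_ids, num_classes)


class GapLinearHead(Module):
    """Auxiliary classifier: global average pool + one affine map."""

    def __init__(self, in_channels: int, num_classes: int, rng=None):
        self.fc = Linear(in_channels, num_classes, rng=rng)

    def forward(self, feature: Tensor) -> Tensor:
        return self.fc(_gap(feature))


class BottleneckConvHead(Module):
    """Optional richer head: 1x1x1 bottleneck conv + ReLU, then pool + affine."""

    def __init__(self, in_channels: int, num_classes: int, rng=None):
        mid = max(in_channels // 2, 1)
        self.conv = Conv3d(in_channels, mid, 1, rng=rng)
        self.fc = Linear(mid, num_classes, rng=rng)

    def forward(self, feature: Tensor) -> Tensor:
        return self.fc(_gap(self.conv(feature).relu()))


def _infer_out_channels(stage: Module) -> int | None:
    if hasattr(stage, "out_channels"):
        return int(stage.out_channels)
    if isinstance(stage, Sequential):
        for layer in reversed(stage.layers):
            c = _infer_out_channels(layer)
            if c is not None:
                return c
    return None


class DistillableModel(Module):
    """StagedModel + auxiliary heads on the student stages + the shared
    attention module.  Training-only additions live here, never on the
    backbone itself."""

    def __init__(
        self,
        staged: StagedModel,
        aux_heads: dict[int, Module],
        student_stages: tuple[int, ...],
        am: AttentionModule,
    ):
        self.staged = staged
        self.aux_heads = dict(aux_heads)
        self.student_stages = tuple(student_stages)
        self.am = am

    @property
    def num_classes(self) -> int:
        return self.staged.num_classes

    @property
    def n_stages(self) -> int:
        return self.staged.n_stages

    def forward_with_taps(self, x) -> tuple[StageFeatureSet, list[Tensor]]:
        """Features for every registered stage plus logits for every
        attached head, teacher last.  The teacher logits are identical to
        a plain forward of the unwrapped backbone."""
        feats = self.staged.forward_features(x)
        logits = [self.aux_heads[s](feats[s - 1]) for s in self.student_stages]
        logits.append(self.staged.backbone.classify(feats.teacher))
        return feats, logits

    def forward(self, x) -> Tensor:
        return self.staged(x)


def attach_aux_heads(
    model: StagedModel,
    student_stages,
    head: str = "gap_linear",
    stage_channels: dict[int, int] | None = None,
    kernel: tuple[int, int, int] = (1, 7, 7),
    sigmoid: bool = False,
    seed: int = 0,
) -> DistillableModel:
    """Attach an auxiliary classifier to each selected student stage
    (1-based indices, strictly below the teacher stage K)."""
    student_stages = tuple(sorted(set(int(s) for s in student_stages)))
    if not student_stages:
        raise ValueError("student_stages must be nonempty: base self-distillation needs >= 1 student")
    K = model.n_stages
    bad = [s for s in student_stages if not (1 <= s <= K - 1)]
    if bad:
        raise ValueError(f"student stages {bad} outside the valid range 1..{K - 1} (stage {K} is the teacher)")
    rng = np.random.default_rng(seed)
    head_cls = {"gap_linear": GapLinearHead, "bottleneck_conv": BottleneckConvHead}.get(head)
    if head_cls is None:
        raise ValueError(f"unknown head type {head!r}")
    heads: dict[int, Module] = {}
    for s in student_stages:
        c = None
        if stage_channels and s in stage_channels:
            c = stage_channels[s]
        else:
            c = _infer_out_channels(getattr(model.backbone, model.stage_ids[s - 1]))
        if c is None:
            raise ValueError(
                f"cannot infer channel width of stage {model.stage_ids[s - 1]!r}; "
                "pass stage_channels={stage_index: channels}"
            )
        heads[s] = head_cls(c, model.num_classes, rng=rng)
    am = AttentionModule(kernel=kernel, sigmoid=sigmoid, rng=rng)
    return DistillableModel(model, heads, student_stages, am)


def strip_auxiliaries(model: DistillableModel | StagedModel | Module) -> Module:
    """Return the plain inference backbone: exactly the original parameter
    set, outputs bitwise equal to the distillable model's teacher branch."""
    if isinstance(model, DistillableModel):
        return model.staged.backbone
    if isinstance(model, StagedModel):
        return model.backbone
    return model
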