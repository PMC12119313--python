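"""The self-distillation objective and the combined dual-guided loss.

The base self-distillation (SD) loss sums cross-entropy over every
classifier head (auxiliary students plus the deepest, teacher, head) and
adds a temperature-softened KL term pulling each student's class
distribution toward the teacher's:

    L_SD = sum_i CE(c_i, y) + alpha * sum_{i<K} KL(p_K || p_i) * tau^2

The overall objective adds the relation-matrix and attention-map
distillation terms:

    L = L_SD + beta * L_RGSD + gamma * L_AGSD

with any component switchable off (contributing exactly 0), mirroring
the standard ablation grid over {SD, RGSD, AGSD}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .adapter import DistillableModel, StageFeatureSet
from .attention import AttentionModule, agsd_loss, align_attention, attention_map
from .nn import Tensor, as_tensor, cross_entropy, log_softmax
from .relation import align_relation, flatten_spatial, relation_matrix, rgsd_loss

__all__ = [
    "ObjectiveConfig",
    "LossBreakdown",
    "softened_kl",
    "sd_loss",
    "overall_loss",
    "model_loss",
]


@dataclass(frozen=True)
class ObjectiveConfig:
    """Weights and switches of the training objective.

    alpha weighs the softened-KL term inside L_SD; beta and gamma weigh
    the relation and attention distillation terms.  Defaults are chosen
    so the components have comparable magnitude on the synthetic smoke
    setup.  tau=1 recovers the unsoftened KL.
    """

    alpha: float = 0.3
    beta: float = 0.1
    gamma: float = 0.1
    temperature: float = 3.0
    components: frozenset[str] = frozenset({"SD", "RGSD", "AGSD"})
    kl_teacher_reference: bool = True  # KL(teacher || student); False swaps
    detach_teacher_kl: bool = True
    rgsd_mode: str = "frobenius"
    rgsd_reduction: str = "frobenius"
    rgsd_detach_teacher: bool = True
    rgsd_stages: tuple[int, ...] | None = None  # None = all student stages
    agsd_normalize: bool = True
    agsd_detach_teacher: bool = False
    agsd_stages: tuple[int, ...] | None = None
    feature_hint: bool = False  # optional L2 feature matching; not implemented

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("loss weights must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        unknown = set(self.components) - {"SD", "RGSD", "AGSD"}
        if unknown:
            raise ValueError(f"unknown components {sorted(unknown)}")


@dataclass
class LossBreakdown:
    """Named scalar components of one objective evaluation."""

    ce_per_head: list[float]
    kl_per_student: list[float]
    rgsd: float
    agsd: float
    total: float
    total_tensor: Tensor | None = field(default=None, repr=False)

    def as_dict(self) -> dict[str, float]:
        return {
            "ce_sum": float(sum(self.ce_per_head)),
            "kl_sum": float(sum(self.kl_per_student)),
            "rgsd": self.rgsd,
            "agsd": self.agsd,
            "total": self.total,
        }


def _check_finite(logits: Tensor, name: str) -> None:
    if not np.all(np.isfinite(logits.data)):
        raise ValueError(f"non-finite values in {name} logits")


def softened_kl(
    student_logits,
    teacher_logits,
    temperature: float = 1.0,
    detach_teacher: bool = True,
    teacher_reference: bool = True,
) -> Tensor:
    """tau^2-scaled KL divergence between temperature-softened class
    distributions, averaged over the batch.

    With ``teacher_reference`` (default) the direction is
    KL(p_teacher || p_student), the usual distillation convention.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    s = as_tensor(student_logits)
    t = as_tensor(teacher_logits)
    _check_finite(s, "student")
    _check_finite(t, "teacher")
    if s.shape != t.shape:
        raise ValueError(f"logit shapes differ: {s.shape} vs {t.shape}")
    if detach_teacher:
        t = t.detach()
    if s.ndim == 1:
        s = s.reshape(1, -1)
        t = t.reshape(1, -1)
    if not teacher_reference:
        s, t = t, s
    log_p_ref = log_softmax(t / temperature, axis=1)
    log_p_other = log_softmax(s / temperature, axis=1)
    p_ref = log_p_ref.exp()
    kl = (p_ref * (log_p_ref - log_p_other)).sum(axis=1).mean()
    return kl * (temperature**2)


def sd_loss(
    logits_all_heads: list, labels, config: ObjectiveConfig
) -> tuple[Tensor, dict]:
    """Base self-distillation loss over all K heads (teacher last)."""
    if not logits_all_heads:
        raise ValueError("need at least one classifier head")
    labels = np.asarray(labels)
    heads = [as_tensor(l) for l in logits_all_heads]
    teacher = heads[-1]
    ce_terms = [cross_entropy(h if h.ndim == 2 else h.reshape(1, -1), np.atleast_1d(labels)) for h in heads]
    kl_terms = [
        softened_kl(
            h,
            teacher,
            temperature=config.temperature,
            detach_teacher=config.detach_teacher_kl,
            teacher_reference=config.kl_teacher_reference,
        )
        for h in heads[:-1]
    ]
    total = ce_terms[0]
    for t in ce_terms[1:]:
        total = total + t
    for k in kl_terms:
        total = total + config.alpha * k
    components = {
        "ce_per_head": [float(t.data) for t in ce_terms],
        "kl_per_student": [float(k.data) for k in kl_terms],
    }
    return total, components


def _student_subset(requested: tuple[int, ...] | None, students: tuple[int, ...]) -> tuple[int, ...]:
    if requested is None:
        return students
    bad = set(requested) - set(students)
    if bad:
        raise ValueError(f"stages {sorted(bad)} have no attached auxiliaries")
    return tuple(sorted(requested))


def overall_loss(
    stage_features: StageFeatureSet,
    logits_all_heads: list,
    labels,
    config: ObjectiveConfig,
    am: AttentionModule | None = None,
    student_stages: tuple[int, ...] | None = None,
) -> LossBreakdown:
    """Assemble the full training objective from one tapped forward pass.

    ``stage_features`` holds every registered stage's features (teacher
    last); ``logits_all_heads`` holds one logit set per attached head
    plus the teacher's.  Disabled components contribute exactly zero.
    ``student_stages`` are the 1-based stage indices of the attached
    heads (defaults to 1..K-1 matching the feature list).
    """
    if config.feature_hint:
        raise NotImplementedError(
            "the optional feature-hint (L2 feature-matching) term is a stub; "
            "the default objective does not include it"
        )
    labels = np.atleast_1d(np.asarray(labels))
    K = len(stage_features)
    if student_stages is None:
        student_stages = tuple(range(1, K))

    # -- classification part ------------------------------------------------
    if "SD" in config.components:
        sd_total, comp = sd_loss(logits_all_heads, labels, config)
        ce_per_head = comp["ce_per_head"]
        kl_per_student = comp["kl_per_student"]
        total = sd_total
    else:
        teacher_logits = as_tensor(logits_all_heads[-1])
        teacher_ce = cross_entropy(
            teacher_logits if teacher_logits.ndim == 2 else teacher_logits.reshape(1, -1), labels
        )
        ce_per_head = [float(teacher_ce.data)]
        kl_per_student = []
        total = teacher_ce

    # -- relation distillation ----------------------------------------------
    rgsd_val = 0.0
    if "RGSD" in config.components:
        stages = _student_subset(config.rgsd_stages, student_stages)
        R_K = relation_matrix(flatten_spatial(stage_features.teacher), mode=config.rgsd_mode)
        T_K = R_K.matrix.shape[-1]
        student_Rs = [
            align_relation(
                relation_matrix(flatten_spatial(stage_features[s - 1]), mode=config.rgsd_mode),
                T_K,
            )
            for s in stages
        ]
        rgsd = rgsd_loss(
            student_Rs,
            R_K,
            reduction=config.rgsd_reduction,
            detach_teacher=config.rgsd_detach_teacher,
        )
        rgsd_val = float(rgsd.data)
        total = total + config.beta * rgsd

    # -- attention distillation ---------------------------------------------
    agsd_val = 0.0
    if "AGSD" in config.components:
        if am is None:
            raise ValueError("AGSD enabled but no attention module given")
        stages = _student_subset(config.agsd_stages, student_stages)
        M_K = attention_map(stage_features.teacher, am, stage=K)
        teacher_shape = tuple(M_K.map.shape[-3:])
        student_Ms = [
            align_attention(attention_map(stage_features[s - 1], am, stage=s), teacher_shape)
            for s in stages
        ]
        agsd = agsd_loss(
            student_Ms,
            M_K,
            normalize=config.agsd_normalize,
            detach_teacher=config.agsd_detach_teacher,
        )
        agsd_val = float(agsd.data)
        total = total + config.gamma * agsd

    return LossBreakdown(
        ce_per_head=ce_per_head,
        kl_per_student=kl_per_student,
        rgsd=rgsd_val,
        agsd=agsd_val,
        total=float(total.data),
        total_tensor=total,
    )


def model_loss(
    model: DistillableModel, batch, labels, config: ObjectiveConfig
) -> LossBreakdown:
    """Convenience: forward a batch through a distillable model and build
    the full loss breakdown."""
    feats, logits = model.forward_with_taps(batch)
    return overall_loss(
        feats, logits, labels, config, am=model.am, student_stages=model.student_stages
    )
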