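"""The two-phase training schedule.

Phase 1 fine-tunes the backbone (optionally only its later stages) and the
shared classifier with the dynamically class-balanced BCE, using gradient
accumulation so the effective batch can exceed the micro-batch.

Phase 2 trains the pixel-correlation module alone, with every other weight
frozen, using a weight-shared Siamese pass: one branch sees the affinely
transformed image, the other applies the same transform to the CAMs of the
untransformed image; their agreement (ECR with OHEM) plus a multi-label
soft-margin loss on the globally average-pooled refined CAMs of both
branches is the objective.  Because the refined maps never enter the
score path, phase 2 leaves classification output exactly unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .backbone import MultiResCamModel
from .cam_head import CAMStack, suppress_non_maximum
from .losses import (SeamLossConfig, class_balance_weights, ecr_with_ohem,
                     multilabel_soft_margin, seam_total, weighted_bce)
from .nn import Tensor
from .nn import autograd as _ag
from .pcm import refine_cams

__all__ = ["Phase1Config", "Phase2Config", "TrainConfig", "SiameseOutputs",
           "train_phase1", "siamese_forward", "train_phase2_pcm",
           "rotate_batch"]


@dataclass(frozen=True)
class Phase1Config:
    lr: float = 3e-4
    betas: tuple[float, float] = (0.9, 0.9)
    epochs: int = 35
    micro_batch: int = 32
    accumulation_steps: int = 3

    @property
    def effective_batch(self) -> int:
        return self.micro_batch * self.accumulation_steps


@dataclass(frozen=True)
class Phase2Config:
    lr: float = 1e-6
    betas: tuple[float, float] = (0.9, 0.9)
    epochs: int = 3
    micro_batch: int = 32
    rotation_range_deg: tuple[float, float] = (-30.0, 30.0)
    seam: SeamLossConfig = field(default_factory=SeamLossConfig)


@dataclass(frozen=True)
class TrainConfig:
    phase1: Phase1Config = field(default_factory=Phase1Config)
    phase2: Phase2Config = field(default_factory=Phase2Config)
    seed: int = 0


Dataset = tuple[np.ndarray, np.ndarray]      # (images (N,3,S,S), labels (N,n))


def _batches(n: int, size: int, rng: np.random.Generator | None):
    order = np.arange(n) if rng is None else rng.permutation(n)
    for start in range(0, n, size):
        yield order[start:start + size]


def _epoch_loss(model: MultiResCamModel, data: Dataset, batch: int) -> float:
    """Mean weighted-BCE over a dataset, eval mode, no autodiff graph."""
    x, y = data
    model.eval()
    losses, weights = [], []
    with nn.no_grad():
        for idx in _batches(len(x), batch, None):
            z, _, _ = model(Tensor(x[idx]))
            w = class_balance_weights(y[idx])
            losses.append(weighted_bce(z.z.sigmoid(), y[idx], w).item())
            weights.append(len(idx))
    model.train()
    return float(np.average(losses, weights=weights))


def train_phase1(train: Dataset, val: Dataset | None, model: MultiResCamModel,
                 cfg: Phase1Config = Phase1Config(), seed: int = 0,
                 trainable_stages: list[int] | None = None
                 ) -> dict[str, list[float]]:
    """Fine-tune backbone + classifier with class-balanced BCE.

    The optimizer steps once every ``accumulation_steps`` micro-batches, each
    micro-batch loss scaled by 1/accumulation_steps, so the update equals a
    single step on the concatenated effective batch (for batch-independent
    losses).  Returns per-epoch train/val loss history.
    """
    x, y = train
    if len(x) == 0:
        raise ValueError("empty training set")
    if trainable_stages is not None:
        model.base.set_trainable_stages(trainable_stages)
    rng = np.random.default_rng(seed)
    params = [p for p in model.parameters() if p.requires_grad]
    opt = nn.Adam(params, lr=cfg.lr, betas=cfg.betas)
    history: dict[str, list[float]] = {"train": [], "val": []}
    model.train()
    for _ in range(cfg.epochs):
        epoch_losses = []
        micro = 0
        opt.zero_grad()
        for idx in _batches(len(x), cfg.micro_batch, rng):
            z, _, _ = model(Tensor(x[idx]))
            w = class_balance_weights(y[idx])
            loss = weighted_bce(z.z.sigmoid(), y[idx], w)
            (loss * (1.0 / cfg.accumulation_steps)).backward()
            epoch_losses.append(loss.item())
            micro += 1
            if micro % cfg.accumulation_steps == 0:
                opt.step()
                opt.zero_grad()
        if micro % cfg.accumulation_steps:
            opt.step()                       # flush the partial accumulation
            opt.zero_grad()
        history["train"].append(float(np.mean(epoch_losses)))
        if val is not None and len(val[0]):
            history["val"].append(_epoch_loss(model, val, cfg.micro_batch))
    return history


# ---------------------------------------------------------------------------
# Siamese phase
# ---------------------------------------------------------------------------

@dataclass
class SiameseOutputs:
    """Raw (suppressed) and refined CAM stacks of the two weight-shared
    branches, plus the sampled per-image rotation angles."""

    yhat_o: CAMStack
    y_o: CAMStack
    yhat_t: CAMStack
    y_t: CAMStack
    angles: np.ndarray

    def transform(self, stack: CAMStack | Tensor) -> Tensor:
        """Apply the sampled transform A in CAM space."""
        maps = stack.maps if isinstance(stack, CAMStack) else stack
        return rotate_batch(maps, self.angles)

    def valid_mask(self) -> np.ndarray:
        """(N, 1, h, w) mask of CAM pixels untouched by rotation borders."""
        _, _, h, w = self.yhat_o.maps.shape
        return np.stack([_ag.rotation_valid_mask(h, w, a)[None]
                         for a in self.angles])


def rotate_batch(x: Tensor, angles: np.ndarray | list[float]) -> Tensor:
    """Rotate each sample of an (N, C, H, W) tensor by its own angle."""
    parts = [_ag.rotate(x[i:i + 1], float(a)) for i, a in enumerate(angles)]
    return nn.concatenate(parts, axis=0)


def siamese_forward(images: Tensor | np.ndarray, model: MultiResCamModel,
                    angles: np.ndarray | list[float]) -> SiameseOutputs:
    """Run both branches of the weight-shared Siamese network.

    Branch t feeds the rotated images through the network; branch o feeds the
    originals (the transform is applied to its CAMs later, inside the ECR
    loss).  Non-maximum suppression precedes PCM refinement in both branches.
    """
    if model.pcm is None:
        raise ValueError("model has no PCM attached (pcm.attach_pcm)")
    x = images if isinstance(images, Tensor) else Tensor(np.asarray(images))
    angles = np.asarray(angles, dtype=float)
    _, cams_o, fm_o = model(x)
    x_t = rotate_batch(x, angles)
    _, cams_t, fm_t = model(x_t)
    yhat_o = suppress_non_maximum(cams_o)
    yhat_t = suppress_non_maximum(cams_t)
    y_o = refine_cams(yhat_o, fm_o, model.pcm)
    y_t = refine_cams(yhat_t, fm_t, model.pcm)
    return SiameseOutputs(yhat_o=yhat_o, y_o=y_o, yhat_t=yhat_t, y_t=y_t,
                          angles=angles)


def train_phase2_pcm(train: Dataset, model: MultiResCamModel,
                     cfg: Phase2Config = Phase2Config(), seed: int = 0
                     ) -> dict[str, list[float]]:
    """Train the PCM embedding with the SEAM objective; everything else frozen.

    Per image a rotation angle is drawn uniformly from
    ``cfg.rotation_range_deg`` (flips are never sampled).  Only PCM
    parameters receive optimizer updates; all other weights are bit-identical
    before and after.
    """
    if model.pcm is None:
        raise ValueError("PCM is disabled; attach it before phase-2 training")
    x, y = train
    rng = np.random.default_rng(seed)
    pcm_params = set(id(p) for p in model.pcm.parameters())
    for p in model.parameters():
        p.requires_grad = id(p) in pcm_params
    opt = nn.Adam(model.pcm.parameters(), lr=cfg.lr, betas=cfg.betas)
    model.eval()   # frozen backbone: batch-norm must use running statistics
    history: dict[str, list[float]] = {"total": [], "msml": [], "ecr": []}
    for _ in range(cfg.epochs):
        tot, msml_l, ecr_l = [], [], []
        for idx in _batches(len(x), cfg.micro_batch, rng):
            angles = rng.uniform(*cfg.rotation_range_deg, size=len(idx))
            out = siamese_forward(x[idx], model, angles)
            gap_o = out.y_o.maps.mean(axis=(2, 3))
            gap_t = out.y_t.maps.mean(axis=(2, 3))
            msml = (multilabel_soft_margin(gap_o, y[idx])
                    + multilabel_soft_margin(gap_t, y[idx])) * 0.5
            ecr = ecr_with_ohem(out.y_o, out.y_t, out.yhat_o, out.yhat_t,
                                transform=out.transform,
                                keep_fraction=cfg.seam.ohem_keep_fraction,
                                valid_mask=out.valid_mask())
            loss = seam_total(msml, ecr, cfg.seam)
            opt.zero_grad()
            loss.backward()
            opt.step()
            tot.append(loss.item())
            msml_l.append(msml.item())
            ecr_l.append(ecr.item())
        history["total"].append(float(np.mean(tot)))
        history["msml"].append(float(np.mean(msml_l)))
        history["ecr"].append(float(np.mean(ecr_l)))
    return history
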