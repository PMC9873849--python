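"""Loss functions: class-balanced BCE, multi-label soft margin, equivariant
cross regularization with online hard example mining, and their combination.

Class balancing.  With |P_c| positive and |N_c| negative samples of class c
in the batch, the BCE terms are weighted by

    beta_P^c = (|P_c| + |N_c|) / |P_c|,   beta_N^c = (|P_c| + |N_c|) / |N_c|

recomputed for every batch, so each class contributes the same total weight
regardless of its batch prevalence (1/beta_P + 1/beta_N = 1 whenever both
counts are positive).  A zero count would make the corresponding weight
infinite, but its loss term vanishes identically, so the weight is set to 0.

Equivariant cross regularization (ECR).  For an affine transform A and the
raw/refined CAM stacks of the two Siamese branches, the per-pixel losses

    |A(y^o) - yhat^t|   and   |A(yhat^o) - y^t|

are each reduced by keeping only the largest ``keep_fraction`` of elements
(OHEM) and averaging them; the two reductions are added.  (Adding — rather
than subtracting, as one printed form of the objective suggests — is the only
reading that leaves the loss bounded below and matches the consistency
construction ECR derives from.)  Pixels the transform pulls in from outside
the frame are masked out before selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .cam_head import CAMStack
from .nn import Tensor

__all__ = ["ClassBalanceWeights", "SeamLossConfig", "class_balance_weights",
           "weighted_bce", "multilabel_soft_margin", "ecr_with_ohem",
           "seam_total"]

_LOG_EPS = 1e-7


@dataclass(frozen=True)
class ClassBalanceWeights:
    beta_P: np.ndarray
    beta_N: np.ndarray


@dataclass(frozen=True)
class SeamLossConfig:
    lambda_msml: float = 1.5
    lambda_ecr: float = 1.0
    ohem_keep_fraction: float = 0.20

    def __post_init__(self):
        if not 0 < self.ohem_keep_fraction <= 1:
            raise ValueError("ohem_keep_fraction must be in (0, 1]")
        if self.lambda_msml < 0 or self.lambda_ecr < 0:
            raise ValueError("loss weights must be non-negative")


def class_balance_weights(labels_batch: np.ndarray) -> ClassBalanceWeights:
    """Per-class (beta_P, beta_N) from a (B, n) multi-hot label batch."""
    y = np.asarray(labels_batch)
    if y.ndim != 2 or y.shape[0] < 1:
        raise ValueError("labels batch must be (B, n) with B >= 1")
    pos = y.sum(axis=0).astype(float)
    total = float(y.shape[0])
    neg = total - pos
    with np.errstate(divide="ignore"):
        beta_p = np.where(pos > 0, total / np.maximum(pos, 1e-12), 0.0)
        beta_n = np.where(neg > 0, total / np.maximum(neg, 1e-12), 0.0)
    return ClassBalanceWeights(beta_P=beta_p, beta_N=beta_n)


def weighted_bce(probs: Tensor | np.ndarray, labels: np.ndarray,
                 weights: ClassBalanceWeights) -> Tensor:
    """Dynamically weighted binary cross-entropy.

    ``probs`` are probabilities in (0, 1) (clamped at 1e-7 from both ends);
    the per-sample class sums are averaged over the batch, so the magnitude
    is invariant to batch size.
    """
    f = probs if isinstance(probs, Tensor) else Tensor(np.asarray(probs, float))
    y = np.asarray(labels, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be 0/1 multi-hot")
    if f.shape != y.shape:
        raise ValueError("probs and labels shapes differ")
    f = f.clip(_LOG_EPS, 1.0 - _LOG_EPS)
    bp = weights.beta_P[None, :]
    bn = weights.beta_N[None, :]
    terms = (f.log() * (-bp * y)) + ((1.0 - f).log() * (-bn * (1.0 - y)))
    return terms.sum(axis=1).mean()


def multilabel_soft_margin(scores: Tensor | np.ndarray,
                           labels: np.ndarray) -> Tensor:
    """Mean over samples and classes of
    y*log(1 + e^{-z}) + (1-y)*log(1 + e^{z})  (== -[y log s(z) + (1-y) log s(-z)]).
    """
    z = scores if isinstance(scores, Tensor) else Tensor(np.asarray(scores, float))
    y = np.asarray(labels, dtype=float)

    def softplus(t: Tensor) -> Tensor:   # log(1 + e^t), overflow-safe
        return t.relu() + (((t.abs() * -1.0).exp()) + 1.0).log()

    loss = softplus(z * -1.0) * y + softplus(z) * (1.0 - y)
    return loss.mean()


def _as_maps(stack) -> Tensor:
    return stack.maps if isinstance(stack, CAMStack) else (
        stack if isinstance(stack, Tensor) else Tensor(np.asarray(stack)))


def _ohem_mean(per_elem: Tensor, keep_fraction: float,
               valid: np.ndarray | None) -> Tensor:
    """Average of the largest ``keep_fraction`` of the (masked) elements.

    Selection indices come from the current values (no gradient through the
    choice itself, as in standard hard-example mining)."""
    vals = per_elem.data.reshape(-1)
    if valid is None:
        valid_flat = np.ones(vals.size, dtype=bool)
    else:
        valid_flat = np.broadcast_to(valid, per_elem.shape).reshape(-1)
    n_valid = int(valid_flat.sum())
    if n_valid == 0:
        raise ValueError("no valid pixels for OHEM selection")
    k = int(np.ceil(keep_fraction * n_valid))
    masked = np.where(valid_flat, vals, -np.inf)
    keep_idx = np.argpartition(masked, -k)[-k:]
    mask = np.zeros(vals.size)
    mask[keep_idx] = 1.0
    flat = per_elem.reshape(per_elem.data.size)
    return (flat * mask).sum() * (1.0 / k)


def ecr_with_ohem(y_o, y_t, yhat_o, yhat_t,
                  transform: Callable[[Tensor], Tensor] | None = None,
                  keep_fraction: float = 0.20,
                  valid_mask: np.ndarray | None = None) -> Tensor:
    """Equivariant cross regularization with OHEM.

    ``transform`` applies A to the original branch's stacks in CAM space
    (identity when None); ``valid_mask`` (broadcastable to the stack shape)
    marks pixels whose transformed value is trustworthy — border pixels a
    rotation pulls in from outside the frame are excluded before selection.
    """
    if keep_fraction <= 0:
        raise ValueError("keep_fraction must be positive")
    yo, yt = _as_maps(y_o), _as_maps(y_t)
    ho, ht = _as_maps(yhat_o), _as_maps(yhat_t)
    if not (yo.shape == yt.shape == ho.shape == ht.shape):
        raise ValueError("all four CAM stacks must share a shape")
    A = transform if transform is not None else (lambda t: t)
    term1 = (A(yo) - ht).abs()
    term2 = (A(ho) - yt).abs()
    return _ohem_mean(term1, keep_fraction, valid_mask) \
        + _ohem_mean(term2, keep_fraction, valid_mask)


def seam_total(msml, ecr, cfg: SeamLossConfig = SeamLossConfig()):
    """Combined objective: lambda_MSML * MSML + lambda_ECR * ECR."""
    return msml * cfg.lambda_msml + ecr * cfg.lambda_ecr
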