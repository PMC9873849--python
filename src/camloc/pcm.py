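"""Pixel Correlation Module (PCM): self-attention refinement of CAMs.

Each refined CAM pixel is a weighted average of every pixel of the original
(suppressed) CAM; the weights are ReLU-clipped cosine similarities between
learned linear embeddings of the backbone features, normalized per row:

    y_i = (1 / C(x_i)) * sum_j ReLU( cos(theta(x_i), theta(x_j)) ) * yhat_j
    C(x_i) = sum_j ReLU( cos(theta(x_i), theta(x_j)) )

theta is a 1x1 convolution with no non-linearity and is the module's only
trainable part.  Row normalization by the ReLU'd-cosine row sum makes every
refined pixel an exact convex combination of the original CAM pixels, so
refinement can relocate activation mass but never leave the original range.
The classification path never sees the refined maps.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .cam_head import CAMStack
from .nn import Tensor
from .nn import autograd as _ag

__all__ = ["PixelCorrelationModule", "embed_and_affinity", "refine_cams",
           "attach_pcm"]

_EPS = 1e-8   # guard on embedding norms (zero-norm pixels get uniform-safe rows)


class PixelCorrelationModule(nn.Module):
    """theta embedding + affinity computation.

    ``embed_channels`` defaults to a quarter of the input channels (the
    embedding only has to preserve relative orientation, not content).
    """

    def __init__(self, in_channels: int, embed_channels: int | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if embed_channels is None:
            embed_channels = max(1, in_channels // 4)
        self.theta = nn.Conv2d(in_channels, embed_channels, 1, bias=False,
                               rng=rng)

    def forward(self, features: Tensor) -> Tensor:
        return self.theta(features)


def embed_and_affinity(features: Tensor | np.ndarray,
                       params: PixelCorrelationModule) -> Tensor:
    """Row-stochastic affinity matrix W, shape (N, h*w, h*w).

    W[i, j] = ReLU(cos(theta(x_i), theta(x_j))) / C(x_i).  Rows whose ReLU'd
    similarities sum to ~0 (possible only for zero-norm embeddings) fall back
    to the identity row, keeping W row-stochastic everywhere.
    """
    x = features if isinstance(features, Tensor) else Tensor(np.asarray(features))
    if x.ndim == 3:
        x = x.reshape(1, *x.shape)
    n, _, h, w = x.shape
    e = params(x)                                   # (N, Ce, h, w)
    ce = e.shape[1]
    e = e.reshape(n, ce, h * w)
    norms = ((e ** 2).sum(axis=1, keepdims=True) + _EPS ** 2) ** 0.5
    e_hat = e / norms
    cos = e_hat.transpose(0, 2, 1) @ e_hat          # (N, hw, hw)
    sim = cos.relu()
    row_sum = sim.sum(axis=2, keepdims=True)
    degenerate = row_sum.data < 1e-6                # zero-embedding rows
    if degenerate.any():
        eye = np.broadcast_to(np.eye(h * w), (n, h * w, h * w))
        sim = sim + Tensor(eye * degenerate)
        row_sum = sim.sum(axis=2, keepdims=True)
    return sim / row_sum


def refine_cams(cams: CAMStack, features: Tensor | np.ndarray,
                params: PixelCorrelationModule) -> CAMStack:
    """Refine a (suppressed) CAM stack by the feature affinity of its image.

    Features are bilinearly interpolated to the CAM's spatial size when they
    differ.  Returns a new stack flagged ``refined=True``; the input stack is
    untouched (the class-score path is never affected by refinement).
    """
    x = features if isinstance(features, Tensor) else Tensor(np.asarray(features))
    if x.ndim == 3:
        x = x.reshape(1, *x.shape)
    maps = cams.maps
    if maps.ndim == 3:
        maps = maps.reshape(1, *maps.shape)
    n, c, h, w = maps.shape
    if x.shape[2:] != (h, w):
        x = _ag.resize_bilinear(x, h, w)
    if x.shape[0] != n:
        raise ValueError("feature and CAM batch sizes differ")
    aff = embed_and_affinity(x, params)             # (N, hw, hw)
    flat = maps.reshape(n, c, h * w)
    refined = flat @ aff.transpose(0, 2, 1)         # y_i = sum_j W[i,j] yhat_j
    return CAMStack(maps=refined.reshape(n, c, h, w),
                    resolution_level=cams.resolution_level, refined=True,
                    suppressed=cams.suppressed)


def attach_pcm(model, embed_channels: int | None = None,
               seed: int | None = None) -> PixelCorrelationModule:
    """Attach a PCM to an assembled model (operating on its output feature map)."""
    from .backbone import MultiResCamModel
    assert isinstance(model, MultiResCamModel)
    rng = np.random.default_rng(seed)
    in_ch = model.base.stage_channels[model.finest_level]
    model.pcm = PixelCorrelationModule(in_ch, embed_channels, rng=rng)
    return model.pcm
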