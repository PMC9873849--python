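"""Classification scores and class activation maps from the output feature map.

The classifier is a single affine map from channel space to class space,
applied at every spatial location (a 1x1 convolution).  Applying it per pixel
yields the class activation maps (CAMs); log-sum-exp (LSE) pooling each class
map yields the prediction scores, so CAMs and scores share one set of
weights and ``lse_pool(CAM_c) == z_c`` holds exactly.

LSE pooling interpolates between mean pooling (gamma -> 0) and max pooling
(gamma -> inf):

    s = (1 / gamma) * log( mean_ij exp(gamma * x_ij) )

computed with a max shift so large gamma cannot overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .nn import autograd as _ag

__all__ = ["CAMStack", "PredictionVector", "lse_pool", "forward_classify",
           "suppress_non_maximum", "rescale_heatmap"]


@dataclass
class CAMStack:
    """Per-class activation maps at feature resolution.

    ``maps`` is (N, n_classes, h, w) (a batch) — single images travel as
    batches of one.  ``refined`` is False for the raw classifier output and
    True after pixel-correlation refinement.
    """

    maps: Tensor
    resolution_level: int = 5
    refined: bool = False
    suppressed: bool = False

    @property
    def array(self) -> np.ndarray:
        return self.maps.data


@dataclass
class PredictionVector:
    z: Tensor                     # (N, n_classes) raw scores

    @property
    def probabilities(self) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.z.data))


def lse_pool(feature_map: Tensor | np.ndarray, gamma: float = 10.0) -> Tensor:
    """LSE-pool the spatial dimensions of a (N, C, h, w) or (C, h, w) map."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    x = feature_map if isinstance(feature_map, Tensor) else Tensor(np.asarray(feature_map))
    if not np.all(np.isfinite(x.data)):
        raise ValueError("feature map contains non-finite values")
    squeeze = x.ndim == 3
    if squeeze:
        x = x.reshape(1, *x.shape)
    m = x.data.max(axis=(2, 3), keepdims=True)     # constant shift: dLSE/dm = 0
    shifted = ((x - m) * gamma).exp().mean(axis=(2, 3), keepdims=True)
    out = Tensor(m) + shifted.log() * (1.0 / gamma)
    out = out.reshape(x.shape[0], x.shape[1])
    return out.reshape(x.shape[1]) if squeeze else out


def forward_classify(output_feature_map: Tensor | np.ndarray,
                     classifier: nn.Conv2d,
                     gamma: float = 10.0) -> tuple[PredictionVector, CAMStack]:
    """Apply the shared classifier: per-pixel -> CAMs, LSE-pooled -> scores.

    CAM_c(i, j) = w_c . map(:, i, j) + b_c  and  z_c = lse_pool(CAM_c).
    """
    fm = output_feature_map if isinstance(output_feature_map, Tensor) \
        else Tensor(np.asarray(output_feature_map))
    if fm.ndim == 3:
        fm = fm.reshape(1, *fm.shape)
    if fm.shape[1] != classifier.weight.shape[1]:
        raise ValueError(f"feature channels {fm.shape[1]} do not match "
                         f"classifier input {classifier.weight.shape[1]}")
    cams = classifier(fm)
    z = lse_pool(cams, gamma)
    return PredictionVector(z), CAMStack(maps=cams)


def suppress_non_maximum(cams: CAMStack) -> CAMStack:
    """Zero all but the strongest class at each pixel (foreground selection).

    Activations are first clipped at zero (negative evidence is background by
    construction of the CAM), then at every pixel only the class with the
    maximal activation keeps its value; ties go to the lowest class index.
    The operation is idempotent.
    """
    if cams.refined:
        raise ValueError("suppression applies to unrefined CAM stacks")
    x = cams.maps.relu()
    arg = x.data.argmax(axis=1, keepdims=True)     # ties -> lowest index
    mask = np.zeros_like(x.data)
    np.put_along_axis(mask, arg, 1.0, axis=1)
    return CAMStack(maps=x * mask, resolution_level=cams.resolution_level,
                    refined=False, suppressed=True)


def rescale_heatmap(cam: np.ndarray | Tensor, out_side: int) -> np.ndarray:
    """Upsample one class map to ``out_side`` square and quantize to 8 bits.

    Bilinear upsampling, then per-map min-max normalization to [0, 1] and
    rounding to [0, 255] with numpy's round-half-to-even rule (a mid value
    such as 127.5 becomes 128).  A constant map has no localization signal
    and maps to all zeros.
    """
    arr = cam.data if isinstance(cam, Tensor) else np.asarray(cam, dtype=float)
    if arr.ndim != 2:
        raise ValueError("rescale_heatmap expects a single-class 2-D map")
    if out_side < arr.shape[0] or out_side < arr.shape[1]:
        raise ValueError("out_side must not be smaller than the map")
    if arr.shape != (out_side, out_side):
        with nn.no_grad():
            arr = _ag.resize_bilinear(Tensor(arr[None, None]), out_side,
                                      out_side).data[0, 0]
    lo, hi = arr.min(), arr.max()
    if hi - lo < 1e-12:
        return np.zeros((out_side, out_side), dtype=np.uint8)
    return np.rint((arr - lo) / (hi - lo) * 255).astype(np.uint8)
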