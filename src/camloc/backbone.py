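"""Multi-resolution feature extractors.

A staged classification CNN yields raw feature maps F^l at resolution levels
l = 2..5 (spatial side = input_side / 2^l).  The coarse, semantically strong
map F^5 is re-fused with the earlier, spatially finer maps through Merge
Blocks, coarse to fine:

    F_o^5 = F^5
    F_o^l = g(F_o^{l+1}, F^l)        l = 4, 3, ..., finest_level

where g reduces the channels of both inputs by 4 with 1x1 convolutions
(ReLU), bilinearly upsamples the coarse input x2, concatenates, and projects
back to F^l's channel count with a final 1x1 convolution (ReLU).  The output
F_o^finest preserves the fine level's resolution while carrying coarse
semantics, so class activation maps computed from it are spatially sharp.

Three bases are provided: ResNet50 (the reference backbone, faithfully
reproducing the standard parameter count), EfficientNetB4 (constructed for
architecture/parameter parity), and a width-reduced "tiny" base for
CPU-scale training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "FeaturePyramid", "MergeBlock", "build_base", "assemble_multires_model",
    "extract_stage_features", "count_parameters", "MultiResCamModel",
    "SUPPORTED_BASES",
]

SUPPORTED_BASES = ("resnet50", "efficientnet_b4", "tiny")


@dataclass
class FeaturePyramid:
    """Per-level activations: ``raw[l]`` = F^l straight from the base network,
    ``merged[l]`` = resolution-preserving F_o^l (present after merging)."""

    raw: dict[int, Tensor]
    merged: dict[int, Tensor] = field(default_factory=dict)


def count_parameters(model: nn.Module) -> int:
    """Total number of parameter elements (trainable or frozen; buffers such
    as batch-norm running statistics are not parameters)."""
    return model.count_parameters()


# ---------------------------------------------------------------------------
# bases
# ---------------------------------------------------------------------------

class _StagedBackbone(nn.Module):
    """Common interface: ``stages`` 1..5 where stage l's output is F^l for
    l >= 2 (stage 1 is the stem at level 1 or 2 depending on the base)."""

    #: channel count of F^l for l = 2..5
    stage_channels: dict[int, int]

    def forward_features(self, x: Tensor) -> dict[int, Tensor]:
        raise NotImplementedError

    def set_trainable_stages(self, trainable: list[int]) -> None:
        """Freeze every stage not listed (its parameters stop receiving
        gradients and the optimizer must simply not update them)."""
        for idx, stage in self.numbered_stages():
            flag = idx in trainable
            for p in stage.parameters():
                p.requires_grad = flag

    def numbered_stages(self) -> list[tuple[int, nn.Module]]:
        raise NotImplementedError


def _conv_bn_act(cin: int, cout: int, k: int, stride: int, rng,
                 act: type = nn.ReLU, groups: int = 1) -> nn.Sequential:
    return nn.Sequential(
        nn.Conv2d(cin, cout, k, stride=stride, padding=k // 2, groups=groups,
                  bias=False, rng=rng),
        nn.BatchNorm2d(cout),
        act(),
    )


class TinyBackbone(_StagedBackbone):
    """Width-reduced 5-stage CNN (8–64 channels) for desk-scale training;
    same stage/level contract as the big bases."""

    stage_channels = {2: 16, 3: 32, 4: 64, 5: 64}

    def __init__(self, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng()
        self.stage1 = _conv_bn_act(3, 8, 3, 2, rng)          # level 1
        self.stage2 = nn.Sequential(_conv_bn_act(8, 16, 3, 2, rng),
                                    _conv_bn_act(16, 16, 3, 1, rng))
        self.stage3 = nn.Sequential(_conv_bn_act(16, 32, 3, 2, rng),
                                    _conv_bn_act(32, 32, 3, 1, rng))
        self.stage4 = _conv_bn_act(32, 64, 3, 2, rng)
        self.stage5 = _conv_bn_act(64, 64, 3, 2, rng)

    def numbered_stages(self):
        return [(1, self.stage1), (2, self.stage2), (3, self.stage3),
                (4, self.stage4), (5, self.stage5)]

    def forward_features(self, x: Tensor) -> dict[int, Tensor]:
        x = self.stage1(x)
        f2 = self.stage2(x)
        f3 = self.stage3(f2)
        f4 = self.stage4(f3)
        f5 = self.stage5(f4)
        return {2: f2, 3: f3, 4: f4, 5: f5}


class _Bottleneck(nn.Module):
    expansion = 4

    def __init__(self, cin: int, mid: int, stride: int, rng):
        super().__init__()
        cout = mid * self.expansion
        self.conv1 = nn.Conv2d(cin, mid, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(mid)
        self.conv2 = nn.Conv2d(mid, mid, 3, stride=stride, padding=1,
                               bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(mid)
        self.conv3 = nn.Conv2d(mid, cout, 1, bias=False, rng=rng)
        self.bn3 = nn.BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.downsample = nn.Sequential(
                nn.Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng),
                nn.BatchNorm2d(cout))
        else:
            self.downsample = nn.Identity()

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        return (out + self.downsample(x)).relu()


class ResNet50Backbone(_StagedBackbone):
    """ResNet50 feature extractor; 3/4/6/3 bottleneck blocks per stage.

    Stage numbering follows the residual blocks: stages 1-4 are the four
    bottleneck layers (stage l emits F^{l+1}); the stem is separate and is
    frozen together with stage 1.
    """

    stage_channels = {2: 256, 3: 512, 4: 1024, 5: 2048}

    def __init__(self, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng()
        self.conv1 = nn.Conv2d(3, 64, 7, stride=2, padding=3, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(64)
        self.maxpool = nn.MaxPool2d(3, stride=2, padding=1)
        self.layer1 = self._make_layer(64, 64, 3, 1, rng)
        self.layer2 = self._make_layer(256, 128, 4, 2, rng)
        self.layer3 = self._make_layer(512, 256, 6, 2, rng)
        self.layer4 = self._make_layer(1024, 512, 3, 2, rng)

    @staticmethod
    def _make_layer(cin: int, mid: int, blocks: int, stride: int, rng):
        layers = [_Bottleneck(cin, mid, stride, rng)]
        for _ in range(blocks - 1):
            layers.append(_Bottleneck(mid * 4, mid, 1, rng))
        return nn.Sequential(*layers)

    def numbered_stages(self):
        stem = nn.Sequential(self.conv1, self.bn1)
        return [(1, nn.Sequential(stem, self.layer1)), (2, self.layer2),
                (3, self.layer3), (4, self.layer4)]

    def forward_features(self, x: Tensor) -> dict[int, Tensor]:
        x = self.bn1(self.conv1(x)).relu()
        x = self.maxpool(x)
        f2 = self.layer1(x)
        f3 = self.layer2(f2)
        f4 = self.layer3(f3)
        f5 = self.layer4(f4)
        return {2: f2, 3: f3, 4: f4, 5: f5}


# -- EfficientNet-B4 ---------------------------------------------------------

def _make_divisible(v: float, divisor: int = 8) -> int:
    new_v = max(divisor, int(v + divisor / 2) // divisor * divisor)
    if new_v < 0.9 * v:
        new_v += divisor
    return new_v


class _SqueezeExcite(nn.Module):
    def __init__(self, channels: int, squeeze: int, rng):
        super().__init__()
        self.pool = nn.AdaptiveAvgPool2d()
        self.fc1 = nn.Conv2d(channels, squeeze, 1, bias=True, rng=rng)
        self.fc2 = nn.Conv2d(squeeze, channels, 1, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        s = self.fc2(self.fc1(self.pool(x)).silu()).sigmoid()
        return x * s


class _MBConv(nn.Module):
    def __init__(self, cin: int, cout: int, kernel: int, stride: int,
                 expand_ratio: int, rng):
        super().__init__()
        expanded = cin * expand_ratio
        self.use_res = stride == 1 and cin == cout
        blocks: list[nn.Module] = []
        if expand_ratio != 1:
            blocks.append(_conv_bn_act(cin, expanded, 1, 1, rng, act=nn.SiLU))
        blocks.append(_conv_bn_act(expanded, expanded, kernel, stride, rng,
                                   act=nn.SiLU, groups=expanded))
        blocks.append(_SqueezeExcite(expanded, max(1, cin // 4), rng))
        blocks.append(nn.Sequential(
            nn.Conv2d(expanded, cout, 1, bias=False, rng=rng),
            nn.BatchNorm2d(cout)))
        self.block = nn.Sequential(*blocks)

    def forward(self, x: Tensor) -> Tensor:
        out = self.block(x)
        return out + x if self.use_res else out


class EfficientNetB4Backbone(_StagedBackbone):
    """EfficientNet-B4: the B0 MBConv plan scaled by width 1.4 / depth 1.8.

    Built for architecture and parameter parity with the published model
    (no pretrained weights are shipped).  Levels: F^2 after stage 3 input...
    concretely, feature levels 2/3/4/5 are taken after the blocks that
    stride down to 1/4, 1/8, 1/16 and 1/32 resolution.
    """

    # B0 plan: (expand_ratio, kernel, stride, in_ch, out_ch, repeats)
    _B0 = [(1, 3, 1, 32, 16, 1), (6, 3, 2, 16, 24, 2), (6, 5, 2, 24, 40, 2),
           (6, 3, 2, 40, 80, 3), (6, 5, 1, 80, 112, 3), (6, 5, 2, 112, 192, 4),
           (6, 3, 1, 192, 320, 1)]
    _WIDTH, _DEPTH = 1.4, 1.8

    def __init__(self, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng()
        w, d = self._WIDTH, self._DEPTH
        stem_ch = _make_divisible(32 * w)
        self.stem = _conv_bn_act(3, stem_ch, 3, 2, rng, act=nn.SiLU)
        groups: list[list[_MBConv]] = []
        for (er, k, s, ci, co, n) in self._B0:
            ci, co = _make_divisible(ci * w), _make_divisible(co * w)
            reps = int(np.ceil(n * d))
            blocks = []
            for i in range(reps):
                blocks.append(_MBConv(ci if i == 0 else co, co, k,
                                      s if i == 0 else 1, er, rng))
            groups.append(blocks)
        self.blocks = nn.Sequential(*[nn.Sequential(*g) for g in groups])
        head_in = _make_divisible(320 * w)
        self.head_channels = 4 * head_in
        self.head = _conv_bn_act(head_in, self.head_channels, 1, 1, rng,
                                 act=nn.SiLU)
        # stride-2 transitions occur entering block groups 1, 2, 3 and 5
        self.stage_channels = {2: _make_divisible(24 * w),
                               3: _make_divisible(40 * w),
                               4: _make_divisible(112 * w),
                               5: self.head_channels}

    def numbered_stages(self):
        return [(1, nn.Sequential(self.stem, self.blocks[0], self.blocks[1])),
                (2, self.blocks[2]),
                (3, nn.Sequential(self.blocks[3], self.blocks[4])),
                (4, nn.Sequential(self.blocks[5], self.blocks[6], self.head))]

    def forward_features(self, x: Tensor) -> dict[int, Tensor]:
        x = self.stem(x)
        feats = {}
        for i, group in enumerate(self.blocks):
            x = group(x)
            if i == 1:
                feats[2] = x
            elif i == 2:
                feats[3] = x
            elif i == 4:
                feats[4] = x
        feats[5] = self.head(x)
        return feats


def build_base(name: str, rng: np.random.Generator | None = None,
               seed: int | None = None) -> _StagedBackbone:
    """Construct a backbone by name; raises naming the supported bases."""
    if rng is None:
        rng = np.random.default_rng(seed)
    if name == "resnet50":
        return ResNet50Backbone(rng)
    if name == "efficientnet_b4":
        return EfficientNetB4Backbone(rng)
    if name == "tiny":
        return TinyBackbone(rng)
    raise ValueError(f"unsupported base {name!r}; supported: {SUPPORTED_BASES}")


# ---------------------------------------------------------------------------
# merge block and assembled model
# ---------------------------------------------------------------------------

class MergeBlock(nn.Module):
    """g(F_o^{l+1}, F^l): reduce both channel counts by 4 (1x1 conv + ReLU),
    bilinearly upsample the coarse map x2, concatenate, and project back to
    F^l's channel count (1x1 conv + ReLU)."""

    def __init__(self, coarse_channels: int, fine_channels: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if coarse_channels % 4 or fine_channels % 4:
            raise ValueError("merge block requires channel counts divisible by 4")
        rng = rng if rng is not None else np.random.default_rng()
        self.reduce_coarse = nn.Conv2d(coarse_channels, coarse_channels // 4, 1,
                                       bias=True, rng=rng)
        self.reduce_fine = nn.Conv2d(fine_channels, fine_channels // 4, 1,
                                     bias=True, rng=rng)
        self.upsample = nn.UpsampleBilinear2d(2)
        self.project = nn.Conv2d((coarse_channels + fine_channels) // 4,
                                 fine_channels, 1, bias=True, rng=rng)

    def forward(self, f_coarse: Tensor, f_fine: Tensor) -> Tensor:
        if (f_coarse.shape[2] * 2, f_coarse.shape[3] * 2) != f_fine.shape[2:]:
            raise ValueError(
                f"coarse map {f_coarse.shape[2:]} must be half the fine map "
                f"{f_fine.shape[2:]}")
        c = self.upsample(self.reduce_coarse(f_coarse).relu())
        f = self.reduce_fine(f_fine).relu()
        return self.project(nn.concatenate([c, f], axis=1)).relu()


def merge_block_forward(f_o_coarse: Tensor, f_fine: Tensor,
                        params: MergeBlock) -> Tensor:
    return params(f_o_coarse, f_fine)


def extract_stage_features(batch, base_model: _StagedBackbone,
                           trainable_stages: list[int] | None = None
                           ) -> FeaturePyramid:
    """Run the base network and return the raw pyramid F^2..F^5."""
    x = batch if isinstance(batch, Tensor) else Tensor(np.asarray(batch))
    if x.ndim != 4 or x.shape[1] != 3:
        raise ValueError("batch must be (N, 3, H, W)")
    if x.shape[2] % 32 or x.shape[3] % 32:
        raise ValueError(f"input side {x.shape[2:]} must be divisible by 32")
    if trainable_stages is not None:
        base_model.set_trainable_stages(trainable_stages)
    return FeaturePyramid(raw=base_model.forward_features(x))


class MultiResCamModel(nn.Module):
    """Backbone + Merge Blocks + shared pixel-wise classifier.

    In multi-resolution mode the classifier (a 1x1 convolution: one affine
    map from channel space to class space, applied at every location) runs on
    the resolution-preserving map F_o^finest; in standard mode it runs on the
    raw F^5.  The same weights produce both the class activation maps and,
    after log-sum-exp pooling of each class map, the prediction vector.
    """

    def __init__(self, base: _StagedBackbone, n_classes: int,
                 multires: bool = True, finest_level: int = 2,
                 gamma: float = 10.0, rng: np.random.Generator | None = None):
        super().__init__()
        if multires and finest_level not in (2, 3, 4):
            raise ValueError("finest_level must be in {2, 3, 4}")
        rng = rng if rng is not None else np.random.default_rng()
        self.base = base
        self.multires = multires
        self.finest_level = finest_level if multires else 5
        self.n_classes = n_classes
        self.gamma = gamma
        if multires:
            merges = []
            for lvl in range(4, finest_level - 1, -1):
                merges.append(MergeBlock(base.stage_channels[lvl + 1],
                                         base.stage_channels[lvl], rng))
            self.merges = nn.Sequential(*merges)
        else:
            self.merges = nn.Sequential()
        out_ch = base.stage_channels[self.finest_level]
        self.classifier = nn.Conv2d(out_ch, n_classes, 1, bias=True, rng=rng)
        self.pcm = None  # attached by camloc.pcm.attach_pcm when enabled

    def feature_pyramid(self, x: Tensor) -> FeaturePyramid:
        pyr = FeaturePyramid(raw=self.base.forward_features(x))
        pyr.merged[5] = pyr.raw[5]
        if self.multires:
            for i, lvl in enumerate(range(4, self.finest_level - 1, -1)):
                pyr.merged[lvl] = self.merges[i](pyr.merged[lvl + 1], pyr.raw[lvl])
        return pyr

    def output_feature_map(self, x: Tensor) -> Tensor:
        return self.feature_pyramid(x).merged[self.finest_level]

    def forward(self, x: Tensor):
        """Returns ``(z, cams, features)``; see :mod:`camloc.cam_head` for the
        score/CAM conventions."""
        from .cam_head import forward_classify  # local import: no cycle at load
        fm = self.output_feature_map(x)
        z, cams = forward_classify(fm, self.classifier, gamma=self.gamma)
        return z, cams, fm


def assemble_multires_model(base: str | _StagedBackbone, n_classes: int,
                            finest_level: int = 2, multires: bool = True,
                            gamma: float = 10.0, seed: int | None = None
                            ) -> MultiResCamModel:
    """Build the full classification/CAM model from a base name or instance."""
    rng = np.random.default_rng(seed)
    if isinstance(base, str):
        base = build_base(base, rng=rng)
    return MultiResCamModel(base, n_classes, multires=multires,
                            finest_level=finest_level, gamma=gamma, rng=rng)
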