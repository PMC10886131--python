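"""Model assembly: plain U-net and its three cumulative upgrades.

The four reachable variants form the ablation ladder

    unet       plain U-net encoder, plain decoder
    unet_1     ResNeXt-50 (32x4d) encoder
    unet_12    + deformable 3x3 convolutions in the deepest decoder layer
    unet_123   + scSE attention after decoder layers 2-4   (alias rds_unet)

All variants share one decoder skeleton: each decoder layer bilinearly
upsamples by 2, concatenates the encoder tap of matching resolution (the
skip/jump connection), and applies two same-padded 3x3 convolutions that
reduce to the tap's channel width. Layer 1 is the deepest (consuming the
coarsest feature map); when the deformable toggle is on, its two
convolutions become 3x3 deformable convolutions. When the scSE toggle is
on, an scSE block follows the convolutions of layers 2, 3 and 4. After the
last decoder layer a final upsample (if needed) restores input resolution
and a 1x1 convolution maps to the class logits.

Initialization is split into per-component RNG streams (encoder / each
decoder layer's convolutions / each scSE / head) so that toggling one
component never perturbs the initial weights of another — the property
that makes ablation runs directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np

from . import nn
from .errors import ShapeError, SpecificationError
from .resnext import FeaturePyramid, ResNeXtEncoder
from .scse import SCSE

N_CLASSES = 3  # background / corn / weed

PRESETS = {
    "unet": dict(encoder="plain_unet", deformable_layer1=False,
                 scse_layers234=False),
    "unet_1": dict(encoder="resnext50", deformable_layer1=False,
                   scse_layers234=False),
    "unet_12": dict(encoder="resnext50", deformable_layer1=True,
                    scse_layers234=False),
    "unet_123": dict(encoder="resnext50", deformable_layer1=True,
                     scse_layers234=True),
}
PRESET_ALIASES = {"rds_unet": "unet_123"}


@dataclass(frozen=True)
class ModelVariant:
    encoder: str = "resnext50"
    deformable_layer1: bool = False
    scse_layers234: bool = False
    n_classes: int = N_CLASSES
    input_channels: int = 3

    def __post_init__(self):
        if self.encoder not in ("plain_unet", "resnext50"):
            raise SpecificationError(
                f"unknown encoder {self.encoder!r}; "
                "choose 'plain_unet' or 'resnext50'")


def preset(name: str) -> ModelVariant:
    """The named ablation-ladder variant ('rds_unet' aliases 'unet_123')."""
    key = PRESET_ALIASES.get(name, name)
    if key not in PRESETS:
        valid = sorted(PRESETS) + sorted(PRESET_ALIASES)
        raise SpecificationError(
            f"unknown preset {name!r}; valid presets: {', '.join(valid)}")
    return ModelVariant(**PRESETS[key])


def variant_name(v: ModelVariant) -> str:
    for name, kw in PRESETS.items():
        if all(getattr(v, k) == val for k, val in kw.items()):
            return name
    return "custom"


# ---------------------------------------------------------------------------
# plain U-net encoder
# ---------------------------------------------------------------------------

class _DoubleConv(nn.Module):
    def __init__(self, cin: int, cout: int, *, deformable: bool = False,
                 norm: bool = True, rng=None):
        super().__init__()
        bn = nn.BatchNorm2d if norm else (lambda _: nn.Identity())
        conv = (lambda a, b: nn.DeformableConv2d(a, b, 3, rng=rng)) \
            if deformable else \
            (lambda a, b: nn.Conv2d(a, b, 3, bias=not norm, rng=rng))
        self.c1, self.n1 = conv(cin, cout), bn(cout)
        self.c2, self.n2 = conv(cout, cout), bn(cout)

    def forward(self, x):
        x = self.n1(self.c1(x)).relu()
        return self.n2(self.c2(x)).relu()


class PlainUNetEncoder(nn.Module):
    """Classic U-net contracting path: double 3x3 convs and 2x2 max pools,
    feature channels doubling at every level (64 -> 1024 over 4 pools)."""

    widths = (64, 128, 256, 512, 1024)

    def __init__(self, *, norm: bool = True, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        w = self.widths
        self.inc = _DoubleConv(3, w[0], norm=norm, rng=rng)
        self.downs = [_DoubleConv(w[i], w[i + 1], norm=norm, rng=rng)
                      for i in range(4)]
        self.pool = nn.MaxPool2d(2, stride=2)

    @property
    def out_channels(self):
        return self.widths

    def forward(self, x) -> List[nn.Tensor]:
        taps = [self.inc(x)]                      # stride 1
        for down in self.downs:
            taps.append(down(self.pool(taps[-1])))
        return taps                               # strides 1,2,4,8,16


# ---------------------------------------------------------------------------
# shared decoder
# ---------------------------------------------------------------------------

class DecoderLayer(nn.Module):
    """One upsampling step: 2x bilinear up, skip concat, double conv,
    optional scSE. Layer 1 is the deepest."""

    def __init__(self, up_ch: int, skip_ch: int, out_ch: int, *,
                 deformable: bool = False, scse: bool = False,
                 norm: bool = True, conv_rng=None, scse_rng=None):
        super().__init__()
        self.up = nn.UpsampleBilinear(2)
        self.block = _DoubleConv(up_ch + skip_ch, out_ch,
                                 deformable=deformable, norm=norm,
                                 rng=conv_rng)
        self.scse = SCSE(out_ch, rng=scse_rng) if scse else None

    def forward(self, x, skip):
        y = self.block(nn.cat([self.up(x), skip], axis=1))
        return self.scse(y) if self.scse is not None else y


class SegmentationModel(nn.Module):
    """Encoder-decoder segmentation network mapping (B, 3, H, W) images to
    (B, n_classes, H, W) logits; H and W must be divisible by 32."""

    def __init__(self, variant: ModelVariant, *, norm: bool = True,
                 seed: int = 0):
        super().__init__()
        self.variant = variant
        ss = np.random.SeedSequence(seed)
        enc_ss, head_ss, *layer_ss = ss.spawn(2 + 8)
        if variant.encoder == "resnext50":
            self.encoder = ResNeXtEncoder(
                norm=norm, rng=np.random.default_rng(enc_ss))
            enc_ch = list(self.encoder.out_channels)   # 64,256,512,1024,2048
            self.final_upsample = True
        else:
            self.encoder = PlainUNetEncoder(
                norm=norm, rng=np.random.default_rng(enc_ss))
            enc_ch = list(self.encoder.out_channels)   # 64,...,1024
            self.final_upsample = False
        deep = enc_ch[-1]
        skips = enc_ch[-2::-1]                         # shallow-ward
        self.layers = []
        up_ch = deep
        for i, skip_ch in enumerate(skips, start=1):
            out_ch = skip_ch if skip_ch >= 64 else 64
            self.layers.append(DecoderLayer(
                up_ch, skip_ch, out_ch,
                deformable=(variant.deformable_layer1 and i == 1),
                scse=(variant.scse_layers234 and i >= 2),
                norm=norm,
                conv_rng=np.random.default_rng(layer_ss[2 * (i - 1)]),
                scse_rng=np.random.default_rng(layer_ss[2 * (i - 1) + 1])))
            up_ch = out_ch
        if self.final_upsample:
            self.up_out = nn.UpsampleBilinear(2)
        self.head = nn.Conv2d(up_ch, variant.n_classes, 1,
                              rng=np.random.default_rng(head_ss))

    def _check_input(self, x: nn.Tensor):
        if x.ndim != 4 or x.shape[1] != self.variant.input_channels:
            raise ShapeError(
                f"expected (B, {self.variant.input_channels}, H, W) input, "
                f"got shape {tuple(x.shape)}")
        h, w = x.shape[2], x.shape[3]
        if h % 32 or w % 32:
            raise ShapeError(
                f"input height/width must be multiples of 32, got {h}x{w}")

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        self._check_input(x)
        feats = self.encoder(x)
        if isinstance(feats, FeaturePyramid):
            taps = feats.as_list()
        else:
            taps = feats
        y = taps[-1]
        for layer, skip in zip(self.layers, taps[-2::-1]):
            y = layer(y, skip)
        if self.final_upsample:
            y = self.up_out(y)
        return self.head(y)


def build_model(variant: Union[str, ModelVariant], *, seed: int = 0,
                norm: bool = True) -> SegmentationModel:
    if isinstance(variant, str):
        variant = preset(variant)
    return SegmentationModel(variant, norm=norm, seed=seed)


def forward(model: SegmentationModel, images: np.ndarray) -> np.ndarray:
    """Deterministic evaluation-mode forward pass on a numpy batch.

    images: (B, 3, H, W) float array (already normalized). Returns logits
    (B, n_classes, H, W). ``argmax(axis=1)`` of the result is the predicted
    mask; numpy argmax breaks ties toward the lowest class index.
    """
    was_training = model.training
    model.eval()
    try:
        with nn.no_grad():
            out = model(nn.Tensor(images)).data
    finally:
        model.train(was_training)
    return out


def predict_mask(model: SegmentationModel, images: np.ndarray) -> np.ndarray:
    return forward(model, images).argmax(axis=1).astype(np.uint8)
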