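"""UNet-family segmentation networks at configurable (desk) scale.

Three encoder-decoder architectures over single-channel 2-D inputs:

* ``unet`` — double-conv blocks, 2x2 max-pool encoder, nearest-neighbour
  upsampling decoder with skip concatenation;
* ``attention_unet`` — additive attention gates reweight each skip with a
  sigmoid mask computed from the decoder (gating) signal;
* ``unet_plusplus`` — nested dense skip pathways (node X[i][j] consumes all
  same-level predecessors plus the upsampled deeper node).

All use ReLU non-linearities, He initialisation, optional dropout, and a
final 1x1 convolution to a single-channel logit map of the input's spatial
shape. ``depth`` is the number of pooling steps, so H and W must be
divisible by 2**depth.

The literature also names "U-Net+" and (2-D) "V-Net" variants without
defining their topology; these are accepted as config aliases that map to
``unet`` with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .exceptions import InvalidShape

__all__ = ["ModelSpec", "build_model", "predict_mask", "SegmentationNet"]

logger = logging.getLogger(__name__)

_ALIASES = {"unet_plus": "unet", "vnet": "unet", "u-net+": "unet", "v-net": "unet"}
_ARCHITECTURES = ("unet", "unet_plusplus", "attention_unet")


@dataclass(frozen=True)
class ModelSpec:
    architecture: str = "attention_unet"
    depth: int = 3
    base_channels: int = 8
    dropout_rate: float = 0.1

    def __post_init__(self):
        arch = self.architecture.lower()
        if arch in _ALIASES:
            logger.warning("architecture %r has no defined topology; using 'unet'", self.architecture)
            arch = _ALIASES[arch]
        if arch not in _ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}; choose from {_ARCHITECTURES}")
        object.__setattr__(self, "architecture", arch)
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


# -- layers -------------------------------------------------------------------


class _Conv2d:
    """3x3 (or 1x1) stride-1 convolution with He-normal initialisation."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, kernel: int = 3):
        fan_in = cin * kernel * kernel
        std = float(np.sqrt(2.0 / fan_in))
        self.w = ad.Tensor(rng.normal(0.0, std, size=(cout, cin, kernel, kernel)).astype(np.float32),
                           requires_grad=True)
        self.b = ad.Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)
        self.padding = kernel // 2

    def __call__(self, x: ad.Tensor) -> ad.Tensor:
        return ad.conv2d(x, self.w, self.b, padding=self.padding)

    def parameters(self):
        return [self.w, self.b]


class _BatchNorm2d:
    """Per-channel batch normalisation with running statistics for eval."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = ad.Tensor(np.ones((1, channels, 1, 1), dtype=np.float32), requires_grad=True)
        self.beta = ad.Tensor(np.zeros((1, channels, 1, 1), dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros((1, channels, 1, 1), dtype=np.float32)
        self.running_var = np.ones((1, channels, 1, 1), dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: ad.Tensor, training: bool) -> ad.Tensor:
        if training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data)
            norm = xc * ((var + self.eps) ** -0.5)
        else:
            norm = (x - self.running_mean) * ((self.running_var + self.eps) ** -0.5)
        return norm * self.gamma + self.beta

    def parameters(self):
        return [self.gamma, self.beta]


class _DoubleConv:
    """(conv3x3 - BN - ReLU) x2, with dropout after the block in training mode."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, dropout: float):
        self.c1 = _Conv2d(cin, cout, rng)
        self.n1 = _BatchNorm2d(cout)
        self.c2 = _Conv2d(cout, cout, rng)
        self.n2 = _BatchNorm2d(cout)
        self.dropout = dropout

    def __call__(self, x: ad.Tensor, net: "SegmentationNet") -> ad.Tensor:
        h = ad.relu(self.n1(self.c1(x), net.training))
        h = ad.relu(self.n2(self.c2(h), net.training))
        if net.training and self.dropout > 0 and net._dropout_rng is not None:
            keep = 1.0 - self.dropout
            mask = (net._dropout_rng.random(h.data.shape) < keep).astype(np.float32) / keep
            h = h * mask
        return h

    def parameters(self):
        return (self.c1.parameters() + self.n1.parameters()
                + self.c2.parameters() + self.n2.parameters())


class _AttentionGate:
    """Additive attention gate: skip * sigmoid(psi(relu(Wg g + Wx x)))."""

    def __init__(self, gate_ch: int, skip_ch: int, rng: np.random.Generator):
        inter = max(skip_ch // 2, 1)
        self.wg = _Conv2d(gate_ch, inter, rng, kernel=1)
        self.wx = _Conv2d(skip_ch, inter, rng, kernel=1)
        self.psi = _Conv2d(inter, 1, rng, kernel=1)

    def __call__(self, gate: ad.Tensor, skip: ad.Tensor) -> ad.Tensor:
        att = ad.sigmoid(self.psi(ad.relu(self.wg(gate) + self.wx(skip))))
        return skip * att

    def parameters(self):
        return self.wg.parameters() + self.wx.parameters() + self.psi.parameters()


class _UpConv:
    """Nearest-neighbour 2x upsampling followed by a 3x3 channel-reducing conv."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv = _Conv2d(cin, cout, rng)

    def __call__(self, x: ad.Tensor) -> ad.Tensor:
        return ad.relu(self.conv(ad.upsample2x(x)))

    def parameters(self):
        return self.conv.parameters()


# -- networks -----------------------------------------------------------------


@dataclass
class SegmentationNet:
    """A parameterised segmentation network (forward via ``__call__``)."""

    spec: ModelSpec
    seed: int
    training: bool = False
    _blocks: dict = field(default_factory=dict, repr=False)
    _dropout_rng: np.random.Generator | None = field(default=None, repr=False)

    def __post_init__(self):
        rng = np.random.default_rng(self.seed)
        s, c, d = self.spec, self.spec.base_channels, self.spec.depth
        ch = [c * 2**i for i in range(d + 1)]  # encoder rows + bottleneck
        blocks = {}
        if s.architecture in ("unet", "attention_unet"):
            blocks["enc"] = [_DoubleConv(1 if i == 0 else ch[i - 1], ch[i], rng, s.dropout_rate)
                             for i in range(d)]
            blocks["bottleneck"] = _DoubleConv(ch[d - 1], ch[d], rng, s.dropout_rate)
            blocks["up"] = [_UpConv(ch[i + 1], ch[i], rng) for i in reversed(range(d))]
            blocks["dec"] = [_DoubleConv(2 * ch[i], ch[i], rng, s.dropout_rate)
                             for i in reversed(range(d))]
            if s.architecture == "attention_unet":
                blocks["gates"] = [_AttentionGate(ch[i], ch[i], rng) for i in reversed(range(d))]
        else:  # unet_plusplus
            nodes = {}
            for i in range(d + 1):
                nodes[(i, 0)] = _DoubleConv(1 if i == 0 else ch[i - 1], ch[i], rng, s.dropout_rate)
            for j in range(1, d + 1):
                for i in range(d + 1 - j):
                    cin = j * ch[i] + ch[i]  # j same-level skips + upsampled deeper node
                    nodes[(i, j)] = _DoubleConv(cin, ch[i], rng, s.dropout_rate)
            blocks["nodes"] = nodes
            blocks["ups"] = {(i, j): _UpConv(ch[i + 1], ch[i], rng)
                             for j in range(1, d + 1) for i in range(d + 1 - j)}
        blocks["head"] = _Conv2d(ch[0], 1, rng, kernel=1)
        # background-dominant prior: lesions cover a few percent of pixels,
        # so starting the output logits negative skips the phase where the
        # network must unlearn a 50/50 foreground prior
        blocks["head"].b.data[:] = -3.0
        self._blocks = blocks

    # -- bookkeeping ---------------------------------------------------------

    def parameters(self) -> list[ad.Tensor]:
        params: list[ad.Tensor] = []

        def collect(obj):
            if hasattr(obj, "parameters"):
                params.extend(obj.parameters())
            elif isinstance(obj, (list, tuple)):
                for o in obj:
                    collect(o)
            elif isinstance(obj, dict):
                for o in obj.values():
                    collect(o)

        collect(self._blocks)
        return params

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train_mode(self, dropout_rng: np.random.Generator | None = None) -> None:
        self.training = True
        self._dropout_rng = dropout_rng

    def eval_mode(self) -> None:
        self.training = False
        self._dropout_rng = None

    def _norm_layers(self) -> list["_BatchNorm2d"]:
        layers: list[_BatchNorm2d] = []

        def collect(obj):
            for attr in ("n1", "n2"):
                if hasattr(obj, attr):
                    layers.append(getattr(obj, attr))
            if isinstance(obj, (list, tuple)):
                for o in obj:
                    collect(o)
            elif isinstance(obj, dict):
                for o in obj.values():
                    collect(o)

        collect(self._blocks)
        return layers

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {str(i): p.data.copy() for i, p in enumerate(self.parameters())}
        for i, bn in enumerate(self._norm_layers()):
            state[f"bn{i}_mean"] = bn.running_mean.copy()
            state[f"bn{i}_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        norms = self._norm_layers()
        if len(state) != len(params) + 2 * len(norms):
            raise ValueError("state dict does not match the network's parameters")
        for i, p in enumerate(params):
            p.data = np.asarray(state[str(i)], dtype=np.float32).copy()
        for i, bn in enumerate(norms):
            bn.running_mean = np.asarray(state[f"bn{i}_mean"], dtype=np.float32).copy()
            bn.running_var = np.asarray(state[f"bn{i}_var"], dtype=np.float32).copy()

    # -- forward -------------------------------------------------------------

    def __call__(self, x) -> ad.Tensor:
        x = ad.as_tensor(x)
        if x.ndim == 2:
            x = x.reshape(1, 1, *x.shape)
        elif x.ndim == 3:
            x = x.reshape(x.shape[0], 1, *x.shape[1:])
        n, _, h, w = x.shape
        step = 2**self.spec.depth
        if h % step or w % step:
            raise InvalidShape(f"spatial shape {(h, w)} not divisible by 2**depth = {step}")
        if self.spec.architecture in ("unet", "attention_unet"):
            return self._forward_unet(x)
        return self._forward_nested(x)

    def _forward_unet(self, x: ad.Tensor) -> ad.Tensor:
        b = self._blocks
        skips = []
        h = x
        for enc in b["enc"]:
            h = enc(h, self)
            skips.append(h)
            h = ad.maxpool2x2(h)
        h = b["bottleneck"](h, self)
        for lvl, (up, dec) in enumerate(zip(b["up"], b["dec"])):
            h = up(h)
            skip = skips[-1 - lvl]
            if "gates" in b:
                skip = b["gates"][lvl](h, skip)
            h = dec(ad.concat([skip, h], axis=1), self)
        return b["head"](h)

    def _forward_nested(self, x: ad.Tensor) -> ad.Tensor:
        b = self._blocks
        d = self.spec.depth
        grid: dict[tuple[int, int], ad.Tensor] = {}
        h = x
        for i in range(d + 1):
            h = b["nodes"][(i, 0)](h, self)
            grid[(i, 0)] = h
            if i < d:
                h = ad.maxpool2x2(h)
        for j in range(1, d + 1):
            for i in range(d + 1 - j):
                up = b["ups"][(i, j)](grid[(i + 1, j - 1)])
                feats = [grid[(i, k)] for k in range(j)] + [up]
                grid[(i, j)] = b["nodes"][(i, j)](ad.concat(feats, axis=1), self)
        return b["head"](grid[(0, d)])


def build_model(spec: ModelSpec, seed: int) -> SegmentationNet:
    """Construct a network with deterministic seed-controlled initialisation."""
    return SegmentationNet(spec=spec, seed=int(seed))


def predict_mask(model: SegmentationNet, image) -> np.ndarray:
    """Hard binary mask from a [0,1] image: sigma(logits) > 0.5."""
    was_training, rng = model.training, model._dropout_rng
    model.eval_mode()
    arr = np.asarray(image, dtype=np.float32)
    batched = arr if arr.ndim == 3 else arr[None]
    chunks = []
    for start in range(0, len(batched), 32):  # bounded activation memory
        logits = model(batched[start:start + 32])
        chunks.append(logits.data.copy())
    if was_training:
        model.train_mode(rng)
    logits_all = np.concatenate(chunks, axis=0)
    mask = (logits_all > 0.0).astype(np.uint8)  # sigma(x) > 0.5 iff x > 0
    return mask[0, 0] if arr.ndim == 2 else mask[:, 0]
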