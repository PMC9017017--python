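"""Network architectures for nuclei analysis.

Four models share one construction kit:

* ``densenet`` / ``dcrn`` — densely connected classifiers (4 blocks of 7
  layers, growth rate 12).  Every layer sees the concatenation of all earlier
  feature maps; in the DCRN variant each layer is a recurrent convolution
  unrolled for ``time_steps`` steps instead of a plain one.
* ``r2unet`` — an encoder/decoder on the channel schedule
  1-32-64-128-256-128-64-32-1 whose convolutional units are recurrent, with
  skip concatenation between mirrored stages and a per-pixel softmax head.
* ``udnet`` — the same skeleton run as a regressor (``time_steps=3``,
  bounded sigmoid head) that predicts a Gaussian density surface for
  detection.

A recurrent convolutional layer computes, after a BN+ReLU pre-activation
``a``::

    h(0) = conv_f(a)
    h(s) = conv_f(a) + conv_r[s](h(s-1)),   s = 1..t

so the feed-forward response is carried additively through every unrolled
step.  ``weight_mode`` controls whether ``conv_r`` is one kernel reused each
step or a separate kernel per step; the recurrent kernel may be a dense or a
depthwise convolution.  The shipped per-variant defaults live in
``configs/architectures.yaml`` and were calibrated once against the published
parameter totals.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from . import nn
from .nn import autograd as ag
from .nn.autograd import Tensor

#: Feature maps are plain float32 arrays of shape (batch, height, width, channels).
FeatureMap = np.ndarray

CLASSIFIER_VARIANTS = ("densenet", "dcrn")
SEGMENTER_VARIANTS = ("r2unet", "udnet")
DEFAULT_SCHEDULE = (1, 32, 64, 128, 256, 128, 64, 32, 1)


def as_feature_map(values) -> FeatureMap:
    """Validate and coerce an array to a 4-D float32 feature map."""
    x = np.asarray(values, dtype=np.float32)
    if x.ndim != 4:
        raise ValueError(f"feature map must be 4-D (NHWC), got shape {x.shape}")
    if min(x.shape[1:]) < 1:
        raise ValueError("feature map dims must be positive")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature map contains non-finite values")
    return x


# ---------------------------------------------------------------------------
# configuration records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RCLConfig:
    """Recurrent convolutional layer configuration."""

    out_channels: int
    kernel_size: int = 3
    time_steps: int = 2
    weight_mode: str = "shared"           # shared | distinct
    recurrent_kernel: str = "full"        # full | depthwise
    bias: bool = True

    def __post_init__(self):
        if self.time_steps < 0:
            raise ValueError("time_steps must be non-negative")
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ValueError("kernel_size must be odd")
        if self.weight_mode not in ("shared", "distinct"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")
        if self.recurrent_kernel not in ("full", "depthwise"):
            raise ValueError(f"unknown recurrent_kernel {self.recurrent_kernel!r}")
        if self.out_channels < 1:
            raise ValueError("out_channels must be positive")


@dataclass(frozen=True)
class DenseBlockConfig:
    """Densely connected block: layer ``l`` has ``k*(l-1) + k0`` input maps."""

    input_channels: int
    num_layers: int = 7
    growth_rate: int = 12
    time_steps: int = 2
    weight_mode: str = "shared"
    recurrent_kernel: str = "full"

    def __post_init__(self):
        if self.num_layers < 0:
            raise ValueError("num_layers must be >= 0")
        if self.growth_rate < 1 or self.input_channels < 1:
            raise ValueError("growth_rate and input_channels must be >= 1")

    @property
    def output_channels(self) -> int:
        return self.input_channels + self.num_layers * self.growth_rate


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one of the four model variants."""

    variant: str
    input_shape: tuple = (32, 32, 3)
    num_outputs: int = 4
    channel_schedule: tuple = DEFAULT_SCHEDULE
    blocks: int = 4
    layers_per_block: int = 7
    growth_rate: int = 12
    time_steps: int = 2
    head: str = "softmax"                 # softmax | sigmoid-regression
    weight_mode: str = "shared"
    recurrent_kernel: str = "full"
    stem_channels: int = 160
    transition_channels: tuple = (256, 332, 300)
    upsample: str = "nearest"             # nearest | tconv
    residual_projection: str = "none"     # none | needed
    head_channels: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.variant not in CLASSIFIER_VARIANTS + SEGMENTER_VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant in SEGMENTER_VARIANTS:
            sched = tuple(self.channel_schedule)
            if sched != sched[::-1]:
                raise ValueError("encoder/decoder channel schedule must be symmetric")


def _manifest() -> dict:
    res = importlib.resources.files("nucleikit") / "configs" / "architectures.yaml"
    return yaml.safe_load(res.read_text())


def model_spec(variant: str, **overrides) -> ModelSpec:
    """The calibrated default :class:`ModelSpec` for a variant, with overrides."""
    manifest = _manifest()
    if variant not in manifest:
        raise ValueError(f"unknown variant {variant!r}; have {sorted(manifest)}")
    entry = dict(manifest[variant])
    entry.pop("task", None)
    entry = {k: tuple(v) if isinstance(v, list) else v for k, v in entry.items()}
    entry.update(overrides)
    return ModelSpec(**entry)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class RecurrentConvLayer(nn.Module):
    """BN -> ReLU -> iterated convolution (t = 0 reduces to a plain conv layer)."""

    def __init__(self, in_channels: int, cfg: RCLConfig,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.in_channels = in_channels
        self.bn = nn.BatchNorm2d(in_channels)
        self.conv_f = nn.Conv2d(in_channels, cfg.out_channels, cfg.kernel_size,
                                bias=cfg.bias, rng=rng)
        n_kernels = 0 if cfg.time_steps == 0 else (
            1 if cfg.weight_mode == "shared" else cfg.time_steps)
        self.recurrent = nn.ModuleList(
            self._make_recurrent(cfg, rng) for _ in range(n_kernels))

    @staticmethod
    def _make_recurrent(cfg: RCLConfig, rng) -> nn.Module:
        if cfg.recurrent_kernel == "depthwise":
            return nn.DepthwiseConv2d(cfg.out_channels, cfg.kernel_size, rng=rng)
        return nn.Conv2d(cfg.out_channels, cfg.out_channels, cfg.kernel_size,
                         bias=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        a = ag.relu(self.bn(x))
        f = self.conv_f(a)
        h = f
        for s in range(self.cfg.time_steps):
            rec = self.recurrent[0 if self.cfg.weight_mode == "shared" else s]
            h = ag.add(f, rec(h))
        return h


class RecurrentResidualUnit(nn.Module):
    """Identity skip around a stack of recurrent convolutional layers.

    The input is lifted to ``cfg.out_channels`` with a 1x1 projection when the
    channel counts differ, then ``n_layers`` recurrent conv layers form the
    branch ``F`` and the unit returns ``x + F(x)``.
    """

    def __init__(self, in_channels: int, cfg: RCLConfig, n_layers: int = 2,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.proj = None
        if in_channels != cfg.out_channels:
            self.proj = nn.Conv2d(in_channels, cfg.out_channels, 1,
                                  bias=cfg.bias, rng=rng)
        self.layers = nn.ModuleList(
            RecurrentConvLayer(cfg.out_channels, cfg, rng) for _ in range(n_layers))

    def forward(self, x: Tensor) -> Tensor:
        xp = self.proj(x) if self.proj is not None else x
        h = xp
        for layer in self.layers:
            h = layer(h)
        return ag.add(xp, h)


class DenseRecurrentBlock(nn.Module):
    """Dense connectivity: every layer consumes all earlier feature maps."""

    def __init__(self, cfg: DenseBlockConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        layers = []
        for layer_index in range(1, cfg.num_layers + 1):
            cin = cfg.growth_rate * (layer_index - 1) + cfg.input_channels
            layers.append(RecurrentConvLayer(
                cin,
                RCLConfig(out_channels=cfg.growth_rate,
                          time_steps=cfg.time_steps,
                          weight_mode=cfg.weight_mode,
                          recurrent_kernel=cfg.recurrent_kernel),
                rng))
        self.layers = nn.ModuleList(layers)

    def forward(self, x: Tensor) -> Tensor:
        feats = [x]
        for layer in self.layers:
            inp = feats[0] if len(feats) == 1 else ag.concat(feats, axis=-1)
            feats.append(layer(inp))
        return feats[0] if len(feats) == 1 else ag.concat(feats, axis=-1)


class TransitionBlock(nn.Module):
    """BN -> ReLU -> 1x1 conv -> 2x2 average pooling (halves spatial dims)."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.bn = nn.BatchNorm2d(in_channels)
        self.conv = nn.Conv2d(in_channels, out_channels, 1, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return ag.avg_pool2x2(self.conv(ag.relu(self.bn(x))))


# ---------------------------------------------------------------------------
# full models
# ---------------------------------------------------------------------------

class DenseClassifier(nn.Module):
    """DenseNet / DCRN classifier ending in global average pooling + softmax."""

    def __init__(self, spec: ModelSpec):
        super().__init__()
        rng = np.random.default_rng(spec.seed)
        self.spec = spec
        t = 0 if spec.variant == "densenet" else spec.time_steps
        in_ch = spec.input_shape[-1]
        self.stem = nn.Conv2d(in_ch, spec.stem_channels, 3, bias=True, rng=rng)
        blocks, transitions = [], []
        c = spec.stem_channels
        for b in range(spec.blocks):
            blocks.append(DenseRecurrentBlock(DenseBlockConfig(
                input_channels=c, num_layers=spec.layers_per_block,
                growth_rate=spec.growth_rate, time_steps=t,
                weight_mode=spec.weight_mode,
                recurrent_kernel=spec.recurrent_kernel), rng))
            c += spec.layers_per_block * spec.growth_rate
            if b < spec.blocks - 1:
                out = spec.transition_channels[b]
                transitions.append(TransitionBlock(c, out, rng))
                c = out
        self.blocks = nn.ModuleList(blocks)
        self.transitions = nn.ModuleList(transitions)
        self.feature_channels = c
        self.head_bn = nn.BatchNorm2d(c)
        self.classifier = nn.Linear(c, spec.num_outputs, rng=rng)

    def features(self, x: Tensor) -> Tensor:
        """Pre-head bottleneck representation: (n, feature_channels)."""
        x = self.stem(x)
        for b, block in enumerate(self.blocks):
            x = block(x)
            if b < len(self.transitions):
                x = self.transitions[b](x)
        return ag.global_avg_pool(ag.relu(self.head_bn(x)))

    def forward(self, x: Tensor) -> Tensor:
        """Class logits of shape (n, num_outputs)."""
        return self.classifier(self.features(x))

    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Softmax class probabilities for a float array of NHWC images in [0, 1]."""
        self.eval()
        out = []
        with ag.no_grad():
            for i in range(0, len(images), batch_size):
                logits = self(Tensor(images[i:i + batch_size]))
                out.append(ag.softmax(logits).data)
        return np.concatenate(out, axis=0)


class _CodecUnit(nn.Module):
    """One encoder/decoder stage: recurrent conv with optional residual projection."""

    def __init__(self, in_channels: int, cfg: RCLConfig, project: bool, rng):
        super().__init__()
        self.rcl = RecurrentConvLayer(in_channels, cfg, rng)
        self.proj = None
        if project:
            self.proj = nn.Conv2d(in_channels, cfg.out_channels, 1,
                                  bias=cfg.bias, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.rcl(x)
        if self.proj is not None:
            h = ag.add(h, self.proj(x))
        return h


class EncoderDecoder(nn.Module):
    """R2U-Net / UD-Net: symmetric encoder-decoder with skip concatenation."""

    def __init__(self, spec: ModelSpec):
        super().__init__()
        rng = np.random.default_rng(spec.seed)
        self.spec = spec
        sched = list(spec.channel_schedule)
        widths = sched[1:len(sched) // 2 + 1]        # e.g. [32, 64, 128, 256]
        self.depth = len(widths) - 1
        project = spec.residual_projection == "needed"

        def unit(cin, cout):
            cfg = RCLConfig(out_channels=cout, time_steps=spec.time_steps,
                            weight_mode=spec.weight_mode,
                            recurrent_kernel=spec.recurrent_kernel)
            return _CodecUnit(cin, cfg, project and cin != cout, rng)

        enc = [unit(sched[0], widths[0])]
        for cin, cout in zip(widths[:-1], widths[1:]):
            enc.append(unit(cin, cout))
        self.encoder = nn.ModuleList(enc)

        ups, dec = [], []
        for cskip in reversed(widths[1:]):           # 256, 128, 64
            cout = cskip // 2
            if spec.upsample == "tconv":
                ups.append(nn.ConvTranspose2x2(cskip, cout, bias=True, rng=rng))
                dec.append(unit(cout + cout, cout))
            else:
                ups.append(nn.UpsampleNearest2x())
                dec.append(unit(cskip + cout, cout))
        self.upsamplers = nn.ModuleList(ups)
        self.decoder = nn.ModuleList(dec)

        self.head_bn = nn.BatchNorm2d(widths[0])
        self.head_conv = nn.Conv2d(widths[0], spec.head_channels, 1,
                                   bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        """Per-pixel map (n, h, w): foreground probability or regressed density."""
        n, h, w, c = x.shape
        factor = 2 ** self.depth
        if h % factor or w % factor:
            raise ValueError(
                f"spatial dims must be multiples of {factor}, got {h}x{w}")
        skips = []
        for i, unit in enumerate(self.encoder):
            x = unit(x)
            if i < self.depth:
                skips.append(x)
                x = ag.max_pool2x2(x)
        for up, unit, skip in zip(self.upsamplers, self.decoder, reversed(skips)):
            x = ag.concat([up(x), skip], axis=-1)
            x = unit(x)
        x = self.head_conv(ag.relu(self.head_bn(x)))
        if self.spec.head == "sigmoid-regression":
            out = ag.sigmoid(x)
            return _squeeze_last(out)
        probs = ag.softmax(x, axis=-1)
        return _take_last(probs, 1)

    def predict_map(self, images: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Per-pixel output maps for NHWC (or NHW) float images in [0, 1]."""
        arr = np.asarray(images, dtype=np.float32)
        if arr.ndim == 3:
            arr = arr[..., None]
        self.eval()
        out = []
        with ag.no_grad():
            for i in range(0, len(arr), batch_size):
                out.append(self(Tensor(arr[i:i + batch_size])).data)
        return np.concatenate(out, axis=0)


def _squeeze_last(t: Tensor) -> Tensor:
    out = t.data[..., 0]

    def backward(g):
        ag._accum(t, g[..., None])

    return ag._make(out, (t,), backward)


def _take_last(t: Tensor, index: int) -> Tensor:
    out = np.ascontiguousarray(t.data[..., index])

    def backward(g):
        full = np.zeros_like(t.data)
        full[..., index] = g
        ag._accum(t, full, own=True)

    return ag._make(out, (t,), backward)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def build_model(spec: ModelSpec | str) -> nn.Module:
    """Construct a model from a spec (or variant name, using calibrated defaults)."""
    if isinstance(spec, str):
        spec = model_spec(spec)
    if spec.variant in CLASSIFIER_VARIANTS:
        return DenseClassifier(spec)
    if spec.variant in SEGMENTER_VARIANTS:
        return EncoderDecoder(spec)
    raise ValueError(f"unknown variant {spec.variant!r}")


def count_parameters(model: nn.Module) -> int:
    """Number of trainable scalars (BN scale/shift included, frozen excluded)."""
    return model.trainable_parameter_count


def _apply(module: nn.Module, x) -> FeatureMap:
    module.eval()
    with ag.no_grad():
        return module(Tensor(as_feature_map(x))).data


def recurrent_conv_layer(x, cfg: RCLConfig, seed: int = 0) -> FeatureMap:
    """Apply a freshly initialised recurrent conv layer (inference mode)."""
    x = as_feature_map(x)
    return _apply(RecurrentConvLayer(x.shape[-1], cfg,
                                     np.random.default_rng(seed)), x)


def recurrent_residual_unit(x, cfg: RCLConfig, n_layers: int = 2,
                            seed: int = 0) -> FeatureMap:
    x = as_feature_map(x)
    return _apply(RecurrentResidualUnit(x.shape[-1], cfg, n_layers,
                                        np.random.default_rng(seed)), x)


def dense_recurrent_block(x, cfg: DenseBlockConfig, seed: int = 0) -> FeatureMap:
    x = as_feature_map(x)
    if x.shape[-1] != cfg.input_channels:
        raise ValueError(
            f"input has {x.shape[-1]} channels, config says {cfg.input_channels}")
    return _apply(DenseRecurrentBlock(cfg, np.random.default_rng(seed)), x)


def transition_block(x, out_channels: int, seed: int = 0) -> FeatureMap:
    x = as_feature_map(x)
    return _apply(TransitionBlock(x.shape[-1], out_channels,
                                  np.random.default_rng(seed)), x)
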