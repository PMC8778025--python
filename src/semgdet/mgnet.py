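"""MGNet: MobileNetV2 bottlenecks + a Ghost stage, for signal images.

The feature extractor follows the MobileNetV2 inverted-residual design
(expand 1x1 -> depthwise 3x3 -> project 1x1, stride-2 convolutions
instead of pooling) with one change: the stage whose bottleneck would
repeat more than three times is replaced by a cycle of Ghost modules.
A Ghost module produces half its output channels with a pointwise 1x1
convolution and the other half with a cheap 3x3 depthwise convolution
applied to the primary half, then concatenates the two.

The default block table maps a 448x448x3 image through strides
2,1,2,2,2,2,1,2,1 to a 7x7x1280 feature map, global average pooling,
and a K=6 classifier head plus a two-scalar regression head (action
width, action peak).  The joint loss is

    loss = CrossEntropy + alpha * |width residual| + beta * |peak residual|

with alpha = 0.13 and beta = 0.26 by default.

A ``width_multiplier`` scales every channel count so scaled-down
training runs fit on one CPU; the audits run at multiplier 1.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .errors import ConfigError, ConstructionError, ValidationError

# ---------------------------------------------------------------------------
# Block specification


@dataclass(frozen=True)
class BlockSpec:
    """One row of the architecture table."""

    kind: str                  # conv | bottleneck | ghost | conv1x1 | avgpool | classifier
    t: int | None = None       # expansion factor
    c: int | None = None       # output channels
    n: int = 1                 # repetitions
    s: int = 1                 # stride (applied once per stage)


#: The default architecture, row for row.
DEFAULT_SPECS = (
    BlockSpec("conv", None, 32, 1, 2),
    BlockSpec("bottleneck", 1, 16, 1, 1),
    BlockSpec("bottleneck", 6, 24, 2, 2),
    BlockSpec("bottleneck", 6, 32, 3, 2),
    BlockSpec("ghost", None, 64, 4, 2),
    BlockSpec("bottleneck", 6, 96, 3, 2),
    BlockSpec("bottleneck", 6, 128, 3, 1),
    BlockSpec("bottleneck", 6, 160, 3, 2),
    BlockSpec("bottleneck", 6, 320, 1, 1),
    BlockSpec("conv1x1", None, 1280, 1, 1),
    BlockSpec("avgpool"),
    BlockSpec("classifier", c=6),
)

#: Declared (side, channels) entering each row for a 448x448x3 input.
DEFAULT_INPUT_SIZES = (
    (448, 3), (224, 32), (224, 16), (112, 24), (56, 32), (28, 64),
    (14, 96), (14, 128), (7, 160), (7, 320), (7, 1280), (1, 1280),
)


@dataclass(frozen=True)
class LossWeights:
    """Coefficients of the width (alpha) and peak (beta) residual terms."""

    alpha: float = 0.13
    beta: float = 0.26

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ConfigError("loss weights must be non-negative")


@dataclass(frozen=True)
class ClassifierTarget:
    """Label array (class, action width px, action peak px)."""

    class_id: int
    action_width: float
    action_peak: float

    def __post_init__(self):
        if self.action_width <= 0 or self.action_peak <= 0:
            raise ValidationError("action width and peak must be positive")


def _scale_channels(c: int, wm: float) -> int:
    """Scale a channel count, keeping it even (the Ghost split needs that)."""
    if wm == 1.0:
        return c
    return max(2, int(round(c * wm / 2)) * 2)


# ---------------------------------------------------------------------------
# Blocks


class Bottleneck(nn.Module):
    """Inverted residual: expand 1x1 -> depthwise 3x3 -> project 1x1.

    No expansion convolution when t == 1; a skip connection when the
    block keeps resolution and channel count.
    """

    def __init__(self, cin: int, cout: int, t: int, stride: int,
                 rng: np.random.Generator):
        hidden = cin * t
        if t != 1:
            self.expand_conv = nn.Conv2d(cin, hidden, 1, rng=rng)
            self.expand_bn = nn.BatchNorm2d(hidden)
            self.expand_act = nn.ReLU6()
        else:
            self.expand_conv = None
        self.dw_conv = nn.DepthwiseConv2d(hidden, 3, stride, rng=rng)
        self.dw_bn = nn.BatchNorm2d(hidden)
        self.dw_act = nn.ReLU6()
        self.project_conv = nn.Conv2d(hidden, cout, 1, rng=rng)
        self.project_bn = nn.BatchNorm2d(cout)
        self.use_skip = stride == 1 and cin == cout

    def forward(self, x):
        y = x
        if self.expand_conv is not None:
            y = self.expand_act.forward(self.expand_bn.forward(
                self.expand_conv.forward(y)))
        y = self.dw_act.forward(self.dw_bn.forward(self.dw_conv.forward(y)))
        y = self.project_bn.forward(self.project_conv.forward(y))
        return x + y if self.use_skip else y

    def backward(self, gout):
        g = self.project_conv.backward(self.project_bn.backward(gout))
        g = self.dw_conv.backward(self.dw_bn.backward(self.dw_act.backward(g)))
        if self.expand_conv is not None:
            g = self.expand_conv.backward(self.expand_bn.backward(
                self.expand_act.backward(g)))
        return gout + g if self.use_skip else g


class GhostModule(nn.Module):
    """Primary 1x1 conv for half the channels, cheap 3x3 depthwise for
    the other half, concatenated."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        if cout % 2:
            raise ConstructionError(
                f"ghost output channels must be even, got {cout}")
        half = cout // 2
        self.half = half
        self.primary_conv = nn.Conv2d(cin, half, 1, rng=rng)
        self.primary_bn = nn.BatchNorm2d(half)
        self.primary_act = nn.ReLU6()
        self.cheap_conv = nn.DepthwiseConv2d(half, 3, 1, rng=rng)
        self.cheap_bn = nn.BatchNorm2d(half)
        self.cheap_act = nn.ReLU6()

    def forward(self, x):
        p = self.primary_act.forward(self.primary_bn.forward(
            self.primary_conv.forward(x)))
        g = self.cheap_act.forward(self.cheap_bn.forward(
            self.cheap_conv.forward(p)))
        return np.concatenate([p, g], axis=1)

    def backward(self, gout):
        gp, gg = gout[:, :self.half], gout[:, self.half:]
        gp2 = self.cheap_conv.backward(self.cheap_bn.backward(
            self.cheap_act.backward(gg)))
        return self.primary_conv.backward(self.primary_bn.backward(
            self.primary_act.backward(gp + gp2)))


def ghost_forward(x: np.ndarray, out_channels: int,
                  rng: np.random.Generator | None = None,
                  module: GhostModule | None = None) -> np.ndarray:
    """Run one Ghost module on a feature map (convenience wrapper)."""
    if module is None:
        module = GhostModule(x.shape[1], out_channels,
                             rng or np.random.default_rng(0))
    return module.forward(x)


class BottleneckStage(nn.Module):
    def __init__(self, cin: int, cout: int, t: int, n: int, stride: int,
                 rng: np.random.Generator):
        self.blocks = [Bottleneck(cin, cout, t, stride, rng)]
        self.blocks += [Bottleneck(cout, cout, t, 1, rng) for _ in range(n - 1)]

    def forward(self, x):
        for b in self.blocks:
            x = b.forward(x)
        return x

    def backward(self, gout):
        for b in reversed(self.blocks):
            gout = b.backward(gout)
        return gout


class GhostStage(nn.Module):
    """n Ghost modules; a stride-2 depthwise conv downsamples at the end."""

    def __init__(self, cin: int, cout: int, n: int, stride: int,
                 rng: np.random.Generator):
        self.modules = [GhostModule(cin, cout, rng)]
        self.modules += [GhostModule(cout, cout, rng) for _ in range(n - 1)]
        if stride == 2:
            self.modules += [nn.DepthwiseConv2d(cout, 3, 2, rng=rng),
                             nn.BatchNorm2d(cout), nn.ReLU6()]

    def forward(self, x):
        for m in self.modules:
            x = m.forward(x)
        return x

    def backward(self, gout):
        for m in reversed(self.modules):
            gout = m.backward(gout)
        return gout


# ---------------------------------------------------------------------------
# The network


class MGNet(nn.Module):
    """Feature extractor + classifier + (width, peak) regression heads."""

    def __init__(self, specs=DEFAULT_SPECS, num_classes: int = 6,
                 width_multiplier: float = 1.0, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.specs = tuple(specs)
        self.num_classes = num_classes
        self.width_multiplier = width_multiplier
        self.stages = []
        self.stage_strides = []        # cumulative stride entering each stage
        self.classifier = None
        self.reg_head = None
        self.pool = None

        cin = 3
        cum = 1
        for spec in self.specs:
            if spec.kind == "conv":
                cout = _scale_channels(spec.c, width_multiplier)
                self.stages.append(nn.conv_bn_relu(cin, cout, 3, spec.s, rng))
            elif spec.kind == "bottleneck":
                cout = _scale_channels(spec.c, width_multiplier)
                self.stages.append(
                    BottleneckStage(cin, cout, spec.t, spec.n, spec.s, rng))
            elif spec.kind == "ghost":
                cout = _scale_channels(spec.c, width_multiplier)
                self.stages.append(GhostStage(cin, cout, spec.n, spec.s, rng))
            elif spec.kind == "conv1x1":
                cout = _scale_channels(spec.c, width_multiplier)
                self.stages.append(nn.conv_bn_relu(cin, cout, 1, 1, rng))
            elif spec.kind == "avgpool":
                self.pool = nn.GlobalAvgPool()
                cout = cin
            elif spec.kind == "classifier":
                self.classifier = nn.Linear(cin, spec.c, rng=rng)
                self.reg_head = nn.Linear(cin, 2, rng=rng)
                cout = spec.c
            else:
                raise ConstructionError(f"unknown block kind {spec.kind!r}")
            if spec.kind in ("conv", "bottleneck", "ghost", "conv1x1"):
                self.stage_strides.append(cum)
                cum *= spec.s
            cin = cout if spec.kind not in ("avgpool", "classifier") else cin
        if self.classifier is None or self.pool is None:
            raise ConstructionError("specs must end with avgpool + classifier")
        self.final_channels = self.stages and self._stage_out_channels()
        # deepest stage whose *output* stride is 16 / 32
        out_strides = [self.stage_strides[i + 1] if i + 1 < len(self.stage_strides)
                       else cum for i in range(len(self.stages))]
        self.tap_index = {}
        for target in (16, 32):
            idxs = [i for i, s in enumerate(out_strides) if s == target]
            if idxs:
                self.tap_index[target] = max(idxs)
        self._tap_cache = None

    def _stage_out_channels(self):
        sizes = []
        for spec in self.specs:
            if spec.kind in ("conv", "bottleneck", "ghost", "conv1x1"):
                sizes.append(_scale_channels(spec.c, self.width_multiplier))
        return sizes

    @property
    def cumulative_stride(self) -> int:
        s = 1
        for spec in self.specs:
            if spec.kind in ("conv", "bottleneck", "ghost", "conv1x1"):
                s *= spec.s
        return s

    # -- full classification path ------------------------------------------

    def forward(self, x):
        """x: (N, 3, H, W) float32 -> (logits (N, K), regression (N, 2))."""
        h = x
        for stage in self.stages:
            h = stage.forward(h)
        pooled = self.pool.forward(h)
        return self.classifier.forward(pooled), self.reg_head.forward(pooled)

    def backward(self, dlogits, dreg):
        g = self.classifier.backward(dlogits) + self.reg_head.backward(dreg)
        g = self.pool.backward(g)
        for stage in reversed(self.stages):
            g = stage.backward(g)
        return g

    # -- detector taps ------------------------------------------------------

    def forward_taps(self, x):
        """Run the backbone up to the stride-32 tap; return (f16, f32)."""
        if 16 not in self.tap_index or 32 not in self.tap_index:
            raise ConstructionError("backbone lacks stride-16/32 taps")
        i16, i32 = self.tap_index[16], self.tap_index[32]
        h = x
        f16 = None
        for i, stage in enumerate(self.stages[:i32 + 1]):
            h = stage.forward(h)
            if i == i16:
                f16 = h
        self._tap_cache = (i16, i32)
        return f16, h

    def backward_taps(self, g16, g32):
        i16, i32 = self._tap_cache
        g = g32
        for stage in reversed(self.stages[i16 + 1:i32 + 1]):
            g = stage.backward(g)
        g = g + g16
        for stage in reversed(self.stages[:i16 + 1]):
            g = stage.backward(g)
        return g


# ---------------------------------------------------------------------------
# Loss


def mgnet_loss(pred, target: ClassifierTarget,
               w: LossWeights = LossWeights()) -> float:
    """Joint loss for one sample.

    ``pred`` is (class_scores length-K, width, peak).  Cross-entropy on
    the class scores plus the weighted Manhattan distances of the width
    and peak predictions.
    """
    scores, width, peak = pred
    scores = np.asarray(scores, dtype=float)
    if not (np.isfinite(scores).all() and np.isfinite([width, peak]).all()):
        raise ValidationError("non-finite values in prediction")
    p = nn.softmax(scores[None, :], axis=1)[0]
    ce = -float(np.log(p[target.class_id - 1] + 1e-12))
    return (ce + w.alpha * abs(float(width) - target.action_width)
            + w.beta * abs(float(peak) - target.action_peak))


# ---------------------------------------------------------------------------
# Audits


def architecture_audit(net: MGNet, input_size: int = 448,
                       declared=DEFAULT_INPUT_SIZES) -> list:
    """Compare each row's declared input feature-map size with the size
    the built network actually produces, by running a forward pass."""
    x = np.zeros((1, 3, input_size, input_size), dtype=np.float32)
    actual = []
    h = x
    for stage in net.stages:
        actual.append((h.shape[2], h.shape[1]))
        h = stage.forward(h)
    actual.append((h.shape[2], h.shape[1]))            # entering avgpool
    pooled = net.pool.forward(h)
    actual.append((1, pooled.shape[1]))                # entering classifier
    rows = []
    for i, (dec, act) in enumerate(zip(declared, actual)):
        rows.append({"row": i, "declared": dec, "actual": act,
                     "match": dec == act})
    return rows


def count_parameters(net: nn.Module, include_bn: bool = True,
                     include_bias: bool = True) -> int:
    """Count trainable weights.

    ``include_bn`` counts batch-norm scale/shift pairs; ``include_bias``
    counts convolution/linear biases.  Kernel weights always count.
    """
    total = 0
    for mod in _walk(net):
        if isinstance(mod, nn.BatchNorm2d):
            if include_bn:
                total += mod.gamma.size + mod.beta.size
        elif isinstance(mod, (nn.Conv2d, nn.DepthwiseConv2d, nn.Linear)):
            total += mod.weight.size
            if include_bias and getattr(mod, "bias", None) is not None:
                total += mod.bias.size
    return total


def _walk(mod):
    yield mod
    for attr in vars(mod).values():
        if isinstance(attr, nn.Module):
            yield from _walk(attr)
        elif isinstance(attr, (list, tuple)):
            for item in attr:
                if isinstance(item, nn.Module):
                    yield from _walk(item)


def kernel_parameter_table(net: MGNet) -> list:
    """Per-kernel parameter counts in construction order, for auditing
    against a printed parameter table."""
    rows = []
    for mod in _walk(net):
        if isinstance(mod, nn.Conv2d):
            co, ci, k, _ = mod.weight.value.shape
            rows.append({"layer": f"conv {k}x{k}x{ci}x{co}",
                         "count": mod.weight.size})
        elif isinstance(mod, nn.DepthwiseConv2d):
            c, k, _ = mod.weight.value.shape
            rows.append({"layer": f"dw {k}x{k}x{c}", "count": mod.weight.size})
        elif isinstance(mod, nn.Linear):
            co, ci = mod.weight.value.shape
            rows.append({"layer": f"linear {ci}x{co}", "count": mod.weight.size})
    return rows


# ---------------------------------------------------------------------------
# Training


@dataclass
class TrainSpec:
    """Classifier training hyperparameters.

    Defaults follow the reference protocol (learning rate 3e-4, batch
    16, up to 3000 epochs, rate halved after 3 stagnant epochs,
    checkpoint every 200 epochs); scaled-down runs override
    ``max_epochs``, ``input_size`` and ``width_multiplier``.
    """

    lr: float = 3e-4
    batch_size: int = 16
    max_epochs: int = 3000
    lr_factor: float = 0.5
    lr_patience: int = 3
    checkpoint_every: int = 200
    out_dir: str | None = None
    seed: int = 0
    width_multiplier: float = 1.0
    input_size: int = 448
    num_classes: int = 6
    loss_weights: LossWeights = field(default_factory=LossWeights)


def _to_input(image) -> np.ndarray:
    pixels = image.pixels if hasattr(image, "pixels") else np.asarray(image)
    x = pixels.astype(np.float32) / 255.0 - 0.5
    return x.transpose(2, 0, 1)


def spec_hash(net: MGNet) -> str:
    payload = json.dumps([vars(s) for s in net.specs]
                         + [net.width_multiplier, net.num_classes])
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def save_checkpoint(net: MGNet, path) -> None:
    arrays = {f"p{i}": p.value for i, p in enumerate(net.params())}
    for i, bn in enumerate(m for m in _walk(net)
                           if isinstance(m, nn.BatchNorm2d)):
        arrays[f"rm{i}"] = bn.running_mean
        arrays[f"rv{i}"] = bn.running_var
    np.savez(path, spec_hash=np.array(spec_hash(net)), **arrays)


def load_checkpoint(net: MGNet, path) -> None:
    data = np.load(path, allow_pickle=False)
    if str(data["spec_hash"]) != spec_hash(net):
        raise ConfigError("checkpoint architecture hash does not match")
    for i, p in enumerate(net.params()):
        p.value[...] = data[f"p{i}"]
    for i, bn in enumerate(m for m in _walk(net)
                           if isinstance(m, nn.BatchNorm2d)):
        bn.running_mean[...] = data[f"rm{i}"]
        bn.running_var[...] = data[f"rv{i}"]


def train_classifier(dataset, hyper: TrainSpec = TrainSpec()):
    """Train MGNet on (image, ClassifierTarget) pairs.

    Returns (net, history); history has per-epoch loss and learning
    rate.  Deterministic for a fixed ``hyper.seed``.
    """
    if not dataset:
        raise ValidationError("empty training dataset")
    w = hyper.loss_weights
    net = MGNet(num_classes=hyper.num_classes,
                width_multiplier=hyper.width_multiplier, seed=hyper.seed)
    X = np.stack([_to_input(img) for img, _ in dataset])
    y = np.array([t.class_id - 1 for _, t in dataset])
    widths = np.array([t.action_width for _, t in dataset], dtype=np.float32)
    peaks = np.array([t.action_peak for _, t in dataset], dtype=np.float32)

    opt = nn.Adam(net.params(), lr=hyper.lr)
    sched = nn.ReduceLROnPlateau(opt, factor=hyper.lr_factor,
                                 patience=hyper.lr_patience)
    rng = np.random.default_rng(hyper.seed)
    history = {"epoch_loss": [], "lr": []}
    n = len(dataset)
    for epoch in range(hyper.max_epochs):
        order = rng.permutation(n)
        total, seen = 0.0, 0
        for start in range(0, n, hyper.batch_size):
            idx = order[start:start + hyper.batch_size]
            xb, yb = X[idx], y[idx]
            logits, reg = net.forward(xb)
            ce, dlogits = nn.softmax_cross_entropy(logits, yb)
            dw_res = reg[:, 0] - widths[idx]
            dh_res = reg[:, 1] - peaks[idx]
            loss = (ce + w.alpha * np.mean(np.abs(dw_res))
                    + w.beta * np.mean(np.abs(dh_res)))
            dreg = np.stack(
                [w.alpha * np.sign(dw_res), w.beta * np.sign(dh_res)],
                axis=1).astype(np.float32) / len(idx)
            opt.zero_grad()
            net.backward(dlogits, dreg)
            opt.step()
            total += loss * len(idx)
            seen += len(idx)
        epoch_loss = total / seen
        history["epoch_loss"].append(float(epoch_loss))
        history["lr"].append(opt.lr)
        sched.step(epoch_loss)
        if (hyper.out_dir is not None
                and (epoch + 1) % hyper.checkpoint_every == 0):
            out = Path(hyper.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            save_checkpoint(net, out / f"mgnet_epoch{epoch + 1:05d}.npz")
    return net, history


def predict_classifier(net: MGNet, images) -> tuple:
    """(class ids 1..K, widths, peaks) for a batch of images."""
    net.set_training(False)
    X = np.stack([_to_input(img) for img in images])
    logits, reg = net.forward(X)
    net.set_training(True)
    return logits.argmax(axis=1) + 1, reg[:, 0], reg[:, 1]
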