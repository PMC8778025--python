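"""Two-scale single-stage detector on the MGNet backbone.

The neck is a reduced PANet: the backbone is tapped at strides 16 and
32 (26x26 and 13x13 grids for a 416x416 input), laterally projected,
fused top-down (upsample + splice + conv) and bottom-up (stride-2 conv
+ splice + conv), and each fused scale feeds a 1x1 head that emits,
per grid cell and anchor, (tx, ty, th, tw, objectness, K class
scores).  Mosaic augmentation is deliberately unsupported.

Box-regression loss (per assigned anchor):

    loss = 1 - IoU + rho^2(d, d_gt) / c^2 + |L_gt/W_gt - L/W|

where rho is the centre distance, c the diagonal of the smallest box
enclosing both, L/W the half-width/half-height.  The aspect term is
wrapped in an absolute value by default (``absolute_aspect``); the raw
signed difference is available as mode ``literal``.

Soft non-maximum suppression decays overlapping same-class confidences
by a Gaussian factor exp(-IoU^2 / sigma) instead of deleting them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image

from . import nn
from .errors import ConfigError, ConstructionError, ValidationError
from .imaging import BoxLabel, SignalImage
from .mgnet import MGNet


# ---------------------------------------------------------------------------
# Geometry


@dataclass
class Box:
    """Axis-aligned box: centre + half extents, pixels."""

    cx: float
    cy: float
    half_w: float
    half_h: float

    def __post_init__(self):
        if self.half_w <= 0 or self.half_h <= 0:
            raise ValidationError(
                f"box half-extents must be positive, got "
                f"({self.half_w}, {self.half_h})")

    @property
    def corners(self) -> tuple:
        return (self.cx - self.half_w, self.cy - self.half_h,
                self.cx + self.half_w, self.cy + self.half_h)

    @property
    def area(self) -> float:
        return 4.0 * self.half_w * self.half_h

    @classmethod
    def from_label(cls, label: BoxLabel) -> "Box":
        return cls(float(label.cx), float(label.cy),
                   float(label.half_w), float(label.half_h))


def box_iou(a: Box, b: Box) -> float:
    ax0, ay0, ax1, ay1 = a.corners
    bx0, by0, bx1, by1 = b.corners
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (a.area + b.area - inter)


def detection_loss(pred: Box, gt: Box, mode: str = "absolute_aspect") -> float:
    """Box-regression loss: overlap + centre distance + aspect mismatch."""
    if mode not in ("absolute_aspect", "literal"):
        raise ConfigError(f"unknown loss mode {mode!r}")
    iou = box_iou(pred, gt)
    rho2 = (pred.cx - gt.cx) ** 2 + (pred.cy - gt.cy) ** 2
    px0, py0, px1, py1 = pred.corners
    gx0, gy0, gx1, gy1 = gt.corners
    ex0, ey0 = min(px0, gx0), min(py0, gy0)
    ex1, ey1 = max(px1, gx1), max(py1, gy1)
    c2 = (ex1 - ex0) ** 2 + (ey1 - ey0) ** 2
    aspect = gt.half_w / gt.half_h - pred.half_w / pred.half_h
    if mode == "absolute_aspect":
        aspect = abs(aspect)
    return (1.0 - iou) + rho2 / c2 + aspect


@dataclass
class Detection:
    box: Box
    class_id: int
    confidence: float
    image_path: str = ""

    def __post_init__(self):
        if not (0.0 <= self.confidence <= 1.0):
            raise ValidationError(
                f"confidence must be in [0, 1], got {self.confidence}")


@dataclass
class DetectorConfig:
    input_size: int = 416
    strides: tuple = (16, 32)
    anchors: tuple | None = None       # ((w, h) x3 for stride 16, x3 for 32)
    num_classes: int = 6
    neck_channels: int = 64
    conf_threshold: float = 0.3
    soft_nms_sigma: float = 0.5
    soft_nms_score_floor: float = 0.0498   # exp(-3): three sigma of decay

    def __post_init__(self):
        for s in self.strides:
            if self.input_size % s:
                raise ConfigError(
                    f"input size {self.input_size} not divisible by stride {s}")
        if self.anchors is None:
            # sensible defaults for signal-image boxes; training replaces
            # them with k-means anchors from the labels
            self.anchors = (((60.0, 30.0), (90.0, 60.0), (120.0, 90.0)),
                            ((150.0, 100.0), (200.0, 140.0), (280.0, 200.0)))

    @property
    def grids(self) -> tuple:
        return tuple(self.input_size // s for s in self.strides)

    @property
    def anchors_per_scale(self) -> int:
        return len(self.anchors[0])


# ---------------------------------------------------------------------------
# Soft NMS


def soft_nms(detections, cfg: DetectorConfig | None = None,
             sigma: float | None = None, score_floor: float | None = None):
    """Gaussian soft-NMS per class; the input list is left unmodified.

    Returns surviving detections ordered by decayed confidence.
    """
    cfg = cfg or DetectorConfig()
    sigma = cfg.soft_nms_sigma if sigma is None else sigma
    floor = cfg.soft_nms_score_floor if score_floor is None else score_floor
    remaining = [replace(d) for d in detections]
    kept = []
    while remaining:
        best = max(range(len(remaining)), key=lambda i: remaining[i].confidence)
        top = remaining.pop(best)
        if top.confidence < floor:
            continue
        kept.append(top)
        for d in remaining:
            if d.class_id != top.class_id or d.image_path != top.image_path:
                continue
            iou = box_iou(d.box, top.box)
            if iou > 0:
                decay = math.exp(-(iou ** 2) / sigma) if sigma > 0 else \
                    (0.0 if iou > 0 else 1.0)
                d.confidence *= decay
        remaining = [d for d in remaining if d.confidence >= floor]
    return kept


# ---------------------------------------------------------------------------
# Anchors


def kmeans_anchors(labels, k: int = 6, seed: int = 0, iters: int = 50) -> tuple:
    """K-means (IoU distance) on label box sizes; returns anchors split
    into (stride-16 triple, stride-32 triple), sorted by area."""
    wh = np.array([[2.0 * l.half_w, 2.0 * l.half_h] for l in labels], dtype=float)
    if len(wh) == 0:
        raise ValidationError("no labels to cluster")
    rng = np.random.default_rng(seed)
    if len(wh) < k:
        wh = np.vstack([wh] * int(np.ceil(k / len(wh))))
    centers = wh[rng.choice(len(wh), size=k, replace=False)]

    def wh_iou(boxes, cents):
        iw = np.minimum(boxes[:, None, 0], cents[None, :, 0])
        ih = np.minimum(boxes[:, None, 1], cents[None, :, 1])
        inter = iw * ih
        union = (boxes[:, 0] * boxes[:, 1])[:, None] + \
            (cents[:, 0] * cents[:, 1])[None, :] - inter
        return inter / union

    assign = None
    for _ in range(iters):
        new_assign = wh_iou(wh, centers).argmax(axis=1)
        if assign is not None and (new_assign == assign).all():
            break
        assign = new_assign
        for j in range(k):
            members = wh[assign == j]
            if len(members):
                centers[j] = np.median(members, axis=0)
    order = np.argsort(centers[:, 0] * centers[:, 1])
    centers = np.maximum(centers[order], 2.0)
    half = k // 2
    return (tuple(map(tuple, centers[:half])), tuple(map(tuple, centers[half:])))


# ---------------------------------------------------------------------------
# Network


class DetectorNet(nn.Module):
    """MGNet backbone + two-scale PANet neck + per-scale heads."""

    def __init__(self, backbone: MGNet, cfg: DetectorConfig, seed: int = 0):
        if 16 not in backbone.tap_index or 32 not in backbone.tap_index:
            raise ConstructionError("backbone lacks stride-16/32 taps")
        rng = np.random.default_rng(seed)
        self.backbone = backbone
        self.cfg = cfg
        ch = backbone._stage_out_channels()
        c16 = ch[backbone.tap_index[16]]
        c32 = ch[backbone.tap_index[32]]
        nc = cfg.neck_channels
        a = cfg.anchors_per_scale
        head_ch = a * (5 + cfg.num_classes)

        self.lat16 = nn.conv_bn_relu(c16, nc, 1, 1, rng)
        self.lat32 = nn.conv_bn_relu(c32, nc, 1, 1, rng)
        self.up = nn.Upsample2x()
        self.fuse16 = nn.conv_bn_relu(2 * nc, nc, 3, 1, rng)   # top-down splice
        self.down = nn.conv_bn_relu(nc, nc, 3, 2, rng)
        self.fuse32 = nn.conv_bn_relu(2 * nc, nc, 3, 1, rng)   # bottom-up splice
        self.head16 = nn.Conv2d(nc, head_ch, 1, rng=rng, bias=True)
        self.head32 = nn.Conv2d(nc, head_ch, 1, rng=rng, bias=True)
        # near-zero head init: raw outputs start ~0 so boxes start
        # anchor-sized at cell centres; objectness bias starts at a low
        # prior so the background is not half-confident at step one
        for head in (self.head16, self.head32):
            head.weight.value *= 0.03
            bias = head.bias.value.reshape(a, 5 + cfg.num_classes)
            bias[:, 4] = -2.0
        self._nc = nc

    def forward(self, x):
        f16, f32 = self.backbone.forward_taps(x)
        l16 = self.lat16.forward(f16)
        l32 = self.lat32.forward(f32)
        td = np.concatenate([l16, self.up.forward(l32)], axis=1)
        n16 = self.fuse16.forward(td)
        bu = np.concatenate([self.down.forward(n16), l32], axis=1)
        n32 = self.fuse32.forward(bu)
        return self.head16.forward(n16), self.head32.forward(n32)

    def backward(self, g_head16, g_head32):
        nc = self._nc
        g_n32 = self.head32.backward(g_head32)
        g_bu = self.fuse32.backward(g_n32)
        g_n16 = self.head16.backward(g_head16) + \
            self.down.backward(g_bu[:, :nc])
        g_l32 = g_bu[:, nc:]
        g_td = self.fuse16.backward(g_n16)
        g_l16 = g_td[:, :nc]
        g_l32 = g_l32 + self.up.backward(g_td[:, nc:])
        g_f16 = self.lat16.backward(g_l16)
        g_f32 = self.lat32.backward(g_l32)
        return self.backbone.backward_taps(g_f16, g_f32)


def build_detector(backbone: MGNet | None = None,
                   cfg: DetectorConfig = DetectorConfig(),
                   width_multiplier: float = 1.0, seed: int = 0) -> DetectorNet:
    """Assemble the detector; builds a fresh backbone when none given."""
    if backbone is None:
        backbone = MGNet(width_multiplier=width_multiplier, seed=seed)
    return DetectorNet(backbone, cfg, seed=seed)


# ---------------------------------------------------------------------------
# Decoding


def _reshape_raw(raw: np.ndarray, a: int, k: int):
    n, c, h, w = raw.shape
    if c != a * (5 + k):
        raise ConfigError(
            f"head channels {c} != anchors {a} x (5 + {k} classes)")
    return raw.reshape(n, a, 5 + k, h, w)


def decode_predictions(raw_outputs, cfg: DetectorConfig,
                       image_paths=None, apply_nms: bool = True) -> list:
    """Raw head tensors -> per-image lists of Detections.

    Per cell and anchor: centre = (cell + sigmoid(txy)) * stride, half
    extents = anchor/2 * exp(t), confidence = sigmoid(objectness) *
    sigmoid(best class score).
    """
    k = cfg.num_classes
    a = cfg.anchors_per_scale
    n_img = raw_outputs[0].shape[0]
    paths = image_paths or [""] * n_img
    per_image = [[] for _ in range(n_img)]
    for raw, stride, anchors in zip(raw_outputs, cfg.strides, cfg.anchors):
        r = _reshape_raw(raw, a, k)
        n, _, _, h, w = r.shape
        txy = nn.sigmoid(r[:, :, 0:2])
        th = np.exp(np.clip(r[:, :, 2], -3, 3))
        tw = np.exp(np.clip(r[:, :, 3], -3, 3))
        obj = nn.sigmoid(r[:, :, 4])
        cls = nn.sigmoid(r[:, :, 5:])
        gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        for img in range(n):
            for ai, (aw, ah) in enumerate(anchors):
                conf_cls = cls[img, ai].max(axis=0)
                cls_id = cls[img, ai].argmax(axis=0)
                conf = obj[img, ai] * conf_cls
                ys, xs = np.nonzero(conf >= cfg.conf_threshold)
                for y, x in zip(ys, xs):
                    per_image[img].append(Detection(
                        box=Box(
                            cx=(x + txy[img, ai, 0, y, x]) * stride,
                            cy=(y + txy[img, ai, 1, y, x]) * stride,
                            half_h=ah / 2.0 * th[img, ai, y, x],
                            half_w=aw / 2.0 * tw[img, ai, y, x],
                        ),
                        class_id=int(cls_id[y, x]) + 1,
                        confidence=float(conf[y, x]),
                        image_path=paths[img]))
    if apply_nms:
        per_image = [soft_nms(dets, cfg) for dets in per_image]
    return per_image


# ---------------------------------------------------------------------------
# Training


@dataclass
class DetectorTrainSpec:
    """Scaled-down detector training settings (demo profile defaults)."""

    input_size: int = 160
    width_multiplier: float = 0.25
    neck_channels: int = 32
    iterations: int = 300
    lr: float = 1e-3
    seed: int = 0
    mosaic: bool = False
    conf_threshold: float = 0.3
    # asymmetric objectness weights: one positive cell per image faces
    # hundreds of background cells, so positives are up-weighted
    obj_pos_weight: float = 20.0
    obj_neg_weight: float = 0.5
    eval_every: int = 0        # 0: no mid-run evaluation
    box_mode: str = "absolute_aspect"


def _prepare_sample(image, label: BoxLabel, size: int):
    """Resize image + rescale label to the detector input size."""
    pixels = image.pixels if isinstance(image, SignalImage) else np.asarray(image)
    h, w = pixels.shape[:2]
    if not label.inside(h, w):
        raise ValidationError(f"label {label.to_array()} outside {h}x{w} image")
    if (h, w) != (size, size):
        pil = Image.fromarray(pixels).resize((size, size), Image.BILINEAR)
        pixels = np.asarray(pil)
        sx, sy = size / w, size / h
        label = replace(label, cx=int(round(label.cx * sx)),
                        cy=int(round(label.cy * sy)),
                        half_w=max(int(round(label.half_w * sx)), 1),
                        half_h=max(int(round(label.half_h * sy)), 1))
    x = pixels.astype(np.float32) / 255.0 - 0.5
    return x.transpose(2, 0, 1), label


def _box_grad(pred: Box, gt: Box, mode: str, eps: float = 1e-3):
    """d detection_loss / d (cx, cy, half_w, half_h), central differences.

    The loss is a cheap scalar of four coordinates, so numerical
    differentiation here is exact enough (the loss is piecewise smooth)
    and avoids hand-deriving the IoU/enclosing-box gradients.
    """
    grads = np.zeros(4)
    base = [pred.cx, pred.cy, pred.half_w, pred.half_h]
    for i in range(4):
        hi, lo = list(base), list(base)
        hi[i] += eps
        lo[i] -= eps
        if i >= 2 and lo[i] <= 0:   # keep half-extents positive
            lo[i] = base[i]
        step = hi[i] - lo[i]
        grads[i] = (detection_loss(Box(*hi), gt, mode)
                    - detection_loss(Box(*lo), gt, mode)) / step
    return grads


def _assign_anchor(label: BoxLabel, cfg: DetectorConfig):
    """Best anchor (by width/height IoU) across both scales."""
    w, h = 2.0 * label.half_w, 2.0 * label.half_h
    best, best_iou = None, -1.0
    for si, anchors in enumerate(cfg.anchors):
        for ai, (aw, ah) in enumerate(anchors):
            inter = min(w, aw) * min(h, ah)
            iou = inter / (w * h + aw * ah - inter)
            if iou > best_iou:
                best_iou, best = iou, (si, ai)
    return best


def train_detector(dataset, hyper: DetectorTrainSpec = DetectorTrainSpec(),
                   test_dataset=None):
    """Train the detector to localise and classify action boxes.

    ``dataset`` is a list of (image, BoxLabel) pairs; images are
    resized to the configured input size (mosaic composition is
    rejected outright).  Loss per iteration = box-regression loss on
    assigned anchors + binary objectness cross-entropy everywhere +
    class cross-entropy on assigned anchors.

    Returns (net, cfg, history); history carries the train/test box
    and class loss curves.
    """
    if hyper.mosaic:
        raise ConfigError("mosaic augmentation is not supported by design")
    if not dataset:
        raise ValidationError("empty detector training dataset")

    size = hyper.input_size
    prepared = [_prepare_sample(img, lab, size) for img, lab in dataset]
    X = np.stack([x for x, _ in prepared])
    # every image needs a distinct id so evaluation matches per image
    labels = [replace(lab, image_path=lab.image_path or f"img{i}")
              for i, (_, lab) in enumerate(prepared)]
    anchors = kmeans_anchors(labels, k=6, seed=hyper.seed)
    cfg = DetectorConfig(input_size=size, anchors=anchors,
                         neck_channels=hyper.neck_channels,
                         conf_threshold=hyper.conf_threshold)
    net = build_detector(cfg=cfg, width_multiplier=hyper.width_multiplier,
                         seed=hyper.seed)
    opt = nn.Adam(net.params(), lr=hyper.lr)
    k = cfg.num_classes
    a = cfg.anchors_per_scale

    test_X, test_labels = None, None
    if test_dataset:
        tp = [_prepare_sample(img, lab, size) for img, lab in test_dataset]
        test_X = np.stack([x for x, _ in tp])
        test_labels = [lab for _, lab in tp]

    history = {"box_loss": [], "cls_loss": [], "obj_loss": [],
               "test_box_loss": [], "test_cls_loss": [], "map50": []}

    assignments = [ _assign_anchor(lab, cfg) for lab in labels ]

    def run_losses(raw16, raw32, labels_, assignments_, with_grad: bool):
        raws = [_reshape_raw(raw16, a, k), _reshape_raw(raw32, a, k)]
        grads = [np.zeros_like(r) for r in raws] if with_grad else None
        box_loss = cls_loss = 0.0
        n_img = raws[0].shape[0]
        for img in range(n_img):
            lab = labels_[img]
            si, ai = assignments_[img]
            stride = cfg.strides[si]
            aw, ah = cfg.anchors[si][ai]
            gx = min(int(lab.cx // stride), raws[si].shape[4] - 1)
            gy = min(int(lab.cy // stride), raws[si].shape[3] - 1)
            r = raws[si][img, ai, :, gy, gx]
            sx, sy = nn.sigmoid(r[0:2])
            eh = float(np.exp(np.clip(r[2], -3, 3)))
            ew = float(np.exp(np.clip(r[3], -3, 3)))
            pred = Box(cx=(gx + sx) * stride, cy=(gy + sy) * stride,
                       half_w=aw / 2.0 * ew, half_h=ah / 2.0 * eh)
            gt = Box.from_label(lab)
            box_loss += detection_loss(pred, gt, hyper.box_mode)
            cls_logits = r[5:]
            target = np.zeros(k)
            target[lab.class_id - 1] = 1.0
            l_cls, d_cls = nn.bce_with_logits(cls_logits, target)
            cls_loss += l_cls
            if with_grad:
                # clip the raw box gradient: the aspect term is unbounded
                # and can otherwise drive exponential scale runaway
                db = np.clip(_box_grad(pred, gt, hyper.box_mode), -2.0, 2.0) / n_img
                g = grads[si][img, ai, :, gy, gx]
                g[0] = db[0] * stride * sx * (1 - sx)
                g[1] = db[1] * stride * sy * (1 - sy)
                g[2] = db[3] * pred.half_h   # d half_h / d t_h = half_h
                g[3] = db[2] * pred.half_w
                # respect the exp clamp: no gradient pushing past +-3
                if (r[2] >= 3 and g[2] < 0) or (r[2] <= -3 and g[2] > 0):
                    g[2] = 0.0
                if (r[3] >= 3 and g[3] < 0) or (r[3] <= -3 and g[3] > 0):
                    g[3] = 0.0
                grads[si][img, ai, 5:, gy, gx] = d_cls * k / n_img
        # objectness over every cell/anchor of both scales
        obj_loss = 0.0
        for si in (0, 1):
            obj_target = np.zeros_like(raws[si][:, :, 4])
            for img in range(n_img):
                lab, (s_a, ai) = labels_[img], assignments_[img]
                if s_a == si:
                    stride = cfg.strides[si]
                    gx = min(int(lab.cx // stride), raws[si].shape[4] - 1)
                    gy = min(int(lab.cy // stride), raws[si].shape[3] - 1)
                    obj_target[img, ai, gy, gx] = 1.0
            # sum over cells, mean over images; positives up-weighted
            z = raws[si][:, :, 4].astype(np.float64)
            sig = nn.sigmoid(z)
            wmap = np.where(obj_target > 0, hyper.obj_pos_weight,
                            hyper.obj_neg_weight)
            per_cell = (np.maximum(z, 0) - z * obj_target
                        + np.log1p(np.exp(-np.abs(z))))
            obj_loss += float(np.sum(wmap * per_cell) / n_img)
            if with_grad:
                grads[si][:, :, 4] += (wmap * (sig - obj_target)
                                       / n_img).astype(np.float32)
        box_loss /= n_img
        cls_loss /= n_img
        if with_grad:
            g16 = grads[0].reshape(raw16.shape)
            g32 = grads[1].reshape(raw32.shape)
            return box_loss, cls_loss, obj_loss, g16, g32
        return box_loss, cls_loss, obj_loss

    for it in range(hyper.iterations):
        raw16, raw32 = net.forward(X)
        box_l, cls_l, obj_l, g16, g32 = run_losses(
            raw16, raw32, labels, assignments, with_grad=True)
        opt.zero_grad()
        net.backward(g16.astype(np.float32), g32.astype(np.float32))
        opt.step()
        history["box_loss"].append(box_l)
        history["cls_loss"].append(cls_l)
        history["obj_loss"].append(obj_l)
        if test_X is not None:
            net.set_training(False)
            t16, t32 = net.forward(test_X)
            tb, tc, _ = run_losses(t16, t32, test_labels,
                                   [_assign_anchor(l, cfg) for l in test_labels],
                                   with_grad=False)
            net.set_training(True)
            history["test_box_loss"].append(tb)
            history["test_cls_loss"].append(tc)
        if hyper.eval_every and (it + 1) % hyper.eval_every == 0:
            from .evaluation import mean_ap
            dets = predict(net, X, cfg,
                           image_paths=[l.image_path for l in labels])
            flat = [d for dd in dets for d in dd]
            history["map50"].append(mean_ap(flat, labels).map50)
    return net, cfg, history


def predict(net: DetectorNet, images, cfg: DetectorConfig,
            image_paths=None) -> list:
    """Detections per image (images already network-shaped NCHW or a
    list of SignalImage/HWC arrays)."""
    if isinstance(images, np.ndarray) and images.ndim == 4:
        X = images
    else:
        planes = []
        for img in images:
            pixels = img.pixels if isinstance(img, SignalImage) else np.asarray(img)
            if pixels.shape[:2] != (cfg.input_size, cfg.input_size):
                pil = Image.fromarray(pixels).resize(
                    (cfg.input_size, cfg.input_size), Image.BILINEAR)
                pixels = np.asarray(pil)
            planes.append(pixels.astype(np.float32).transpose(2, 0, 1)
                          / 255.0 - 0.5)
        X = np.stack(planes)
    net.set_training(False)
    raw16, raw32 = net.forward(X)
    net.set_training(True)
    return decode_predictions([raw16, raw32], cfg, image_paths=image_paths)
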