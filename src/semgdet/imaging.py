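"""Signal-image rendering, rectangle labels and augmentation.

The classifier and detector consume *signal images*: a fixed-size
(default 448x448) plot of the fused sEMG trace, amplitude against
time, drawn as a 2-px dark line on a white background with no axes or
text.  The axis maps are explicit and invertible so that box geometry
can be converted back to physical quantities:

* time -> x: linear over the record duration across the image width;
* amplitude -> y: linear, zero amplitude on the baseline row (image
  centre), y increasing downward, with a dataset-wide full-scale
  amplitude so the same voltage lands on the same row in every image.

A rectangle label covers the action: horizontally from burst start to
burst end, vertically from the baseline row to the peak-excursion row.
Labels are stored centre + half-extents in the array order
``[cx, cy, half_h, half_w]`` and serialized to JSON companion files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .errors import LabelSchemaError, NoLabelError, ValidationError
from .synth import SemgRecord

_BG = 255
_FG = 0
_LINE_WIDTH = 2


@dataclass
class AxisMapping:
    """Invertible linear maps between (time, amplitude) and pixels."""

    duration: float        # seconds across the full width
    width: int
    height: int
    amp_range: float       # amplitude (mV) mapped to full half-height
    margin: int = 8        # rows kept clear at top/bottom

    @property
    def baseline_row(self) -> float:
        return (self.height - 1) / 2.0

    @property
    def px_per_mv(self) -> float:
        return (self.baseline_row - self.margin) / self.amp_range

    def x_of_time(self, t) -> np.ndarray:
        return np.asarray(t) / self.duration * (self.width - 1)

    def time_of_x(self, x) -> np.ndarray:
        return np.asarray(x) * self.duration / (self.width - 1)

    def y_of_amp(self, a) -> np.ndarray:
        return self.baseline_row - np.asarray(a) * self.px_per_mv

    def amp_of_y(self, y) -> np.ndarray:
        return (self.baseline_row - np.asarray(y)) / self.px_per_mv


@dataclass
class SignalImage:
    """Rendered signal plot plus the axis maps that produced it."""

    pixels: np.ndarray          # H x W x 3 uint8
    axis: AxisMapping
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValidationError(f"pixels must be HxWx3, got {self.pixels.shape}")

    @property
    def size(self) -> tuple:
        return self.pixels.shape[0], self.pixels.shape[1]

    def to_pil(self) -> Image.Image:
        return Image.fromarray(self.pixels)

    def save(self, path) -> None:
        self.to_pil().save(path)


@dataclass
class BoxLabel:
    """Rectangle label: centre + half-extents, array form [cx, cy, half_h, half_w].

    ``half_h`` is the distance from the upper boundary of the box to its
    centre, ``half_w`` from the left boundary to the centre.
    """

    cx: int
    cy: int
    half_h: int
    half_w: int
    class_id: int
    image_path: str = ""

    def __post_init__(self):
        if self.half_h <= 0 or self.half_w <= 0:
            raise ValidationError(
                f"box half-extents must be positive, got ({self.half_h}, {self.half_w})"
            )

    def to_array(self) -> list:
        return [self.cx, self.cy, self.half_h, self.half_w]

    @property
    def corners(self) -> tuple:
        return (self.cx - self.half_w, self.cy - self.half_h,
                self.cx + self.half_w, self.cy + self.half_h)

    def inside(self, height: int, width: int) -> bool:
        x0, y0, x1, y1 = self.corners
        return x0 >= 0 and y0 >= 0 and x1 <= width - 1 and y1 <= height - 1


def render_signal_image(record: SemgRecord, size: int = 448,
                        amp_range: float | None = None) -> SignalImage:
    """Render a single-channel record as a deterministic line plot.

    ``amp_range`` is the amplitude that maps to the full half-height;
    pass the dataset-wide maximum so box ordinates are comparable
    across images (``dataset_amp_range``).  Defaults to this record's
    own maximum absolute amplitude.
    """
    if record.n_samples == 0:
        raise ValidationError("cannot render an empty record")
    if record.n_channels != 1:
        raise ValidationError(
            f"render expects a single (fused) channel, got {record.n_channels}"
        )
    x = record.samples[0]
    if amp_range is None:
        amp_range = float(np.max(np.abs(x)))
    if amp_range <= 0:
        amp_range = 1.0
    axis = AxisMapping(duration=record.duration, width=size, height=size,
                       amp_range=amp_range)
    xs = axis.x_of_time(record.times)
    ys = axis.y_of_amp(x)
    img = Image.new("RGB", (size, size), (_BG, _BG, _BG))
    draw = ImageDraw.Draw(img)
    draw.line(list(zip(xs.tolist(), ys.tolist())), fill=(_FG, _FG, _FG),
              width=_LINE_WIDTH)
    return SignalImage(pixels=np.asarray(img), axis=axis,
                       meta={"motion_id": record.motion.id,
                             "angle_fraction": record.angle_fraction})


def dataset_amp_range(records) -> float:
    """Dataset-wide full-scale amplitude (max absolute sample)."""
    return float(max(np.max(np.abs(r.samples)) for r in records))


def auto_label(image: SignalImage, record: SemgRecord,
               image_path: str = "") -> BoxLabel:
    """Derive the rectangle label from the record's ground truth.

    Horizontal extent: burst start to burst end.  Vertical extent:
    baseline row to the row of the peak excursion (signed, so
    opposite-going antagonist actions get boxes on opposite sides of
    the baseline).  The centre ordinate therefore encodes the action's
    peak voltage.
    """
    b0, b1 = record.burst_extent
    if record.peak <= 0 or b1 <= b0 or np.max(np.abs(record.samples)) == 0:
        raise NoLabelError("record contains no action burst to label")
    axis = image.axis
    x0 = float(axis.x_of_time(b0))
    x1 = float(axis.x_of_time(b1))
    sig = record.samples[0]
    extreme = float(sig[np.argmax(np.abs(sig))])   # signed peak excursion
    y_peak = float(axis.y_of_amp(extreme))
    y_base = axis.baseline_row
    top, bottom = min(y_base, y_peak), max(y_base, y_peak)
    h_px, w_px = image.size
    cx = int(round((x0 + x1) / 2))
    cy = int(round((top + bottom) / 2))
    # clamp so the box stays fully inside the image after rounding
    half_w = max(min(int(round((x1 - x0) / 2)), cx, w_px - 1 - cx), 1)
    half_h = max(min(int(round((bottom - top) / 2)), cy, h_px - 1 - cy), 1)
    return BoxLabel(cx=cx, cy=cy, half_h=half_h, half_w=half_w,
                    class_id=record.motion.id, image_path=image_path)


_LABEL_KEYS = ("image_path", "class_id", "cx", "cy", "half_h", "half_w")


def write_labels_json(labels, path) -> None:
    """Serialize labels to a JSON array of objects."""
    payload = [
        {"image_path": l.image_path, "class_id": l.class_id, "cx": l.cx,
         "cy": l.cy, "half_h": l.half_h, "half_w": l.half_w}
        for l in labels
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_labels_json(path) -> list:
    """Read labels; schema violations raise LabelSchemaError naming the key."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise LabelSchemaError(f"{path}: malformed JSON at line {e.lineno}: {e.msg}")
    if not isinstance(payload, list):
        raise LabelSchemaError(f"{path}: top level must be a JSON array")
    labels = []
    for i, obj in enumerate(payload):
        for key in _LABEL_KEYS:
            if key not in obj:
                raise LabelSchemaError(f"{path}: label {i} missing key {key!r}")
        labels.append(BoxLabel(cx=int(obj["cx"]), cy=int(obj["cy"]),
                               half_h=int(obj["half_h"]),
                               half_w=int(obj["half_w"]),
                               class_id=int(obj["class_id"]),
                               image_path=str(obj["image_path"])))
    return labels


# ---------------------------------------------------------------------------
# Augmentation


@dataclass
class AugmentSpec:
    """Bounded, label-consistent augmentation settings.

    ops is a subset of {horizontal_flip, shift_crop, color_jitter,
    rotate, random_scale}.  Geometric magnitudes are bounded so boxes
    stay inside the image; out-of-image boxes are clipped or rejected
    per ``out_of_image``.
    """

    ops: tuple = ("horizontal_flip", "shift_crop", "color_jitter",
                  "rotate", "random_scale")
    max_shift: int = 16
    max_rotate: float = 5.0     # degrees
    scale_range: tuple = (0.9, 1.1)
    jitter: float = 0.15        # relative brightness jitter
    out_of_image: str = "clip"  # or "reject"
    seed: int = 0


def _affine_pixels(image: SignalImage, fwd: np.ndarray) -> np.ndarray:
    """Apply a forward 2x3 affine map to the pixels (white fill)."""
    a, b, c = fwd[0]
    d, e, f = fwd[1]
    det = a * e - b * d
    inv = np.array([[e / det, -b / det, (b * f - c * e) / det],
                    [-d / det, a / det, (c * d - a * f) / det]])
    h, w = image.size
    out = image.to_pil().transform(
        (w, h), Image.AFFINE,
        (inv[0, 0], inv[0, 1], inv[0, 2], inv[1, 0], inv[1, 1], inv[1, 2]),
        resample=Image.NEAREST, fillcolor=(_BG, _BG, _BG))
    return np.asarray(out)


def _affine_label(label: BoxLabel, fwd: np.ndarray, height: int, width: int,
                  mode: str) -> BoxLabel:
    x0, y0, x1, y1 = label.corners
    corners = np.array([[x0, y0, 1], [x1, y0, 1], [x0, y1, 1], [x1, y1, 1]]).T
    mapped = fwd @ corners
    nx0, ny0 = mapped[0].min(), mapped[1].min()
    nx1, ny1 = mapped[0].max(), mapped[1].max()
    if mode == "reject":
        if nx0 < 0 or ny0 < 0 or nx1 > width - 1 or ny1 > height - 1:
            raise ValidationError("augmentation pushed the box out of the image")
    else:
        nx0, ny0 = max(nx0, 0.0), max(ny0, 0.0)
        nx1, ny1 = min(nx1, width - 1.0), min(ny1, height - 1.0)
    if nx1 <= nx0 or ny1 <= ny0:
        raise ValidationError("augmentation pushed the box out of the image")
    return replace(label,
                   cx=int(round((nx0 + nx1) / 2)),
                   cy=int(round((ny0 + ny1) / 2)),
                   half_w=max(int(round((nx1 - nx0) / 2)), 1),
                   half_h=max(int(round((ny1 - ny0) / 2)), 1))


def horizontal_flip(image: SignalImage, label: BoxLabel):
    """Mirror time; an involution on both pixels and label."""
    w = image.size[1]
    pixels = np.ascontiguousarray(image.pixels[:, ::-1])
    return (replace(image, pixels=pixels),
            replace(label, cx=w - 1 - label.cx))


def shift(image: SignalImage, label: BoxLabel, dx: int, dy: int,
          mode: str = "clip"):
    fwd = np.array([[1.0, 0.0, float(dx)], [0.0, 1.0, float(dy)]])
    h, w = image.size
    return (replace(image, pixels=_affine_pixels(image, fwd)),
            _affine_label(label, fwd, h, w, mode))


def rotate(image: SignalImage, label: BoxLabel, degrees: float,
           mode: str = "clip"):
    """Rotate pixels and box about the image centre."""
    if degrees == 0.0:
        return image, label
    h, w = image.size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    th = np.deg2rad(degrees)
    co, si = np.cos(th), np.sin(th)
    fwd = np.array([[co, -si, cx - co * cx + si * cy],
                    [si, co, cy - si * cx - co * cy]])
    return (replace(image, pixels=_affine_pixels(image, fwd)),
            _affine_label(label, fwd, h, w, mode))


def random_scale(image: SignalImage, label: BoxLabel, factor: float,
                 mode: str = "clip"):
    """Scale pixels and box about the image centre."""
    if factor == 1.0:
        return image, label
    h, w = image.size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    fwd = np.array([[factor, 0.0, cx * (1 - factor)],
                    [0.0, factor, cy * (1 - factor)]])
    return (replace(image, pixels=_affine_pixels(image, fwd)),
            _affine_label(label, fwd, h, w, mode))


def color_jitter(image: SignalImage, label: BoxLabel, factors):
    """Per-channel brightness scaling; the label is untouched."""
    f = np.asarray(factors, dtype=float).reshape(1, 1, 3)
    pixels = np.clip(image.pixels.astype(float) * f, 0, 255).astype(np.uint8)
    return replace(image, pixels=pixels), label


def augment(image: SignalImage, label: BoxLabel, spec: AugmentSpec,
            rng: np.random.Generator | None = None):
    """Apply the enabled ops with randomly drawn, bounded magnitudes."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    img, lab = image, label
    for op in spec.ops:
        if op == "horizontal_flip":
            if rng.random() < 0.5:
                img, lab = horizontal_flip(img, lab)
        elif op == "shift_crop":
            dx = int(rng.integers(-spec.max_shift, spec.max_shift + 1))
            dy = int(rng.integers(-spec.max_shift, spec.max_shift + 1))
            img, lab = shift(img, lab, dx, dy, spec.out_of_image)
        elif op == "color_jitter":
            factors = 1.0 + rng.uniform(-spec.jitter, spec.jitter, size=3)
            img, lab = color_jitter(img, lab, factors)
        elif op == "rotate":
            img, lab = rotate(img, lab,
                              float(rng.uniform(-spec.max_rotate, spec.max_rotate)),
                              spec.out_of_image)
        elif op == "random_scale":
            img, lab = random_scale(img, lab,
                                    float(rng.uniform(*spec.scale_range)),
                                    spec.out_of_image)
        else:
            raise ValidationError(f"unknown augmentation op {op!r}")
    return img, lab
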