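"""Maximum joint-angle decoding from box geometry.

The centre ordinate of an action's box encodes the peak voltage of
the movement, which in turn encodes how far the joint travelled.  With
``h`` the reference-frame centre ordinate (full-range action) and
``h'`` the predicted-frame centre ordinate, the decoded maximum angle
is

    C_pre = (h' / h) * C_max   if |h'| < |h|
    C_pre = C_max              otherwise

i.e. the prediction saturates at the joint's anatomical maximum
C_max.  Ordinates are measured relative to the rendered baseline row
(the zero-voltage axis), which makes the absolute values meaningful
for excursions below the baseline.

Only the elbow maximum (135 deg) is fixed by the reference protocol;
the wrist defaults (flexion/extension 80 deg, pronation/supination
90 deg) are package conventions, overridable in config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DomainError

DEFAULT_MAX_ANGLES = {"elbow": 135.0, "wrist_fe": 80.0, "wrist_ps": 90.0}


@dataclass(frozen=True)
class AngleSpec:
    """Per-joint maximum motion angle, degrees."""

    max_angles: dict = field(default_factory=lambda: dict(DEFAULT_MAX_ANGLES))

    def __post_init__(self):
        for joint, c_max in self.max_angles.items():
            if c_max <= 0:
                raise ConfigError(f"max angle for {joint!r} must be > 0")

    def c_max(self, joint: str) -> float:
        try:
            return self.max_angles[joint]
        except KeyError:
            raise KeyError(f"unknown joint {joint!r}") from None


def decode_angle(h_pred: float, h_ref: float, spec: AngleSpec = AngleSpec(),
                 joint: str = "elbow") -> float:
    """Decode the predicted maximum joint angle, degrees.

    ``h_pred`` (h') and ``h_ref`` (h) are the prediction- and
    reference-frame centre ordinates relative to the baseline row.
    ``|h'| >= |h|`` saturates at C_max; the two branches agree at
    ``|h'| == |h|``.
    """
    if not (np.isfinite(h_pred) and np.isfinite(h_ref)):
        raise DomainError("box ordinates must be finite")
    if h_ref == 0:
        raise DomainError("reference ordinate h must be non-zero")
    c_max = spec.c_max(joint)
    if abs(h_pred) < abs(h_ref):
        return (h_pred / h_ref) * c_max
    return c_max


def joint_of_motion(motion_id: int) -> str:
    """Map a motion class id (1..6) to its joint group."""
    if motion_id in (1, 2):
        return "wrist_fe"
    if motion_id in (3, 4):
        return "wrist_ps"
    if motion_id in (5, 6):
        return "elbow"
    raise DomainError(f"motion id must be 1..6, got {motion_id}")


def ordinate_from_box(cy: float, baseline_row: float) -> float:
    """Box-centre ordinate measured from the rendered baseline row.

    Positive when the box centre sits above the baseline (smaller pixel
    row), i.e. excursions drawn upward.
    """
    return baseline_row - cy


def angle_from_detection(det_box, ref_box=None, baseline_row: float | None = None,
                         full_scale_h: float | None = None,
                         spec: AngleSpec = AngleSpec(),
                         joint: str = "elbow") -> float:
    """Decode an angle from a predicted box.

    Two reference modes:

    * against a labelled reference frame (``ref_box``), as in validation
      against ground truth;
    * against a calibrated full-scale ordinate (``full_scale_h``), for
      inference on new images where no reference frame exists.

    ``baseline_row`` converts raw pixel rows to baseline-relative
    ordinates; when omitted, ``cy`` values are assumed already relative.
    """
    if (ref_box is None) == (full_scale_h is None):
        raise ConfigError("provide exactly one of ref_box or full_scale_h")
    cy_pred = det_box.cy
    if baseline_row is not None:
        h_pred = ordinate_from_box(cy_pred, baseline_row)
        h_ref = (ordinate_from_box(ref_box.cy, baseline_row)
                 if ref_box is not None else full_scale_h)
    else:
        h_pred = cy_pred
        h_ref = ref_box.cy if ref_box is not None else full_scale_h
    return decode_angle(h_pred, h_ref, spec, joint)
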