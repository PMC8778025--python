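"""Noise removal and active-window extraction.

sEMG energy is concentrated in 20-450 Hz; everything outside that band
is treated as noise, and mains interference sits at 50 Hz.  The chain
is a zero-phase Butterworth band-pass (order 4), a Q=30 IIR notch at
50 Hz, and a crop of the steady part of the movement (default 2-4 s,
avoiding the acceleration/deceleration transients).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, RangeError
from .synth import SemgRecord


@dataclass(frozen=True)
class FilterSpec:
    band_low: float = 20.0
    band_high: float = 450.0
    notch_freq: float = 50.0
    notch_q: float = 30.0
    filter_order: int = 4

    def __post_init__(self):
        if not (0 < self.band_low < self.band_high):
            raise ConfigError(
                f"need 0 < band_low < band_high, got [{self.band_low}, {self.band_high}]"
            )
        if not (self.band_low < self.notch_freq < self.band_high):
            raise ConfigError(
                f"notch {self.notch_freq} Hz must lie inside the pass band"
            )

    def validate_fs(self, fs: float) -> None:
        if fs <= 2 * self.band_high:
            raise ConfigError(
                f"fs={fs} Hz too low for band top {self.band_high} Hz"
            )


def _apply(record: SemgRecord, filt) -> SemgRecord:
    filtered = np.vstack([filt(ch) for ch in record.samples])
    return replace(record, samples=filtered)


def bandpass_filter(record: SemgRecord, spec: FilterSpec = FilterSpec()) -> SemgRecord:
    """Zero-phase Butterworth band-pass, per channel; removes DC."""
    spec.validate_fs(record.fs)
    sos = sps.butter(spec.filter_order, (spec.band_low, spec.band_high),
                     btype="bandpass", fs=record.fs, output="sos")
    return _apply(record, lambda x: sps.sosfiltfilt(sos, x))


def notch_filter(record: SemgRecord, spec: FilterSpec = FilterSpec()) -> SemgRecord:
    """Zero-phase narrow-band rejection at the mains frequency."""
    spec.validate_fs(record.fs)
    b, a = sps.iirnotch(spec.notch_freq, spec.notch_q, fs=record.fs)
    return _apply(record, lambda x: sps.filtfilt(b, a, x))


def denoise(record: SemgRecord, spec: FilterSpec = FilterSpec()) -> SemgRecord:
    """Band-pass followed by notch (the two commute; both are LTI)."""
    return notch_filter(bandpass_filter(record, spec), spec)


def segment_active_window(record: SemgRecord, t0: float = 2.0,
                          t1: float = 4.0) -> SemgRecord:
    """Crop samples in [t0, t1) seconds; class/angle metadata preserved.

    The burst-extent metadata is re-expressed relative to the new
    time origin and clipped to the window.
    """
    if not (0.0 <= t0 < t1 <= record.duration + 1e-9):
        raise RangeError(
            f"window [{t0}, {t1}) outside record of {record.duration:.3f} s"
        )
    i0 = int(round(t0 * record.fs))
    i1 = int(round(t1 * record.fs))
    b0, b1 = record.burst_extent
    new_extent = (max(b0 - t0, 0.0), min(max(b1 - t0, 0.0), t1 - t0))
    return replace(record, samples=record.samples[:, i0:i1],
                   burst_extent=new_extent)
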