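"""Synthetic multi-channel surface-EMG generator.

Emulates the acquisition protocol the downstream pipeline was designed
for: four retained muscle channels sampled at 2000 Hz for 5 s per
motion, six upper-limb motion classes (wrist flexion/extension, wrist
pronation/supination, elbow flexion/extension), a stochastic carrier
band-limited to 20-450 Hz, 50 Hz mains contamination and slow baseline
drift.  Every record carries its ground truth (class, burst extent,
angle fraction, peak amplitude) so every downstream stage is testable
without any recorded dataset.

Model
-----
Each channel is

    x_ch(t) = g_ch * A * e(t) * w_ch(n(t)) + mains(t) + drift(t) + floor(t)

where ``n(t)`` is zero-mean Gaussian noise band-pass filtered to
20-450 Hz and normalised to unit envelope, ``e(t)`` a trapezoidal burst
envelope (10% rise/fall of the burst duration), ``A = peak_amplitude *
angle_fraction`` so the plateau amplitude monotonically encodes the
joint angle, and ``g_ch`` the class-conditional channel gain.
``w_ch`` skews positive vs negative half-waves of the dominant channel
(sign flipped between antagonist classes) so that flexion/extension
pairs show opposite-going excursions while sharing the same active
muscles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ConfigError, DomainError

#: Ordered muscle channels retained after channel reduction.
CHANNEL_NAMES = (
    "biceps_brachii",
    "triceps_brachii",
    "extensor_carpi_ulnaris",
    "extensor_carpi_radialis",
)

_MOTION_NAMES = {
    1: "wrist_flexion",
    2: "wrist_extension",
    3: "wrist_pronation",
    4: "wrist_supination",
    5: "elbow_flexion",
    6: "elbow_extension",
}


@dataclass(frozen=True)
class MotionClass:
    """One of the six upper-limb motions, identified by its integer label.

    Ids 1/2 are wrist flexion/extension, 3/4 wrist pronation/supination,
    5/6 elbow flexion/extension.
    """

    id: int
    name: str

    def __post_init__(self):
        if self.id not in _MOTION_NAMES:
            raise DomainError(f"motion id must be 1..6, got {self.id}")
        if self.name != _MOTION_NAMES[self.id]:
            raise DomainError(
                f"motion id {self.id} is {_MOTION_NAMES[self.id]!r}, not {self.name!r}"
            )

    @classmethod
    def from_id(cls, motion_id: int) -> "MotionClass":
        if motion_id not in _MOTION_NAMES:
            raise DomainError(f"motion id must be 1..6, got {motion_id}")
        return cls(motion_id, _MOTION_NAMES[motion_id])

    @property
    def joint(self) -> str:
        """Joint group: ``wrist_fe``, ``wrist_ps`` or ``elbow``."""
        return {1: "wrist_fe", 2: "wrist_fe", 3: "wrist_ps", 4: "wrist_ps",
                5: "elbow", 6: "elbow"}[self.id]


#: All six classes, keyed by id.
MOTION_CLASSES = {i: MotionClass.from_id(i) for i in range(1, 7)}


def _default_gain_matrix() -> np.ndarray:
    # rows: class ids 1..6; cols: CHANNEL_NAMES order
    # wrist flexion/extension load on extensor carpi ulnaris,
    # pronation/supination on extensor carpi radialis,
    # elbow classes on biceps/triceps (agonist heavier than antagonist).
    return np.array(
        [
            [0.05, 0.05, 1.00, 0.15],  # 1 wrist_flexion
            [0.05, 0.05, 1.00, 0.15],  # 2 wrist_extension
            [0.05, 0.05, 0.15, 1.00],  # 3 wrist_pronation
            [0.05, 0.05, 0.15, 1.00],  # 4 wrist_supination
            [1.00, 0.35, 0.05, 0.05],  # 5 elbow_flexion
            [0.35, 1.00, 0.05, 0.05],  # 6 elbow_extension
        ]
    )


def _default_asymmetry() -> np.ndarray:
    # Half-wave skew of the dominant channel, sign flipped between
    # antagonists so flexion/extension excursions point opposite ways.
    return np.array([0.6, -0.6, 0.6, -0.6, 0.6, -0.6])


@dataclass
class SynthConfig:
    """Generator settings; defaults mirror the acquisition protocol."""

    fs: float = 2000.0
    duration: float = 5.0
    channel_names: tuple = CHANNEL_NAMES
    gain_matrix: np.ndarray = field(default_factory=_default_gain_matrix)
    asymmetry: np.ndarray = field(default_factory=_default_asymmetry)
    burst_start: float = 1.0
    burst_end: float = 4.0
    peak_amplitude: float = 1.0  # mV at angle_fraction == 1
    mains_amplitude: float = 0.05  # mV, 50 Hz
    drift_amplitude: float = 0.08  # mV, slow baseline wander
    drift_freq: float = 0.3  # Hz
    noise_floor: float = 0.01  # mV broadband
    band: tuple = (20.0, 450.0)
    seed: int = 0

    def __post_init__(self):
        self.gain_matrix = np.asarray(self.gain_matrix, dtype=float)
        self.asymmetry = np.asarray(self.asymmetry, dtype=float)
        if self.fs <= 2 * self.band[1]:
            raise ConfigError(
                f"fs={self.fs} must exceed twice the band top {self.band[1]}"
            )
        if not (0 <= self.burst_start < self.burst_end <= self.duration):
            raise ConfigError(
                f"burst window [{self.burst_start}, {self.burst_end}] must lie "
                f"inside [0, {self.duration}]"
            )
        if self.gain_matrix.shape != (6, len(self.channel_names)):
            raise ConfigError(
                f"gain_matrix must be 6 x {len(self.channel_names)}, "
                f"got {self.gain_matrix.shape}"
            )
        if (self.gain_matrix < 0).any():
            raise ConfigError("gain_matrix entries must be non-negative")
        if not (self.gain_matrix.max(axis=1) > 0).all():
            raise ConfigError("every gain_matrix row needs a positive entry")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


@dataclass
class SemgRecord:
    """A multi-channel sEMG trace with its ground truth.

    ``samples`` is a (channels x time) array in mV.  ``peak`` is the
    plateau amplitude actually applied on the dominant channel, i.e. the
    quantity the image label's vertical extent encodes.
    """

    samples: np.ndarray
    fs: float
    motion: MotionClass
    angle_fraction: float
    burst_extent: tuple
    peak: float
    channel_names: tuple = CHANNEL_NAMES

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] != len(self.channel_names):
            raise ConfigError(
                f"{self.samples.shape[0]} channels but "
                f"{len(self.channel_names)} channel names"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel(self, name: str) -> np.ndarray:
        try:
            i = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None
        return self.samples[i]


def _bandlimited_noise(n: int, fs: float, band: tuple, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise band-pass filtered to ``band``."""
    white = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def trapezoid_envelope(times: np.ndarray, start: float, end: float,
                       ramp_fraction: float = 0.1) -> np.ndarray:
    """Unit-plateau trapezoid over [start, end] with proportional ramps."""
    ramp = ramp_fraction * (end - start)
    env = np.zeros_like(times)
    up = (times >= start) & (times < start + ramp)
    plateau = (times >= start + ramp) & (times <= end - ramp)
    down = (times > end - ramp) & (times <= end)
    if ramp > 0:
        env[up] = (times[up] - start) / ramp
        env[down] = (end - times[down]) / ramp
    env[plateau] = 1.0
    return env


def _skew_halfwaves(x: np.ndarray, a: float) -> np.ndarray:
    """Scale positive half-waves by (1+a) and negative by (1-a).

    Keeps the extreme excursion of a roughly symmetric carrier at
    (1+|a|) times the symmetric peak, pointing up for a>0, down for a<0.
    """
    return np.where(x >= 0, (1.0 + a) * x, (1.0 - a) * x)


def generate_record(motion, angle_fraction: float, config: SynthConfig,
                    seed: int | None = None) -> SemgRecord:
    """Generate one synthetic sEMG record.

    Parameters
    ----------
    motion : MotionClass or int
        Target motion class (1..6).
    angle_fraction : float in [0, 1]
        Fraction of the joint's maximum motion angle; scales the burst
        plateau amplitude linearly.
    config : SynthConfig
    seed : int, optional
        Overrides ``config.seed``.
    """
    if isinstance(motion, (int, np.integer)):
        motion = MotionClass.from_id(int(motion))
    if not (0.0 <= angle_fraction <= 1.0):
        raise DomainError(f"angle_fraction must be in [0, 1], got {angle_fraction}")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    n = config.n_samples
    t = np.arange(n) / config.fs
    env = trapezoid_envelope(t, config.burst_start, config.burst_end)
    amp = config.peak_amplitude * angle_fraction
    gains = config.gain_matrix[motion.id - 1]
    asym = config.asymmetry[motion.id - 1]
    dominant = int(np.argmax(gains))

    out = np.empty((len(config.channel_names), n))
    for ch in range(out.shape[0]):
        carrier = _bandlimited_noise(n, config.fs, config.band, rng)
        # normalise so the envelope peak is controlled: carrier peak ~ its max
        peak_norm = np.max(np.abs(carrier))
        if peak_norm > 0:
            carrier = carrier / peak_norm
        if ch == dominant:
            # skew the half-waves, then re-band-limit: rectification
            # leaks energy below 20 Hz which must not reach the carrier
            carrier = _skew_halfwaves(carrier, asym)
            sos = sps.butter(4, config.band, btype="bandpass",
                             fs=config.fs, output="sos")
            carrier = sps.sosfiltfilt(sos, carrier)
            carrier_extreme = np.max(np.abs(carrier))
            if carrier_extreme > 0:
                carrier = carrier / carrier_extreme
        burst = amp * gains[ch] * env * carrier
        mains = config.mains_amplitude * np.sin(
            2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
        drift = config.drift_amplitude * np.sin(
            2 * np.pi * config.drift_freq * t + rng.uniform(0, 2 * np.pi))
        floor = config.noise_floor * rng.standard_normal(n)
        out[ch] = burst + mains + drift + floor

    peak = amp * gains[dominant]
    return SemgRecord(
        samples=out,
        fs=config.fs,
        motion=motion,
        angle_fraction=float(angle_fraction),
        burst_extent=(config.burst_start, config.burst_end),
        peak=float(peak),
        channel_names=tuple(config.channel_names),
    )


def generate_dataset(n_per_class: int, angle_sampler=None,
                     config: SynthConfig | None = None) -> list:
    """Generate a class-balanced list of records.

    ``angle_sampler`` maps an ``numpy.random.Generator`` to an angle
    fraction; the default draws uniformly from [0.2, 1.0].  Per-record
    seeds are ``config.seed + record_index`` so the dataset is
    reproducible record-by-record.
    """
    if n_per_class < 1:
        raise ConfigError(f"n_per_class must be >= 1, got {n_per_class}")
    config = config if config is not None else SynthConfig()
    if angle_sampler is None:
        angle_sampler = lambda rng: rng.uniform(0.2, 1.0)

    records = []
    index = 0
    for motion_id in range(1, 7):
        for _ in range(n_per_class):
            seed = config.seed + index
            angle = float(angle_sampler(np.random.default_rng(seed ^ 0x5EED)))
            records.append(generate_record(motion_id, angle, config, seed=seed))
            index += 1
    return records


def write_csv(record: SemgRecord, path) -> None:
    """Write a record as plain CSV: time column plus one column per channel."""
    frame = pd.DataFrame({"time_s": record.times})
    for i, name in enumerate(record.channel_names):
        frame[name] = record.samples[i]
    frame.to_csv(path, index=False)


def read_csv(path, fs: float | None = None, motion=None,
             angle_fraction: float = 0.0, burst_extent=(0.0, 0.0),
             peak: float = 0.0) -> SemgRecord:
    """Read a CSV written by :func:`write_csv` (or the same dialect).

    The sampling rate is inferred from the time column when not given.
    Ground-truth metadata is not stored in the CSV; callers supply it
    when known.
    """
    frame = pd.read_csv(path)
    if "time_s" not in frame.columns:
        raise ConfigError(f"{path}: missing 'time_s' column")
    channels = [c for c in frame.columns if c != "time_s"]
    t = frame["time_s"].to_numpy()
    if fs is None:
        if len(t) < 2:
            raise ConfigError(f"{path}: cannot infer fs from {len(t)} samples")
        fs = 1.0 / float(np.median(np.diff(t)))
    if isinstance(motion, (int, np.integer)):
        motion = MotionClass.from_id(int(motion))
    if motion is None:
        motion = MOTION_CLASSES[1]
    return SemgRecord(
        samples=frame[channels].to_numpy().T,
        fs=fs,
        motion=motion,
        angle_fraction=angle_fraction,
        burst_extent=tuple(burst_extent),
        peak=peak,
        channel_names=tuple(channels),
    )
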