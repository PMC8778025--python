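"""Channel-subset evaluation and weighted linear channel fusion.

Multi-channel sEMG carries redundant information; retaining fewer
channels speeds up recognition at a small accuracy cost.  This module
provides the comparative-experiment harness that quantifies that
trade-off on a dataset (train a lightweight classifier per channel
subset, report verification accuracy and wall time) and the weighted
linear summation that fuses the retained channels into the single
trace the imaging stage renders.  Fusion weights are constrained to
sum to 1.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .errors import ValidationError
from .synth import SemgRecord

#: Channels retained after the comparative experiments: the elbow pair
#: and the two wrist extensors.
RETAINED_CHANNELS = (
    "biceps_brachii",
    "triceps_brachii",
    "extensor_carpi_ulnaris",
    "extensor_carpi_radialis",
)


@dataclass(frozen=True)
class FusionWeights:
    """Non-negative per-channel weights summing to 1."""

    weights: dict

    def __post_init__(self):
        vals = np.array(list(self.weights.values()), dtype=float)
        if (vals < 0).any():
            raise ValidationError("fusion weights must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"fusion weights must sum to 1, got {vals.sum():.12g}"
            )

    @classmethod
    def uniform(cls, channel_names=RETAINED_CHANNELS) -> "FusionWeights":
        w = 1.0 / len(channel_names)
        return cls({name: w for name in channel_names})


def fuse_channels(record: SemgRecord, weights: FusionWeights) -> SemgRecord:
    """Weighted linear summation of channels into a single-channel record."""
    for name in weights.weights:
        if name not in record.channel_names:
            raise KeyError(f"unknown channel {name!r}")
    fused = np.zeros(record.n_samples)
    for name, w in weights.weights.items():
        fused += w * record.channel(name)
    # peak metadata is re-measured on the fused trace inside the burst
    b0, b1 = record.burst_extent
    i0, i1 = int(b0 * record.fs), max(int(b1 * record.fs), int(b0 * record.fs) + 1)
    window = fused[i0:i1] if i1 > i0 and len(fused[i0:i1]) else fused
    peak = float(np.max(np.abs(window))) if record.peak > 0 else 0.0
    return replace(record, samples=fused[None, :], peak=peak,
                   channel_names=("fused",))


@dataclass
class ClassifierBudget:
    """Training budget for the subset comparison.

    The default classifier is multinomial logistic regression on
    per-channel amplitude features (RMS, mean absolute value, skewness)
    -- a deliberately lightweight stand-in for the full image classifier
    so that the comparative procedure runs at desk scale.
    """

    train_fraction: float = 0.8
    max_iter: int = 500
    regularization_c: float = 10.0
    seed: int = 0


def _features(record: SemgRecord, channel_names) -> np.ndarray:
    feats = []
    for name in channel_names:
        x = record.channel(name)
        feats.append(np.sqrt(np.mean(x**2)))       # RMS
        feats.append(np.mean(np.abs(x)))           # MAV
        feats.append(stats.skew(x))                # half-wave asymmetry
    return np.array(feats)


def evaluate_channel_subsets(dataset, subsets, budget: ClassifierBudget | None = None,
                             ) -> pd.DataFrame:
    """Train one classifier per channel subset, report accuracy and time.

    Parameters
    ----------
    dataset : list of SemgRecord
        Balanced, labelled records.
    subsets : list of sequences of channel names
    budget : ClassifierBudget

    Returns
    -------
    DataFrame with columns ``subset``, ``accuracy``, ``time_s`` in the
    order the subsets were given.
    """
    budget = budget or ClassifierBudget()
    for subset in subsets:
        if len(subset) == 0:
            raise ValidationError("channel subset must not be empty")
        for name in subset:
            if name not in dataset[0].channel_names:
                raise KeyError(f"unknown channel {name!r}")

    y = np.array([r.motion.id for r in dataset])
    rng = np.random.default_rng(budget.seed)
    order = rng.permutation(len(dataset))
    n_train = int(round(budget.train_fraction * len(dataset)))
    train_idx, test_idx = order[:n_train], order[n_train:]
    if len(test_idx) == 0:
        raise ValidationError("train_fraction leaves no verification data")

    rows = []
    for subset in subsets:
        t0 = time.perf_counter()
        X = np.vstack([_features(r, subset) for r in dataset])
        mu, sd = X[train_idx].mean(0), X[train_idx].std(0) + 1e-12
        Xz = (X - mu) / sd
        clf = LogisticRegression(max_iter=budget.max_iter,
                                 C=budget.regularization_c,
                                 random_state=budget.seed)
        clf.fit(Xz[train_idx], y[train_idx])
        acc = float(np.mean(clf.predict(Xz[test_idx]) == y[test_idx]))
        rows.append({"subset": tuple(subset), "accuracy": acc,
                     "time_s": time.perf_counter() - t0})
    return pd.DataFrame(rows)
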