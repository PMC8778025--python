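"""Shared fixtures: small synthetic datasets and rendered image sets.

Everything is generated programmatically with fixed seeds; nothing is
read from disk.
"""

import numpy as np
import pytest

from semgdet import channels, imaging, synth


@pytest.fixture(scope="session")
def synth_config():
    return synth.SynthConfig(seed=7)


@pytest.fixture(scope="session")
def quiet_config():
    """No mains, drift or floor noise: the carrier alone."""
    return synth.SynthConfig(mains_amplitude=0.0, drift_amplitude=0.0,
                             noise_floor=0.0, seed=7)


@pytest.fixture(scope="session")
def demo_detection_set(synth_config):
    """Eight rendered 160-px signal images with labels, one box each.

    The mix covers all six motion classes at varied angle fractions;
    this is the memorization target for the scaled-down end-to-end
    detector runs.
    """
    plan = [(1, .9), (2, .7), (3, .8), (4, .6), (5, 1.0), (6, .5),
            (5, .7), (2, .95)]
    records = [synth.generate_record(mid, ang, synth_config, seed=100 + i)
               for i, (mid, ang) in enumerate(plan)]
    fw = channels.FusionWeights.uniform(synth_config.channel_names)
    fused = [channels.fuse_channels(r, fw) for r in records]
    amp = imaging.dataset_amp_range(fused)
    dataset = []
    for i, rec in enumerate(fused):
        img = imaging.render_signal_image(rec, size=160, amp_range=amp)
        lab = imaging.auto_label(img, rec, image_path=f"img{i}")
        dataset.append((img, lab, rec))
    return dataset


@pytest.fixture(scope="session")
def rendered_example(synth_config):
    """One fused record rendered at 448 px with its label."""
    record = synth.generate_record(5, 0.8, synth_config, seed=42)
    fw = channels.FusionWeights.uniform(synth_config.channel_names)
    fused = channels.fuse_channels(record, fw)
    img = imaging.render_signal_image(fused, size=448, amp_range=0.5)
    label = imaging.auto_label(img, fused, image_path="example.png")
    return img, label, fused
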