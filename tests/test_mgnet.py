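"""MGNet architecture, Ghost module, joint loss and classifier training."""

import numpy as np
import pytest

from semgdet import mgnet, nn
from semgdet.errors import ConstructionError, ValidationError


@pytest.fixture(scope="module")
def full_net():
    """Full-width network; built once, shared by the audits."""
    return mgnet.MGNet()


class TestArchitecture:
    def test_every_table_row_matches_built_feature_map(self, full_net):
        rows = mgnet.architecture_audit(full_net, input_size=448)
        assert all(r["match"] for r in rows), rows

    def test_classifier_emits_six_scores_and_two_regressions(self):
        net = mgnet.MGNet(width_multiplier=0.25, seed=0)
        x = np.zeros((2, 3, 64, 64), dtype=np.float32)
        logits, reg = net.forward(x)
        assert logits.shape == (2, 6)
        assert reg.shape == (2, 2)

    def test_kernel_parameter_spot_checks(self, full_net):
        assert full_net.stages[0].modules[0].weight.size == 864
        assert full_net.stages[2].blocks[0].expand_conv.weight.size == 1536
        ghost = full_net.stages[4].modules[0]
        assert ghost.primary_conv.weight.size == 1024
        assert ghost.cheap_conv.weight.size == 288
        assert full_net.stages[9].modules[0].weight.size == 409600

    def test_count_parameters_modes_are_consistent(self, full_net):
        kernels = mgnet.count_parameters(full_net, include_bn=False,
                                         include_bias=False)
        with_bn = mgnet.count_parameters(full_net, include_bn=True,
                                         include_bias=False)
        assert with_bn > kernels > 0

    def test_no_expansion_conv_when_t_is_one(self, full_net):
        assert full_net.stages[1].blocks[0].expand_conv is None

    def test_bad_spec_rejected(self):
        with pytest.raises(ConstructionError):
            mgnet.MGNet(specs=(mgnet.BlockSpec("conv", None, 32, 1, 2),))


class TestGhostModule:
    def test_ghost_stage_shape(self):
        """56x56x32 in, 64 channels out at stride 2 -> 28x28x64."""
        rng = np.random.default_rng(0)
        stage = mgnet.GhostStage(32, 64, n=4, stride=2, rng=rng)
        out = stage.forward(np.zeros((1, 32, 56, 56), dtype=np.float32))
        assert out.shape == (1, 64, 28, 28)

    def test_output_is_concatenation_of_primary_and_cheap(self):
        rng = np.random.default_rng(1)
        gm = mgnet.GhostModule(8, 16, rng)
        x = rng.standard_normal((2, 8, 6, 6)).astype(np.float32)
        out = gm.forward(x)
        assert out.shape[1] == 16
        primary = gm.primary_act.forward(gm.primary_bn.forward(
            gm.primary_conv.forward(x)))
        np.testing.assert_allclose(out[:, :8], primary, atol=1e-5)

    def test_odd_output_channels_rejected(self):
        with pytest.raises(ConstructionError):
            mgnet.GhostModule(8, 15, np.random.default_rng(0))

    def test_ghost_forward_wrapper(self):
        out = mgnet.ghost_forward(np.zeros((1, 8, 6, 6), dtype=np.float32), 16,
                                  rng=np.random.default_rng(0))
        assert out.shape == (1, 16, 6, 6)


class TestLoss:
    def test_zero_residuals_reduce_to_cross_entropy(self):
        scores = np.array([10.0, 0, 0, 0, 0, 0])
        t = mgnet.ClassifierTarget(1, 50.0, 20.0)
        loss = mgnet.mgnet_loss((scores, 50.0, 20.0), t)
        ce = -np.log(nn.softmax(scores[None])[0, 0])
        assert loss == pytest.approx(ce, abs=1e-9)
        assert loss < 1e-3

    def test_hand_arithmetic(self):
        """CE 0.5 plus residuals 1 px with default weights -> 0.89."""
        # build scores whose CE is exactly 0.5 for class 1
        p0 = np.exp(-0.5)
        rest = (1 - p0) / 5
        scores = np.log([p0] + [rest] * 5)
        t = mgnet.ClassifierTarget(1, 50.0, 20.0)
        loss = mgnet.mgnet_loss((scores, 51.0, 21.0), t)
        assert loss == pytest.approx(0.5 + 0.13 + 0.26, abs=1e-6)

    def test_default_weights(self):
        w = mgnet.LossWeights()
        assert (w.alpha, w.beta) == (0.13, 0.26)

    def test_loss_non_negative_random(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            scores = rng.standard_normal(6)
            t = mgnet.ClassifierTarget(int(rng.integers(1, 7)),
                                       float(rng.uniform(1, 100)),
                                       float(rng.uniform(1, 100)))
            assert mgnet.mgnet_loss(
                (scores, rng.uniform(0, 100), rng.uniform(0, 100)), t) >= 0

    def test_alpha_beta_zero_equals_pure_ce(self):
        rng = np.random.default_rng(4)
        scores = rng.standard_normal(6)
        t = mgnet.ClassifierTarget(2, 40.0, 10.0)
        w0 = mgnet.LossWeights(alpha=0.0, beta=0.0)
        ce = -np.log(nn.softmax(scores[None])[0, 1] + 1e-12)
        assert mgnet.mgnet_loss((scores, 999.0, 999.0), t, w0) == \
            pytest.approx(ce, abs=1e-9)


def tiny_classification_set(n=60, size=64, seed=0):
    """Synthetic image set: class-coded blobs with width/peak targets."""
    rng = np.random.default_rng(seed)
    data = []
    for i in range(n):
        cls = i % 6 + 1
        img = np.full((size, size, 3), 255, np.uint8)
        w = 10 + 4 * cls
        h = 6 + 3 * cls
        x0 = (size - w) // 2
        y0 = (size - h) // 2
        img[y0:y0 + h, x0:x0 + w] = 40 * cls % 256
        img = np.clip(img.astype(int) + rng.integers(-8, 8, img.shape), 0,
                      255).astype(np.uint8)
        data.append((img, mgnet.ClassifierTarget(cls, float(w), float(h))))
    return data


class TestTraining:
    def test_loss_decreases_over_first_epochs(self):
        data = tiny_classification_set()
        hyper = mgnet.TrainSpec(lr=1e-3, batch_size=16, max_epochs=8,
                                width_multiplier=0.25, input_size=64, seed=0)
        net, history = mgnet.train_classifier(data, hyper)
        losses = history["epoch_loss"]
        # smoothed over pairs: the early trend must be downward
        first = np.mean(losses[:2])
        fifth = np.mean(losses[3:5])
        assert fifth <= first
        assert losses[4] < losses[0]

    def test_default_hyperparameters(self):
        hyper = mgnet.TrainSpec()
        assert hyper.lr == pytest.approx(3e-4)
        assert hyper.batch_size == 16
        assert hyper.max_epochs == 3000
        assert hyper.checkpoint_every == 200
        assert hyper.lr_factor == 0.5 and hyper.lr_patience == 3

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValidationError):
            mgnet.train_classifier([], mgnet.TrainSpec())

    def test_checkpoint_round_trip(self, tmp_path):
        data = tiny_classification_set(n=12)
        hyper = mgnet.TrainSpec(lr=1e-3, batch_size=6, max_epochs=1,
                                width_multiplier=0.25, input_size=64, seed=1)
        net, _ = mgnet.train_classifier(data, hyper)
        path = tmp_path / "ck.npz"
        mgnet.save_checkpoint(net, path)
        net2 = mgnet.MGNet(width_multiplier=0.25, seed=99)
        mgnet.load_checkpoint(net2, path)
        x = np.zeros((1, 3, 64, 64), dtype=np.float32)
        net.set_training(False)
        net2.set_training(False)
        a, _ = net.forward(x)
        b, _ = net2.forward(x)
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_training_is_reproducible(self):
        data = tiny_classification_set(n=12)
        hyper = mgnet.TrainSpec(lr=1e-3, batch_size=6, max_epochs=2,
                                width_multiplier=0.25, input_size=64, seed=5)
        _, h1 = mgnet.train_classifier(data, hyper)
        _, h2 = mgnet.train_classifier(data, hyper)
        assert h1["epoch_loss"] == h2["epoch_loss"]
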