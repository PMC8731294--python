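"""U-net segmenter: softmax/Dice-loss oracles, backprop check, training."""

import numpy as np
import pytest

import spinereg as sr
from spinereg.exceptions import ConfigError
from spinereg.unetseg import UNetSegmenter, _UNet, softmax_energy
from conftest import heldout_dice


class TestSoftmaxEnergy:
    def test_equal_scores_give_uniform(self):
        for k in (2, 3, 5):
            np.testing.assert_allclose(softmax_energy(np.zeros(k)), 1.0 / k)

    def test_shift_invariance(self):
        s = np.array([0.3, -1.2, 2.0, 0.0])
        np.testing.assert_allclose(softmax_energy(s),
                                   softmax_energy(s + 57.0), atol=1e-12)

    def test_matches_direct_exp_normalize(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=4)
        direct = np.exp(s) / np.exp(s).sum()  # independent literal formula
        np.testing.assert_allclose(softmax_energy(s), direct, atol=1e-12)

    def test_simplex_everywhere(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=(3, 16, 16)) * 10
        p = softmax_energy(s, axis=0)
        np.testing.assert_allclose(p.sum(axis=0), 1.0, atol=1e-12)
        assert np.all(p > 0) and np.all(p < 1)

    def test_argmax_preserved(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=(50, 4))
        p = softmax_energy(s, axis=1)
        np.testing.assert_array_equal(p.argmax(axis=1), s.argmax(axis=1))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            softmax_energy(np.array([1.0, np.inf]))


class TestDiceLoss:
    def test_perfect_one_hot_is_zero(self):
        t = np.zeros((8, 8), int)
        t[2:6, 2:6] = 1
        p = np.stack([1.0 - t, t]).astype(float)
        assert sr.dice_loss(p, t, eps=1e-9) == pytest.approx(0.0, abs=1e-6)

    def test_fully_disjoint_is_one(self):
        t = np.zeros((8, 8), int)
        t[:4] = 1
        p_wrong = np.stack([t, 1 - t]).astype(float)  # predicts the inverse
        assert sr.dice_loss(p_wrong, t, eps=1e-9) == pytest.approx(
            1.0, abs=1e-6)

    def test_uniform_prediction_closed_form(self):
        """Uniform 1/k maps have a hand-computable soft Dice."""
        k = 2
        t = np.zeros((10, 10), int)
        t[:5] = 1
        p = np.full((k, 10, 10), 1.0 / k)
        eps = 1.0
        n_fg = float(t.sum())
        expected = 1.0 - (2 * (0.5 * n_fg) + eps) / (0.5 * 100 + n_fg + eps)
        assert sr.dice_loss(p, t, eps=eps) == pytest.approx(expected,
                                                            abs=1e-12)

    def test_loss_decreases_toward_target(self):
        """Moving straight toward the target one-hot reduces the loss."""
        rng = np.random.default_rng(3)
        t = (rng.random((8, 8)) > 0.5).astype(int)
        onehot = np.stack([1 - t, t]).astype(float)
        start = softmax_energy(rng.normal(size=(2, 8, 8)), axis=0)
        losses = [sr.dice_loss((1 - a) * start + a * onehot, t)
                  for a in np.linspace(0, 1, 6)]
        assert all(b < a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_label_out_of_range(self):
        p = np.full((2, 4, 4), 0.5)
        with pytest.raises(ValueError):
            sr.dice_loss(p, np.full((4, 4), 3))


class TestBackprop:
    def test_gradients_match_finite_differences(self):
        """Analytic gradients of the Dice loss through the whole net."""
        rng = np.random.default_rng(0)
        est = UNetSegmenter(n_classes=2, depth=1, base_channels=2)
        net = _UNet(2, 1, 2, rng)
        x = rng.normal(size=(2, 1, 8, 8))
        t = (rng.random((2, 8, 8)) > 0.5).astype(int)

        def loss_of(net):
            scores = net.forward(x, train=False)
            return sr.dice_loss(softmax_energy(scores, axis=1), t)

        # analytic
        scores = net.forward(x, train=True)
        probs = softmax_energy(scores, axis=1)
        loss, dprobs = est._dice_loss_grad(probs, t)
        inner = (dprobs * probs).sum(axis=1, keepdims=True)
        net.backward(probs * (dprobs - inner))
        convs = net.conv_layers()
        h = 1e-5
        for conv in (convs[0], convs[-1]):
            W = conv.W
            for idx in [(0, 0), (W.shape[0] - 1, W.shape[1] - 1)]:
                orig = W[idx]
                W[idx] = orig + h
                lp = loss_of(net)
                W[idx] = orig - h
                lm = loss_of(net)
                W[idx] = orig
                fd = (lp - lm) / (2 * h)
                assert conv.dW[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestTraining:
    def test_heldout_dice_noise_free(self, segmenter_noisefree):
        """>= 0.95 held-out hard Dice on noise-free phantoms."""
        model, _, test = segmenter_noisefree
        dices = heldout_dice(model, test)
        assert np.mean(dices) >= 0.95

    def test_heldout_dice_noisy(self, segmenter_noisy):
        """>= 0.90 held-out hard Dice at the noisy study condition."""
        model, _, test = segmenter_noisy
        assert np.mean(heldout_dice(model, test)) >= 0.90

    def test_loss_curve_decreases_over_windows(self, segmenter_noisy):
        """Epoch-mean loss is non-increasing over 5-epoch windows."""
        model, _, _ = segmenter_noisy
        curve = model.loss_curve_
        window = [np.mean(curve[i:i + 5])
                  for i in range(len(curve) - 4)]
        assert all(b <= a + 1e-9 for a, b in zip(window, window[1:]))

    def test_memorization_at_least_heldout(self, segmenter_noisefree):
        model, train_set, test = segmenter_noisefree
        train_dice = np.mean(heldout_dice(model, train_set[:10]))
        test_dice = np.mean(heldout_dice(model, test))
        assert train_dice >= test_dice - 0.02

    def test_untrained_worse_than_trained(self, segmenter_noisefree):
        model, _, test = segmenter_noisefree
        rng = np.random.default_rng(model.seed)
        fresh = UNetSegmenter()
        fresh.norm_mean_, fresh.norm_std_ = model.norm_mean_, model.norm_std_
        fresh.model_ = _UNet(2, fresh.depth, fresh.base_channels, rng)
        fresh.classes_ = np.arange(2)
        assert np.mean(heldout_dice(fresh, test)) < \
            np.mean(heldout_dice(model, test))

    def test_training_is_seed_deterministic(self):
        """Identical seed and data give bit-identical weights."""
        data = sr.segmentation_dataset(6, sr.PhantomConfig(seed=2))
        cfg = sr.SegNetConfig(epochs=2, seed=7)
        h1 = sr.train(data, cfg).weights_hash()
        h2 = sr.train(data, cfg).weights_hash()
        assert h1 == h2

    def test_shape_not_divisible_rejected(self):
        data = [(sr.ImageVolume(np.zeros((48, 48))),
                 sr.LabelMask(np.zeros((48, 48), int)))]
        with pytest.raises(ConfigError):
            sr.train(data, sr.SegNetConfig(depth=5, epochs=1))


class TestSegment:
    def test_labels_in_range(self, segmenter_noisefree, phantom2d):
        model, _, _ = segmenter_noisefree
        vol, _, _ = phantom2d
        mask = sr.segment(model, vol)
        assert mask.labels.min() >= 0 and mask.labels.max() < 2
        assert mask.shape == vol.shape

    def test_constant_input_constant_interior(self, segmenter_noisefree):
        model, _, _ = segmenter_noisefree
        vol = sr.ImageVolume(np.full((64, 64), 77.0))
        labels = sr.segment(model, vol).labels
        interior = labels[8:-8, 8:-8]
        assert len(np.unique(interior)) == 1

    def test_scoremap_simplex(self, segmenter_noisefree, phantom2d):
        model, _, _ = segmenter_noisefree
        vol, _, _ = phantom2d
        sm = model.predict_scores(vol)
        np.testing.assert_allclose(sm.probs.sum(axis=0), 1.0, atol=1e-12)

    def test_save_load_round_trip(self, tmp_path, segmenter_noisefree,
                                  phantom2d):
        model, _, _ = segmenter_noisefree
        vol, _, _ = phantom2d
        path = tmp_path / "model.npz"
        model.save(path)
        back = UNetSegmenter.load(path)
        np.testing.assert_array_equal(sr.segment(back, vol).labels,
                                      sr.segment(model, vol).labels)


class TestPipelineDirection:
    def test_registration_plus_segmentation_beats_plain(
            self, recovery_trials, segmenter_noisefree):
        """Aligning the floating segmentation to the reference mask via
        the recovered transform never scores below the unaligned one."""
        model, _, _ = segmenter_noisefree
        for trial in recovery_trials:
            pred = sr.segment(model, trial["volume"])
            q = trial["reference_mask"]
            q_vert = (q.labels >= 1) & (q.labels <= 5)
            plain = sr.dice(q_vert, pred.labels == 1)
            warped = trial["result"].transform.warp_mask(pred)
            aligned = sr.dice(q_vert, warped.labels == 1)
            assert aligned >= plain, f"seed {trial['seed']}"
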