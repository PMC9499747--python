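"""U-Net architecture contracts, gradient correctness, training mechanics.

Heavy training lives in the acceptance suite; everything here uses tiny
configurations (side 16, base 2-4 channels) so the whole file runs in
seconds.
"""

import numpy as np
import pytest

from gliopipe import UNetConfig, UNetClassifier, build_unet, describe_architecture
from gliopipe import nn as gnn
from gliopipe.unet_classify import UNet


class TestArchitectureDescription:
    def test_default_depth_and_channel_doubling(self):
        d = describe_architecture(UNetConfig())
        assert d["n_encoder_blocks"] == 5
        assert d["n_decoder_blocks"] == 4
        assert d["encoder_channels"] == [64, 128, 256, 512, 1024]
        assert d["deepest_channels"] == 1024

    def test_240_input_reaches_15_at_bottleneck(self):
        d = describe_architecture(UNetConfig(input_side=240))
        assert d["bottleneck_side"] == 15
        assert d["output_side"] == 240

    def test_no_dense_layer_in_segmentation_path(self):
        d = describe_architecture(UNetConfig())
        assert d["dense_in_segmentation_path"] is False
        # and by introspection of a small concrete model: nothing linear
        # between input and segmentation head
        net = build_unet(UNetConfig(n_encoder_blocks=3, base_channels=2,
                                    input_side=16), seed=0)
        seg_path = [ly for blk in net.enc_blocks for ly in blk]
        for dec in net.dec_blocks:
            seg_path += [dec["up"], *dec["convs"]]
        seg_path.append(net.seg_head)
        assert not any(isinstance(ly, gnn.Linear) for ly in seg_path)

    def test_indivisible_input_side_names_requirement(self):
        with pytest.raises(ValueError, match=r"divisible by 2\*\*"):
            describe_architecture(UNetConfig(input_side=100))

    def test_decoder_block_count_constraint(self):
        with pytest.raises(ValueError, match="decoder blocks"):
            describe_architecture(UNetConfig(n_decoder_blocks=3))

    @pytest.mark.parametrize("blocks,base", [(4, 8), (5, 4), (6, 2)])
    def test_configurable_block_range(self, blocks, base):
        d = describe_architecture(UNetConfig(
            n_encoder_blocks=blocks, base_channels=base,
            input_side=2 ** (blocks + 1)))
        assert d["encoder_channels"] == [base * 2**b for b in range(blocks)]


@pytest.fixture(scope="module")
def tiny():
    cfg = UNetConfig(n_encoder_blocks=3, base_channels=2,
                     dropout_rate=0.5, n_classes=3, input_side=16)
    return UNet(cfg, np.random.default_rng(0))


@pytest.fixture(scope="module")
def toy_data():
    rng = np.random.default_rng(0)
    X = rng.uniform(0, 255, (8, 16, 16))
    X[:4, 4:10, 4:10] += 80  # a bright blob marks class "b"
    y = np.array(["b"] * 4 + ["a"] * 4)
    masks = np.zeros((8, 16, 16))
    masks[:4, 4:10, 4:10] = 1.0
    return np.clip(X, 0, 255), y, masks


class TestForwardContracts:

    def test_seg_map_matches_input_shape(self, tiny, rng):
        x = rng.random((2, 1, 16, 16))
        seg, cls = tiny.forward(x, train=False)
        assert seg.shape == (2, 1, 16, 16)
        assert cls.shape == (2, 3)

    def test_softmax_probabilities_sum_to_one(self, tiny, rng):
        _, cls = tiny.forward(rng.random((3, 1, 16, 16)), train=False)
        p = gnn.softmax(cls)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p >= 0)

    def test_gradients_match_finite_differences(self):
        cfg = UNetConfig(n_encoder_blocks=2, base_channels=2,
                         dropout_rate=0.0, n_classes=2, input_side=8)
        net = UNet(cfg, np.random.default_rng(1))
        rng = np.random.default_rng(2)
        x = rng.random((2, 1, 8, 8))
        t = np.array([0, 1])
        m = (rng.random((2, 1, 8, 8)) > 0.5).astype(float)

        def loss():
            seg, cls = net.forward(x, train=False)
            l1, _ = gnn.softmax_cross_entropy(cls, t)
            l2, _ = gnn.sigmoid_bce(seg, m)
            return l1 + l2

        seg, cls = net.forward(x, train=False)
        _, dcls = gnn.softmax_cross_entropy(cls, t)
        _, dseg = gnn.sigmoid_bce(seg, m)
        net.backward(dseg, dcls)
        for ly in net.layers():
            for k, p in ly.params.items():
                idx = tuple(rng.integers(0, s) for s in p.shape)
                eps, old = 1e-6, p[idx]
                p[idx] = old + eps
                lp = loss()
                p[idx] = old - eps
                lm = loss()
                p[idx] = old
                num = (lp - lm) / (2 * eps)
                assert ly.grads[k][idx] == pytest.approx(num, rel=1e-4,
                                                         abs=1e-8)


class TestUNetClassifierEstimator:
    def _clf(self, **kw):
        return UNetClassifier(n_encoder_blocks=3, base_channels=2,
                              dropout_rate=0.0, random_state=0, **kw)

    def test_zero_epochs_leaves_history_empty(self, toy_data):
        X, y, _ = toy_data
        clf = self._clf(epochs=0).fit(X, y)
        assert clf.history_ == []
        assert clf.predict_proba(X).shape == (8, 2)

    def test_same_seed_identical_final_loss(self, toy_data):
        X, y, masks = toy_data
        a = self._clf(epochs=3).fit(X, y, masks=masks)
        b = self._clf(epochs=3).fit(X, y, masks=masks)
        assert a.history_[-1] == b.history_[-1]

    def test_predict_seg_in_unit_interval(self, toy_data):
        X, y, masks = toy_data
        clf = self._clf(epochs=2).fit(X, y, masks=masks)
        seg = clf.predict_seg(X)
        assert seg.shape == (8, 16, 16)
        assert seg.min() >= 0.0 and seg.max() <= 1.0

    def test_shape_mismatch_at_predict_rejected(self, toy_data):
        X, y, _ = toy_data
        clf = self._clf(epochs=1).fit(X, y)
        with pytest.raises(ValueError, match="does not match"):
            clf.predict(np.zeros((2, 32, 32)))

    def test_missing_declared_class_rejected(self, toy_data):
        X, y, _ = toy_data
        with pytest.raises(ValueError, match="absent"):
            self._clf(epochs=1, classes=("a", "b", "c")).fit(X, y)

    def test_single_class_rejected(self, toy_data):
        X, _, _ = toy_data
        with pytest.raises(ValueError, match="two classes"):
            self._clf(epochs=1).fit(X, np.array(["a"] * 8))
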