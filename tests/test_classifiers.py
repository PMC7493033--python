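"""Volume-classifier architecture arithmetic, CBAM contract and training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octfmap import nn
from octfmap.classifiers import (LSVMClassifier, VolumeClassifierConfig,
                                 VolumeCNN, cbam_refine, conv_block_forward,
                                 load_classifier, predict_volume,
                                 save_classifier, shape_chain,
                                 train_volume_classifier)
from octfmap.feature_map import FeatureMap
from octfmap.nn.autodiff import Tensor
from octfmap.synthetic import SynthMapSpec, generate_feature_maps


def floor_halving_oracle(rows, cols, n):
    """Independent shape oracle: repeated floor-halving of both dims."""
    out = []
    h, w = rows, cols
    for _ in range(n):
        h, w = h // 2, w // 2
        out.append((h, w))
    return out


class TestShapeChain:
    def test_duke_n4_chain(self):
        """n=4 on a 100x2048 map: (4,50,1024),(4,25,512),(4,12,256),(4,6,128),
        flattened FC input 3072."""
        model = VolumeCNN(VolumeClassifierConfig(kind="cnn", n_blocks=4),
                          (100, 2048))
        model.eval()
        outs = model.block_outputs(Tensor(np.zeros((1, 1, 100, 2048))))
        assert [o.shape[1:] for o in outs] == [
            (4, 50, 1024), (4, 25, 512), (4, 12, 256), (4, 6, 128)]
        assert model.flat_len == 3072

    def test_25row_n3_chain(self):
        model = VolumeCNN(VolumeClassifierConfig(kind="cnn", n_blocks=3),
                          (25, 2048))
        model.eval()
        outs = model.block_outputs(Tensor(np.zeros((1, 1, 25, 2048))))
        assert [o.shape[1:] for o in outs] == [
            (4, 12, 1024), (4, 6, 512), (4, 3, 256)]

    def test_conv_block_minimal_case(self):
        block = nn.ConvBlock(1, 4, 3, 0.01, np.random.default_rng(0))
        block.eval()
        assert conv_block_forward(np.zeros((1, 2, 2)), block).shape == (4, 1, 1)

    def test_invariant_2_pow_n_less_than_rows(self):
        with pytest.raises(ValueError, match="2\\*\\*n_blocks"):
            VolumeCNN(VolumeClassifierConfig(kind="cnn", n_blocks=4), (16, 64))

    @settings(max_examples=60, deadline=None)
    @given(rows=st.integers(2, 4096), cols=st.integers(2, 4096),
           n=st.integers(1, 6))
    def test_shape_chain_matches_oracle(self, rows, cols, n):
        """Property sweep: the chain equals the floor-halving oracle for
        every admissible (rows, cols, n)."""
        if 2 ** n >= rows or cols // 2 ** n < 1:
            return
        chain = shape_chain(rows, cols, n)
        assert [(h, w) for _, h, w in chain] == floor_halving_oracle(rows, cols, n)


class TestCBAM:
    @pytest.fixture
    def cbam(self):
        return nn.CBAM(4, 2, 7, np.random.default_rng(1))

    def test_shape_preserved(self, cbam):
        x = np.random.default_rng(2).normal(size=(4, 6, 128))
        assert cbam_refine(x, cbam).shape == (4, 6, 128)

    def test_attention_attenuates(self, cbam):
        """Both gates lie in (0,1), so |output| <= |input| elementwise."""
        x = np.random.default_rng(3).normal(size=(4, 5, 9))
        out = cbam_refine(x, cbam)
        assert np.all(np.abs(out) <= np.abs(x) + 1e-12)
        assert not np.allclose(out, x)

    def test_identical_channels_get_equal_weights(self, cbam):
        """With a channel-symmetric bottleneck, identical channels receive
        identical attention weights (the pooled descriptors are equal)."""
        cbam.fc1.weight.data[:] = 0.3
        cbam.fc1.bias.data[:] = 0.1
        cbam.fc2.weight.data[:] = 0.2
        cbam.fc2.bias.data[:] = 0.0
        x = np.tile(np.random.default_rng(4).normal(size=(1, 5, 9)), (4, 1, 1))
        att = cbam.channel_attention(Tensor(x[None])).data[0]
        assert np.allclose(att, att[0])

    def test_reduction_exceeding_channels_rejected(self):
        with pytest.raises(ValueError):
            nn.CBAM(4, 8, 7, np.random.default_rng(5))

    def test_all_ones_attention_reduces_to_plain_cnn(self):
        """Forcing both attention maps to 1 makes CNN_CBAM equal CNN."""
        cfg = VolumeClassifierConfig(kind="cnn_cbam", n_blocks=2, seed=3)
        cbam_model = VolumeCNN(cfg, (12, 40))
        plain = VolumeCNN(VolumeClassifierConfig(kind="cnn", n_blocks=2, seed=99),
                          (12, 40))
        # share every non-CBAM parameter, then force open attention
        for pb, cb in zip(plain.blocks, cbam_model.blocks):
            pb.load_state_arrays(cb.state_arrays())
        plain.fc.load_state_arrays(cbam_model.fc.state_arrays())
        cbam_model.cbam.channel_attention = lambda x: Tensor(
            np.ones((x.shape[0], x.shape[1])))
        cbam_model.cbam.spatial_attention = lambda x: Tensor(
            np.ones((x.shape[0], 1) + x.shape[2:]))
        x = Tensor(np.random.default_rng(6).normal(size=(3, 1, 12, 40)))
        plain.eval()
        cbam_model.eval()
        assert np.allclose(plain(x).data, cbam_model(x).data, atol=1e-5)


class TestForward:
    def test_softmax_probabilities_sum_to_one(self):
        cfg = VolumeClassifierConfig(kind="cnn_cbam", n_blocks=3, seed=0)
        model = VolumeCNN(cfg, (25, 64))
        model.eval()
        probs = nn.softmax(model(Tensor(
            np.random.default_rng(7).random((4, 1, 25, 64)))).data)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def _separable_maps(n_per_class=20, seed=0):
    return generate_feature_maps(SynthMapSpec(
        n_per_class=n_per_class, rows=12, cols=24, class_mean_shift=2.0,
        noise_sd=0.2, seed=seed))


class TestTraining:
    def test_lsvm_separable_training_accuracy(self):
        maps = _separable_maps(seed=1)
        clf, _ = train_volume_classifier(
            maps, VolumeClassifierConfig(kind="lsvm", seed=0))
        acc = np.mean([predict_volume(clf, m)[0] == m.label for m in maps])
        assert acc == 1.0

    def test_training_map_predicts_own_label(self):
        maps = _separable_maps(seed=2)
        clf, _ = train_volume_classifier(
            maps, VolumeClassifierConfig(kind="lsvm", seed=0))
        assert predict_volume(clf, maps[0])[0] == maps[0].label

    def test_zero_epochs_predictions_near_uniform(self):
        maps = _separable_maps(seed=3)
        clf, losses = train_volume_classifier(
            maps, VolumeClassifierConfig(kind="cnn", n_blocks=2, epochs=0,
                                         seed=0))
        assert losses == []
        _, probs = predict_volume(clf, maps[0])
        assert np.all(np.abs(probs - 0.5) < 0.2)

    def test_training_deterministic_under_seed(self):
        maps = _separable_maps(10, seed=4)
        cfg = VolumeClassifierConfig(kind="cnn_cbam", n_blocks=2, epochs=3,
                                     batch_size=16, seed=5)
        _, l1 = train_volume_classifier(maps, cfg)
        _, l2 = train_volume_classifier(maps, cfg)
        assert np.allclose(l1[-1], l2[-1], atol=1e-6)

    def test_same_map_same_prediction(self):
        maps = _separable_maps(10, seed=6)
        clf, _ = train_volume_classifier(
            maps, VolumeClassifierConfig(kind="cnn", n_blocks=2, epochs=2,
                                         batch_size=16, seed=0))
        a = predict_volume(clf, maps[3])
        b = predict_volume(clf, maps[3])
        assert a[0] == b[0] and np.array_equal(a[1], b[1])

    def test_shape_mismatch_rejected(self):
        maps = _separable_maps(10, seed=7)
        clf, _ = train_volume_classifier(
            maps, VolumeClassifierConfig(kind="lsvm", seed=0))
        with pytest.raises(ValueError, match="shape"):
            predict_volume(clf, FeatureMap(np.zeros((3, 3)), "bad"))

    def test_heterogeneous_shapes_rejected(self):
        maps = _separable_maps(4, seed=8)
        maps.append(FeatureMap(np.zeros((2, 2)), "odd", "NOR"))
        with pytest.raises(ValueError, match="heterogeneous"):
            train_volume_classifier(maps,
                                    VolumeClassifierConfig(kind="lsvm"))

    def test_single_class_rejected(self):
        maps = [m for m in _separable_maps(4, seed=9) if m.label == "NOR"]
        with pytest.raises(ValueError):
            train_volume_classifier(maps, VolumeClassifierConfig(kind="lsvm"))

    def test_lsvm_invariant_to_consistent_permutation(self):
        """Applying one fixed permutation to every flattened sample leaves
        the decision function's predictions unchanged."""
        maps = _separable_maps(10, seed=10)
        rng = np.random.default_rng(11)
        perm = rng.permutation(maps[0].values.size)
        permuted = [FeatureMap(m.values.reshape(-1)[perm].reshape(m.values.shape),
                               m.volume_id, m.label, m.extractor_id)
                    for m in maps]
        cfg = VolumeClassifierConfig(kind="lsvm", seed=0)
        clf_a, _ = train_volume_classifier(maps, cfg)
        clf_b, _ = train_volume_classifier(permuted, cfg)
        pred_a = [predict_volume(clf_a, m)[0] for m in maps]
        pred_b = [predict_volume(clf_b, m)[0] for m in permuted]
        assert pred_a == pred_b


class TestCheckpoint:
    def test_cnn_roundtrip(self, tmp_path):
        maps = _separable_maps(6, seed=12)
        clf, _ = train_volume_classifier(
            maps, VolumeClassifierConfig(kind="cnn_cbam", n_blocks=2,
                                         epochs=2, batch_size=8, seed=0))
        save_classifier(clf, tmp_path / "c.ckpt")
        back = load_classifier(tmp_path / "c.ckpt")
        for m in maps[:3]:
            la, sa = predict_volume(clf, m)
            lb, sb = predict_volume(back, m)
            assert la == lb and np.allclose(sa, sb)

    def test_lsvm_roundtrip(self, tmp_path):
        maps = _separable_maps(6, seed=13)
        clf, _ = train_volume_classifier(
            maps, VolumeClassifierConfig(kind="lsvm", seed=0))
        save_classifier(clf, tmp_path / "s.ckpt")
        back = load_classifier(tmp_path / "s.ckpt")
        assert isinstance(back, LSVMClassifier)
        for m in maps[:3]:
            assert predict_volume(clf, m)[0] == predict_volume(back, m)[0]
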