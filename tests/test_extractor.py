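"""B-scan sample generation, normalization, augmentation and fine-tuning."""

import numpy as np
import pytest

from octfmap.data_model import Volume
from octfmap.extractor import (ExtractorConfig, FineTuneConfig,
                               augment_bscan,
                               create_extractor, fine_tune, load_extractor,
                               make_bscan_training_set, normalize_bscan,
                               save_extractor, unnormalize_bscan)


def _volumes(n_vols=4, n_bscans=25, labels=("AMD", "NOR")):
    rng = np.random.default_rng(0)
    return [Volume(f"v{i}", rng.random((n_bscans, 16, 16)),
                   labels[i % len(labels)]) for i in range(n_vols)]


class TestTrainingSet:
    def test_sample_count_is_total_bscan_count(self):
        samples = make_bscan_training_set(_volumes(4, 25))
        assert len(samples) == 100

    def test_labels_inherited_from_volume(self):
        vol = Volume("a1", np.zeros((7, 8, 8)), "AMD")
        samples = make_bscan_training_set([vol])
        assert all(s.label == "AMD" and s.source_volume_id == "a1"
                   for s in samples)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            make_bscan_training_set([])


class TestNormalization:
    @pytest.mark.parametrize("pixel,expected", [
        (0.45, 0.0),
        (0.68, 1.0),
        (1.0, (1.0 - 0.45) / 0.23),  # = 2.3913...
    ])
    def test_standardization_values(self, pixel, expected):
        out = normalize_bscan(np.array([[pixel]]))
        assert out.shape == (3, 1, 1)
        assert np.allclose(out, expected)

    def test_replicated_across_channels(self):
        img = np.random.default_rng(1).random((5, 6))
        out = normalize_bscan(img)
        assert np.array_equal(out[0], out[1]) and np.array_equal(out[1], out[2])

    def test_unnormalize_is_inverse(self):
        img = np.random.default_rng(2).random((4, 4))
        assert np.allclose(unnormalize_bscan(normalize_bscan(img)), img,
                           atol=1e-6)


class TestAugmentation:
    def test_output_size_fixed(self):
        rng = np.random.default_rng(3)
        img = rng.random((37, 61))
        for size in (224, 24):
            out = augment_bscan(img, rng, size)
            assert out.shape == (size, size)

    def test_identity_path(self):
        """Full-frame crop with flips disabled reproduces the resized input."""
        rng = np.random.default_rng(4)
        img = rng.random((24, 24))
        out = augment_bscan(img, rng, 24, crop_scale_range=(1.0, 1.0),
                            aspect_ratio_range=(1.0, 1.0), flip_prob=0.0)
        assert np.array_equal(out, img)

    def test_flip_frequency_near_half(self):
        """Monte-Carlo: the flip fires with frequency 0.5 +/- 0.02."""
        rng = np.random.default_rng(5)
        img = np.zeros((4, 4))
        img[:, 0] = 1.0  # asymmetric marker column
        flips = sum(
            augment_bscan(img, rng, 4, crop_scale_range=(1.0, 1.0),
                          aspect_ratio_range=(1.0, 1.0))[0, -1] == 1.0
            for _ in range(10_000))
        assert abs(flips / 10_000 - 0.5) < 0.02

    def test_tiny_image_rejected(self):
        with pytest.raises(ValueError):
            augment_bscan(np.zeros((1, 5)), np.random.default_rng(0), 8)


class TestExtraction:
    def test_tiny_cnn_feature_length(self):
        ext = create_extractor(ExtractorConfig(), seed=0)
        vec = ext.extract_feature(np.random.default_rng(6).random((32, 32)))
        assert vec.shape == (64,)

    def test_reference_backbone_config_geometry(self):
        cfg = ExtractorConfig.resnet50()
        assert cfg.feature_length == 2048
        assert cfg.input_size == 224

    def test_reference_backbone_requires_weights(self):
        with pytest.raises(RuntimeError, match="weights"):
            create_extractor(ExtractorConfig.resnet50())

    def test_inference_is_deterministic(self):
        ext = create_extractor(ExtractorConfig(), seed=1)
        img = np.random.default_rng(7).random((24, 24))
        assert np.array_equal(ext.extract_feature(img), ext.extract_feature(img))

    def test_batch_equals_one_by_one(self):
        """Permutation consistency: batching does not change features."""
        ext = create_extractor(ExtractorConfig(), seed=2)
        imgs = np.random.default_rng(8).random((5, 24, 24))
        batch = ext.extract_features(imgs)
        single = np.stack([ext.extract_feature(im) for im in imgs])
        assert np.allclose(batch, single, rtol=1e-5)


@pytest.fixture(scope="module")
def separable_samples():
    """200 B-scans where class differs by a bright square."""
    rng = np.random.default_rng(9)
    vols = []
    for i in range(8):
        scans = rng.random((25, 24, 24)) * 0.2
        label = "AMD" if i % 2 else "NOR"
        if label == "AMD":
            scans[:, 8:16, 8:16] += 0.7
        vols.append(Volume(f"v{i}", np.clip(scans, 0, 1), label))
    return make_bscan_training_set(vols)


class TestFineTune:
    def test_loss_decreases_on_separable_data(self, separable_samples):
        ext = create_extractor(ExtractorConfig(), seed=3)
        cfg = FineTuneConfig(frozen_blocks=frozenset(), lr=1e-2, epochs=3,
                             batch_size=64, seed=0)
        ext, losses = fine_tune(ext, separable_samples, cfg)
        per_epoch = int(np.ceil(len(separable_samples) / 64))
        assert len(losses) == 3 * per_epoch
        assert np.mean(losses[-per_epoch:]) < np.mean(losses[:per_epoch])

    def test_frozen_stages_bit_identical(self, separable_samples):
        ext = create_extractor(ExtractorConfig(), seed=4)
        frozen_before = {k: v.copy() for k, v in ext.conv1.state_arrays().items()}
        frozen_before.update({f"2{k}": v.copy() for k, v in
                              ext.conv2.state_arrays().items()})
        cfg = FineTuneConfig(frozen_blocks=frozenset({"conv1", "conv2"}),
                             lr=1e-2, epochs=1, seed=0)
        ext, _ = fine_tune(ext, separable_samples, cfg)
        after = dict(ext.conv1.state_arrays())
        after.update({f"2{k}": v for k, v in ext.conv2.state_arrays().items()})
        for key, before in frozen_before.items():
            assert before.tobytes() == after[key].tobytes(), key
        # the unfrozen stage did change
        assert not np.array_equal(
            frozen_before.get("conv.weight"), ext.conv3.conv.weight.data[:1])

    def test_zero_epochs_is_identity(self, separable_samples):
        ext = create_extractor(ExtractorConfig(), seed=5)
        before = {k: v.copy() for k, v in ext.state_arrays().items()}
        ext, losses = fine_tune(ext, separable_samples,
                                FineTuneConfig(epochs=0))
        assert losses == []
        for k, v in ext.state_arrays().items():
            assert np.array_equal(before[k], v)

    def test_single_class_rejected(self):
        vol = Volume("x", np.zeros((4, 16, 16)), "AMD")
        with pytest.raises(ValueError):
            fine_tune(create_extractor(ExtractorConfig(), seed=6),
                      make_bscan_training_set([vol]), FineTuneConfig())


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path):
        ext = create_extractor(ExtractorConfig(), seed=7)
        ext.class_names = ["AMD", "NOR"]
        img = np.random.default_rng(10).random((24, 24))
        save_extractor(ext, tmp_path / "e.ckpt")
        back = load_extractor(tmp_path / "e.ckpt")
        assert np.array_equal(back.extract_feature(img), ext.extract_feature(img))
        assert back.class_names == ["AMD", "NOR"]
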