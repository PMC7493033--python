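"""Volume/manifest/feature-map I/O contracts and round trips."""

import numpy as np
import pytest

from octfmap.data_model import (DatasetManifest, ManifestEntry, Volume,
                                read_feature_map, read_manifest, read_volume,
                                write_feature_map, write_manifest,
                                write_volume)
from octfmap.feature_map import FeatureMap


@pytest.fixture
def volume():
    rng = np.random.default_rng(0)
    return Volume(volume_id="v1", bscans=rng.random((5, 12, 16)), label="AMD")


class TestVolumeIO:
    def test_roundtrip_preserves_pixels(self, volume, tmp_path):
        write_volume(volume, tmp_path / "v1")
        back = read_volume(tmp_path / "v1", volume_id="v1", label="AMD")
        assert back.n_bscans == 5
        # 16-bit container: quantization error bounded by half a level
        assert np.abs(back.bscans - volume.bscans).max() <= 0.5 / 65535

    def test_rereading_is_deterministic(self, volume, tmp_path):
        write_volume(volume, tmp_path / "v1")
        a = read_volume(tmp_path / "v1")
        b = read_volume(tmp_path / "v1")
        assert np.array_equal(a.bscans, b.bscans)

    def test_single_bscan_volume(self, tmp_path):
        vol = Volume("solo", np.zeros((1, 8, 8)))
        write_volume(vol, tmp_path / "solo")
        assert read_volume(tmp_path / "solo").n_bscans == 1

    def test_order_follows_manifest_rule(self, volume, tmp_path):
        paths = write_volume(volume, tmp_path / "v1")
        reordered = [p.name for p in reversed(paths)]
        back = read_volume(tmp_path / "v1", order_rule="manifest",
                           bscan_files=reordered)
        assert np.allclose(back.bscans, volume.bscans[::-1], atol=1e-4)

    def test_mixed_sizes_rejected(self, tmp_path):
        from PIL import Image
        d = tmp_path / "bad"
        d.mkdir()
        Image.fromarray(np.zeros((8, 8), dtype=np.uint8)).save(d / "a.png")
        Image.fromarray(np.zeros((9, 8), dtype=np.uint8)).save(d / "b.png")
        with pytest.raises(ValueError, match="mixed"):
            read_volume(d)

    def test_missing_path_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "nope")

    def test_intensities_scaled_to_unit_interval(self, tmp_path):
        from PIL import Image
        d = tmp_path / "v"
        d.mkdir()
        Image.fromarray(np.full((4, 4), 255, dtype=np.uint8)).save(d / "a.png")
        vol = read_volume(d)
        assert vol.bscans.max() == 1.0

    def test_mat_container_roundtrip(self, tmp_path):
        from scipy.io import savemat
        arr = np.random.default_rng(1).random((10, 12, 6))  # H, W, B
        savemat(tmp_path / "vol.mat", {"images": arr})
        vol = read_volume(tmp_path / "vol.mat", mat_axis_order=(0, 1, 2))
        assert vol.bscans.shape == (6, 10, 12)
        assert np.allclose(vol.bscans, np.transpose(arr, (2, 0, 1)))


class TestManifest:
    def _write(self, tmp_path, rows, **kwargs):
        entries = [ManifestEntry(volume_id=f"{lab}{i}", path=f"{lab}{i}", label=lab)
                   for lab, n in rows for i in range(n)]
        m = DatasetManifest(entries=entries, **kwargs)
        return write_manifest(m, tmp_path / "manifest.csv")

    def test_class_counts_duke_sizes(self, tmp_path):
        """A 269 AMD + 115 NOR manifest reports exactly those class counts."""
        p = self._write(tmp_path, [("AMD", 269), ("NOR", 115)],
                        class_names=["NOR", "AMD"], positive_class="AMD")
        m = read_manifest(p, class_names=["NOR", "AMD"], positive_class="AMD")
        assert m.class_counts() == {"AMD": 269, "NOR": 115}

    def test_singleton_manifest(self, tmp_path):
        p = self._write(tmp_path, [("AMD", 1)], class_names=["AMD"],
                        positive_class="AMD")
        assert len(read_manifest(p).entries) == 1

    def test_unknown_label_rejected(self, tmp_path):
        p = self._write(tmp_path, [("AMD", 2), ("DME", 1)],
                        class_names=["AMD", "DME"], positive_class="DME")
        with pytest.raises(ValueError, match="label"):
            read_manifest(p, class_names=["AMD", "NOR"], positive_class="AMD")

    def test_duplicate_ids_rejected(self):
        e = ManifestEntry(volume_id="x", path="x", label="A")
        with pytest.raises(ValueError, match="duplicate"):
            DatasetManifest(entries=[e, e], class_names=["A"], positive_class="A")

    def test_exactly_one_positive_class(self, tmp_path):
        p = self._write(tmp_path, [("AMD", 2), ("NOR", 2)],
                        class_names=["NOR", "AMD"], positive_class="AMD")
        m = read_manifest(p, class_names=["NOR", "AMD"], positive_class="AMD")
        assert m.positive_class == "AMD"
        assert m.negative_class() == "NOR"


class TestFeatureMapIO:
    def test_hdf5_roundtrip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(2)
        fmap = FeatureMap(rng.random((100, 2048)), "v9", "NOR", "ext1")
        write_feature_map(fmap, tmp_path / "m.h5")
        back = read_feature_map(tmp_path / "m.h5")
        assert np.array_equal(back.values, fmap.values)
        assert (back.volume_id, back.label, back.extractor_id) == ("v9", "NOR", "ext1")

    def test_one_by_one_roundtrip(self, tmp_path):
        fmap = FeatureMap(np.array([[3.5]]), "tiny", None, "e")
        write_feature_map(fmap, tmp_path / "m.h5")
        assert read_feature_map(tmp_path / "m.h5").values.item() == 3.5

    def test_csv_roundtrip_within_tolerance(self, tmp_path):
        fmap = FeatureMap(np.random.default_rng(3).random((4, 6)), "c", "AMD", "e")
        write_feature_map(fmap, tmp_path / "m.csv")
        back = read_feature_map(tmp_path / "m.csv")
        assert np.allclose(back.values, fmap.values, atol=1e-6)

    def test_corrupted_metadata_rejected(self, tmp_path):
        import h5py
        p = tmp_path / "bad.h5"
        with h5py.File(p, "w") as f:
            ds = f.create_dataset("feature_map", data=np.zeros((3, 4)))
            ds.attrs["L"] = 99  # inconsistent with the 4 columns
        with pytest.raises(IOError, match="mismatch"):
            read_feature_map(p)

    def test_nonfinite_values_rejected(self, tmp_path):
        fmap = FeatureMap(np.array([[np.nan, 1.0]]), "n", None, "e")
        with pytest.raises(ValueError, match="finite"):
            write_feature_map(fmap, tmp_path / "m.h5")
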