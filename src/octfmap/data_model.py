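"""Volume data model and I/O: volumes, manifests, labels, feature maps.

An OCT volume is an ordered stack of grayscale B-scans with one volume-level
label. Volumes are read from directories of PNG/TIFF images (ordering from a
manifest or lexicographic filenames) or from MAT containers holding one 3-D
array. Feature maps are serialized to HDF5 (lossless) with CSV as a
human-readable alternative.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "Volume", "DatasetManifest", "ManifestEntry",
    "read_volume", "write_volume", "read_manifest", "write_manifest",
    "read_feature_map", "write_feature_map",
]

_BIT_DEPTH_MAX = {np.dtype("uint8"): 255.0, np.dtype("uint16"): 65535.0}
_IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


@dataclass
class Volume:
    """An ordered stack of same-size grayscale B-scans with one label.

    Intensities are stored as float arrays scaled to [0, 1]. B-scan order is
    the acquisition order and is preserved end-to-end; indexing is 0-based.
    """

    volume_id: str
    bscans: np.ndarray  # (n_bscans, height, width), float in [0, 1]
    label: str | None = None

    def __post_init__(self):
        self.bscans = np.asarray(self.bscans, dtype=np.float64)
        if self.bscans.ndim != 3 or self.bscans.shape[0] < 1:
            raise ValueError(
                f"volume {self.volume_id!r}: bscans must be a (n>=1, H, W) stack, "
                f"got shape {self.bscans.shape}")

    @property
    def n_bscans(self) -> int:
        return self.bscans.shape[0]

    @property
    def bscan_shape(self) -> tuple[int, int]:
        return self.bscans.shape[1], self.bscans.shape[2]


@dataclass(frozen=True)
class ManifestEntry:
    volume_id: str
    path: str
    label: str
    n_bscans: int | None = None


@dataclass
class DatasetManifest:
    """Listing of volumes with labels, plus the class roster.

    ``class_names`` is the ordered list of the K classes; exactly one class
    is designated positive, which orients sensitivity/specificity.
    """

    entries: list[ManifestEntry]
    class_names: Sequence[str]
    positive_class: str

    def __post_init__(self):
        if not self.entries:
            raise ValueError("manifest has no entries")
        ids = [e.volume_id for e in self.entries]
        dupes = {v for v in ids if ids.count(v) > 1}
        if dupes:
            raise ValueError(f"duplicate volume_id(s) in manifest: {sorted(dupes)}")
        if self.positive_class not in self.class_names:
            raise ValueError(
                f"positive class {self.positive_class!r} not in class_names "
                f"{list(self.class_names)}")
        for e in self.entries:
            if e.label not in self.class_names:
                raise ValueError(
                    f"volume {e.volume_id!r} has label {e.label!r} not in "
                    f"class_names {list(self.class_names)}")

    @property
    def volume_ids(self) -> list[str]:
        return [e.volume_id for e in self.entries]

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.entries]

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.class_names}
        for e in self.entries:
            counts[e.label] += 1
        return counts

    def negative_class(self) -> str:
        """The non-positive class of a two-class manifest."""
        others = [c for c in self.class_names if c != self.positive_class]
        if len(others) != 1:
            raise ValueError("negative class defined only for two-class manifests")
        return others[0]

    def subset(self, volume_ids: Sequence[str]) -> "DatasetManifest":
        wanted = set(volume_ids)
        return DatasetManifest(
            entries=[e for e in self.entries if e.volume_id in wanted],
            class_names=list(self.class_names),
            positive_class=self.positive_class)


# --------------------------------------------------------------------- images

def _load_image(path: Path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("I") if im.mode in ("I;16", "I") else im.convert("L"))
    except Exception as exc:  # noqa: BLE001 - re-raise with the offending file
        raise IOError(f"unreadable image file: {path}") from exc
    if arr.dtype == np.int32:  # Pillow "I" mode for 16-bit sources
        arr = arr.astype(np.uint16)
    scale = _BIT_DEPTH_MAX.get(arr.dtype)
    if scale is None:
        raise IOError(f"unsupported pixel type {arr.dtype} in {path}")
    return arr.astype(np.float64) / scale


def _natural_key(name: str):
    return [int(tok) if tok.isdigit() else tok for tok in re.split(r"(\d+)", name)]


def read_volume(path: str | Path, volume_id: str | None = None,
                label: str | None = None, order_rule: str = "lexicographic",
                bscan_files: Sequence[str] | None = None,
                mat_axis_order: tuple[int, int, int] = (0, 1, 2)) -> Volume:
    """Read one OCT volume from an image directory or a MAT container.

    Parameters
    ----------
    path:
        Directory of PNG/TIFF B-scans, or a ``.mat`` file with one 3-D array.
    order_rule:
        ``"lexicographic"`` (natural-sort filenames) or ``"manifest"``
        (explicit ``bscan_files`` list, acquisition order).
    mat_axis_order:
        Positions of (height, width, n_bscans) in the MAT array; default
        follows the Duke layout (height, width, n_bscans).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume path does not exist: {path}")
    vid = volume_id if volume_id is not None else path.stem
    if path.is_file() and path.suffix.lower() == ".mat":
        stack = _read_mat_stack(path, mat_axis_order)
    else:
        if order_rule == "manifest":
            if bscan_files is None:
                raise ValueError("order_rule='manifest' requires bscan_files")
            files = [path / f for f in bscan_files]
        elif order_rule == "lexicographic":
            files = sorted(
                (p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES),
                key=lambda p: _natural_key(p.name))
        else:
            raise ValueError(f"unknown order_rule {order_rule!r}")
        if not files:
            raise FileNotFoundError(f"no B-scan images found under {path}")
        images = [_load_image(f) for f in files]
        shapes = {im.shape for im in images}
        if len(shapes) > 1:
            raise ValueError(
                f"mixed B-scan sizes {sorted(shapes)} within volume directory {path}")
        stack = np.stack(images, axis=0)
    return Volume(volume_id=vid, bscans=stack, label=label)


def _read_mat_stack(path: Path, axis_order: tuple[int, int, int]) -> np.ndarray:
    """Load the single 3-D array from a MAT file (v7.3/HDF5 or classic)."""
    arrays: dict[str, np.ndarray] = {}
    try:
        from scipy.io import loadmat
        mat = loadmat(path)
        arrays = {k: np.asarray(v) for k, v in mat.items()
                  if not k.startswith("__") and np.asarray(v).ndim == 3}
    except (NotImplementedError, ValueError):
        with h5py.File(path, "r") as f:
            for k in f:
                d = f[k]
                if isinstance(d, h5py.Dataset) and d.ndim == 3:
                    arrays[k] = d[()]
    if len(arrays) != 1:
        raise IOError(
            f"expected exactly one 3-D array in MAT container {path}, "
            f"found {sorted(arrays)}")
    arr = next(iter(arrays.values())).astype(np.float64)
    h_ax, w_ax, b_ax = axis_order
    arr = np.transpose(arr, (b_ax, h_ax, w_ax))
    peak = arr.max()
    if peak > 1.0:
        scale = 255.0 if peak <= 255.0 else 65535.0
        arr = arr / scale
    return np.clip(arr, 0.0, 1.0)


def write_volume(volume: Volume, out_dir: str | Path, fmt: str = "png") -> list[Path]:
    """Write a volume as 16-bit images, one per B-scan, index-named."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, scan in enumerate(volume.bscans):
        arr = np.round(np.clip(scan, 0.0, 1.0) * 65535.0).astype(np.uint16)
        p = out_dir / f"bscan_{i:04d}.{fmt}"
        Image.fromarray(arr).save(p)
        paths.append(p)
    return paths


# ------------------------------------------------------------------ manifests

def read_manifest(path: str | Path, class_names: Sequence[str] | None = None,
                  positive_class: str | None = None) -> DatasetManifest:
    """Read a CSV/TSV manifest with columns volume_id, path, label.

    ``class_names``/``positive_class`` default to the sorted labels present
    and the first class name respectively; pass them explicitly to pin the
    positive-class convention (e.g. AMD positive vs NOR negative).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"volume_id", "path", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest {path} must have columns {sorted(required)}")
    if df.empty:
        raise ValueError(f"manifest {path} is empty")
    if class_names is None:
        class_names = sorted(df["label"].unique())
    if positive_class is None:
        positive_class = class_names[0]
    n_col = pd.to_numeric(df["n_bscans"], errors="coerce") if "n_bscans" in df.columns else None
    entries = [
        ManifestEntry(
            volume_id=row.volume_id, path=row.path, label=row.label,
            n_bscans=(int(n_col.iloc[i])
                      if n_col is not None and pd.notna(n_col.iloc[i]) else None))
        for i, row in enumerate(df.itertuples(index=False))]
    return DatasetManifest(entries=entries, class_names=list(class_names),
                           positive_class=positive_class)


def write_manifest(manifest: DatasetManifest, path: str | Path) -> Path:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.DataFrame(
        {"volume_id": [e.volume_id for e in manifest.entries],
         "path": [e.path for e in manifest.entries],
         "label": [e.label for e in manifest.entries],
         "n_bscans": [e.n_bscans for e in manifest.entries]})
    df.to_csv(path, sep=sep, index=False)
    return path


# ---------------------------------------------------------------- feature maps

def write_feature_map(fmap, path: str | Path) -> Path:
    """Serialize a feature map to HDF5 (bit-exact) or CSV (1e-6 accurate)."""
    from .feature_map import FeatureMap  # local import to avoid a cycle

    assert isinstance(fmap, FeatureMap)
    if not np.all(np.isfinite(fmap.values)):
        raise ValueError("feature map contains non-finite values")
    path = Path(path)
    if path.suffix.lower() == ".csv":
        np.savetxt(path, fmap.values, delimiter=",",
                   header=f"volume_id={fmap.volume_id} label={fmap.label} "
                          f"extractor_id={fmap.extractor_id}")
        return path
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("feature_map", data=fmap.values)
        ds.attrs["volume_id"] = fmap.volume_id
        ds.attrs["label"] = fmap.label if fmap.label is not None else ""
        ds.attrs["extractor_id"] = fmap.extractor_id
        ds.attrs["L"] = fmap.values.shape[1]
    return path


def read_feature_map(path: str | Path):
    from .feature_map import FeatureMap

    path = Path(path)
    if path.suffix.lower() == ".csv":
        with open(path) as fh:
            header = fh.readline().lstrip("# ").split()
        meta = dict(tok.split("=", 1) for tok in header if "=" in tok)
        values = np.loadtxt(path, delimiter=",", ndmin=2)
        return FeatureMap(values=values, volume_id=meta.get("volume_id", ""),
                          label=meta.get("label") or None,
                          extractor_id=meta.get("extractor_id", ""))
    with h5py.File(path, "r") as f:
        if "feature_map" not in f:
            raise IOError(f"{path}: missing 'feature_map' dataset")
        ds = f["feature_map"]
        values = ds[()]
        if values.ndim != 2:
            raise IOError(f"{path}: feature_map dataset is not 2-D")
        stored_l = int(ds.attrs.get("L", values.shape[1]))
        if stored_l != values.shape[1]:
            raise IOError(
                f"{path}: shape metadata mismatch (L={stored_l}, "
                f"columns={values.shape[1]})")
        label = str(ds.attrs.get("label", "")) or None
        return FeatureMap(values=values, volume_id=str(ds.attrs.get("volume_id", "")),
                          label=label, extractor_id=str(ds.attrs.get("extractor_id", "")))
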