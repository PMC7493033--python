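"""2-D feature maps: row-stacked B-scan feature vectors of one OCT volume.

The global representation of a volume with ``|Xi|`` B-scans and an extractor
of feature length ``L`` is the ``(|Xi|, L)`` matrix whose row ``i`` is the
feature vector of B-scan ``i`` in acquisition order. For the Duke geometry
(100 B-scans of 1000x512 pixels, L=2048) this reduces 51,200,000 voxels to
204,800 matrix elements — a 250:1 reduction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_model import Volume

__all__ = [
    "FeatureMap", "build_feature_map", "flatten_lexicographic",
    "unflatten_lexicographic", "reduction_ratio", "plot_feature_map",
    "plot_feature_vectors",
]


@dataclass
class FeatureMap:
    """Row-stacked B-scan features of one volume, shape (n_bscans, L)."""

    values: np.ndarray
    volume_id: str
    label: str | None = None
    extractor_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"feature map must be 2-D, got shape {self.values.shape}")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def feature_length(self) -> int:
        return self.values.shape[1]


def build_feature_map(volume: Volume, extractor) -> FeatureMap:
    """Extract every B-scan's feature vector and stack them row-by-row.

    The extractor must be in inference mode; row ``i`` of the result equals
    ``extractor.extract_feature`` applied to B-scan ``i`` alone.
    """
    if volume.n_bscans < 1:
        raise ValueError("cannot build a feature map from an empty volume")
    rows = extractor.extract_features(volume.bscans)
    return FeatureMap(values=rows, volume_id=volume.volume_id, label=volume.label,
                      extractor_id=extractor.extractor_id)


def flatten_lexicographic(fmap: FeatureMap | np.ndarray) -> np.ndarray:
    """Flatten a map row-major: element (i, j) lands at index i*L + j."""
    values = fmap.values if isinstance(fmap, FeatureMap) else np.asarray(fmap)
    return values.reshape(-1, order="C").copy()


def unflatten_lexicographic(vec: np.ndarray, n_rows: int, feature_length: int) -> np.ndarray:
    """Inverse of :func:`flatten_lexicographic`."""
    vec = np.asarray(vec)
    if vec.size != n_rows * feature_length:
        raise ValueError(
            f"vector of size {vec.size} cannot reshape to ({n_rows}, {feature_length})")
    return vec.reshape(n_rows, feature_length, order="C")


def reduction_ratio(n_bscans: int, height: int, width: int, feature_length: int
                    ) -> tuple[int, int, float]:
    """Voxel count, feature-map element count and their ratio.

    For 100 B-scans of 1000x512 and L=2048: (51_200_000, 204_800, 250.0).
    """
    voxels = height * n_bscans * width
    elements = n_bscans * feature_length
    return voxels, elements, voxels / elements


def plot_feature_map(fmap: FeatureMap, out_path: str | Path,
                     vmin: float | None = None, vmax: float | None = None) -> Path:
    """Render the map as a heat map with a color bar over the value range."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    im = ax.imshow(fmap.values, aspect="auto", cmap="viridis", vmin=vmin, vmax=vmax)
    ax.set_xlabel("feature index")
    ax.set_ylabel("B-scan index")
    title = fmap.volume_id + (f" ({fmap.label})" if fmap.label else "")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="feature value")
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return out_path


def plot_feature_vectors(fmap: FeatureMap, rows: slice | list[int],
                         out_path: str | Path) -> Path:
    """Line plot of selected rows (B-scan feature vectors) of one map."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    selected = fmap.values[rows]
    fig, ax = plt.subplots(figsize=(8, 4))
    for vec in np.atleast_2d(selected):
        ax.plot(vec, lw=0.6, alpha=0.7)
    ax.set_xlabel("feature index")
    ax.set_ylabel("feature value")
    ax.set_title(f"{fmap.volume_id}: {np.atleast_2d(selected).shape[0]} B-scan feature vectors")
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return out_path
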