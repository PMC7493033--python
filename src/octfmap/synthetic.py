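"""Synthetic two-class OCT-like volumes and 2-D feature maps.

Two generators make every downstream stage testable without any external
download:

* :func:`generate_volumes` emulates retina-like B-scans: a dark background
  with one bright horizontal band whose depth varies smoothly across columns
  and across B-scans, plus Gaussian pixel noise. Diseased ("AMD"-like)
  volumes additionally carry Gaussian-profile bumps that deform the band and
  add a fluid-like hyper-reflective blob beneath it — but only in a
  contiguous 30-70% subset of their B-scans, so a diseased volume contains
  normal-looking B-scans and inherited B-scan labels are genuinely noisy.

* :func:`generate_feature_maps` emulates the class contrast of real 2-D
  feature maps: the normal-like class is more uniform and higher-valued,
  rows carry AR(1) correlation (B-scan features of neighbouring slices are
  correlated), and all values are clipped to [0, 5].

With zero effect size (``lesion_amplitude=0`` / ``class_mean_shift=0``) the
two classes are identical in distribution; a fixed seed yields
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_model import DatasetManifest, ManifestEntry, Volume, write_manifest, write_volume
from .feature_map import FeatureMap

__all__ = [
    "SynthVolumeSpec", "SynthMapSpec", "generate_volumes",
    "generate_feature_maps", "band_roughness", "write_volume_dataset",
]

POSITIVE_CLASS = "AMD"   # lesion-carrying class
NEGATIVE_CLASS = "NOR"


@dataclass(frozen=True)
class SynthVolumeSpec:
    """Study conditions for the synthetic volume generator.

    Defaults give 50+50 small volumes (16 B-scans of 24x24) whose classes
    are strongly separable (amplitude 0.5 vs pixel noise 0.05) — the
    high-separability regime used for end-to-end recovery checks.
    """

    n_volumes_per_class: int = 50
    n_bscans: int = 16
    height: int = 24
    width: int = 24
    lesion_amplitude: float = 0.5
    lesion_width: float = 6.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if min(self.n_volumes_per_class, self.n_bscans, self.height, self.width) < 1:
            raise ValueError("all counts and dimensions must be positive")
        if not (0.0 <= self.lesion_amplitude <= 1.0):
            raise ValueError("lesion_amplitude must lie in [0, 1]")


@dataclass(frozen=True)
class SynthMapSpec:
    """Study conditions for the synthetic feature-map generator."""

    n_per_class: int = 50
    rows: int = 25
    cols: int = 64
    class_mean_shift: float = 1.0
    row_corr: float = 0.6
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")
        if not (0.0 <= self.row_corr < 1.0):
            raise ValueError("row_corr must lie in [0, 1)")


def _band_image(height: int, width: int, centers: np.ndarray,
                band_sigma: float, brightness: np.ndarray | float) -> np.ndarray:
    """Render one B-scan: bright band of Gaussian depth profile per column."""
    rows = np.arange(height)[:, None]
    return brightness * np.exp(-0.5 * ((rows - centers[None, :]) / band_sigma) ** 2)


def generate_volumes(spec: SynthVolumeSpec) -> tuple[list[Volume], DatasetManifest]:
    """Generate labeled two-class volumes plus an in-memory manifest.

    Negative-class ("NOR") volumes show a smooth band; positive-class
    ("AMD") volumes carry, in a contiguous 30-70% stretch of their B-scans,
    a Gaussian bump of width ``lesion_width`` that pushes the band upward
    and deposits extra intensity of scale ``lesion_amplitude`` beneath it.
    """
    rng = np.random.default_rng(spec.seed)
    h, w, nb = spec.height, spec.width, spec.n_bscans
    cols = np.arange(w)
    band_sigma = max(h / 16.0, 1.0)
    volumes: list[Volume] = []
    entries: list[ManifestEntry] = []
    for label in (NEGATIVE_CLASS, POSITIVE_CLASS):
        for v in range(spec.n_volumes_per_class):
            vid = f"{label}{v:03d}"
            base_depth = rng.uniform(0.35, 0.65) * h
            tilt = rng.uniform(-0.1, 0.1)
            drift_phase = rng.uniform(0, 2 * np.pi)
            drift_amp = rng.uniform(0.0, 0.05) * h
            brightness = rng.uniform(0.75, 0.9)
            lesioned = np.zeros(nb, dtype=bool)
            if label == POSITIVE_CLASS and spec.lesion_amplitude > 0:
                frac = rng.uniform(0.3, 0.7)
                span = max(1, int(round(frac * nb)))
                start = int(rng.integers(0, nb - span + 1))
                lesioned[start:start + span] = True
                lesion_col = rng.uniform(0.25, 0.75) * w
            scans = np.empty((nb, h, w))
            for b in range(nb):
                # smooth depth variation across columns and across B-scans
                centers = (base_depth + tilt * (cols - w / 2)
                           + drift_amp * np.sin(2 * np.pi * b / nb + drift_phase))
                img = _band_image(h, w, centers, band_sigma, brightness)
                img += 0.05  # dim background
                if lesioned[b]:
                    bump = np.exp(-0.5 * ((cols - lesion_col) / spec.lesion_width) ** 2)
                    # bump deforms the band upward ...
                    deformed = centers - spec.lesion_amplitude * 0.25 * h * bump
                    img = _band_image(h, w, deformed, band_sigma, brightness) + 0.05
                    # ... and leaves a fluid-like bright pocket beneath it
                    rows = np.arange(h)[:, None]
                    pocket = np.exp(-0.5 * (((rows - centers[None, :]) / (2 * band_sigma)) ** 2
                                            + ((cols[None, :] - lesion_col) / spec.lesion_width) ** 2))
                    img += spec.lesion_amplitude * 0.5 * pocket
                img += rng.normal(0.0, spec.noise_sd, size=(h, w))
                scans[b] = np.clip(img, 0.0, 1.0)
            volumes.append(Volume(volume_id=vid, bscans=scans, label=label))
            entries.append(ManifestEntry(volume_id=vid, path=vid, label=label,
                                         n_bscans=nb))
    manifest = DatasetManifest(entries=entries,
                               class_names=[NEGATIVE_CLASS, POSITIVE_CLASS],
                               positive_class=POSITIVE_CLASS)
    return volumes, manifest


def band_roughness(volume: Volume, smooth: int = 3) -> float:
    """Band-deviation statistic: how far the bright band departs from a
    straight course anywhere in the volume.

    Per B-scan, the band depth is the per-column intensity-argmax, smoothed
    with a short moving average to suppress single-column noise, then
    detrended with a linear fit (the clean band is a tilted line). The
    statistic is the maximum absolute residual over columns, maximised over
    B-scans. Lesion bumps push the band off its line, so a simple threshold
    separates the classes at high amplitude — a learning-free separability
    check that needs no training.
    """
    kernel = np.ones(smooth) / smooth
    per_scan = []
    for scan in volume.bscans:
        depth = scan.argmax(axis=0).astype(float)
        depth_s = np.convolve(depth, kernel, mode="valid")
        x = np.arange(depth_s.size)
        coef = np.polyfit(x, depth_s, 1)
        per_scan.append(np.abs(depth_s - np.polyval(coef, x)).max())
    return float(np.max(per_scan))


def generate_feature_maps(spec: SynthMapSpec) -> list[FeatureMap]:
    """Generate labeled two-class 2-D feature maps, values clipped to [0, 5].

    Each map is a class mean pattern plus AR(1)-correlated row offsets
    (coefficient ``row_corr``) plus i.i.d. noise. The normal-like class has
    the higher mean and the smaller row-to-row variance; both the mean gap
    and the variance gap scale with ``class_mean_shift``, so a zero shift
    makes the classes identical in distribution.
    """
    rng = np.random.default_rng(spec.seed)
    maps: list[FeatureMap] = []
    base = 2.5
    col_texture = 0.3 * np.sin(np.linspace(0, 4 * np.pi, spec.cols))
    for label in (NEGATIVE_CLASS, POSITIVE_CLASS):
        if label == NEGATIVE_CLASS:
            mean = base + spec.class_mean_shift / 2.0
            row_sd = spec.noise_sd
        else:
            mean = base - spec.class_mean_shift / 2.0
            row_sd = spec.noise_sd * (1.0 + spec.class_mean_shift)
        for v in range(spec.n_per_class):
            offsets = np.empty(spec.rows)
            innov_sd = row_sd * np.sqrt(1.0 - spec.row_corr ** 2)
            offsets[0] = rng.normal(0.0, row_sd)
            for i in range(1, spec.rows):
                offsets[i] = spec.row_corr * offsets[i - 1] + rng.normal(0.0, innov_sd)
            values = (mean + col_texture[None, :] + offsets[:, None]
                      + rng.normal(0.0, spec.noise_sd / 2.0, size=(spec.rows, spec.cols)))
            maps.append(FeatureMap(values=np.clip(values, 0.0, 5.0),
                                   volume_id=f"{label}{v:03d}", label=label,
                                   extractor_id="synthetic"))
    return maps


def write_volume_dataset(volumes: list[Volume], manifest: DatasetManifest,
                         out_dir: str | Path) -> Path:
    """Write volumes as PNG directories plus a ``manifest.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for vol, entry in zip(volumes, manifest.entries):
        vol_dir = out_dir / vol.volume_id
        write_volume(vol, vol_dir)
        entries.append(ManifestEntry(volume_id=entry.volume_id, path=vol.volume_id,
                                     label=entry.label, n_bscans=vol.n_bscans))
    on_disk = DatasetManifest(entries=entries, class_names=list(manifest.class_names),
                              positive_class=manifest.positive_class)
    return write_manifest(on_disk, out_dir / "manifest.csv")
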