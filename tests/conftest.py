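"""Shared fixtures: small synthetic datasets and a fitted tiny extractor.

Everything is generated programmatically with fixed seeds; session scope
keeps the expensive pieces (extractor fine-tuning) to one run.
"""

from __future__ import annotations

import pytest

from octfmap.classifiers import VolumeClassifierConfig
from octfmap.extractor import (ExtractorConfig, FineTuneConfig,
                               create_extractor, fine_tune,
                               make_bscan_training_set)
from octfmap.feature_map import build_feature_map
from octfmap.synthetic import SynthMapSpec, SynthVolumeSpec, generate_volumes, generate_feature_maps

# desk-scale training protocol: from-scratch learning rate for the tiny
# backbone and a minibatch scaled to the small map sets
DESK_FT = FineTuneConfig(frozen_blocks=frozenset(), lr=1e-2, epochs=3,
                         augment=False, seed=0)
DESK_CLF = VolumeClassifierConfig(kind="cnn_cbam", n_blocks=2, epochs=30,
                                  batch_size=16, seed=0)


@pytest.fixture(scope="session")
def small_volume_dataset():
    """12+12 tiny volumes (8 B-scans of 24x24), strongly separable."""
    spec = SynthVolumeSpec(n_volumes_per_class=12, n_bscans=8, seed=42)
    return generate_volumes(spec)


@pytest.fixture(scope="session")
def synthetic_maps():
    spec = SynthMapSpec(n_per_class=20, seed=7)
    return generate_feature_maps(spec)


@pytest.fixture(scope="session")
def fitted_extractor(small_volume_dataset):
    """Tiny-cnn extractor fine-tuned on the small synthetic training set."""
    volumes, _ = small_volume_dataset
    ext = create_extractor(ExtractorConfig(), n_classes=2, seed=3)
    samples = make_bscan_training_set(volumes)
    ext, losses = fine_tune(ext, samples, DESK_FT)
    return ext, losses


@pytest.fixture(scope="session")
def small_feature_maps(small_volume_dataset, fitted_extractor):
    volumes, _ = small_volume_dataset
    ext, _ = fitted_extractor
    return [build_feature_map(v, ext) for v in volumes]
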