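"""Shared fixtures: a small phantom archive and desk-scale model configs.

Everything is generated programmatically at test time; nothing is read from
checked-in data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from cbmir.model import FeatureExtractor, TrainConfig
from cbmir.phantom import PhantomConfig, generate_phantom_dataset, split_patients


@pytest.fixture(scope="session")
def mini_config() -> PhantomConfig:
    # 7 classes x 2 patients x 6-8 slices at 128 px: enough structure for
    # integration tests while staying fast
    return PhantomConfig(
        patients_per_class=2,
        slices_per_patient=(6, 8),
        image_size=128,
        lesion_size_range=(4, 18),
        seed=7,
    )


@pytest.fixture(scope="session")
def mini_dataset(mini_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("phantom")
    ds = generate_phantom_dataset(mini_config, out_dir=out, keep_pixels=True, keep_masks=True)
    ds.out_dir = out
    return ds


@pytest.fixture(scope="session")
def mini_manifest(mini_dataset):
    return split_patients(mini_dataset.manifest, 0.5, seed=11)


@pytest.fixture(scope="session")
def tiny_model() -> FeatureExtractor:
    """Untrained tiny-backbone extractor (deterministic init) for plumbing tests."""
    cfg = TrainConfig.desk(seed=5, iterations=1, tiny_channels=32, embedding_dim=64)
    return FeatureExtractor(cfg, rng=np.random.default_rng(5))
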