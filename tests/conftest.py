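"""Shared fixtures.

The expensive end-to-end training runs (used by the scaled-down recovery
and ablation acceptance tests) are computed once per session and shared.
"""

from __future__ import annotations

import numpy as np
import pytest

from lungpaste.metrics import roc_auc
from lungpaste.model import TrainConfig, build_model, extract_features
from lungpaste.phantom import default_spec, generate_normal_phantom
from lungpaste.pipeline import make_phantom_set
from lungpaste.scoring import kde_raw_scores
from lungpaste.segmentation import SegmentationParams, segment_lungs
from lungpaste.train import train

TINY_SIZE = 64
E2E_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def phantom_256():
    return generate_normal_phantom(default_spec(rng_seed=0))


@pytest.fixture(scope="session")
def phantom_64():
    return generate_normal_phantom(default_spec(image_size=TINY_SIZE, rng_seed=0))


@pytest.fixture(scope="session")
def lung_mask_64(phantom_64):
    return segment_lungs(phantom_64.image, SegmentationParams.for_image_size(TINY_SIZE))


@pytest.fixture(scope="session")
def segmented_phantoms_256():
    """20 default phantoms with their segmentation outputs (shared by several tests)."""
    samples, masks = [], []
    for seed in range(20):
        sample = generate_normal_phantom(default_spec(rng_seed=seed))
        samples.append(sample)
        masks.append(segment_lungs(sample.image))
    return samples, masks


def _run_end_to_end(seed: int, mode: str) -> dict:
    """One scaled-down training run; returns test AUCs for trained and random-init."""
    from lungpaste.augment import AugmentParams

    train_set, _ = make_phantom_set(200, 0, TINY_SIZE, seed, "train")
    images = [s.image for s in train_set]
    seg_params = SegmentationParams.for_image_size(TINY_SIZE)
    masks = [segment_lungs(im, seg_params) for im in images]
    val_set, val_labels = make_phantom_set(20, 20, TINY_SIZE, seed, "val")
    test_set, test_labels = make_phantom_set(50, 50, TINY_SIZE, seed, "test")

    config = TrainConfig.tiny(seed=seed, epochs=20)
    aug_params = AugmentParams.for_image_size(TINY_SIZE, mode=mode)
    result = train(images, masks, [s.image for s in val_set], val_labels, config, aug_params)

    test_stack = np.stack([s.image for s in test_set])
    bank = extract_features(result.model, np.stack(images))
    trained_auc = roc_auc(kde_raw_scores(extract_features(result.model, test_stack), bank), test_labels)

    untrained = build_model(config)
    untrained.norm_mean, untrained.norm_std = result.model.norm_mean, result.model.norm_std
    bank0 = extract_features(untrained, np.stack(images))
    random_auc = roc_auc(kde_raw_scores(extract_features(untrained, test_stack), bank0), test_labels)

    return {
        "trained_auc": trained_auc,
        "random_init_auc": random_auc,
        "best_val_auc": result.best_val_auc,
        "log": result.log,
    }


@pytest.fixture(scope="session")
def e2e_full_runs():
    """Mode=full end-to-end runs over three seeds (several minutes; shared)."""
    return {seed: _run_end_to_end(seed, "full") for seed in E2E_SEEDS}


@pytest.fixture(scope="session")
def e2e_no_blur_runs():
    """Mode=no_blur ablation runs over the same three seeds."""
    return {seed: _run_end_to_end(seed, "no_blur") for seed in E2E_SEEDS}
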