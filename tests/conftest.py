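"""Shared fixtures.

``pipeline`` runs the full scaled-down simulated-data experiment once
per session (it is the expensive fixture all end-to-end and
acceptance-level tests share); ``tiny_model`` is a quickly trained
small model for tests that only need a plausible trained network.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

import hrcam
from hrcam import (CNNClassifier, HRCAM, SimulationConfig, TrainConfig,
                   generate_dataset)

PIPELINE_SEED = 11


@dataclass
class Pipeline:
    """Artifacts of the end-to-end simulated-data experiment."""

    model: CNNClassifier
    stage1: "hrcam.ClassifierResults"
    stage2: "hrcam.HRCAMResults"
    train_images: list
    test_images: list


@pytest.fixture(scope="session")
def pipeline() -> Pipeline:
    """600 training + 200 validation synthetic 64x64 images, default
    simulator settings; stage-1 CNN then stage-2 head; 60 held-out
    abnormal test images from a disjoint seed stream."""
    images = generate_dataset(
        SimulationConfig(n_per_class=400, seed=PIPELINE_SEED))
    model = hrcam.build_backbone("simple", (64, 64), 2)
    stage1 = model.fit(images, TrainConfig(
        epochs=20, validation_fraction=0.25, seed=PIPELINE_SEED))
    stage2 = HRCAM(model).fit(images, TrainConfig(
        epochs=50, validation_fraction=0.25, weight_decay=1e-4,
        seed=PIPELINE_SEED))
    test_images = generate_dataset(
        SimulationConfig(n_per_class=60, seed=PIPELINE_SEED + 10_000))
    return Pipeline(model=model, stage1=stage1, stage2=stage2,
                    train_images=images, test_images=test_images)


@pytest.fixture(scope="session")
def tiny_dataset() -> list:
    return generate_dataset(SimulationConfig(
        n_per_class=30, image_size=(32, 32), seed=5))


@pytest.fixture(scope="session")
def tiny_model(tiny_dataset) -> CNNClassifier:
    """A quickly trained 32x32 model (quality irrelevant, shape matters)."""
    model = hrcam.build_backbone("simple", (32, 32), 2)
    model.fit(tiny_dataset, TrainConfig(
        epochs=2, validation_fraction=0.2, seed=5,
        augment_flip=False, augment_shift=False, augment_rotate=False))
    return model
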