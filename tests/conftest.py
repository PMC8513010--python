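"""Shared fixtures.

Two tiers: a *small* generated dataset with a briefly-trained model for
unit tests, and one *reference* stack at study scale (100 training
actions per class, the full 60-epoch protocol, three seeds per
architecture) that the end-to-end property tests share so the expensive
training happens exactly once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from ttstroke.models import ModelConfig, TrainConfig, build_model, evaluate, train
from ttstroke.synth import GeneratorConfig, dataset_keyframes, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(
        actions_per_class={"train": 12, "val": 6, "major_test": 6, "amateur_test": 6},
        seed=3,
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    dataset, truths = generate_dataset(small_config)
    arrays = dataset_keyframes(dataset)
    return {"dataset": dataset, "truths": truths, "arrays": arrays}


@pytest.fixture(scope="session")
def small_model(small_data):
    """An MDFF classifier trained briefly on the small dataset."""
    x, y = small_data["arrays"]["train"]
    xv, yv = small_data["arrays"]["val"]
    model = build_model(ModelConfig(input_cols=x.shape[2], class_count=5, seed=0), "mdff")
    train(model, x, y, xv, yv, TrainConfig(epochs=8, seed=0))
    return model


@pytest.fixture(scope="session")
def reference_stack():
    """Study-scale stack: dataset, trained models, and their test metrics.

    100 training actions per class; the fusion network and the plain CNN
    are each trained with three seeds under the full 60-epoch protocol.
    """
    config = GeneratorConfig(seed=7)
    dataset, truths = generate_dataset(config)
    arrays = dataset_keyframes(dataset)
    xtr, ytr = arrays["train"]
    xva, yva = arrays["val"]
    xte, yte = arrays["major_test"]
    xam, yam = arrays["amateur_test"]

    models = {"mdff": [], "plain_cnn": []}
    metrics = {"mdff": [], "plain_cnn": []}
    for variant in ("mdff", "plain_cnn"):
        for seed in range(3):
            model = build_model(
                ModelConfig(input_cols=xtr.shape[2], class_count=5, seed=seed), variant
            )
            if seed == 0:
                train(model, xtr, ytr, xva, yva, TrainConfig(epochs=60, seed=seed))
            else:
                train(model, xtr, ytr, tc=TrainConfig(epochs=60, seed=seed))
            models[variant].append(model)
            metrics[variant].append(
                {
                    "major_test": evaluate(model, xte, yte),
                    "amateur_test": evaluate(model, xam, yam),
                }
            )
    return {
        "config": config,
        "dataset": dataset,
        "truths": truths,
        "arrays": arrays,
        "models": models,
        "metrics": metrics,
    }
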