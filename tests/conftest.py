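"""Shared fixtures: small datasets and a quickly trained compact recogniser.

The compact model (3 hidden layers, 4,000 windows) reaches R^2 ~ 0.995 in a
few seconds and is accurate enough (baseline error ~1-2 %DO) to exercise the
controller closed-loop; the full-size architecture is trained only in the
acceptance tests.
"""

import numpy as np
import pytest

from neurostat.mlp import (
    BaselineRecognition,
    ModelConfig,
    TrainingConfig,
    build_model,
    train,
)
from neurostat.synth import GeneratorParams, SyntheticDataset, generate_dataset

SMALL_CONFIG = ModelConfig(hidden_sizes=(256, 128, 64))


@pytest.fixture(scope="session")
def small_dataset() -> SyntheticDataset:
    return generate_dataset(4000, GeneratorParams(), seed=7)


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """Compact recogniser trained on the small dataset (train/test halves kept)."""
    recognition = BaselineRecognition(small_dataset, SMALL_CONFIG, split_seed=7)
    return recognition.fit(TrainingConfig(epochs=40, seed=0))


@pytest.fixture(scope="session")
def small_model(small_fit):
    return small_fit.model


@pytest.fixture(scope="session")
def flat_model():
    """Compact net trained on flat, noise-free, spike-free traces.

    On this corpus the baseline is fully observed (label equals the final
    window value), so a converged model must recover the level almost
    exactly; this isolates the normalisation/training/prediction pipeline
    from the harder spike-inference problem.
    """
    params = GeneratorParams(
        trend_weights=(1.0, 0.0, 0.0),
        drift_max=0.0,
        include_noise=False,
        gap_range=(1e9, 1e9),  # first spike onset beyond any trace: no spikes
    )
    ds = generate_dataset(2000, params, seed=11)
    recognition = BaselineRecognition(ds, SMALL_CONFIG, split_seed=11)
    fit = recognition.fit(TrainingConfig(epochs=80, seed=0))
    return fit
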