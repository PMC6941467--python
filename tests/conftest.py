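"""Shared fixtures: synthetic recordings and cached pipeline runs.

Everything is generated programmatically with fixed seeds; the heavier
60 s grid recordings are session-scoped so each is synthesised and
processed once.
"""

from __future__ import annotations

import numpy as np
import pytest

from fasciq.config import PipelineConfig
from fasciq.pipeline import run_pipeline
from fasciq.synth import SynthParams, generate_recording, preset_params
from fasciq.voluntary import make_training_table, train_classifier


@pytest.fixture()
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def partial_fixture():
    """Partially relaxed 60 s recording: one 7 Hz unit over 21-36 s."""
    return generate_recording(preset_params("partially_relaxed", seed=3))


@pytest.fixture(scope="session")
def partial_run_0(partial_fixture):
    rec, _ = partial_fixture
    return run_pipeline(rec, PipelineConfig(strategy="0"))


@pytest.fixture(scope="session")
def partial_run_1a(partial_fixture):
    rec, _ = partial_fixture
    return run_pipeline(rec, PipelineConfig(strategy="1A"))


@pytest.fixture(scope="session")
def clean_runs():
    """Two clean low-noise recordings with their truths and strategy-0 runs."""
    out = []
    for seed in (1, 2):
        params = SynthParams(
            duration_s=60.0, fasciculation_rate_per_min=40.0,
            noise_sd_uv=2.0, seed=seed,
        )
        rec, truth = generate_recording(params)
        out.append((truth, run_pipeline(rec, PipelineConfig(strategy="0"))))
    return out


@pytest.fixture(scope="session")
def busy_ensemble():
    """Recordings with embedded trains amid dense fasciculation firing.

    High background rates make short intervals common, which is the regime
    where sensitive and specific block durations genuinely trade off.
    """
    out = []
    for seed in (11, 12, 13, 14):
        params = SynthParams(
            duration_s=60.0, fasciculation_rate_per_min=120.0,
            n_voluntary_units=1, voluntary_rate_hz=7.5,
            voluntary_epochs=((20.0, 38.0),), seed=seed,
        )
        rec, truth = generate_recording(params)
        out.append((truth, run_pipeline(rec, PipelineConfig(strategy="0"))))
    return out


@pytest.fixture(scope="session")
def trained_clf():
    X, y = make_training_table(120, seed=7)
    return train_classifier(X, y, PipelineConfig(rng_seed=7))


def included_times(result) -> np.ndarray:
    return np.array([p.peak_time_s for p in result.superchannel.potentials if p.included])
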