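"""Shared fixtures.

Expensive artifacts (sessions, tensor sets, backbone features) are built once
per test session. Unit tests run a reduced geometry — 64 scales / 64x64
images and 20-trial sessions — which exercises every code path at a fraction
of the full 250x250, 160-trial cost; the acceptance tests use the full
geometry.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from cdml_eeg import (PipelineConfig, SyntheticSpec, TrainConfig,
                      build_dataset, extract_trials, simulate_session)


def small_pipeline_config(**synthetic_overrides) -> PipelineConfig:
    synthetic_overrides.setdefault("n_trials", 20)
    syn = SyntheticSpec(**synthetic_overrides)
    return PipelineConfig(synthetic=syn, n_scales=64, out_size=(64, 64),
                          n_subjects=1)


@pytest.fixture(scope="session")
def small_cfg() -> PipelineConfig:
    return small_pipeline_config()


@pytest.fixture(scope="session")
def session_recording(small_cfg):
    rng = np.random.default_rng(1234)
    return simulate_session(small_cfg.synthetic, subject_id="S01", rng=rng)


@pytest.fixture(scope="session")
def trials(session_recording):
    return extract_trials(session_recording)


@pytest.fixture(scope="session")
def small_tensors(trials, small_cfg):
    return build_dataset(trials, small_cfg)


@pytest.fixture(scope="session")
def separable_cfg() -> PipelineConfig:
    """High class-contrast, low noise: near-perfectly separable by design."""
    return small_pipeline_config(n_trials=160, erd_depth=0.9, ers_gain=0.5,
                                 noise_sigma=4.0)


@pytest.fixture(scope="session")
def separable_tensors(separable_cfg):
    rng = np.random.default_rng(99)
    rec = simulate_session(separable_cfg.synthetic, subject_id="S01", rng=rng)
    return build_dataset(extract_trials(rec), separable_cfg)


@pytest.fixture(scope="session")
def quick_train() -> TrainConfig:
    return TrainConfig(epochs=30, seed=7)
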