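"""Shared fixtures: one standard corpus, trained classifier and cohort,
built once per session at the study's standard sizes."""

from __future__ import annotations

import numpy as np
import pytest

from bbbeeg.classifier import TrainConfig
from bbbeeg.pipeline import (RunConfig, apply_to_cohort, make_cohort, make_corpus,
                             train_on_corpus)
from bbbeeg.synth import default_profiles, generate_recording

SEED = 1234


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def run_config():
    return RunConfig(seed=SEED, n_animals=4)


@pytest.fixture(scope="session")
def std_corpus(run_config):
    """Training corpus at the standard size: 715 feature windows per class."""
    return make_corpus(run_config)


@pytest.fixture(scope="session")
def trained(std_corpus, run_config):
    """Classifier results and split counts from the standard corpus."""
    return train_on_corpus(std_corpus, run_config.window_spec,
                           run_config.classifier_spec,
                           TrainConfig(seed=SEED))


@pytest.fixture(scope="session")
def cohort(run_config):
    """Four synthetic animals: baseline -> 1 % -> 4 % isoflurane."""
    return make_cohort(run_config)


@pytest.fixture(scope="session")
def cohort_summaries(trained, cohort, run_config):
    """(traces, summary) per normalization on the standard cohort."""
    results, _ = trained
    return {
        norm: apply_to_cohort(results, cohort, norm, run_config.window_spec,
                              run_config.smooth_window_s, run_config.min_run_s)
        for norm in (1, 2)
    }


@pytest.fixture(scope="session")
def short_recording(profiles):
    """A stationary 300-s baseline recording (25 shifting windows)."""
    return generate_recording([(profiles["baseline"], 300.0)], seed=SEED,
                              recording_id="short")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)
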