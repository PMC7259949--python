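"""Shared fixtures: a small simulated cohort and its pipeline outputs.

Session-scoped so the classifier stage runs once for the whole suite.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from patcomp import behaviour as beh
from patcomp.datatypes import ClassifierSpec
from patcomp.pipeline import apply_qc, build_trialwise_table, run_mvpa
from patcomp.simulate import SimulationConfig, generate_study


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_participants=10, n_voxels=120, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture(scope="session")
def classified_trials(small_study):
    return beh.classify_trials(small_study.trials)


@pytest.fixture(scope="session")
def clean_trials(small_study):
    return beh.classify_trials(apply_qc(small_study))


@pytest.fixture(scope="session")
def clf_spec() -> ClassifierSpec:
    return ClassifierSpec(n_subsamples=3, n_features_per_category=40,
                          n_permutations=199)


@pytest.fixture(scope="session")
def mvpa_out(small_study, clean_trials, clf_spec):
    return run_mvpa(small_study, clean_trials, clf_spec, seed=13)


@pytest.fixture(scope="session")
def trialwise_table(small_study, clean_trials, mvpa_out):
    return build_trialwise_table(small_study, clean_trials, mvpa_out)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
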