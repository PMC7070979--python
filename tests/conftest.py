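"""Shared fixtures: one small synthetic corpus, featurized once per session."""

from __future__ import annotations

import numpy as np
import pytest

from emggate.features import FeatureBank
from emggate.pipeline import (assemble_alternating,
                              default_activation_threshold, featurize_windows,
                              stratified_contiguous_split)
from emggate.synthetic import GeneratorConfig, gen_corpus

SEED = 3


@pytest.fixture(scope="session")
def small_corpus():
    cfg = GeneratorConfig(budget_contraction_s=20.0, budget_artifact_s=20.0, seed=SEED)
    return gen_corpus(cfg)


@pytest.fixture(scope="session")
def windows(small_corpus):
    return assemble_alternating(small_corpus, window_s=1.0, seed=SEED,
                                activation_threshold=default_activation_threshold())


@pytest.fixture(scope="session")
def fd40(windows):
    return featurize_windows(windows, rate_hz=40)


@pytest.fixture(scope="session")
def split(windows):
    return stratified_contiguous_split(windows, seed=SEED)


@pytest.fixture(scope="session")
def bank():
    return FeatureBank()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)
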