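"""Shared fixtures: one trained code-path system and one EEG-path run.

Both are session-scoped because they are the expensive end-to-end stages
(crossbar training is cheap; the MEMD front-end is not) and every
downstream assertion can share them read-only.
"""

import numpy as np
import pytest

from memhnn import (
    CodeGenConfig,
    EEGGenConfig,
    FeatureConfig,
    MemristiveHNN,
    extract_pipeline,
    gen_codes,
    gen_eeg,
)

SEED = 0


@pytest.fixture(scope="session")
def code_data():
    train, test, protos = gen_codes(CodeGenConfig(seed=SEED))
    return train, test, protos


@pytest.fixture(scope="session")
def trained_system(code_data):
    train, test, _ = code_data
    model = MemristiveHNN(train)
    results = model.fit()
    return model, results, train, test


@pytest.fixture(scope="session")
def eeg_dataset():
    return gen_eeg(EEGGenConfig(seed=SEED))


@pytest.fixture(scope="session")
def eeg_codes(eeg_dataset):
    train, test, log = extract_pipeline(eeg_dataset, FeatureConfig(seed=SEED))
    return train, test, log
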