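import numpy as np
import pytest

import tcreject as tj


@pytest.fixture(scope="session")
def walking():
    """One small walking recording with injected artifact channels."""
    cfg = tj.SynthConfig(n_channels=64, fs=256.0, n_cycles=60, seed=1)
    rec, force, events, truth = tj.generate_walking_eeg(cfg)
    return cfg, rec, force, events, truth


@pytest.fixture(scope="session")
def walking_hp(walking):
    """Same recording after the 1 Hz high-pass, with its TCR result."""
    cfg, rec, force, events, truth = walking
    filtered = tj.highpass(rec)
    result = tj.analyze_condition(filtered, events, event_label="RHS")
    return cfg, filtered, events, truth, result


@pytest.fixture(scope="session")
def ic_mixture():
    """Recording with an exactly known linear decomposition."""
    cfg = tj.SynthConfig(n_channels=32, fs=256.0, n_cycles=40, seed=3)
    rec, events, ic_set, truth = tj.generate_ic_mixture(cfg)
    return cfg, rec, events, ic_set, truth
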