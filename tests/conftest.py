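"""Shared fixtures: configs and cached expensive pipeline runs."""

import numpy as np
import pytest

import tcstream as tc


@pytest.fixture(scope="session")
def cfg():
    """Reduced operating point used for tone/complex simulations."""
    return tc.reduced_config()


@pytest.fixture(scope="session")
def cfg_pitch():
    return tc.reduced_config(pitch=True)


@pytest.fixture(scope="session")
def full_cfg():
    """Full default configuration (4 scales, 9 rates, pitch on)."""
    return tc.RunConfig().validate()


@pytest.fixture(scope="session")
def alternating_run(cfg):
    """Segregated alternating 400/1000 Hz tone sequence (shared by tests)."""
    mix, truth = tc.gen_alternating_tones(400.0, 1000.0, reps=8)
    seg = tc.segregate(mix, cfg, reconstruct_audio=False)
    return mix, truth, seg


@pytest.fixture(scope="session")
def tone_500_spec(cfg):
    w, _ = tc.gen_harmonic_complex(500.0, 8, dur=0.3)
    return tc.auditory_spectrogram(w, cfg)
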