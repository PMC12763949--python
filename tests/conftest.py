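"""Shared fixtures: small synthetic recordings and studies built at test time."""

import numpy as np
import pytest

from vibemg.io import Recording
from vibemg.simulate import SimConfig, iter_study


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture
def short_sim_config():
    """Small, fast study: 2 participants, 12-s trials (above the hard minimum)."""
    return SimConfig(n_participants=2, trial_s=12.0, lead_in_s=2.0, seed=7)


@pytest.fixture
def short_recordings(short_sim_config):
    with pytest.warns(UserWarning, match="duration"):
        return list(iter_study(short_sim_config))


def make_recording(emg, rom, fs_hz=1024.0, **meta) -> Recording:
    kwargs = dict(
        participant_id="P01", session="control", trial_label="pre", duration_tol_s=1e9
    )
    kwargs.update(meta)
    return Recording(fs_hz=fs_hz, emg=np.asarray(emg, float), rom=np.asarray(rom, float), **kwargs)
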