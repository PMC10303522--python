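import numpy as np
import pytest

from emgkin.decomposition import CeemdanConfig, Signal
from emgkin.synthetic import EmgNoiseConfig, GaitProfile, gen_angles, gen_emg

FS = 1000.0


@pytest.fixture(scope="session")
def two_tone():
    """50 Hz + 2 Hz unit sinusoids, 2 s at 1000 Hz."""
    t = np.arange(0, 2, 1 / FS)
    fast = np.sin(2 * np.pi * 50 * t)
    slow = np.sin(2 * np.pi * 2 * t)
    return Signal(fast + slow, FS), fast, slow


@pytest.fixture(scope="session")
def short_trial():
    """One noisy sEMG channel over two gait cycles, with its clean truth."""
    profile = GaitProfile(n_cycles=2)
    angles = gen_angles(profile, seed=42)
    clean, noisy, envs, names = gen_emg(angles, seed=42)
    return {"clean": clean, "noisy": noisy, "envelopes": envs,
            "names": names, "angles": angles, "fs": FS}


@pytest.fixture
def fast_ceemdan():
    """Small-ensemble CEEMDAN settings used throughout the suite."""
    return CeemdanConfig(k=12, eps0=0.2, seed=0)
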