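import numpy as np
import pytest

from cofluct.synthetic import SyntheticConfig, generate_arousal, generate_physio


def circular_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Fisher-Lee circular correlation coefficient."""
    am = np.angle(np.mean(np.exp(1j * a)))
    bm = np.angle(np.mean(np.exp(1j * b)))
    sa, sb = np.sin(a - am), np.sin(b - bm)
    return float((sa @ sb) / np.sqrt((sa @ sa) * (sb @ sb)))


@pytest.fixture(scope="session")
def small_cfg():
    return SyntheticConfig(duration_s=300.0, n_voxels=60, seed=7)


@pytest.fixture(scope="session")
def session_cfg():
    return SyntheticConfig(duration_s=600.0, n_voxels=120, seed=11)


@pytest.fixture(scope="session")
def arousal(session_cfg):
    return generate_arousal(session_cfg)


@pytest.fixture(scope="session")
def physio_session(session_cfg, arousal):
    """Raw physio signals + ground truth for the 600 s session."""
    return generate_physio(session_cfg, arousal)
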