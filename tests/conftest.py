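import numpy as np
import pytest

import noisecat as nc
from noisecat.synth import RateTemplate, DT


@pytest.fixture(scope="session")
def protocol() -> nc.StimulusProtocol:
    return nc.StimulusProtocol()


@pytest.fixture(scope="session")
def small_dataset(protocol) -> nc.Dataset:
    """Two recordings per category, both maskers, tone blocks included."""
    return nc.make_dataset(nc.strong_separation_config(2, seed=42,
                                                       include_tones=True))


@pytest.fixture(scope="session")
def voc_dataset(protocol) -> nc.Dataset:
    """Four recordings per category, vocalization conditions only (fast)."""
    return nc.make_dataset(nc.strong_separation_config(4, seed=7,
                                                       include_tones=False))


def flat_template(rate_hz: float, duration_s: float = 1.0,
                  onset_s: float = 0.0) -> RateTemplate:
    """Homogeneous-rate template spanning [0, duration_s]."""
    n = int(round(duration_s / DT))
    return RateTemplate(np.full(n, float(rate_hz)), (0.0, n * DT),
                        onset_s, duration_s)


def flat_block(rate_hz: float, n_trials: int, duration_s: float = 1.0,
               seed: int = 0, onset_s: float = 0.0,
               condition_id: str = "block") -> nc.TrialBlock:
    """Block of independent homogeneous Poisson trains."""
    return nc.sample_trials(flat_template(rate_hz, duration_s, onset_s),
                            n_trials, 0.0, 0.0,
                            np.random.default_rng(seed), condition_id)


def flat_recording(protocol, rate_hz: float = 15.0, seed: int = 0,
                   include_tones: bool = False) -> nc.Recording:
    """Structureless recording: every condition a flat Poisson response."""
    from noisecat.synth import make_recording
    arch = nc.CategoryArchetype("insensitive", (0.5,) * 3, (0.5,) * 3,
                                baseline_rate_hz=rate_hz, response_gain_hz=0.0,
                                trial_gain_cv=0.0, jitter_sd_s=0.0)
    by_noise = {nt: arch for nt in protocol.noise_types}
    return make_recording(f"flat{seed}", "CN", by_noise, protocol,
                          np.random.default_rng([1234, seed]), include_tones)
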