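import numpy as np
import pytest

from stecg.synthetic_ecg import SynthConfig, synth_record


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def clean_record():
    """A noise-free 150-s synthetic record (360 Hz, all-normal beats)."""
    cfg = SynthConfig(duration_s=150.0, baseline_wander=(0.0, 0.33),
                      powerline=(0.0, 60.0), white_noise_sd=0.0,
                      class_mix={"N": 1.0}, seed=11)
    return synth_record(cfg, record_id="clean")


@pytest.fixture(scope="session")
def noisy_record():
    """A 150-s synthetic record with the generator's default noise."""
    cfg = SynthConfig(duration_s=150.0, seed=21)
    return synth_record(cfg, record_id="noisy")
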