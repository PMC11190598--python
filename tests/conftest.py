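import numpy as np
import pytest

from emghht import EMGSignal, SynthesisConfig, generate_dataset, generate_tone_mixture

FS = 500.0


@pytest.fixture(scope="session")
def two_tone():
    """sin(2*pi*50 t) + sin(2*pi*5 t), 2 s at 500 Hz — the decomposition fixture."""
    return generate_tone_mixture([50.0, 5.0], [1.0, 1.0], fs=FS, duration=2.0)


@pytest.fixture(scope="session")
def pure_tone():
    return generate_tone_mixture([50.0], [1.0], fs=FS, duration=2.0)


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny surrogate dataset: 6 grasp classes x 6 trials x 1 subject, short epochs."""
    cfg = SynthesisConfig(
        vocabulary="HG-6", n_subjects=1, active_duration=1.0, rest_duration=0.5, seed=11
    )
    return generate_dataset(cfg)


def make_signal(samples, fs=FS, **kwargs) -> EMGSignal:
    return EMGSignal(samples=np.asarray(samples, dtype=float), fs=fs, **kwargs)
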