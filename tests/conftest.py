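import numpy as np
import pytest

from cuedgain.voicesynth import Catalog


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def catalog():
    return Catalog.build(n_voices=4, n_words=8, n_textures=3, seed=0)


@pytest.fixture(scope="session")
def stereo_noise_clip():
    from cuedgain.cochlea import AudioClip
    g = np.random.default_rng(7)
    return AudioClip(g.standard_normal((2, int(2.5 * 44100))) * 0.01)
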