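import warnings

import numpy as np
import pandas as pd
import pytest

import speechnet as sn
from speechnet import study


@pytest.fixture(scope="session")
def study_table():
    """Two-group synthetic feature table at study sample sizes."""
    return sn.generate_study_table(12345)


@pytest.fixture(scope="session")
def plain_vowel():
    """Continuously voiced default vowel (f0 180, 0.5% jitter)."""
    return sn.synthesize_vowel(sn.VoiceParams(duration_s=2.0, noise_db=-30.0),
                               seed=11)


@pytest.fixture(scope="session")
def noise_signal():
    rng = np.random.default_rng(3)
    return sn.AudioSignal(rng.normal(0.0, 0.1, 2 * 22050), 22050)


@pytest.fixture()
def quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def independent_table():
    """Edge-free (empty-graph) table over the five speech variables."""
    rng = np.random.default_rng(77)
    return pd.DataFrame(rng.normal(size=(300, 5)),
                        columns=study.SPEECH_VARIABLES)
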