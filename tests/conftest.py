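import numpy as np
import pytest

from painsig import synthdata as sd


@pytest.fixture(scope="session")
def atlas():
    return sd.make_atlas((12, 12, 12), n_networks=7, seed=1)


@pytest.fixture(scope="session")
def signature(atlas):
    return sd.make_signature(atlas, fwhm=2.0, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def two_study_config(seed, n_visceral=15, n_somatic=33, shape=(16, 16, 16), **kw):
    """Training-style cohort: one visceral and one somatic study."""
    studies = [
        sd.StudySpec("rectal", n_visceral, "visceral", d_true=1.21),
        sd.StudySpec("thermal", n_somatic, "somatic", d_true=2.11),
    ]
    return sd.SimulationConfig(studies=studies, shape=shape, seed=seed, **kw)
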