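import numpy as np
import pytest

from dendrofit.synthetic import make_study_fixture, qufg_model


@pytest.fixture(scope="session")
def qufg_truth():
    """The xeric-oak archetype with the observation-noise shape used in
    the recovery experiments."""
    return qufg_model(dispersion=20.0)


@pytest.fixture(scope="session")
def bp_dataset():
    """One simulated xeric-oak site (4 plots, 36 years), reused across
    chronology/pipeline/CLI tests."""
    return make_study_fixture(seed=3, sites=["BP"])["BP"]


@pytest.fixture(scope="session")
def bp_files(bp_dataset, tmp_path_factory):
    """The same site written to disk in the ingest formats."""
    d = tmp_path_factory.mktemp("bp_site")
    bp_dataset.write(d)
    return d


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
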