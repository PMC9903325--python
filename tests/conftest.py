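import numpy as np
import pytest

import speclib as sl


@pytest.fixture(scope="session")
def fixture_cfg():
    return sl.SimConfig(n_peptides=40, seed=42)


@pytest.fixture(scope="session")
def fixture_peptides(fixture_cfg):
    return sl.generate_peptides(fixture_cfg)


@pytest.fixture(scope="session")
def fixture_library(fixture_peptides, fixture_cfg):
    return sl.build_fixture_library(fixture_peptides, fixture_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def simple_spectrum():
    return sl.Spectrum(
        identifier="s1",
        precursor_mz=500.25,
        precursor_charge=2,
        peaks=[
            sl.Peak(200.0, 10.0),
            sl.Peak(300.0, 30.0),
            sl.Peak(400.0, 20.0),
        ],
    )
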