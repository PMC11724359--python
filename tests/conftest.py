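import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mats_sites():
    from xerscan.mats_pssm import load_training_sites

    return load_training_sites()


@pytest.fixture(scope="session")
def mats_pssm(mats_sites):
    from xerscan.mats_pssm import build_pssm, calibrate_threshold

    pssm = build_pssm(mats_sites)
    calibrate_threshold(pssm, mats_sites)
    return pssm


@pytest.fixture(scope="session")
def xrs_seeds():
    from xerscan.xrs_as_detector import load_seed_xrs

    return load_seed_xrs()


@pytest.fixture(scope="session")
def halfsite_pwms(xrs_seeds):
    from xerscan.xrs_as_detector import build_halfsite_pwms

    return build_halfsite_pwms(xrs_seeds)


@pytest.fixture(scope="session")
def scan_params(halfsite_pwms):
    from xerscan.xrs_as_detector import default_params

    return default_params(*halfsite_pwms)


@pytest.fixture(scope="session")
def as_pwms():
    from xerscan.xrs_as_detector import load_as_pwms

    return load_as_pwms()


def random_dna(rng, n, p=None):
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
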