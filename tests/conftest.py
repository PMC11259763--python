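import numpy as np
import pytest

from helr import he, synth


@pytest.fixture(scope="session")
def profiles():
    """Calibrated default site profiles (session-scoped: calibration is MC)."""
    return synth.default_profiles()


@pytest.fixture(scope="session")
def small_cohort(profiles):
    """Complete 1,200-row cohort for site A (no missingness)."""
    return synth.sample_cohort(profiles["A"], 1200, seed=42)


@pytest.fixture()
def he_setup():
    """Small toy HE context (1,024 slots) with keys, evaluator, authority."""
    context = he.HEContext(ring_dim=2 ** 11)
    keys = he.keygen(context, seed=7)
    evaluator = he.Evaluator(keys.public_key, keys.relin_key,
                             keys.rotation_key)
    authority = he.RefreshAuthority(keys)
    return context, keys, evaluator, authority


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
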