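import numpy as np
import pytest

from spaf import SimSpec, SpafConfig, noisy_gaussian_phase, run_spaf


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def paper_sim():
    """One full run of the reference simulation: noisy Gaussian bump,
    SPAF with default schedule.  Shared across tests that only read it."""
    spec = SimSpec(seed=1)
    truth, noisy = noisy_gaussian_phase(spec)
    filtered, trace = run_spaf(noisy, SpafConfig())
    return {
        "spec": spec,
        "truth": truth,
        "noisy": noisy,
        "filtered": filtered,
        "trace": trace,
    }


@pytest.fixture(scope="session")
def small_noisy_phase():
    """A small noisy wrapped bump with residues, for fast engine tests."""
    spec = SimSpec(shape=(80, 120), bump_height=10.0, bump_sigma=20.0, seed=7)
    _, noisy = noisy_gaussian_phase(spec)
    return noisy
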