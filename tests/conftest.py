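import numpy as np
import pytest

from paintract.gradients import make_scheme
from paintract.microstructure import train_estimator
from paintract.phantom import build_phantom, single_bundle_config, synthesize_dwi


@pytest.fixture(scope="session")
def scheme3():
    """Default three-shell scheme (b = 1, 2, 3 ms/um^2; 30 directions each)."""
    return make_scheme()


@pytest.fixture(scope="session")
def scheme_dense():
    """Dense 60-direction shells for powder-average accuracy checks."""
    return make_scheme(n_dirs=60, seed=1)


@pytest.fixture(scope="session")
def phantom_default():
    return build_phantom()


@pytest.fixture(scope="session")
def phantom_single():
    return build_phantom(single_bundle_config())


@pytest.fixture(scope="session")
def scheme_track():
    """Two-shell scheme used for the tractography tests (fewer volumes)."""
    return make_scheme(shell_bvalues=(1.0, 2.0), n_dirs=30)


@pytest.fixture(scope="session")
def dwi_single(phantom_single, scheme_track):
    """Noise-free DWI of the single straight bundle phantom."""
    return synthesize_dwi(phantom_single, scheme_track)


@pytest.fixture(scope="session")
def estimator3(scheme3):
    """Posterior-mean estimator trained once for the whole session."""
    return train_estimator(scheme3, n_samples=30_000, seed=11)
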