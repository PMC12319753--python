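import numpy as np
import pytest

from adaptune import (
    NoiseParams,
    assign_bins,
    build_fmri_run,
    cosine_similarity_matrix,
    default_tuning_grid,
    simulate_bold_run,
    synthetic_feature_norms,
)

QUIET = NoiseParams(ar1_phi=0.0, sigma=0.0, drift_amp=0.0, nuisance_amp=0.0)


@pytest.fixture(scope="session")
def norms():
    return synthetic_feature_norms(seed=0)


@pytest.fixture(scope="session")
def simmat(norms):
    return cosine_similarity_matrix(norms)


@pytest.fixture(scope="session")
def binnings(simmat):
    return assign_bins(simmat, [f"obj{f:02d}_0" for f in range(10)], seed=0)


@pytest.fixture(scope="session")
def fmri_events(binnings):
    return build_fmri_run(binnings, seed=0)


@pytest.fixture(scope="session")
def quiet_run(fmri_events):
    """Noise-free BOLD run on the default planted grid, with nuisance matrix."""
    grid = default_tuning_grid()
    vol, nuis = simulate_bold_run(fmri_events, grid, noise=QUIET, seed=1)
    return grid, vol, nuis


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / denom if denom else np.nan
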