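import warnings

import numpy as np
import pytest

import metadfc as m
from metadfc.states import fit_states, select_k_elbow, standardize_and_concatenate


@pytest.fixture(scope="session")
def atlas():
    return m.default_limbic_atlas()


@pytest.fixture(scope="session")
def two_zone_cfg():
    return m.make_default_two_zone_model()


@pytest.fixture(scope="session")
def default_cohort(two_zone_cfg):
    """20 subjects x 208 frames from the default two-zone model."""
    sessions, truths = m.generate_bold_cohort(two_zone_cfg, 20, 208, seed=2)
    return sessions, truths


@pytest.fixture(scope="session")
def fitted_state_model(default_cohort, two_zone_cfg):
    sessions, _ = default_cohort
    frames = standardize_and_concatenate(sessions)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_states(frames, 4, n_init=100, seed=3, atlas=two_zone_cfg.atlas)
    return frames, model


@pytest.fixture(scope="session")
def elbow_selection(default_cohort):
    sessions, _ = default_cohort
    frames = standardize_and_concatenate(sessions)
    k, curve = select_k_elbow(frames, (1, 8), seed=3)
    return k, curve


def rand_symmetric(n, seed, scale=0.3, diag=1.0):
    rng = np.random.default_rng(seed)
    M = rng.normal(0.0, scale, (n, n))
    M = (M + M.T) / 2
    np.fill_diagonal(M, diag)
    return M
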