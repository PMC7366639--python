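import numpy as np
import pytest

from judgebias.params import HyperParams, ModelSpec
from judgebias.simulate import GenerativeConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structurally complete cohort: 4 subjects x 8 conditions."""
    cfg = GenerativeConfig(n_subjects=4, sessions_per_subject=8, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Minimal cohort for fitting smoke tests: 3 subjects x 2 sessions."""
    spec = ModelSpec(("sigma", "omega", "beta"))
    hyper = HyperParams(
        spec,
        m=np.array([-0.2, -0.2, 0.4]),
        nu=np.array([0.05, 0.05, 0.05]),
        Sigma=np.array([0.05, 0.05]),
    )
    cfg = GenerativeConfig(
        n_subjects=3, sessions_per_subject=2, true_hyper=hyper, seed=7
    )
    return simulate_cohort(cfg)
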