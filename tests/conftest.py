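import numpy as np
import pytest

from mmfnc.dataio import Band
from mmfnc.synthetic import SimulationConfig, simulate_study


def small_cohort_config(**overrides) -> SimulationConfig:
    """A fast cohort: 8+8 subjects, fMRI (C=10, T=120) + MEG delta (C=8)."""
    kwargs = dict(
        n_per_group=(8, 8),
        c_fmri=10,
        c_meg=8,
        t_fmri=120,
        t_meg=120,
        bands=(Band.DELTA,),
        n_states_per_group=2,
        state_divergence=0.8,
        effect_pairs=(
            ("fmri", (0, 1), 0.5),
            ("fmri", (2, 3), -0.4),
            ("delta", (0, 1), 0.5),
        ),
        seed=5,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_study(small_cohort_config())


@pytest.fixture(scope="session")
def null_cohort():
    """No planted effects anywhere: identical groups, shared states."""
    cfg = small_cohort_config(effect_pairs=(), state_divergence=0.0, seed=11)
    return simulate_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
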