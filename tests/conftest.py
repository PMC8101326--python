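import numpy as np
import pytest

from mirpair.io import labels_for
from mirpair.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny cohort for fast unit tests: 30+30 samples, 12 miRNAs."""
    cfg = SimConfig(n_case=30, n_control=30, n_mirna=12,
                    signal_pairs=[(0, 2, 1.5), (1, 2, 1.5)], seed=11)
    expr, meta, truth = simulate_cohort(cfg)
    y = labels_for(expr.sample_ids, meta)
    return cfg, expr, meta, truth, y


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort under the standard study conditions (100+100, 40 miRNAs)."""
    cfg = SimConfig(seed=5)
    expr, meta, truth = simulate_cohort(cfg)
    y = labels_for(expr.sample_ids, meta)
    return cfg, expr, meta, truth, y


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
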