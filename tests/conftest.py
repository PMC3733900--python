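import numpy as np
import pytest

import apoptosim as ap


@pytest.fixture(scope="session")
def params():
    return ap.ModelParameters()


@pytest.fixture(scope="session")
def warm_ssa(params):
    """Trigger numba compilation once per session."""
    ap.ssa_population(params, ap.CopyNumberCondition(100, 100), 10,
                      n_cells=1, t_end=5.0)
    return True


@pytest.fixture(scope="session")
def small_population(params, warm_ssa):
    """A reusable 25-cell stochastic population at [1e4, 1e2], CC=300."""
    return ap.ssa_population(
        params, ap.CopyNumberCondition(1e4, 1e2), 300,
        n_cells=25, base_seed=123, t_end=1500.0,
    )


def assert_close(a, b, rel):
    assert abs(a - b) <= rel * abs(b), f"{a} vs {b} (rel {rel})"
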