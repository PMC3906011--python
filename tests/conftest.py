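"""Shared fixtures: simulated cohorts and replicate studies.

The planted/null replicate studies are the most expensive objects in the
suite, so they are computed once per session and shared by every test that
needs cohort-level statistics.
"""

import numpy as np
import pytest

from scpoim import experiments as ex
from scpoim.synthetic import generate_cohort


class ConstantDuration:
    """Degenerate duration model: a fixed duration in seconds (test stub)."""

    def __init__(self, value: float):
        self.value = float(value)

    def rvs(self, size=None, random_state=None):
        if size is None:
            return self.value
        return np.full(size, self.value)

    def mean(self):
        return self.value

    def support(self):
        return (self.value, self.value)


@pytest.fixture
def constant_duration():
    return ConstantDuration


@pytest.fixture(scope="session")
def planted_study():
    """20 planted-effect cohorts (9+9, one transition cell shifted by 0.3)."""
    return ex.power_study(n_replicates=20, effect=0.3, base_seed=1)


@pytest.fixture(scope="session")
def null_study():
    """20 null cohorts (identical class models)."""
    return ex.power_study(n_replicates=20, effect=0.0, base_seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """One quick 4+4 cohort with short dialogs for unit-level checks."""
    specs = ex.make_cohort_specs(effect=0.3, n_dialogs=4, dialog_length=60)
    return generate_cohort(specs, 11)
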