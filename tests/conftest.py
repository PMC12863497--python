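"""Shared fixtures: small synthetic cohorts and the full default experiment.

Expensive fixtures are session-scoped so the image pipeline runs once per
test session regardless of how many tests consume it.
"""

import numpy as np
import pytest

from habitatmsi.pipeline import run_msi_experiment
from habitatmsi.synthetic import CohortRecipe, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-case cohort (24/8/8) for structural and consistency checks."""
    recipe = CohortRecipe(n_train=24, n_val=8, n_test=8, seed=11)
    return generate_cohort(recipe)


@pytest.fixture(scope="session")
def full_experiment():
    """The default 355-case experiment run end-to-end with a pinned seed."""
    return run_msi_experiment(seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
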