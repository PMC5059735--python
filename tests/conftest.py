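"""Shared fixtures.

The heavy end-to-end simulations (fragmentation sweep, two-condition
experiment) are session-scoped so the several tests that interrogate them
pay for generation and measurement once.
"""

import warnings

import numpy as np
import pytest

from mitomorph.experiments import (
    fragmentation_sweep,
    two_condition_experiment,
)

F_SWEEP = [0.0, 0.25, 0.5, 0.75, 1.0]


@pytest.fixture(scope="session")
def sweep_results():
    """30 single-cell fields per fragmentation condition, fixed seed blocks."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fragmentation_sweep(F_SWEEP, cells_per_condition=30, base_seed=0)


@pytest.fixture(scope="session")
def two_conditions():
    """Control (f=0.15, seeds 1-30) vs fragmented (f=0.75, seeds 31-60),
    measured through both the automatic and the ground-truth-mask route."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return two_condition_experiment(include_semimanual=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
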