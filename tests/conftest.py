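"""Shared fixtures: the standard scenario family used across the suite.

The canonical configuration (a = -2, b = 1, F0 = 1/2, T = 1) with the
three perturbation schedules c(t) = sqrt(t)/2, (T-t)/2 and (T-t)^2/2 is
the reference parameterisation for the GC-process tests; P0 = 1, mu = 5,
k = 1 with p in {1/2, sqrt(2), 2} is the reference for the mutation
model.
"""

import numpy as np
import pytest

from gcsde import (
    RateParameters,
    TimeGrid,
    constant_schedule,
    linear_decay_schedule,
    quadratic_decay_schedule,
    sqrt_schedule,
)


@pytest.fixture
def params():
    """Standard rate parameters a=-2, b=1, F0=0.5 (regime a - b = -3)."""
    return RateParameters(a=-2.0, b=1.0, F0=0.5)


@pytest.fixture
def params_f0_zero():
    """SNP-model start: F0 = 0 (expectation reduces to the SNP curve)."""
    return RateParameters(a=-2.0, b=1.0, F0=0.0, allow_boundary_F0=True)


@pytest.fixture
def grid():
    return TimeGrid(t_end=1.0, n_steps=400)


@pytest.fixture(params=["const", "sqrt", "linear_decay", "quad_decay"])
def any_schedule(request):
    return {
        "const": constant_schedule(0.5, 1.0),
        "sqrt": sqrt_schedule(0.5, 1.0),
        "linear_decay": linear_decay_schedule(0.5, 1.0),
        "quad_decay": quadratic_decay_schedule(0.5, 1.0),
    }[request.param]


@pytest.fixture
def scenario_schedules():
    """The three scenario-family schedules on [0, 1]."""
    return [
        sqrt_schedule(0.5, 1.0),
        linear_decay_schedule(0.5, 1.0),
        quadratic_decay_schedule(0.5, 1.0),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
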