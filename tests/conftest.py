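import numpy as np
import pytest

from stochallee import build_model, make_distribution
from stochallee.experiments import (
    mate_limitation_model,
    mate_limitation_ricker_model,
    predator_saturation_ricker_model,
)


@pytest.fixture
def ricker_persistent():
    """Stochastic Ricker with positive mean log growth (persistent regime)."""
    return build_model(
        "ricker", {"r": make_distribution("normal", mean=0.3, sd=0.5), "a": 1.0}
    )


@pytest.fixture
def ricker_subcritical():
    """Stochastic Ricker with negative mean log growth (extinction regime)."""
    return build_model(
        "ricker", {"r": make_distribution("normal", mean=-0.2, sd=0.5), "a": 1.0}
    )


@pytest.fixture
def mate_limitation_stochastic():
    """Mate-limitation with lognormal fecundity (log-mean 0.1, log-sd 0.5), h=10."""
    return mate_limitation_model(0.5)


@pytest.fixture
def mate_limitation_deterministic():
    """Mate-limitation with fecundity fixed at exp(0.1); Allee threshold h/(lam-1)."""
    return mate_limitation_model(0.0)


@pytest.fixture
def mlr_attractor():
    """Mate-limitation + Ricker skeleton with a positive attractor (rbar=4.5)."""
    return mate_limitation_ricker_model(0.0, rbar=4.5)


@pytest.fixture
def mlr_essential_extinction():
    """Mate-limitation + Ricker skeleton with essential extinction (rbar=7)."""
    return mate_limitation_ricker_model(0.0, rbar=7.0)


@pytest.fixture
def psr_fig3():
    """Predator-saturation + Ricker at the canonical r=4, a=4, h=1/12 scaling."""
    return predator_saturation_ricker_model(0.3, 0.1)
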