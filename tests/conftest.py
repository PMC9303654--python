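import numpy as np
import pytest

from twostage.monitoring import single_stage_sample_size
from twostage.naive import induce_design
from twostage.optimal import optimize_design, optimize_gsd
from twostage.priors import default_planning_prior, point_prior


@pytest.fixture(scope="session")
def planning_prior():
    """Truncated-normal planning prior N(0.4, 0.2^2) on [-0.5, 1]."""
    return default_planning_prior()


@pytest.fixture(scope="session")
def single_design(planning_prior):
    """Single-stage reference design (n = 79 at one-sided 2.5%)."""
    return single_stage_sample_size(planning_prior, 0.025, 0.8)


@pytest.fixture(scope="session")
def induced_naive_design(planning_prior, single_design):
    """Two-stage design induced by mandatory naive recalculation at m = 26."""
    return induce_design(single_design, 26, planning_prior, 0.2, nmin=30, nmax=160)


@pytest.fixture(scope="session")
def optimal_result(planning_prior):
    """Optimal two-stage design for the reference problem."""
    return optimize_design(planning_prior, 0.025, 0.8, seed=0)


@pytest.fixture(scope="session")
def gsd_result():
    """Optimal two-arm group-sequential design, point alternative 0.4,
    binding futility at an observed effect of 0 (effective one-arm scale)."""
    return optimize_gsd(point_prior(0.4), 0.025, 0.8, z_fut_fixed=0.0, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
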