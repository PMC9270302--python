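import numpy as np
import pytest

from qfrpullback import CohortSpec, PullbackTrace, generate_cohort, score_cohort

#: Cohort seed for the shared fixtures; fixed so every run sees the same data.
COHORT_SEED = 42


def make_trace(knots, step=None, vessel_id="t", phase="pre_pci"):
    """Trace through (position, qfr) knots, optionally sampled on a grid."""
    xs = np.asarray([k[0] for k in knots], dtype=float)
    ys = np.asarray([k[1] for k in knots], dtype=float)
    if step is not None:
        grid = np.arange(0.0, xs[-1] + step / 2, step)
        grid[-1] = xs[-1]
        ys = np.interp(grid, xs, ys)
        xs = grid
    return PullbackTrace(vessel_id=vessel_id, positions_mm=xs, qfr=ys, phase=phase)


@pytest.fixture(scope="session")
def default_spec():
    return CohortSpec(seed=COHORT_SEED, n_vessels=500)


@pytest.fixture(scope="session")
def cohort500(default_spec):
    """The default 500-vessel mechanistic cohort used by the directional checks."""
    return generate_cohort(default_spec)


@pytest.fixture(scope="session")
def scored500(cohort500):
    return score_cohort(cohort500)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
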