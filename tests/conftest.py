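import warnings

import numpy as np
import pytest

from rapaflux import gsmm, synthgen


@pytest.fixture(autouse=True)
def _quiet_calibration_warnings():
    """Generator/solver calibration warnings are expected in bulk runs."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def demo_dataset():
    """The default demo dataset (seed 0) used across stages."""
    return synthgen.generate_dataset(seed=0)


@pytest.fixture(scope="session")
def toy_model():
    return synthgen.build_toy_model()


@pytest.fixture(scope="session")
def constrained_model(toy_model):
    return gsmm.apply_experimental_constraints(toy_model)


@pytest.fixture(scope="session")
def wt_flux(constrained_model):
    wt = gsmm.fba(constrained_model)
    assert wt.status == "optimal"
    return wt


def make_random_network(rng: np.random.Generator, n_mets=3, n_rxns=6):
    """A small random metabolic network guaranteed feasible (0 is interior).

    Reactions mix exchanges and conversions; bounds straddle zero so the
    zero flux vector is always feasible and MOMA/FBA stay well posed.
    """
    S = np.zeros((n_mets, n_rxns))
    for j in range(n_rxns):
        mets = rng.choice(n_mets, size=rng.integers(1, min(3, n_mets) + 1),
                          replace=False)
        for m in mets:
            S[m, j] = rng.choice([-2, -1, 1, 2])
    lb = -rng.uniform(0.0, 10.0, n_rxns)
    ub = rng.uniform(0.1, 10.0, n_rxns)
    return S, lb, ub
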