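import math

import numpy as np
import pytest

from thiokin.kinetics import KineticParameters
from thiokin.simulate import fixture_table1


@pytest.fixture(scope="session")
def table1():
    """Published parameter set and IRF (tau in ps, sigma_IRF = 0.087 ps)."""
    return fixture_table1()


def random_scheme(rng: np.random.Generator, allow_infinite: bool = False) -> KineticParameters:
    """Random valid branching scheme: taus log-uniform in [0.05, 500] ps,
    yields drawn uniformly on their simplexes."""

    def tau() -> float:
        if allow_infinite and rng.random() < 0.15:
            return math.inf
        return float(np.exp(rng.uniform(np.log(0.05), np.log(500.0))))

    q21 = float(rng.uniform(0.0, 1.0))
    q22 = float((1.0 - q21) * rng.uniform(0.0, 1.0))
    return KineticParameters(
        tau1=float(np.exp(rng.uniform(np.log(0.05), np.log(500.0)))),
        q21=q21,
        tau21=tau(),
        q22=q22,
        tau22=tau(),
        tau23=math.inf if allow_infinite else tau(),
        q31=float(rng.uniform(0.0, 1.0)),
        tau31=tau() if not allow_infinite else float(np.exp(rng.uniform(np.log(0.05), np.log(500.0)))),
        tau32=tau() if not allow_infinite else float(np.exp(rng.uniform(np.log(0.05), np.log(500.0)))),
        q41=float(rng.uniform(0.0, 1.0)),
        tau41=tau(),
        tau42=math.inf if allow_infinite else tau(),
    )
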