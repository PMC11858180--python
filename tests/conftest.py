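import numpy as np
import pytest
from hypothesis import settings

import rsmkit as rk

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cellulase():
    """The bundled 17-run cellulase optimization experiment."""
    return rk.cellulase_experiment()


@pytest.fixture(scope="session")
def cellulase_model(cellulase):
    design, responses = cellulase
    return rk.fit_quadratic(design, responses)


@pytest.fixture(scope="session")
def three_factors():
    return (
        rk.Factor("speed", "r/min", 100, 150, 200),
        rk.Factor("temp", "degC", 29, 33, 37),
        rk.Factor("time", "h", 18, 27, 36),
    )


@pytest.fixture(scope="session")
def concave_truth(three_factors):
    """A concave quadratic truth with an interior maximum, coefficients at
    the scale of the bundled experiment."""
    coef = np.array([10.61, 0.70, 1.50, 0.79, -0.065, 0.015, 0.33,
                     -3.78, -2.11, -2.99])
    return rk.TruthSpec(factors=three_factors, coef=coef, noise_sd=0.31,
                        n_center=5, seed=2024)
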