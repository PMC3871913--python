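import numpy as np
import pytest

from pulseprey import ModelParameters, example_parameters, existence_margin


@pytest.fixture
def p0() -> ModelParameters:
    """Canonical parameter set (panda-extinction regime at T=1)."""
    return example_parameters()


def random_parameters(rng: np.random.Generator, require_orbits: bool = True) -> ModelParameters:
    """One valid random parameter draw; optionally with both bamboo orbits
    existing with a healthy margin (so Floquet analysis is well posed)."""
    while True:
        p = ModelParameters(
            a10=rng.uniform(0.5, 2.0), a11=rng.uniform(0.2, 1.0), a13=rng.uniform(0.05, 0.5),
            a20=rng.uniform(0.5, 2.0), a22=rng.uniform(0.2, 1.0), a23=rng.uniform(0.05, 0.5),
            a30=rng.uniform(0.1, 1.0), a31=rng.uniform(0.05, 0.5), a32=rng.uniform(0.05, 0.5),
            a33=rng.uniform(0.01, 0.2),
            alpha=rng.uniform(0.0, 0.7), beta=rng.uniform(0.0, 0.7),
            T=rng.uniform(0.5, 3.0), l=rng.uniform(0.2, 0.8),
        )
        if not require_orbits:
            return p
        if (existence_margin(p.a10, p.alpha, p.T) > 0.1
                and existence_margin(p.a20, p.beta, p.T) > 0.1):
            return p
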