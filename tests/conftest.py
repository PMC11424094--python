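import math

import numpy as np
import pytest

from condex import TwoPhaseParams


@pytest.fixture(scope="session")
def laf1():
    """LAF-1 droplet worked example (R in µm, D in µm²/s; only the
    concentration ratio matters)."""
    return TwoPhaseParams(
        R=1.0, D_den=0.0017, D_dil=94.0, c_den=1190.0, c_dil=1.0, kappa=math.inf
    )


@pytest.fixture(scope="session")
def droplet_params():
    """A6B6 droplet system: concentrations in mM, D in µm²/s, R and κ in µm."""
    return TwoPhaseParams(
        R=0.037, D_den=0.013, D_dil=17.0, c_den=8.1, c_dil=0.073, kappa=0.20
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
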