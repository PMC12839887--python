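import numpy as np
import pytest

from itaq import AtomSpec, build_molecular_grid


@pytest.fixture(scope="session")
def grid_h_default():
    """Default-resolution single-center grid (75 x 302) at the origin."""
    return build_molecular_grid([AtomSpec("H", [0.0, 0.0, 0.0])], 75, 302)


@pytest.fixture(scope="session")
def grid_h_coarse():
    """Coarse single-center grid (30 x 110) for fast checks."""
    return build_molecular_grid([AtomSpec("H", [0.0, 0.0, 0.0])], 30, 110)


@pytest.fixture(scope="session")
def toy_quinone():
    from itaq.synth import make_toy_quinone

    return make_toy_quinone(alpha_substituent_perturbation=0.25)


@pytest.fixture(scope="session")
def toy_quinone_unperturbed():
    from itaq.synth import make_toy_quinone

    return make_toy_quinone(alpha_substituent_perturbation=0.0)
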