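import numpy as np
import pytest

from fractmorph import CascadeSpec, binomial_cascade_2d, sierpinski_carpet

#: Cascade weights with a wide, analytically known singularity spectrum.
CASCADE_WEIGHTS = (0.4, 0.3, 0.2, 0.1)


@pytest.fixture(scope="session")
def cascade_field():
    """Deterministic depth-7 binomial cascade (128x128, total mass 1)."""
    return binomial_cascade_2d(CascadeSpec(weights=CASCADE_WEIGHTS, depth=7, shuffle=False))


@pytest.fixture(scope="session")
def carpet5():
    """Depth-5 Sierpinski carpet (243x243 bool image)."""
    return sierpinski_carpet(5)


@pytest.fixture(scope="session")
def uniform_field():
    """256x256 all-foreground image: the homogeneous (monofractal, D=2) limit."""
    return np.ones((256, 256))
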