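import numpy as np
import pytest

from genloewe import MarginalCurve


@pytest.fixture
def agonist_pair():
    """A full agonist and a partial agonist over a shared baseline."""
    return (
        MarginalCurve(b=0.1, m=1.0, ec50=1.0, hill=1.0),
        MarginalCurve(b=0.1, m=0.6, ec50=10.0, hill=2.0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


def random_curve(rng, b=None):
    """Random valid marginal curve (agonist, partial or inverse)."""
    if b is None:
        b = rng.uniform(-0.5, 1.0)
    m = b + rng.choice([-1.0, 1.0]) * rng.uniform(0.2, 1.5)
    ec50 = 10.0 ** rng.uniform(-2, 2)
    hill = rng.uniform(0.3, 4.0)
    return MarginalCurve(b=b, m=m, ec50=ec50, hill=hill)
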