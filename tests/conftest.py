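import numpy as np
import pytest
from scipy.optimize import brentq

import lgrefuge as lg


@pytest.fixture
def example():
    """The canonical worked example: refuge m=0.4, one attractive equilibrium."""
    return lg.EXAMPLE_PARAMETERS


@pytest.fixture
def case2_params():
    """A parameter set with two positive equilibria (found by offline
    randomized search, re-verified here by the classification)."""
    return lg.ModelParameters(
        r1=9.13, b1=3.45, a1=6.67, k1=0.40, r2=0.67, a2=4.28, k2=5.92, m=0.27
    )


@pytest.fixture
def case3_params():
    """A set with m below threshold, B < 0 and negative discriminant:
    no positive equilibrium."""
    return lg.ModelParameters(
        r1=4.511, b1=0.403, a1=0.635, k1=0.109, r2=2.023, a2=0.235, k2=5.052, m=0.248
    )


def nullcline_root_oracle(p, xtol=1e-12):
    """Independent positive-equilibrium finder: bisect the prey nullcline
    composed with the predator nullcline.

    h(x) = a2 (r1 - b1 x)((1-m)x + k1) - a1 r2 (1-m)((1-m)x + k2)
    vanishes exactly at equilibrium prey densities.  Sign changes are
    located on a fine grid over (0, r1/b1] and refined by Brent's method.
    """
    om = 1.0 - p.m

    def h(x):
        return p.a2 * (p.r1 - p.b1 * x) * (om * x + p.k1) - p.a1 * p.r2 * om * (
            om * x + p.k2
        )

    hi = p.r1 / p.b1
    grid = np.linspace(1e-12, hi * (1 + 1e-9), 20001)
    vals = np.array([h(x) for x in grid])
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(h, grid[i], grid[i + 1], xtol=xtol))
    return sorted(roots)


@pytest.fixture
def nullcline_oracle():
    return nullcline_root_oracle
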