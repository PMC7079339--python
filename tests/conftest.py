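"""Shared fixtures and independent oracles used across the suite.

The oracles here deliberately avoid the closed forms under test: tumor
nullcline composition with dense bracketing/bisection for root counting,
and stiff ODE integration for attractor identification.
"""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from cisi.models import (
    FIG2,
    NKCTL_DEFAULT,
    SATURATION_DEFAULT,
    TABLE1,
    rhs_for,
)


@pytest.fixture
def table1():
    return TABLE1


@pytest.fixture
def fig2():
    return FIG2


@pytest.fixture
def saturation_default():
    return SATURATION_DEFAULT


@pytest.fixture
def nkctl_default():
    return NKCTL_DEFAULT


def nullcline_positive_roots(f, t_lo, t_hi, n=4000):
    """Positive zeros of a scalar function by dense log-grid bracketing.

    Independent of any closed-form root formula; used as the numeric oracle
    for equilibrium tumor sizes.
    """
    grid = np.geomspace(t_lo, t_hi, n)
    vals = np.array([f(T) for T in grid])
    roots = []
    for i in range(len(grid) - 1):
        v0, v1 = vals[i], vals[i + 1]
        if not (np.isfinite(v0) and np.isfinite(v1)):
            continue
        if v0 == 0.0:
            roots.append(grid[i])
        elif v0 * v1 < 0:
            roots.append(brentq(f, grid[i], grid[i + 1], xtol=1e-12, rtol=1e-13))
    # collapse near-duplicates
    out = []
    for r in sorted(roots):
        if not out or abs(r - out[-1]) > 1e-6 * max(abs(r), 1.0):
            out.append(r)
    return out


def base_tumor_nullcline(params):
    """dT/dt along the effector nullcline E = sigma / (d - m T)."""

    def f(T):
        E = params.sigma / (params.d - params.m * T)
        return params.a * T * (1.0 - params.b * T) - params.k * T * E

    return f


def integrate_to_attractor(params, x0, t_end=5000.0):
    """Long stiff integration; returns the final state."""
    rhs = rhs_for(params)
    sol = solve_ivp(
        lambda t, y: rhs(np.maximum(y, 0.0), params),
        (0.0, t_end),
        np.asarray(x0, dtype=float),
        method="LSODA",
        rtol=1e-9,
        atol=1e-6,
    )
    assert sol.success
    return sol.y[:, -1]
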