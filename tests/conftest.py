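"""Shared fixtures: canonical parameter sets and a small fitted population.

Everything is generated programmatically and seeded; nothing is read from
disk.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

import tpcfit as t


def brute_force_t_pk(E, E_D, T_h, lo=150.0, hi=450.0):
    """Independent peak finder: coarse grid argmax + golden-section refine."""
    K = t.BOLTZMANN_EV
    grid = np.arange(lo, hi, 0.01)

    def logb(T):
        return -E / K / T - np.logaddexp(0.0, E_D / K * (1 / T_h - 1 / T))

    i = int(np.argmax(logb(grid)))
    a, b = grid[max(i - 2, 0)], grid[min(i + 2, grid.size - 1)]
    g = (math.sqrt(5) - 1) / 2
    c, d = b - g * (b - a), a + g * (b - a)
    for _ in range(120):
        if logb(np.array([c]))[0] > logb(np.array([d]))[0]:
            b, d = d, c
            c = b - g * (b - a)
        else:
            a, c = c, d
            d = a + g * (b - a)
    return (a + b) / 2


@pytest.fixture(scope="session")
def canonical_params() -> t.SSParams:
    """A biologically typical parameter set (E=0.65 eV, clear peak)."""
    return t.SSParams(B0=1.0, E=0.65, E_D=3.0, T_h=310.0, T_ref=283.15)


@pytest.fixture(scope="session")
def noiseless_curve(canonical_params) -> t.TPCurve:
    """12 evenly spaced noiseless points spanning the peak."""
    pairs = t.generate_ss_curves([canonical_params], 0.0, 12, (275.0, 320.0),
                                 np.random.default_rng(0))
    return pairs[0][0]


@pytest.fixture(scope="session")
def small_population():
    """150 beta curves with their specs and no-MCA certificate (seed 1)."""
    pspec = t.PopulationSpec(n_curves=150, seed=1)
    return t.generate_population(pspec)


@pytest.fixture(scope="session")
def small_population_fits(small_population):
    """Sharpe-Schoolfield fits of the 150-curve population at T_ref = 7 C."""
    curves, specs, cert = small_population
    opts = t.FitOptions(T_ref=t.celsius_to_kelvin(7.0), seed=1, n_restarts=3)
    return [t.fit_ss(c, opts) for c in curves], specs, cert
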