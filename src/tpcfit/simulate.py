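"""Synthetic thermal-performance-curve populations.

Two generators live here:

* Beta-density curves: negatively skewed unimodal TPCs whose shape, width
  and height are drawn from normal distributions.  Each curve is the
  beta(alpha, beta) probability density on its unit support, mapped to the
  temperature interval [0, j] degC (width multiplier j) and raised by an
  additive height offset k.  Rejection keeps only negatively skewed curves
  (alpha > beta) with a well-defined interior peak (alpha, beta > 1).  A
  whole population carries a *no-MCA certificate*: the Pearson correlation
  between the true rate at the reference temperature (7 degC by default)
  and the true thermal optimum must be non-significant, so that any
  cold-adaptation signal later "detected" from fitted B0 values is known to
  be an artefact of the estimator, not of the data.

* Sharpe-Schoolfield curves with known parameters and multiplicative
  lognormal noise, for parameter-recovery testing.

Both are pure functions of their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .constants import celsius_to_kelvin, kelvin_to_celsius
from .fit import TPCurve
from .models import SSParams, ss_rate

__all__ = [
    "BetaCurveSpec",
    "PopulationSpec",
    "NoMCACertificate",
    "sample_spec",
    "render_curve",
    "generate_population",
    "generate_ss_curves",
]

# Table of sampling distributions for the beta-curve population:
#   alpha ~ N(10, 3); beta = alpha - i with i ~ N(4, 2);
#   width multiplier j ~ N(25, 4) degC; height offset k ~ N(3, 0.8).
_ALPHA_MU, _ALPHA_SD = 10.0, 3.0
_I_MU, _I_SD = 4.0, 2.0
_J_MU, _J_SD = 25.0, 4.0
_K_MU, _K_SD = 3.0, 0.8

_MAX_REJECTIONS = 10**6


@dataclass(frozen=True)
class BetaCurveSpec:
    """Generator parameters of one beta-density curve and its true shape.

    ``width_mult`` (j) maps the beta unit support to [0, j] degC;
    ``height_offset`` (k) raises every density value, so the curve baseline
    is k, not zero.
    """

    alpha: float
    beta_: float
    width_mult: float
    height_offset: float

    def __post_init__(self):
        if not (self.alpha > self.beta_ > 1.0):
            raise ValueError("negative skew requires alpha > beta > 1")
        if self.width_mult <= 0 or self.height_offset <= 0:
            raise ValueError("width and height parameters must be positive")

    @property
    def mode(self) -> float:
        """Mode of the beta density on the unit support."""
        return (self.alpha - 1.0) / (self.alpha + self.beta_ - 2.0)

    @property
    def true_t_pk_c(self) -> float:
        """Analytic peak temperature (degC): beta mode mapped to [0, j]."""
        return self.width_mult * self.mode

    @property
    def peak_density(self) -> float:
        """Beta density at its mode (the "original height" of the curve)."""
        return float(stats.beta.pdf(self.mode, self.alpha, self.beta_))

    def value_at(self, t_celsius: float) -> float:
        """True curve value at a temperature (degC); baseline k outside [0, j].

        The beta density is normalised to unit peak height before the
        height offset is added, so every curve has baseline k and peak
        1 + k.  Without this normalisation, narrow curves would be
        systematically taller (a density integrates to 1), coupling
        low-temperature performance to the thermal optimum and planting a
        cold-adaptation signal in a population that must not contain one.
        """
        x = t_celsius / self.width_mult
        dens = stats.beta.pdf(x, self.alpha, self.beta_) if 0.0 <= x <= 1.0 else 0.0
        return float(dens) / self.peak_density + self.height_offset

    @property
    def value_at_7c(self) -> float:
        return self.value_at(7.0)


@dataclass(frozen=True)
class NoMCACertificate:
    """Record that a population carries no cold-adaptation signal.

    Pearson correlation (with Fisher-z CI and t-test p) between each curve's
    true value at T_ref and its true thermal optimum, plus the seed that
    produced the accepted population.
    """

    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    seed_used: int
    n_attempts: int
    min_true_t_pk_c: float
    defined: bool = True


@dataclass(frozen=True)
class PopulationSpec:
    """Specification of a beta-curve population."""

    n_curves: int = 1000
    seed: int = 0
    T_ref: float = celsius_to_kelvin(7.0)
    n_grid_points: int = 15
    mca_guard_alpha: float = 0.05

    def __post_init__(self):
        if self.n_curves <= 0:
            raise ValueError("n_curves must be positive")
        if self.n_grid_points < 3:
            raise ValueError("need at least 3 grid points")


def sample_spec(rng: np.random.Generator) -> BetaCurveSpec:
    """Draw one accepted curve specification.

    Whole tuples (alpha, i, j, k) are rejected and redrawn until
    alpha > beta, alpha and beta exceed 1 (interior mode), and the width
    and height parameters are positive.
    """
    for _ in range(_MAX_REJECTIONS):
        alpha = rng.normal(_ALPHA_MU, _ALPHA_SD)
        beta = alpha - rng.normal(_I_MU, _I_SD)
        j = rng.normal(_J_MU, _J_SD)
        k = rng.normal(_K_MU, _K_SD)
        if alpha > beta > 1.0 and j > 0.0 and k > 0.0:
            return BetaCurveSpec(alpha, beta, j, k)
    raise RuntimeError("rejection sampling failed to accept a curve spec")


def render_curve(spec: BetaCurveSpec, n_grid_points: int = 15,
                 curve_id: str = "beta_curve") -> TPCurve:
    """Evaluate a spec on an even temperature grid (no measurement noise).

    The beta density is evaluated on ``n_grid_points`` evenly spaced points
    of its unit support, normalised to unit peak height, the support is
    mapped to [0, j] degC, and the height offset is added to every value
    (see :meth:`BetaCurveSpec.value_at`).
    """
    x = np.linspace(0.0, 1.0, n_grid_points)
    values = (stats.beta.pdf(x, spec.alpha, spec.beta_) / spec.peak_density
              + spec.height_offset)
    return TPCurve.from_celsius(curve_id, x * spec.width_mult, values)


def _pearson_fisher(x: np.ndarray, y: np.ndarray):
    r, p = stats.pearsonr(x, y)
    n = x.size
    z = math.atanh(max(min(r, 1 - 1e-15), -1 + 1e-15))
    half = stats.norm.ppf(0.975) / math.sqrt(n - 3)
    return float(r), math.tanh(z - half), math.tanh(z + half), float(p)


def generate_population(pspec: PopulationSpec
                        ) -> tuple[list[TPCurve], list[BetaCurveSpec],
                                   NoMCACertificate]:
    """Generate an accepted population of beta curves with its certificate.

    A candidate population (a pure function of the seed) is accepted when
    (i) the reference temperature lies below the population's minimum true
    thermal optimum, and (ii) the Pearson test between true value at T_ref
    and true T_pk is non-significant at ``mca_guard_alpha``.  Otherwise the
    seed is incremented and the population regenerated, up to 100 attempts.
    """
    t_ref_c = kelvin_to_celsius(pspec.T_ref)
    for attempt in range(100):
        seed = pspec.seed + attempt
        rng = np.random.default_rng(seed)
        specs = [sample_spec(rng) for _ in range(pspec.n_curves)]
        curves = [render_curve(s, pspec.n_grid_points, curve_id=f"sim_{seed}_{i:04d}")
                  for i, s in enumerate(specs)]
        t_pks = np.array([s.true_t_pk_c for s in specs])
        if pspec.n_curves == 1:
            cert = NoMCACertificate(np.nan, np.nan, np.nan, np.nan, 1, seed,
                                    attempt + 1, float(t_pks.min()), defined=False)
            return curves, specs, cert
        if t_pks.min() <= t_ref_c:
            continue
        vals = np.array([s.value_at(t_ref_c) for s in specs])
        r, lo, hi, p = _pearson_fisher(vals, t_pks)
        if p > pspec.mca_guard_alpha:
            cert = NoMCACertificate(r, lo, hi, p, pspec.n_curves, seed,
                                    attempt + 1, float(t_pks.min()))
            return curves, specs, cert
    raise RuntimeError("no acceptable population within 100 seed attempts")


def generate_ss_curves(true_params: list[SSParams], noise_cv: float,
                       n_points: int, t_range: tuple[float, float],
                       rng: np.random.Generator) -> list[tuple[TPCurve, SSParams]]:
    """Sharpe-Schoolfield curves with known truth, for recovery tests.

    Evaluates each parameter set on an even kelvin grid over ``t_range`` and
    applies multiplicative lognormal noise with coefficient of variation
    ``noise_cv`` (mean 1, so the noise is unbiased on the linear scale).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    temps = np.linspace(*t_range, n_points)
    out = []
    for i, params in enumerate(true_params):
        clean = ss_rate(params, temps)
        if noise_cv > 0:
            sigma = math.sqrt(math.log1p(noise_cv**2))
            noise = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=n_points)
        else:
            noise = 1.0
        curve = TPCurve(f"ss_{i:04d}", temps, clean * noise)
        out.append((curve, params))
    return out
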