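"""Closed-form mathematics of thermal performance curve (TPC) models.

The centrepiece is the four-parameter Sharpe-Schoolfield model, in which a
biological rate rises with temperature following Arrhenius kinetics and falls
beyond a peak because an increasing fraction of the rate-limiting enzyme is
inactivated:

    B(T) = B0 * exp[(-E/k) * (1/T - 1/T_ref)] /
           (1 + exp[(E_D/k) * (1/T_h - 1/T)])

``B0`` is nominally the rate at the reference temperature ``T_ref`` — but only
when the enzyme pool is fully active there.  The model's *actual* prediction
at ``T_ref`` is ``B(T_ref) = B0 / (1 + exp[(E_D/k)(1/T_h - 1/T_ref)])``, which
is strictly below ``B0`` for any finite ``T_h``.  The ratio
``B0 / B(T_ref)`` — the *inflation* of the normalised rate — is what the rest
of the package quantifies and corrects for.

This module also houses the recommended unbiased normalisation alternatives:
the Boltzmann-Arrhenius model (for rise-only data), the Q10 temperature
coefficient, and the intrinsic optimum temperature (highest temperature at
which the enzyme pool is effectively fully active).

All temperatures are kelvin.  Celsius appears only at I/O boundaries
(:mod:`tpcfit.io`, :mod:`tpcfit.cli`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .constants import BOLTZMANN_EV as K_B

__all__ = [
    "SSParams",
    "DerivedQuantities",
    "NoPeakError",
    "ss_rate",
    "activity_fraction",
    "b_at_tref",
    "t_pk",
    "p_pk",
    "inflation_fold",
    "log_fold_increase",
    "derive",
    "ba_rate",
    "q10_estimate",
    "q10_extrapolate",
    "intrinsic_optimum",
]


class NoPeakError(ValueError):
    """The parameter set has no interior rate maximum (requires E_D > E)."""


#: When True, :func:`t_pk` cross-checks its closed form against a coarse
#: temperature grid on every call (cheap insurance for the derivation;
#: enabled in the test suite, off by default in production loops).
DEBUG_CHECK_TPK = False


def _check_temperature(T) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)) or np.any(T <= 0):
        raise ValueError("temperatures must be finite and strictly positive kelvin")
    return T


@dataclass(frozen=True)
class SSParams:
    """Parameters of the four-parameter Sharpe-Schoolfield model.

    Attributes
    ----------
    B0 : float
        Rate value at the reference temperature, assuming full enzyme
        activity there (same units as the input rate, > 0).
    E : float
        Activation energy (eV, > 0); controls the rise up to the peak.
    E_D : float
        Deactivation energy (eV, > 0); controls the fall after the peak.
        A peak exists only when ``E_D > E``.
    T_h : float
        Temperature at which 50% of the enzyme units are inactive (K).
    T_ref : float
        Reference (normalisation) temperature (K).
    """

    B0: float
    E: float
    E_D: float
    T_h: float
    T_ref: float

    def __post_init__(self):
        for name in ("B0", "E", "E_D", "T_h", "T_ref"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"SSParams.{name} must be finite and > 0, got {v!r}")

    @property
    def has_peak(self) -> bool:
        """Whether the model has an interior maximum (``E_D > E``)."""
        return self.E_D > self.E


@dataclass(frozen=True)
class DerivedQuantities:
    """Quantities derived from a Sharpe-Schoolfield parameter set.

    ``T_pk``/``P_pk`` are ``None`` when no interior peak exists.
    ``log_fold_increase`` is ``-inf`` when the inflation is negligible
    (fold within 1e-15 of 1).
    """

    T_pk: float | None
    P_pk: float | None
    B_at_Tref: float
    inflation_fold: float
    log_fold_increase: float


def _log_denominator(E_D: float, T_h: float, T) -> np.ndarray:
    """log(1 + exp[(E_D/k)(1/T_h - 1/T)]), computed overflow-safely."""
    z = (E_D / K_B) * (1.0 / T_h - 1.0 / T)
    return np.logaddexp(0.0, z)


def ss_rate(params: SSParams, T):
    """Sharpe-Schoolfield rate at temperature ``T`` (kelvin; vectorised).

    Exponentials are combined in log space so that extreme parameter sets
    underflow to 0 instead of overflowing.
    """
    T = _check_temperature(T)
    log_num = math.log(params.B0) - (params.E / K_B) * (1.0 / T - 1.0 / params.T_ref)
    out = np.exp(log_num - _log_denominator(params.E_D, params.T_h, T))
    return out if out.ndim else float(out)

def activity_fraction(E_D: float, T_h: float, T):
    """Fraction of the enzyme pool that is active at ``T``; in (0, 1).

    This is the reciprocal of the Sharpe-Schoolfield denominator: strictly
    decreasing in ``T`` and exactly 0.5 at ``T = T_h``.
    """
    if not (E_D > 0 and T_h > 0):
        raise ValueError("E_D and T_h must be positive")
    T = _check_temperature(T)
    z = (E_D / K_B) * (1.0 / T_h - 1.0 / T)
    out = expit(-z)
    return out if out.ndim else float(out)


def b_at_tref(params: SSParams) -> float:
    """True model rate at the reference temperature, ``B(T_ref)``.

    Identically ``ss_rate(params, T_ref)``; always below ``B0``.
    """
    return params.B0 * activity_fraction(params.E_D, params.T_h, params.T_ref)


def t_pk(params: SSParams) -> float:
    """Temperature of peak performance (kelvin).

    Setting d(ln B)/dT = 0 gives the active fraction at the peak as
    ``1 - E/E_D``, i.e. ``(E_D/k)(1/T_h - 1/T_pk) = ln(E/(E_D - E))``, so

        T_pk = E_D * T_h / (E_D + k * T_h * ln((E_D - E)/E)).

    Raises
    ------
    NoPeakError
        If ``E_D <= E`` (monotone increasing curve, no interior maximum),
        or the would-be peak lies at non-physical (non-positive) temperature.
    """
    if not params.has_peak:
        raise NoPeakError(
            f"no peak: requires E_D > E (got E={params.E}, E_D={params.E_D})"
        )
    denom = params.E_D + K_B * params.T_h * math.log((params.E_D - params.E) / params.E)
    if denom <= 0:
        raise NoPeakError("no interior peak at a positive temperature")
    tpk = params.E_D * params.T_h / denom
    if DEBUG_CHECK_TPK:
        grid = np.linspace(max(tpk - 40.0, 1.0), tpk + 40.0, 81)
        if float(ss_rate(params, tpk)) < np.max(ss_rate(params, grid)) * (1 - 1e-9):
            raise AssertionError("closed-form T_pk beaten by a coarse grid")
    return tpk


def p_pk(params: SSParams) -> float:
    """Rate at the peak, ``ss_rate(params, t_pk(params))``."""
    return float(ss_rate(params, t_pk(params)))


def inflation_fold(params: SSParams) -> float:
    """Fold by which ``B0`` overestimates ``B(T_ref)``.

    Equals ``1 + exp[(E_D/k)(1/T_h - 1/T_ref)] = B0 / B(T_ref)``; always
    >= 1, exactly 2 when ``T_ref = T_h``, and +inf when the exponent
    overflows (``T_ref`` far above ``T_h``).
    """
    z = (params.E_D / K_B) * (1.0 / params.T_h - 1.0 / params.T_ref)
    if z > 700.0:  # exp overflow; the fold is effectively infinite
        return math.inf
    return 1.0 + math.exp(z)


def log_fold_increase(params: SSParams) -> float:
    """log2(inflation_fold - 1); the conventional inflation axis.

    Zero means ``B0`` is exactly double the true ``B(T_ref)`` (the
    ``T_ref = T_h`` case).  Folds within 1e-15 of 1 are reported as ``-inf``
    (negligible inflation), not an exception.
    """
    z = (params.E_D / K_B) * (1.0 / params.T_h - 1.0 / params.T_ref)
    # fold - 1 = e^z exactly, so the log2 is z/ln2; sentinel when negligible
    if math.exp(min(z, 1.0)) <= 1e-15:
        return -math.inf
    return z / math.log(2.0)


def derive(params: SSParams) -> DerivedQuantities:
    """All derived quantities for a parameter set, recomputed from scratch."""
    if params.has_peak:
        try:
            tpk = t_pk(params)
            ppk = float(ss_rate(params, tpk))
        except NoPeakError:
            tpk = ppk = None
    else:
        tpk = ppk = None
    return DerivedQuantities(
        T_pk=tpk,
        P_pk=ppk,
        B_at_Tref=b_at_tref(params),
        inflation_fold=inflation_fold(params),
        log_fold_increase=log_fold_increase(params),
    )


# ---------------------------------------------------------------------------
# Unbiased normalisation alternatives
# ---------------------------------------------------------------------------

def ba_rate(B0: float, E: float, T_ref: float, T):
    """Boltzmann-Arrhenius rate: ``B0 * exp[(-E/k)(1/T - 1/T_ref)]``.

    For this rise-only model the normalised rate at ``T_ref`` is exactly
    ``B0`` — there is no inflation to correct.
    """
    if not (B0 > 0 and E >= 0 and T_ref > 0):
        raise ValueError("B0, T_ref must be positive and E non-negative")
    T = _check_temperature(T)
    out = B0 * np.exp(-(E / K_B) * (1.0 / T - 1.0 / T_ref))
    return out if out.ndim else float(out)


def q10_estimate(B1: float, T1: float, B2: float, T2: float) -> float:
    """Q10 temperature coefficient from rates at two temperatures.

    ``Q10 = (B2/B1) ** (10 / (T2 - T1))`` — the factor by which the rate
    changes over a 10-degree rise.
    """
    if not (B1 > 0 and B2 > 0):
        raise ValueError("rates must be positive")
    if T1 == T2:
        raise ValueError("Q10 is undefined for equal temperatures")
    return (B2 / B1) ** (10.0 / (T2 - T1))


def q10_extrapolate(B1: float, T1: float, Q10: float, T_ref: float) -> float:
    """Rate at ``T_ref`` extrapolated from ``B1`` at ``T1`` via a Q10.

    ``B(T_ref) = B1 * Q10 ** ((T_ref - T1)/10)``; the algebraic inverse of
    :func:`q10_estimate`, so the round-trip recovers the second rate exactly.
    """
    if not (B1 > 0 and Q10 > 0):
        raise ValueError("B1 and Q10 must be positive")
    return B1 * Q10 ** ((T_ref - T1) / 10.0)


def intrinsic_optimum(E_D: float, T_h: float, activity_level: float = 0.99) -> float:
    """Highest temperature at which the enzyme pool is ~fully active.

    Solves ``activity_fraction(E_D, T_h, T) = activity_level`` for ``T``;
    since activity is strictly decreasing the solution is unique:

        1/T = 1/T_h + (k/E_D) * ln(activity_level / (1 - activity_level))

    Always below ``T_h``.  ``activity_level`` must lie in (0.5, 1): levels
    at or below 0.5 would place the "optimum" at or above ``T_h``, where
    half the enzyme pool is already inactive.
    """
    if not (0.5 < activity_level < 1.0):
        raise ValueError("activity_level must lie strictly between 0.5 and 1")
    if not (E_D > 0 and T_h > 0):
        raise ValueError("E_D and T_h must be positive")
    inv_t = 1.0 / T_h + (K_B / E_D) * math.log(activity_level / (1.0 - activity_level))
    return 1.0 / inv_t
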