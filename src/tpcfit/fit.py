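"""Nonlinear least-squares estimation of Sharpe-Schoolfield parameters.

The public surface follows the model/results idiom: build a
:class:`SharpeSchoolfield` model from a :class:`TPCurve` (or a long-format
DataFrame), call :meth:`~SharpeSchoolfield.fit`, and work with the returned
:class:`SSFitResult` — fitted parameters, derived quantities (T_pk, P_pk,
B(T_ref), inflation), fit diagnostics, quality-control decision, a
``summary()`` table and a case-resampling bootstrap for B(T_ref) confidence
intervals.  :func:`fit_ss` is the one-call functional wrapper.

Estimation is bounded trust-region least squares (the bounded variant of
Levenberg-Marquardt) on the linear rate scale with unweighted residuals,
multi-started from jittered initial values.  ``E_D > E`` is *not* enforced
during the search — constraining it would bias the SSR — and is only checked
when deriving the peak.

Quality control mirrors standard practice for TPC meta-analyses: reject fits
with R^2 below 0.5 or with fewer than four observations on either side of
the fitted peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .constants import BOLTZMANN_EV as K_B
from .constants import celsius_to_kelvin, kelvin_to_celsius
from .models import (
    DerivedQuantities,
    NoPeakError,
    SSParams,
    b_at_tref,
    derive,
    ss_rate,
    t_pk,
)

__all__ = [
    "TPCurve",
    "FitOptions",
    "SharpeSchoolfield",
    "SSFitResult",
    "BootstrapCI",
    "BoltzmannArrhenius",
    "BAFitResult",
    "fit_ss",
    "fit_ba",
    "qc_filter",
    "tref_sweep",
    "rising_part",
    "SWEEP_COLUMNS",
]

# Box constraints for the bounded search: (B0, E, E_D, T_h).
_LOWER = np.array([1e-12, 1e-9, 1e-9, 150.0])
_UPPER = np.array([np.inf, 30.0, 50.0, 450.0])


@dataclass(frozen=True)
class TPCurve:
    """One empirical or synthetic thermal performance curve.

    Temperatures are kelvin internally; use :meth:`from_celsius` at the I/O
    boundary.  Raw rates may be non-positive — they are dropped (and
    counted) before fitting, since the model is strictly positive.
    """

    curve_id: str
    temperatures: np.ndarray
    rates: np.ndarray
    species: str | None = None
    trait: str | None = None

    def __post_init__(self):
        temps = np.asarray(self.temperatures, dtype=float)
        rates = np.asarray(self.rates, dtype=float)
        if temps.ndim != 1 or temps.shape != rates.shape:
            raise ValueError("temperatures and rates must be equal-length 1-D")
        if temps.size < 2:
            raise ValueError("a curve needs at least 2 points")
        if not np.all(np.isfinite(temps)) or np.any(temps <= 0):
            raise ValueError("temperatures must be finite positive kelvin")
        if not np.all(np.isfinite(rates)):
            raise ValueError("rates must be finite")
        object.__setattr__(self, "temperatures", temps)
        object.__setattr__(self, "rates", rates)

    @classmethod
    def from_celsius(cls, curve_id, temperatures_c, rates, **meta) -> "TPCurve":
        return cls(curve_id, celsius_to_kelvin(np.asarray(temperatures_c, float)),
                   np.asarray(rates, float), **meta)

    def __len__(self) -> int:
        return self.temperatures.size


@dataclass(frozen=True)
class FitOptions:
    """Options controlling fitting, QC and the bootstrap.

    ``T_ref`` is kelvin.  Defaults follow common meta-analysis practice:
    R^2 >= 0.5 and at least four points on each side of the peak.
    """

    T_ref: float = celsius_to_kelvin(7.0)
    r2_min: float = 0.5
    min_points_per_side: int = 4
    n_restarts: int = 10
    seed: int = 0
    bootstrap_reps: int = 999

    def __post_init__(self):
        if not (0.0 <= self.r2_min <= 1.0):
            raise ValueError("r2_min must lie in [0, 1]")
        if self.min_points_per_side < 1 or self.n_restarts < 0:
            raise ValueError("counts must be positive")
        if self.T_ref <= 0:
            raise ValueError("T_ref must be positive kelvin")


@dataclass(frozen=True)
class BootstrapCI:
    """Percentile bootstrap interval for B(T_ref)."""

    estimate: float
    ci_low: float
    ci_high: float
    n_ok: int
    n_failed: int
    reliable: bool


@dataclass
class SSFitResult:
    """Result of fitting the Sharpe-Schoolfield model to one curve.

    Derived quantities are always recomputed from ``params`` (property
    :attr:`derived`), never stored independently.
    """

    curve: TPCurve
    options: FitOptions
    converged: bool
    params: SSParams | None = None
    r_squared: float = np.nan
    ssr: float = np.nan
    n_restarts_used: int = 0
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_used: int = 0
    n_dropped_nonpositive: int = 0
    reason: str | None = None  # why unfittable, if not converged

    @property
    def derived(self) -> DerivedQuantities | None:
        if self.params is None:
            return None
        return derive(self.params)

    def _peak_side_counts(self) -> tuple[int | None, int | None]:
        if self.params is None or not self.params.has_peak:
            return None, None
        try:
            tpk = t_pk(self.params)
        except NoPeakError:
            return None, None
        temps = self._fit_temperatures
        return int(np.sum(temps < tpk)), int(np.sum(temps > tpk))

    @property
    def n_before_peak(self) -> int | None:
        return self._peak_side_counts()[0]

    @property
    def n_after_peak(self) -> int | None:
        return self._peak_side_counts()[1]

    @property
    def _fit_temperatures(self) -> np.ndarray:
        keep = np.isfinite(self.curve.rates) & (self.curve.rates > 0)
        return self.curve.temperatures[keep]

    @property
    def accepted(self) -> bool:
        return qc_filter(self, self.options)[0]

    @property
    def reject_reason(self) -> str | None:
        return qc_filter(self, self.options)[1]

    def predict(self, T) -> np.ndarray:
        if self.params is None:
            raise ValueError("fit did not converge; no parameters to predict with")
        return ss_rate(self.params, T)

    def bootstrap_b_at_tref(self, reps: int | None = None,
                            seed: int | None = None) -> BootstrapCI:
        """Case-resampling bootstrap percentile 95% CI for B(T_ref).

        Resamples the curve's points with replacement, refits, and takes the
        2.5/97.5 percentiles of the replicate B(T_ref) values.  Replicates
        whose fit fails are dropped and counted; the interval is flagged
        unreliable when more than half fail.
        """
        if self.params is None:
            raise ValueError("cannot bootstrap an unconverged fit")
        reps = self.options.bootstrap_reps if reps is None else reps
        seed = self.options.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        temps, rates = self.curve.temperatures, self.curve.rates
        n = temps.size
        # refits start from the full-data solution plus one default start
        fast_opts = replace(self.options, n_restarts=1)
        values = []
        n_failed = 0
        for _ in range(reps):
            idx = rng.integers(0, n, size=n)
            boot = TPCurve(self.curve.curve_id, temps[idx], rates[idx])
            try:
                res = _fit_curve(boot, fast_opts, rng=rng, warm_start=self.params)
            except ValueError:
                n_failed += 1
                continue
            if res.converged and res.params is not None:
                values.append(b_at_tref(res.params))
            else:
                n_failed += 1
        values = np.asarray(values)
        if values.size == 0:
            return BootstrapCI(b_at_tref(self.params), np.nan, np.nan, 0, n_failed, False)
        lo, hi = np.percentile(values, [2.5, 97.5])
        return BootstrapCI(
            estimate=b_at_tref(self.params),
            ci_low=float(lo),
            ci_high=float(hi),
            n_ok=int(values.size),
            n_failed=n_failed,
            reliable=n_failed <= reps / 2,
        )

    def summary(self) -> str:
        """Human-readable summary table of the fit."""
        lines = [
            "Sharpe-Schoolfield fit",
            "======================",
            f"curve_id:        {self.curve.curve_id}",
            f"n points (used): {len(self.curve)} ({self.n_used})",
            f"converged:       {self.converged}"
            + (f"  [{self.reason}]" if self.reason else ""),
        ]
        if self.params is not None:
            d = self.derived
            lines += [
                f"T_ref:           {kelvin_to_celsius(self.params.T_ref):.2f} C",
                f"B0:              {self.params.B0:.6g}",
                f"E:               {self.params.E:.4f} eV",
                f"E_D:             {self.params.E_D:.4f} eV",
                f"T_h:             {kelvin_to_celsius(self.params.T_h):.2f} C",
                f"R^2:             {self.r_squared:.4f}",
                f"B(T_ref):        {d.B_at_Tref:.6g}",
                f"inflation fold:  {d.inflation_fold:.4g}",
            ]
            if d.T_pk is not None:
                lines += [
                    f"T_pk:            {kelvin_to_celsius(d.T_pk):.2f} C",
                    f"P_pk:            {d.P_pk:.6g}",
                    f"points before/after peak: "
                    f"{self.n_before_peak}/{self.n_after_peak}",
                ]
            acc, why = qc_filter(self, self.options)
            lines.append(f"QC accepted:     {acc}" + (f"  [{why}]" if why else ""))
        return "\n".join(lines)


def _ss_model_and_jac(theta: np.ndarray, T: np.ndarray, T_ref: float):
    """Model values and analytic Jacobian for the 4-parameter fit."""
    B0, E, E_D, T_h = theta
    z = (E_D / K_B) * (1.0 / T_h - 1.0 / T)
    log_num = -(E / K_B) * (1.0 / T - 1.0 / T_ref)
    m = B0 * np.exp(log_num - np.logaddexp(0.0, z))
    sig = 1.0 / (1.0 + np.exp(-z))  # inactive fraction weight
    jac = np.empty((T.size, 4))
    jac[:, 0] = m / B0
    jac[:, 1] = m * (-(1.0 / K_B) * (1.0 / T - 1.0 / T_ref))
    jac[:, 2] = m * (-sig * (1.0 / K_B) * (1.0 / T_h - 1.0 / T))
    jac[:, 3] = m * (sig * (E_D / K_B) / T_h**2)
    return m, jac


def _initial_guess(temps: np.ndarray, rates: np.ndarray, T_ref: float) -> np.ndarray:
    """Default start: canonical E = 0.65 eV, E_D = 3 eV, T_h just past the
    observed maximum, B0 from the rising-limb point nearest T_ref."""
    i_max = int(np.argmax(rates))
    t_h0 = float(np.clip(temps[i_max] + 2.0, _LOWER[3] + 1.0, _UPPER[3] - 1.0))
    rising = temps <= temps[i_max]
    t_rise, r_rise = temps[rising], rates[rising]
    b0 = float(r_rise[np.argmin(np.abs(t_rise - T_ref))])
    return np.array([max(b0, 1e-9), 0.65, 3.0, t_h0])


def _fit_curve(curve: TPCurve, options: FitOptions,
               rng: np.random.Generator | None = None,
               warm_start: SSParams | None = None) -> SSFitResult:
    keep = np.isfinite(curve.rates) & (curve.rates > 0)
    temps, rates = curve.temperatures[keep], curve.rates[keep]
    n_dropped = int(curve.rates.size - temps.size)
    if temps.size < 5:
        return SSFitResult(curve, options, converged=False, reason="too_few_points",
                           n_used=int(temps.size), n_dropped_nonpositive=n_dropped)
    if rng is None:
        rng = np.random.default_rng(options.seed)

    x0 = _initial_guess(temps, rates, options.T_ref)
    starts = [x0]
    if warm_start is not None:
        starts.insert(0, np.array([warm_start.B0, warm_start.E,
                                   warm_start.E_D, warm_start.T_h]))
    for _ in range(options.n_restarts):
        jit = np.exp(rng.uniform(np.log(0.5), np.log(1.5), size=3))
        t_h_jit = x0[3] + rng.uniform(-10.0, 10.0)
        starts.append(np.array([x0[0] * jit[0], x0[1] * jit[1],
                                x0[2] * jit[2], t_h_jit]))

    def resid(theta):
        return _ss_model_and_jac(theta, temps, options.T_ref)[0] - rates

    def jac(theta):
        return _ss_model_and_jac(theta, temps, options.T_ref)[1]

    ss_tot = float(np.sum((rates - rates.mean()) ** 2))
    best = None
    n_tried = 0
    for start in starts:
        n_tried += 1
        start = np.clip(start, _LOWER * 1.0000001, _UPPER - 1e-9)
        start[0] = max(start[0], 1e-9)
        try:
            sol = least_squares(resid, start, jac=jac, bounds=(_LOWER, _UPPER),
                                method="trf", max_nfev=400)
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        ssr = float(2.0 * sol.cost)
        if best is None or ssr < best[0]:
            best = (ssr, sol)
        # an essentially perfect fit cannot be improved; stop restarting
        if ss_tot > 0 and 1.0 - ssr / ss_tot > 0.9999:
            break

    if best is None:
        return SSFitResult(curve, options, converged=False, reason="no_convergence",
                           n_used=int(temps.size), n_dropped_nonpositive=n_dropped)
    ssr, sol = best
    b0_f, e_f, ed_f, th_f = (float(v) for v in sol.x)
    try:
        params = SSParams(B0=b0_f, E=e_f, E_D=ed_f, T_h=th_f, T_ref=options.T_ref)
    except ValueError:
        return SSFitResult(curve, options, converged=False, reason="invalid_params",
                           n_used=int(temps.size), n_dropped_nonpositive=n_dropped)
    r2 = 1.0 - ssr / ss_tot if ss_tot > 0 else np.nan
    return SSFitResult(
        curve, options, converged=True, params=params,
        r_squared=float(r2), ssr=ssr, n_restarts_used=n_tried,
        residuals=resid(sol.x), n_used=int(temps.size),
        n_dropped_nonpositive=n_dropped,
    )


class SharpeSchoolfield:
    """Sharpe-Schoolfield model bound to one thermal performance curve.

    Parameters
    ----------
    curve : TPCurve
        The data.  Use :meth:`from_dataframe` for long-format tabular input.
    options : FitOptions, optional
        Fitting/QC options; ``T_ref`` lives here (kelvin).

    Examples
    --------
    >>> model = SharpeSchoolfield(curve, FitOptions(T_ref=280.15))
    >>> res = model.fit()
    >>> res.derived.B_at_Tref < res.params.B0
    True
    """

    def __init__(self, curve: TPCurve, options: FitOptions | None = None):
        self.curve = curve
        self.options = options or FitOptions()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, curve_id: str | None = None,
                       options: FitOptions | None = None) -> "SharpeSchoolfield":
        """Build from a long-format frame with ``temperature_C`` and ``rate``
        columns (one curve; filter by ``curve_id`` first if needed)."""
        if curve_id is not None:
            df = df[df["curve_id"] == curve_id]
        cid = str(df["curve_id"].iloc[0]) if "curve_id" in df else (curve_id or "curve")
        curve = TPCurve.from_celsius(cid, df["temperature_C"].to_numpy(),
                                     df["rate"].to_numpy())
        return cls(curve, options)

    def fit(self, options: FitOptions | None = None) -> SSFitResult:
        opts = options or self.options
        return _fit_curve(self.curve, opts)


def fit_ss(curve: TPCurve, options: FitOptions | None = None) -> SSFitResult:
    """Fit the Sharpe-Schoolfield model to one curve (functional wrapper)."""
    return SharpeSchoolfield(curve, options).fit()


def qc_decision(r_squared: float, n_before_peak: int, n_after_peak: int,
                options: FitOptions) -> tuple[bool, str | None]:
    """Pure QC rule on (R^2, points before peak, points after peak)."""
    if not (np.isfinite(r_squared) and r_squared >= options.r2_min):
        return False, "r2"
    if n_before_peak < options.min_points_per_side:
        return False, "points_before_peak"
    if n_after_peak < options.min_points_per_side:
        return False, "points_after_peak"
    return True, None


def qc_filter(fit: SSFitResult, options: FitOptions | None = None
              ) -> tuple[bool, str | None]:
    """Quality-control decision for a fit: ``(accepted, reject_reason)``.

    Accepted iff the fit converged, has a defined peak, R^2 >= ``r2_min``
    and at least ``min_points_per_side`` observations strictly below and
    strictly above the fitted T_pk (ties at T_pk count on neither side).
    """
    options = options or fit.options
    if not fit.converged:
        return False, "unconverged"
    n_before, n_after = fit._peak_side_counts()
    if n_before is None:
        return False, "no_peak"
    return qc_decision(fit.r_squared, n_before, n_after, options)


SWEEP_COLUMNS = [
    "curve_id", "T_ref_C", "B0", "E", "E_D", "T_h_C", "T_pk_C", "P_pk",
    "B_at_Tref", "inflation_fold", "log_fold_increase", "r_squared",
    "n_before_peak", "n_after_peak", "accepted", "reject_reason",
]


def _fit_row(fit: SSFitResult, t_ref: float) -> dict:
    row = {c: np.nan for c in SWEEP_COLUMNS}
    row["curve_id"] = fit.curve.curve_id
    row["T_ref_C"] = kelvin_to_celsius(t_ref)
    acc, why = qc_filter(fit, fit.options)
    row["accepted"] = acc
    row["reject_reason"] = why if why else ""
    if fit.params is not None:
        d = fit.derived
        row.update(
            B0=fit.params.B0, E=fit.params.E, E_D=fit.params.E_D,
            T_h_C=kelvin_to_celsius(fit.params.T_h),
            B_at_Tref=d.B_at_Tref, inflation_fold=d.inflation_fold,
            log_fold_increase=d.log_fold_increase, r_squared=fit.r_squared,
        )
        if d.T_pk is not None:
            row.update(T_pk_C=kelvin_to_celsius(d.T_pk), P_pk=d.P_pk,
                       n_before_peak=fit.n_before_peak,
                       n_after_peak=fit.n_after_peak)
    return row


def tref_sweep(curves: Sequence[TPCurve], t_ref_values: Sequence[float],
               options: FitOptions | None = None) -> pd.DataFrame:
    """Refit every curve at each reference temperature (kelvin).

    Returns one row per (curve, T_ref) with the fitted parameters and the
    inflation diagnostics; per-curve failures become rejected rows, never
    abort the sweep.  This is the data behind the classic inflation-versus-
    (T_h - T_ref) picture.
    """
    options = options or FitOptions()
    rows = []
    for t_ref in t_ref_values:
        opts = replace(options, T_ref=float(t_ref))
        for curve in curves:
            fit = _fit_curve(curve, opts)
            rows.append(_fit_row(fit, t_ref))
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def bootstrap_b_at_tref(curve: TPCurve, options: FitOptions | None = None
                        ) -> BootstrapCI:
    """Fit a curve and bootstrap the B(T_ref) confidence interval."""
    fit = fit_ss(curve, options)
    if not fit.converged:
        raise ValueError(f"curve {curve.curve_id!r} is unfittable: {fit.reason}")
    return fit.bootstrap_b_at_tref()


# ---------------------------------------------------------------------------
# Boltzmann-Arrhenius (rise-only data)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BAFitResult:
    """Least-squares Boltzmann-Arrhenius fit on the rising limb."""

    B0: float
    E: float
    r_squared: float
    plateau_warning: bool


def rising_part(curve: TPCurve) -> TPCurve:
    """Truncate a curve at its empirical maximum (inclusive)."""
    order = np.argsort(curve.temperatures, kind="stable")
    temps, rates = curve.temperatures[order], curve.rates[order]
    i_max = int(np.argmax(rates))
    return TPCurve(curve.curve_id, temps[:i_max + 1], rates[:i_max + 1],
                   species=curve.species, trait=curve.trait)


class BoltzmannArrhenius:
    """Boltzmann-Arrhenius model for data covering only the rising limb."""

    def __init__(self, curve: TPCurve, T_ref: float):
        self.curve = curve
        self.T_ref = float(T_ref)

    def fit(self) -> BAFitResult:
        keep = np.isfinite(self.curve.rates) & (self.curve.rates > 0)
        temps, rates = self.curve.temperatures[keep], self.curve.rates[keep]
        if temps.size < 2:
            raise ValueError("need at least 2 positive-rate points")
        # log-linear regression supplies the start; refine on the linear scale
        x = -(1.0 / K_B) * (1.0 / temps - 1.0 / self.T_ref)
        slope, intercept = np.polyfit(x, np.log(rates), 1)
        x0 = np.array([math.exp(intercept), max(slope, 0.0)])

        def resid(theta):
            return theta[0] * np.exp(theta[1] * x) - rates

        sol = least_squares(resid, np.maximum(x0, [1e-12, 0.0]),
                            bounds=([1e-12, 0.0], [np.inf, 30.0]), method="trf")
        ssr = float(2.0 * sol.cost)
        ss_tot = float(np.sum((rates - rates.mean()) ** 2))
        r2 = 1.0 - ssr / ss_tot if ss_tot > 0 else np.nan
        order = np.argsort(temps, kind="stable")
        r_sorted = rates[order]
        plateau = bool(r_sorted.size >= 2 and
                       r_sorted[-1] < 1.05 * r_sorted[-2])
        return BAFitResult(B0=float(sol.x[0]), E=float(sol.x[1]),
                           r_squared=float(r2), plateau_warning=plateau)


def fit_ba(curve: TPCurve, T_ref: float) -> BAFitResult:
    """Fit the Boltzmann-Arrhenius model (caller supplies rising-limb data;
    see :func:`rising_part`).  Emits a plateau warning flag when the two
    warmest points rise by less than 5%."""
    return BoltzmannArrhenius(curve, T_ref).fit()
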