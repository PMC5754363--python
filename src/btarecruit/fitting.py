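"""Nonlinear least-squares estimators for the assay readouts.

Three estimators cover the quantitative readouts of the recruitment assays:

* :func:`fit_inhibition` — the apparent inhibition constant from a
  normalized-activity titration, using the hyperbolic competitive-inhibition
  form

      V = V_b + (1 - V_b) * K_i,app / ([I] + K_i,app),

  a two-parameter fit (V_b, K_i,app) since the inhibitable amplitude V_0 is
  constrained to 1 - V_b.  K_i,app is fitted on a log scale to enforce
  positivity; asymptotic standard errors come from the Jacobian.

* :func:`fit_exchange` — the relaxation rate of slow activity recovery,
  fitting A(t) = A_inf + (A_0 - A_inf) exp(-k t) with the endpoints A_0 and
  A_inf fixed from reference samples and only k free.

* :func:`initial_rate` — the substrate-turnover rate as the ordinary
  least-squares slope of the initial, linear portion of a fluorescence
  progress trace, after discarding a configurable instrument dead time
  (default 2 min).

Fits raise :class:`~btarecruit.errors.FitError` on degenerate data rather
than returning silently meaningless estimates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .errors import FitError, ParameterError
from .kinetics import ProgressTrace
from .recruitment import TitrationDataset

_LN2 = math.log(2.0)


def eq1_activity(
    inhibitor_conc: np.ndarray | float, v_b: float, ki_app: float
) -> np.ndarray | float:
    """Hyperbolic inhibition curve ``V_b + (1-V_b) * Ki / ([I] + Ki)``."""
    return v_b + (1.0 - v_b) * ki_app / (np.asarray(inhibitor_conc) + ki_app)


@dataclass(frozen=True)
class InhibitionFitResult:
    """Parameters of the inhibition-curve fit.

    ``v_b`` is the residual activity at saturating inhibitor, ``v_0`` the
    inhibitable amplitude (constrained to ``1 - v_b``), ``ki_app`` the
    apparent inhibition constant in mol/L.
    """

    v_b: float
    ki_app: float
    se_v_b: float
    se_ki_app: float
    rss: float
    n_points: int

    @property
    def v_0(self) -> float:
        return 1.0 - self.v_b


@dataclass(frozen=True)
class ExchangeFitResult:
    """Fixed-endpoint single-exponential fit of an exchange time course."""

    a0: float
    a_inf: float
    rate_per_h: float
    se_rate_per_h: float
    rss: float
    n_points: int

    @property
    def t_half_h(self) -> float:
        return _LN2 / self.rate_per_h


def fit_inhibition(
    data: TitrationDataset, weighted: bool = False
) -> InhibitionFitResult:
    """Fit the hyperbolic inhibition curve to a titration.

    Minimises ``sum w (V_obs - V_model)**2``, unweighted by default; with
    ``weighted=True`` the replicate standard deviations provide ``1/sd**2``
    weights.  Unweighted is the default because replicate s.d. estimated
    from triplicates is itself very noisy, which makes weighted standard
    errors anticonservative.  Initialisation: ``V_b`` from the smallest activity and
    ``K_i,app`` from the concentration nearest the half-amplitude crossing,
    which is robust for hyperbolic decays.

    Raises
    ------
    FitError
        For flat titrations (no inhibition signal) or an unidentifiable
        inhibition constant (estimate pinned at the search bounds).
    """
    conc = np.asarray(data.inhibitor_conc, dtype=float)
    act = np.asarray(data.activity, dtype=float)
    if len(np.unique(conc)) < 3:
        raise ParameterError("need >= 3 distinct inhibitor concentrations")
    if np.ptp(act) < 1e-3:
        raise FitError("titration is flat: no inhibition signal to fit")

    sd = np.asarray(data.sd, dtype=float)
    if weighted and not np.all(sd > 0):
        raise ParameterError("weighted fit requested but some sd are not > 0")

    v_b0 = float(np.clip(act.min(), 0.0, 1.0))
    half = v_b0 + 0.5 * (1.0 - v_b0)
    positive = conc > 0
    if not np.any(positive):
        raise ParameterError("need at least one non-zero inhibitor concentration")
    cand = conc[positive]
    ki0 = float(cand[np.argmin(np.abs(act[positive] - half))])

    def model(c: np.ndarray, v_b: float, log_ki: float) -> np.ndarray:
        return eq1_activity(c, v_b, math.exp(log_ki))

    lo = (0.0, math.log(1e-15))
    hi = (1.0, math.log(1.0))
    popt, pcov = curve_fit(
        model,
        conc,
        act,
        p0=[v_b0, math.log(ki0)],
        sigma=sd if weighted else None,
        bounds=(lo, hi),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        maxfev=20000,
    )
    v_b, log_ki = popt
    ki = math.exp(log_ki)
    if not np.all(np.isfinite(popt)):
        raise FitError("inhibition fit returned non-finite parameters")
    if log_ki < lo[1] + 1.0 or log_ki > hi[1] - 1e-6:
        raise FitError("apparent inhibition constant is unidentifiable from the data")

    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    resid = act - model(conc, *popt)
    rss = float(np.sum(resid**2))

    if conc[positive].min() > ki:
        warnings.warn(
            "no near-zero inhibitor point: V_b and K_i,app may be correlated",
            stacklevel=2,
        )
    if conc.max() < 10.0 * ki:
        warnings.warn(
            "largest inhibitor concentration is < 10x K_i,app: the plateau "
            "is poorly constrained",
            stacklevel=2,
        )
    return InhibitionFitResult(
        v_b=float(v_b),
        ki_app=float(ki),
        se_v_b=float(se[0]),
        se_ki_app=float(ki * se[1]),
        rss=rss,
        n_points=len(conc),
    )


def fit_exchange(
    times_h: Sequence[float],
    activities: Sequence[float],
    a0: float,
    a_inf: float,
) -> ExchangeFitResult:
    """Fit the relaxation rate of a fixed-endpoint exponential recovery.

    Only the rate ``k`` (per hour) is free; the endpoints are fixed from
    reference measurements.  A negative or non-finite rate estimate raises
    :class:`FitError`; grossly counter-directional data trigger a warning.
    """
    t = np.asarray(times_h, dtype=float)
    a = np.asarray(activities, dtype=float)
    if t.shape != a.shape:
        raise ParameterError("times and activities must have equal length")
    if len(t) < 3:
        raise ParameterError("need >= 3 time points")
    if a0 == a_inf:
        raise ParameterError("a0 and a_inf must differ (zero relaxation amplitude)")

    if (a[-1] - a[0]) * (a_inf - a0) < 0:
        warnings.warn(
            "activity trend opposes the fixed endpoints: data may be "
            "non-monotone or endpoints swapped",
            stacklevel=2,
        )

    # rate guess from the point nearest mid-amplitude; fall back to 1/mean t
    frac = (a - a_inf) / (a0 - a_inf)
    usable = (frac > 1e-6) & (frac < 1.0) & (t > 0)
    if np.any(usable):
        idx = np.argmin(np.abs(frac[usable] - 0.5))
        k0 = _LN2 / float(t[usable][idx])
    else:
        k0 = 1.0 / max(float(np.mean(t[t > 0])) if np.any(t > 0) else 1.0, 1e-12)

    def resid(p: np.ndarray) -> np.ndarray:
        return a_inf + (a0 - a_inf) * np.exp(-p[0] * t) - a

    sol = least_squares(
        resid, x0=[k0], xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=10000
    )
    k = float(sol.x[0])
    if not math.isfinite(k) or k <= 0:
        raise FitError(f"exchange fit produced a non-positive rate ({k})")

    rss = float(np.sum(sol.fun**2))
    jtj = float(np.sum(sol.jac**2))
    dof = len(t) - 1
    se_k = math.sqrt(rss / dof / jtj) if dof > 0 and jtj > 0 else float("nan")
    return ExchangeFitResult(
        a0=a0,
        a_inf=a_inf,
        rate_per_h=k,
        se_rate_per_h=se_k,
        rss=rss,
        n_points=len(t),
    )


def initial_rate(
    trace: ProgressTrace,
    *,
    dead_time_s: float = 120.0,
    window_fraction: float = 0.1,
    min_window_points: int = 20,
    min_points: int = 5,
) -> float:
    """Initial substrate-turnover rate from a progress trace (AU/s).

    Discards points before ``dead_time_s`` (instrument mixing latency),
    then takes the first ``window_fraction`` of the remaining duration or
    the first ``min_window_points`` points, whichever window is larger, and
    returns the ordinary least-squares slope of fluorescence versus time.
    Adding a constant baseline to the trace leaves the result unchanged.
    """
    t = np.asarray(trace.time_s, dtype=float)
    f = np.asarray(trace.fluorescence, dtype=float)
    keep = t >= dead_time_s
    if np.count_nonzero(keep) < min_points:
        raise ParameterError(
            "fewer than "
            f"{min_points} points remain after the {dead_time_s} s dead time"
        )
    t, f = t[keep], f[keep]
    duration = t[-1] - t[0]
    in_window = t <= t[0] + window_fraction * duration
    n_window = max(int(np.count_nonzero(in_window)), min_window_points)
    n_window = min(n_window, len(t))
    if n_window < min_points:
        raise ParameterError("initial window contains too few points")
    tw, fw = t[:n_window], f[:n_window]
    slope = np.polyfit(tw, fw, 1)[0]
    return float(slope)


def normalize_rates(
    rates: Sequence[float], reference_rate: float
) -> np.ndarray:
    """Normalize rates to a reference (no-inhibitor control) rate."""
    if not (reference_rate > 0):
        raise ParameterError(f"reference rate must be > 0, got {reference_rate}")
    return np.asarray(rates, dtype=float) / reference_rate
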