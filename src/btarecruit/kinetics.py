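"""Simulators for the kinetic readouts of the recruitment assays.

Covers the three timescales of the system:

* seconds — substrate turnover read out as a fluorescence progress trace
  (:func:`simulate_progress_trace`), integrated in the pseudo-first-order
  regime ``[S] << K_M`` so the initial slope is proportional to the active
  enzyme concentration;
* seconds — unbinding of the 10-bp handle-recruiter duplex
  (:func:`redistribution_halftime`), whose reported off-rate of 0.2 1/s
  makes protein redistribution along and between fibers effectively
  instantaneous on the assay timescale;
* hours — monomer exchange between fibers, observed as a slow single
  exponential activity relaxation (:func:`exchange_timecourse`) with a
  half-life of about 3 h.

The lumped catalytic constant kcat/K_M is not separately identifiable from
normalized activities (every rate is divided by a reference rate), so its
default is an arbitrary plausible value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class EnzymeKinetics:
    """Rate constants of the reporter enzyme and its scaffold attachment.

    ``kcat_over_km`` is the effective second-order constant (1/(M s)) of
    substrate hydrolysis; ``substrate_conc`` the fluorogenic substrate
    concentration (mol/L, assay default 2 uM, assumed well below K_M);
    ``fluorescence_per_product`` converts hydrolysed substrate to the
    fluorescence readout (AU per mol/L); ``duplex_koff`` the dissociation
    rate (1/s) of the 10-bp handle-recruiter duplex.
    """

    kcat_over_km: float = 1e4
    substrate_conc: float = 2e-6
    fluorescence_per_product: float = 1e9
    duplex_koff: float = 0.2

    def __post_init__(self) -> None:
        for name in (
            "kcat_over_km",
            "substrate_conc",
            "fluorescence_per_product",
            "duplex_koff",
        ):
            if not (getattr(self, name) > 0):
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class ProgressTrace:
    """One fluorescence-versus-time substrate-turnover trace."""

    time_s: np.ndarray
    fluorescence: np.ndarray
    label: str = ""
    substrate_conc: float = 2e-6
    dead_time_s: float = 120.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.shape != f.shape or t.ndim != 1:
            raise ParameterError("time and fluorescence must be equal-length 1-D")
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ParameterError("time must be strictly increasing")
        if not np.all(np.isfinite(f)):
            raise ParameterError("fluorescence must be finite")
        if not (self.substrate_conc > 0):
            raise ParameterError("substrate_conc must be > 0")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "fluorescence", f)


def simulate_progress_trace(
    active_enzyme_conc: float,
    kin: EnzymeKinetics,
    duration_s: float,
    dt_s: float = 15.0,
    f0: float = 0.0,
    label: str = "",
) -> ProgressTrace:
    """Noiseless substrate-turnover trace for a given active enzyme level.

    Pseudo-first-order decay ``[S](t) = [S]0 exp(-k1 t)`` with
    ``k1 = (kcat/K_M) * E_active``; fluorescence
    ``F(t) = F0 + c * ([S]0 - [S](t))``.  The initial slope
    ``c * [S]0 * k1`` is exactly proportional to the active enzyme, and the
    long-time plateau is ``F0 + c * [S]0``.
    """
    if active_enzyme_conc < 0:
        raise ParameterError(
            f"active enzyme concentration must be >= 0, got {active_enzyme_conc}"
        )
    if not (0 < dt_s <= duration_s):
        raise ParameterError("require 0 < dt_s <= duration_s")
    t = np.arange(0.0, duration_s + 0.5 * dt_s, dt_s)
    k1 = kin.kcat_over_km * active_enzyme_conc
    s = kin.substrate_conc * np.exp(-k1 * t)
    f = f0 + kin.fluorescence_per_product * (kin.substrate_conc - s)
    return ProgressTrace(
        time_s=t,
        fluorescence=f,
        label=label,
        substrate_conc=kin.substrate_conc,
    )


def exchange_timecourse(
    t_grid_h: np.ndarray, a0: float, a_inf: float, t_half_h: float
) -> np.ndarray:
    """Fixed-endpoint exponential relaxation ``A(t)`` on an hour grid.

    ``A(t) = A_inf + (A_0 - A_inf) * 2**(-t / t_half)``; at ``t = t_half``
    the activity is the exact midpoint of the endpoints.
    """
    if not (t_half_h > 0):
        raise ParameterError(f"t_half must be > 0, got {t_half_h}")
    t = np.asarray(t_grid_h, dtype=float)
    return a_inf + (a0 - a_inf) * 2.0 ** (-t / t_half_h)


def redistribution_halftime(kin: EnzymeKinetics) -> float:
    """Half-time (s) of handle-recruiter duplex unbinding, ``ln 2 / k_off``.

    With the reported 0.2 1/s off-rate this is a few seconds — orders of
    magnitude faster than the hours-long monomer exchange, which is why
    protein redistribution along the fibers is modelled as instantaneous.
    """
    return _LN2 / kin.duplex_koff
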