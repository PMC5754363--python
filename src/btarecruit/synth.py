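"""Seeded generators of synthetic assay datasets.

These emulate the statistical structure of the fluorescence assays —
replicate titrations of normalized activity, slow exchange time courses,
and raw progress traces sampled every 15 s — so that every fitter and
pipeline stage can be exercised without measured data.  Noise is Gaussian
and homoscedastic on the normalized-activity (or fluorescence) scale, with
triplicates by default; the defaults are a deliberate simplification and do
not emulate plate-reader drift, photobleaching, or inner-filter effects.

All generators are pure functions of their parameters and the seed: the
same call yields the identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .kinetics import EnzymeKinetics, ProgressTrace, simulate_progress_trace
from .recruitment import TitrationDataset


@dataclass(frozen=True)
class NoiseModel:
    """Replicate structure and noise magnitudes of the synthetic assays.

    ``sd_activity`` is the Gaussian standard deviation applied to each
    replicate of a normalized activity (default 0.03, chosen to resemble
    typical triplicate error bars; arbitrary); ``sd_fluorescence`` the
    per-sample noise on raw traces (AU); ``n_replicates`` the replicate
    count averaged per reported point; ``seed`` the RNG seed.
    """

    sd_activity: float = 0.03
    sd_fluorescence: float = 0.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_activity < 0 or self.sd_fluorescence < 0:
            raise ParameterError("noise standard deviations must be >= 0")
        if self.n_replicates < 1:
            raise ParameterError("n_replicates must be >= 1")


def _replicate_table(
    truth: np.ndarray, noise: NoiseModel, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Replicate-averaged noisy values and their sample s.d. per point."""
    if noise.sd_activity == 0.0:
        return truth.copy(), np.zeros(truth.size)
    reps = truth[None, :] + rng.normal(
        0.0, noise.sd_activity, size=(noise.n_replicates, truth.size)
    )
    mean = reps.mean(axis=0)
    sd = reps.std(axis=0, ddof=1) if noise.n_replicates > 1 else np.zeros(truth.size)
    return mean, sd


def generate_titration(
    activity_fn: Callable[[np.ndarray], np.ndarray],
    conc_grid: Sequence[float],
    noise: NoiseModel,
) -> TitrationDataset:
    """Noisy replicate titration around a truth curve.

    ``activity_fn`` maps an array of inhibitor concentrations (mol/L) to
    noiseless normalized activities — e.g. a closure over
    :func:`btarecruit.recruitment.titration_curve` or
    :func:`btarecruit.fitting.eq1_activity`.  With ``sd_activity = 0`` the
    output reproduces the truth exactly.
    """
    conc = np.asarray(list(conc_grid), dtype=float)
    truth = np.asarray(activity_fn(conc), dtype=float)
    rng = np.random.default_rng(noise.seed)
    mean, sd = _replicate_table(truth, noise, rng)
    return TitrationDataset(
        inhibitor_conc=conc,
        activity=mean,
        sd=sd,
        n_replicates=np.full(conc.size, noise.n_replicates, dtype=int),
    )


def generate_exchange_series(
    t_grid_h: Sequence[float],
    noise: NoiseModel,
    *,
    a0: float,
    a_inf: float,
    t_half_h: float,
) -> pd.DataFrame:
    """Noisy replicate-averaged exchange time course.

    Columns: ``time_h``, ``activity``, ``sd``, ``n``.  Noiseless
    (``sd_activity = 0``) output matches
    :func:`btarecruit.kinetics.exchange_timecourse` exactly.
    """
    from .kinetics import exchange_timecourse

    t = np.asarray(list(t_grid_h), dtype=float)
    truth = exchange_timecourse(t, a0, a_inf, t_half_h)
    rng = np.random.default_rng(noise.seed)
    mean, sd = _replicate_table(truth, noise, rng)
    return pd.DataFrame(
        {
            "time_h": t,
            "activity": mean,
            "sd": sd,
            "n": np.full(t.size, noise.n_replicates, dtype=int),
        }
    )


def generate_trace_set(
    conditions: Mapping[str, float],
    kin: EnzymeKinetics,
    noise: NoiseModel,
    *,
    enzyme_conc: float = 1e-9,
    duration_s: float = 3600.0,
    dt_s: float = 15.0,
    f0: float = 0.0,
) -> dict[str, ProgressTrace]:
    """One progress trace per assay condition.

    ``conditions`` maps a label to the active enzyme fraction under that
    condition (controls omitting a recruiter or the scaffold have fraction
    1; the fully assembled system has the model-predicted activity).
    Gaussian noise of ``sd_fluorescence`` AU is added per sample.
    """
    for label, frac in conditions.items():
        if frac < 0:
            raise ParameterError(f"condition {label!r}: active fraction must be >= 0")
    rng = np.random.default_rng(noise.seed)
    traces: dict[str, ProgressTrace] = {}
    for label, frac in conditions.items():
        clean = simulate_progress_trace(
            frac * enzyme_conc, kin, duration_s, dt_s, f0=f0, label=label
        )
        noisy = clean.fluorescence + rng.normal(
            0.0, noise.sd_fluorescence, size=clean.fluorescence.size
        )
        traces[label] = ProgressTrace(
            time_s=clean.time_s,
            fluorescence=noisy,
            label=label,
            substrate_conc=kin.substrate_conc,
        )
    return traces
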