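"""Forward model of enzyme activity under scaffold-templated inhibition.

Recruiting an enzyme and its weak inhibitor (solution K_i in the micromolar
range) onto the same fiber raises the inhibitor concentration experienced by
the scaffold-bound enzyme to the in-fiber effective concentration, driving
complex formation at bulk concentrations a thousandfold below K_i.  The
normalized activity observed in a bulk assay is a two-population average:

    V = (1 - f_E) + f_E * (1 - theta),

where ``f_E`` is the scaffold-bound enzyme fraction (set by the
handle-recruiter hybridization equilibrium) and ``theta`` the competitive-
inhibition occupancy of the scaffold-bound enzyme,
``theta = C_eff / (K_i + C_eff)``.  Free enzyme sees only the (negligible)
bulk inhibitor concentration and stays fully active, which is why the
inhibition plateaus at ``1 - f_E`` however much inhibitor is added.

Two conventions exist for the effective inhibitor concentration: the plain
one uses the full bulk inhibitor amount; the occupancy-corrected one (the
default here, ``apply_occupancy_to_inhibitor=True``) counts only the
scaffold-bound inhibitor fraction ``f_I``, since inhibitor left in solution
is not concentrated on the fiber.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .geometry import AssemblyComposition, FiberModel, effective_concentration
from .hybridization import (
    RecruitedSpecies,
    apply_displacement,
    protein_scaffold_fraction,
    solve_competition,
)

#: Solution-phase inhibition constant of the enzyme-inhibitor pair (mol/L);
#: the E104D beta-lactamase / wild-type BLIP pair binds at 1.5 uM.
DEFAULT_KI_SOLUTION = 1.5e-6


@dataclass(frozen=True)
class InhibitionModel:
    """Competitive-inhibition constant of the enzyme-inhibitor pair."""

    ki_solution: float = DEFAULT_KI_SOLUTION

    def __post_init__(self) -> None:
        if not (self.ki_solution > 0):
            raise ParameterError(f"K_i must be > 0, got {self.ki_solution}")


@dataclass(frozen=True)
class TitrationDataset:
    """Normalized activity versus inhibitor concentration.

    Activities are normalized to a no-inhibitor control (== 1 there);
    ``sd`` carries replicate standard deviations (0 for noiseless model
    curves) and ``n_replicates`` the replicate count per point.  Values are
    expected to lie in [0, 1 + 3 sd] up to sampling noise; only gross
    violations are rejected.
    """

    inhibitor_conc: np.ndarray
    activity: np.ndarray
    sd: np.ndarray
    n_replicates: np.ndarray

    def __post_init__(self) -> None:
        conc = np.asarray(self.inhibitor_conc, dtype=float)
        act = np.asarray(self.activity, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        n = np.asarray(self.n_replicates, dtype=int)
        if not (conc.shape == act.shape == sd.shape == n.shape):
            raise ParameterError("titration columns must have equal length")
        if np.any(conc < 0):
            raise ParameterError("inhibitor concentrations must be >= 0")
        if np.any(sd < 0) or np.any(n < 1):
            raise ParameterError("sd must be >= 0 and n_replicates >= 1")
        if np.any(act < -0.2) or np.any(act > 1.5):
            raise ParameterError("activities grossly outside [0, 1]")
        for attr, val in (
            ("inhibitor_conc", conc),
            ("activity", act),
            ("sd", sd),
            ("n_replicates", n),
        ):
            object.__setattr__(self, attr, val)

    def __len__(self) -> int:
        return len(self.inhibitor_conc)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "inhibitor_conc_M": self.inhibitor_conc,
                "activity": self.activity,
                "sd": self.sd,
                "n": self.n_replicates,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TitrationDataset":
        return cls(
            inhibitor_conc=frame["inhibitor_conc_M"].to_numpy(dtype=float),
            activity=frame["activity"].to_numpy(dtype=float),
            sd=frame["sd"].to_numpy(dtype=float)
            if "sd" in frame
            else np.zeros(len(frame)),
            n_replicates=frame["n"].to_numpy(dtype=int)
            if "n" in frame
            else np.ones(len(frame), dtype=int),
        )


def scaffold_inhibited_fraction(ceff_inhibitor: float, model: InhibitionModel) -> float:
    """Occupancy of the scaffold-bound enzyme by inhibitor.

    Single-site competitive binding at the effective concentration:
    ``theta = C_eff / (K_i + C_eff)``, in [0, 1), monotone in C_eff.
    """
    if ceff_inhibitor < 0:
        raise ParameterError(
            f"effective concentration must be >= 0, got {ceff_inhibitor}"
        )
    return ceff_inhibitor / (model.ki_solution + ceff_inhibitor)


def normalized_activity(
    composition: AssemblyComposition,
    fiber: FiberModel,
    enzyme: RecruitedSpecies,
    inhibitor: RecruitedSpecies,
    model: InhibitionModel,
    apply_occupancy_to_inhibitor: bool = True,
    return_details: bool = False,
):
    """Predicted normalized enzyme activity for one assembly condition.

    Solves the shared-handle competition between the enzyme and inhibitor
    recruiters, converts the (optionally occupancy-corrected) bulk inhibitor
    into its in-fiber effective concentration, and combines the free and
    scaffold-bound enzyme populations.  Controls are expressed by zeroing
    totals: no recruiter or no BTA-DNA gives ``f_E = 0`` and activity 1.

    Returns the activity, or ``(activity, details)`` with the model
    internals (``f_E``, ``f_I``, ``ceff_inhibitor``, ``theta``) when
    ``return_details`` is set.
    """
    handle_total = composition.conc_btadna
    if handle_total > 0:
        state = solve_competition(handle_total, [enzyme, inhibitor])
        f_e = protein_scaffold_fraction(enzyme, state)
    else:
        # no receptors on the fiber: nothing is recruited
        state = None
        f_e = 0.0

    f_i = 1.0
    if apply_occupancy_to_inhibitor:
        f_i = (
            protein_scaffold_fraction(inhibitor, state) if state is not None else 0.0
        )

    ceff_i = effective_concentration(
        inhibitor.protein_total * f_i, composition, fiber
    )
    theta = scaffold_inhibited_fraction(ceff_i, model)
    activity = (1.0 - f_e) + f_e * (1.0 - theta)
    if return_details:
        return activity, {
            "f_E": f_e,
            "f_I": f_i,
            "ceff_inhibitor": ceff_i,
            "theta": theta,
        }
    return activity


def titration_curve(
    inhibitor_concs: Sequence[float],
    composition: AssemblyComposition,
    fiber: FiberModel,
    enzyme: RecruitedSpecies,
    inhibitor: RecruitedSpecies,
    model: InhibitionModel,
    apply_occupancy_to_inhibitor: bool = True,
) -> TitrationDataset:
    """Noiseless model titration: activity at each inhibitor concentration.

    ``inhibitor.protein_total`` is replaced point-by-point by the grid
    values; recruiter totals stay fixed.  Output preserves the input order
    and is monotone non-increasing in inhibitor concentration.
    """
    concs = np.asarray(list(inhibitor_concs), dtype=float)
    activities = np.array(
        [
            normalized_activity(
                composition,
                fiber,
                enzyme,
                replace(inhibitor, protein_total=float(c)),
                model,
                apply_occupancy_to_inhibitor,
            )
            for c in concs
        ]
    )
    return TitrationDataset(
        inhibitor_conc=concs,
        activity=activities,
        sd=np.zeros_like(concs),
        n_replicates=np.ones(len(concs), dtype=int),
    )


def density_scan(
    densities: Sequence[float],
    fixed_btadna: float,
    fiber: FiberModel,
    enzyme: RecruitedSpecies,
    inhibitor: RecruitedSpecies,
    model: InhibitionModel,
    apply_occupancy_to_inhibitor: bool = True,
) -> pd.DataFrame:
    """Predicted activity as the receptor density is diluted with inert BTA.

    The BTA-DNA concentration stays fixed (so the hybridization equilibria,
    hence ``f_E``, are unchanged) while the total BTA grows as
    ``fixed_btadna / density``; the inhibitor's effective concentration is
    diluted proportionally and activity recovers once it falls near K_i.

    Returns a tidy frame with columns ``density``, ``total_bta_M``,
    ``ceff_inhibitor_M``, ``theta``, ``f_E``, ``activity``.
    """
    if not (fixed_btadna > 0):
        raise ParameterError(f"fixed BTA-DNA must be > 0, got {fixed_btadna}")
    rows = []
    for d in densities:
        if not (0 < d <= 1):
            raise ParameterError(f"density must be in (0, 1], got {d}")
        comp = AssemblyComposition(
            conc_btadna=fixed_btadna, conc_bta3oh=fixed_btadna / d - fixed_btadna
        )
        activity, details = normalized_activity(
            comp,
            fiber,
            enzyme,
            inhibitor,
            model,
            apply_occupancy_to_inhibitor,
            return_details=True,
        )
        rows.append(
            {
                "density": d,
                "total_bta_M": comp.total,
                "ceff_inhibitor_M": details["ceff_inhibitor"],
                "theta": details["theta"],
                "f_E": details["f_E"],
                "activity": activity,
            }
        )
    return pd.DataFrame(rows)


def displacement_cycle(
    steps: Iterable[tuple[str, float]],
    composition: AssemblyComposition,
    fiber: FiberModel,
    enzyme: RecruitedSpecies,
    inhibitor: RecruitedSpecies,
    model: InhibitionModel,
    apply_occupancy_to_inhibitor: bool = True,
) -> pd.DataFrame:
    """Activity along a sequence of recruiter / displacer additions.

    ``steps`` is a sequence of ``("recruiter", amount)`` or
    ``("displacer", amount)`` additions (mol/L each) of the toehold-bearing
    enzyme recruiter and its fully complementary displacer.  Totals are
    cumulative; at every stage the effective recruiter is the stoichiometric
    excess ``max(0, recruiter - displacer)`` and the activity is recomputed
    at the resulting equilibrium.  Row 0 is the pre-addition baseline.

    In this idealised model full displacement restores the activity to the
    exact pre-recruitment value, and cycles repeat identically.
    """
    if not enzyme.has_toehold:
        raise ParameterError(
            "displacement cycling requires a toehold-bearing enzyme recruiter"
        )
    cum_recruiter = enzyme.recruiter_total
    cum_displacer = 0.0

    def current_activity() -> float:
        stage = apply_displacement(
            replace(enzyme, recruiter_total=cum_recruiter), cum_displacer
        )
        return normalized_activity(
            composition, fiber, stage, inhibitor, model, apply_occupancy_to_inhibitor
        )

    rows = [
        {
            "step": 0,
            "strand": "initial",
            "added_M": 0.0,
            "recruiter_total_M": cum_recruiter,
            "displacer_total_M": cum_displacer,
            "activity": current_activity(),
        }
    ]
    for i, (strand, amount) in enumerate(steps, start=1):
        if amount < 0:
            raise ParameterError(f"step {i}: addition must be >= 0, got {amount}")
        if strand == "recruiter":
            cum_recruiter += amount
        elif strand == "displacer":
            cum_displacer += amount
        else:
            raise ParameterError(
                f"step {i}: strand must be 'recruiter' or 'displacer', got {strand!r}"
            )
        rows.append(
            {
                "step": i,
                "strand": strand,
                "added_M": amount,
                "recruiter_total_M": cum_recruiter,
                "displacer_total_M": cum_displacer,
                "activity": current_activity(),
            }
        )
    return pd.DataFrame(rows)
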