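"""Equilibria of recruiter strands on the shared scaffold handle pool.

Each recruited protein is attached to the fiber by a recruiter
oligonucleotide that forms a 10-bp duplex with the single-stranded DNA
handle displayed by BTA-DNA monomers.  All recruiters compete for the same
pool of handles, so the bound amounts are coupled through the free-handle
concentration ``x``:

    bound_i = R_i * x / (K_i + x),      (independent-site isotherm)
    handle_total = x + sum_i bound_i,   (handle conservation)

where ``R_i`` is the total concentration of recruiter ``i`` and ``K_i`` the
dissociation constant of its handle duplex.  The conservation equation is
strictly monotone in ``x`` on [0, handle_total], so it is solved by plain
bisection with guaranteed convergence.

The 21-nt protein-recruiter duplex is treated as fully formed (its K_d is
far below the nanomolar working concentrations); only the short scaffold
attachment is an equilibrium, so the scaffold-bound fraction of a protein
equals that of its recruiter.  Toehold-bearing recruiters can be removed by
a fully complementary displacer strand; the resulting closed duplex is
thermodynamically dominant over the nicked 10-bp attachment, so displacement
is modelled stoichiometrically.

The default handle-recruiter K_d (0.162 uM) is calibrated so that 0.5 uM
handles and 20 nM recruiter leave 25% of the recruiter — and hence of the
enzyme — free in solution.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Sequence

from .errors import ConvergenceError, ParameterError

#: Default dissociation constant of the 10-bp handle-recruiter duplex
#: (mol/L), calibrated to a 75% bound fraction at 0.5 uM handle / 20 nM
#: recruiter.
DEFAULT_DUPLEX_KD = 0.162e-6

_BISECTION_TOL = 0.0  # bisect to float convergence (cap bounds the work)
_BISECTION_MAX_ITER = 200


@dataclass(frozen=True)
class RecruitedSpecies:
    """One protein-recruiter pair competing for scaffold handles.

    Parameters
    ----------
    name :
        Label used to key per-species results (e.g. ``"enzyme"``).
    recruiter_total :
        Total recruiter strand concentration (mol/L).
    protein_total :
        Total concentration of the DNA-conjugated protein (mol/L).  Must not
        exceed ``recruiter_total`` for the scaffold-fraction mapping to hold.
    duplex_kd :
        Dissociation constant of the handle-recruiter duplex (mol/L).
    has_toehold :
        Whether the recruiter carries a single-stranded toehold overhang and
        can therefore be removed by a displacer strand.
    """

    name: str
    recruiter_total: float
    protein_total: float = 0.0
    duplex_kd: float = DEFAULT_DUPLEX_KD
    has_toehold: bool = False

    def __post_init__(self) -> None:
        if self.recruiter_total < 0 or self.protein_total < 0:
            raise ParameterError(
                f"species {self.name!r}: concentrations must be >= 0"
            )
        if not (self.duplex_kd > 0):
            raise ParameterError(
                f"species {self.name!r}: duplex K_d must be > 0, got {self.duplex_kd}"
            )


@dataclass(frozen=True)
class SpeciesEquilibrium:
    """Solved partitioning of one recruiter between fiber and solution."""

    bound_recruiter: float
    free_recruiter: float
    scaffold_fraction: float


@dataclass(frozen=True)
class EquilibriumState:
    """Joint equilibrium of all recruiters on the shared handle pool.

    ``species`` maps each species name to its
    :class:`SpeciesEquilibrium`.  ``notes`` records degenerate cases, e.g.
    a zero-recruiter species whose scaffold fraction is reported as the
    dilute limit ``x / (K_d + x)``.
    """

    handle_total: float
    free_handle: float
    species: Mapping[str, SpeciesEquilibrium]
    notes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", MappingProxyType(dict(self.species)))

    @property
    def bound_handle(self) -> float:
        return sum(s.bound_recruiter for s in self.species.values())


def _isotherm(recruiter_total: float, kd: float, free_handle: float) -> float:
    return recruiter_total * free_handle / (kd + free_handle)


def solve_competition(
    handle_total: float,
    species: Sequence[RecruitedSpecies],
    *,
    tol: float = _BISECTION_TOL,
    max_iter: int = _BISECTION_MAX_ITER,
) -> EquilibriumState:
    """Solve the coupled handle-recruiter equilibria for all species.

    Bisects the monotone handle-conservation residual
    ``x + sum_i R_i x/(K_i + x) - handle_total`` for the free-handle
    concentration ``x`` on ``[0, handle_total]``, then evaluates every
    species' isotherm at the root.

    Raises
    ------
    ConvergenceError
        If the residual at the returned root is not small relative to
        ``handle_total`` (cannot happen for valid inputs within the default
        iteration cap; kept as a hard guarantee).
    """
    if not (handle_total > 0):
        raise ParameterError(f"handle_total must be > 0, got {handle_total}")
    if len(species) == 0:
        raise ParameterError("at least one species is required")
    names = [s.name for s in species]
    if len(set(names)) != len(names):
        raise ParameterError(f"species names must be unique, got {names}")

    def residual(x: float) -> float:
        return (
            x
            + sum(_isotherm(s.recruiter_total, s.duplex_kd, x) for s in species)
            - handle_total
        )

    lo, hi = 0.0, handle_total
    x = 0.5 * (lo + hi)
    for _ in range(max_iter):
        x = 0.5 * (lo + hi)
        if x <= lo or x >= hi:  # interval collapsed to adjacent floats
            break
        if residual(x) > 0:
            hi = x
        else:
            lo = x
        if hi - lo <= tol:
            break
    x = 0.5 * (lo + hi)

    if abs(residual(x)) > 1e-9 * handle_total:
        raise ConvergenceError(
            "handle-conservation bisection did not converge",
            residual=abs(residual(x)),
        )

    notes: list[str] = []
    per_species: dict[str, SpeciesEquilibrium] = {}
    for s in species:
        bound = _isotherm(s.recruiter_total, s.duplex_kd, x)
        if s.recruiter_total > 0:
            fraction = bound / s.recruiter_total
        else:
            # dilute-tracer limit of the isotherm
            fraction = x / (s.duplex_kd + x)
            notes.append(
                f"{s.name}: zero recruiter; scaffold_fraction is the dilute limit"
            )
        per_species[s.name] = SpeciesEquilibrium(
            bound_recruiter=bound,
            free_recruiter=s.recruiter_total - bound,
            scaffold_fraction=fraction,
        )
    return EquilibriumState(
        handle_total=handle_total,
        free_handle=x,
        species=per_species,
        notes=tuple(notes),
    )


def duplex_fraction_bound(
    handle_total: float, recruiter_total: float, kd: float
) -> tuple[float, EquilibriumState]:
    """Exact bimolecular equilibrium of one recruiter on the handle pool.

    Uses the numerically stable root of the binding quadratic,

        bound = 2 H R / (b + sqrt(b**2 - 4 H R)),   b = H + R + K_d,

    and returns ``(bound / recruiter_total, state)``.  As
    ``recruiter_total -> 0`` the fraction tends to the dilute limit
    ``H / (K_d + H)``, which is returned (and flagged in the state) when the
    recruiter concentration is exactly zero.
    """
    if handle_total < 0 or recruiter_total < 0:
        raise ParameterError("handle and recruiter concentrations must be >= 0")
    if not (kd > 0):
        raise ParameterError(f"duplex K_d must be > 0, got {kd}")

    notes: tuple[str, ...] = ()
    if recruiter_total == 0:
        fraction = handle_total / (kd + handle_total)
        bound = 0.0
        free_handle = handle_total
        notes = ("zero recruiter; fraction is the dilute limit H/(Kd+H)",)
    else:
        b = handle_total + recruiter_total + kd
        disc = b * b - 4.0 * handle_total * recruiter_total
        bound = 2.0 * handle_total * recruiter_total / (b + disc**0.5)
        fraction = bound / recruiter_total
        free_handle = handle_total - bound

    state = EquilibriumState(
        handle_total=handle_total,
        free_handle=free_handle,
        species={
            "species": SpeciesEquilibrium(
                bound_recruiter=bound,
                free_recruiter=recruiter_total - bound,
                scaffold_fraction=fraction,
            )
        },
        notes=notes,
    )
    return fraction, state


def apply_displacement(
    species: RecruitedSpecies, displacer_total: float
) -> RecruitedSpecies:
    """Remove recruiter stoichiometrically with a fully complementary strand.

    The closed recruiter-displacer duplex out-competes the nicked scaffold
    attachment essentially completely, so each displacer strand sequesters
    one recruiter: the effective recruiter total becomes
    ``max(0, recruiter_total - displacer_total)``.
    """
    if not species.has_toehold:
        raise ParameterError(
            f"species {species.name!r} has no toehold: displacement is not possible"
        )
    if displacer_total < 0:
        raise ParameterError(
            f"displacer concentration must be >= 0, got {displacer_total}"
        )
    remaining = max(0.0, species.recruiter_total - displacer_total)
    return dataclasses.replace(species, recruiter_total=remaining)


def protein_scaffold_fraction(
    species: RecruitedSpecies, state: EquilibriumState
) -> float:
    """Fraction of the protein residing on the scaffold.

    The long protein-recruiter duplex is treated as fully formed, so the
    protein follows its recruiter: the scaffold-bound protein fraction
    equals the recruiter's bound fraction, provided the protein does not
    outnumber the recruiter.  A fully displaced recruiter (total zero)
    leaves all protein in solution, fraction 0.
    """
    if species.recruiter_total == 0:
        return 0.0
    if species.protein_total > species.recruiter_total:
        raise ParameterError(
            f"species {species.name!r}: protein_total exceeds recruiter_total; "
            "the protein-limited regime is the only one modelled"
        )
    if species.name not in state.species:
        raise ParameterError(
            f"species {species.name!r} not present in the equilibrium state"
        )
    return state.species[species.name].scaffold_fraction
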