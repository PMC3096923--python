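"""Multi-ligand competitive binding to a single class of immobilized sites.

The binding system is a suspension of target-coated paramagnetic particles in a
buffer containing a mixture of ligands.  Every ligand ``i`` binds the same class
of sites with an association constant ``K_i`` (M^-1); at equilibrium mass action
gives, in concentrations,

    bound_i = K_i * S_free * C_i / (1 + K_i * S_free)

where ``C_i`` is the ligand's total concentration and ``S_free`` the free-site
concentration.  ``S_free`` is the unique root of the site-conservation closure

    S_tot = S_free + sum_i K_i * S_free * C_i / (1 + K_i * S_free)

(all terms in mol/L).  The left side minus the right is strictly decreasing in
``S_free``... strictly, the right side is strictly increasing, so bisection on
``[0, S_tot]`` always brackets the root; a Newton polish then takes it to
machine precision, which matters in the femtomolar-K (tight-binding) regime
where the root can be twenty orders of magnitude below ``S_tot``.

Units convention (used across the package): amounts in pmol, suspension and
extract volumes in uL, system volumes in mL, concentrations in mol/L.
Conversion happens once, at type construction or in the solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "LigandSpecies",
    "TargetPreparation",
    "BindingSystem",
    "EquilibriumState",
    "solve_equilibrium",
    "single_ligand_closed_form",
]

#: pmol per mol
_PMOL = 1e12

ROLES = ("candidate", "reference", "nonspecific")


class ValidationError(ValueError):
    """Raised when a binding system or ligand fails its invariants."""


class SolverError(RuntimeError):
    """Raised when the free-site root cannot be bracketed."""


@dataclass(frozen=True)
class LigandSpecies:
    """One chemical species in the binding system.

    Parameters
    ----------
    id : str
        Short unique label, e.g. ``"BCHA"``.
    role : str
        ``"candidate"``, ``"reference"`` or ``"nonspecific"``.
    K : float
        Association equilibrium constant in M^-1 (simulation truth).
    total_conc : float
        Total molar concentration in the binding system (mol/L).
    mz : int, optional
        m/z channel for selected-ion-monitoring detection (metadata).
    nonspecific_fraction : float
        Fraction of the total bound independently of site occupancy
        (survives target denaturation; models weak matrix adsorption).
    """

    id: str
    role: str = "candidate"
    K: float = 1.0
    total_conc: float = 0.0
    mz: int | None = None
    nonspecific_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r} for ligand {self.id!r}")
        if not (np.isfinite(self.K) and self.K > 0):
            raise ValidationError(f"K must be finite and > 0 for ligand {self.id!r}")
        if not (np.isfinite(self.total_conc) and self.total_conc >= 0):
            raise ValidationError(f"total_conc must be >= 0 for ligand {self.id!r}")
        if not 0.0 <= self.nonspecific_fraction < 1.0:
            raise ValidationError(f"nonspecific_fraction must be in [0, 1) for {self.id!r}")


@dataclass(frozen=True)
class TargetPreparation:
    """A portion of target-particle suspension.

    ``suspension_volume`` in uL, ``site_density`` in pmol binding sites per uL
    of suspension.  A denatured target binds nothing specifically.
    """

    suspension_volume: float
    site_density: float
    denatured: bool = False

    def __post_init__(self) -> None:
        if self.suspension_volume < 0 or self.site_density < 0:
            raise ValidationError("suspension_volume and site_density must be >= 0")

    @property
    def total_sites(self) -> float:
        """Total binding sites in pmol."""
        return self.suspension_volume * self.site_density


@dataclass(frozen=True)
class BindingSystem:
    """A competitive binding system: target suspension plus ligand mixture.

    ``volume`` in mL.  Ligand ids must be unique.
    """

    volume: float
    target: TargetPreparation
    ligands: tuple[LigandSpecies, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ligands", tuple(self.ligands))
        if not (np.isfinite(self.volume) and self.volume > 0):
            raise ValidationError("system volume must be finite and > 0")
        ids = [lig.id for lig in self.ligands]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate ligand ids in system: {ids}")

    @property
    def total_sites(self) -> float:
        return self.target.total_sites

    def ligand(self, ligand_id: str) -> LigandSpecies:
        for lig in self.ligands:
            if lig.id == ligand_id:
                return lig
        raise KeyError(ligand_id)

    def total_amount(self, ligand_id: str) -> float:
        """Total amount of a ligand in pmol."""
        lig = self.ligand(ligand_id)
        return lig.total_conc * self.volume * 1e-3 * _PMOL


@dataclass(frozen=True)
class EquilibriumState:
    """Solution of the binding closure for one system.

    ``bound``/``free`` are per-ligand amounts in pmol, ``BR`` the binding
    ratios (bound/total, dimensionless), ``free_site_conc`` in mol/L and
    ``N_FS`` the unoccupied sites in pmol.
    """

    free_site_conc: float
    bound: dict[str, float]
    free: dict[str, float]
    BR: dict[str, float]
    N_FS: float
    #: site-consuming part of ``bound`` (excludes occupancy-independent
    #: nonspecific binding); sum(bound_specific) + N_FS = total sites
    bound_specific: dict[str, float] = None


def _site_closure(s: float, K: np.ndarray, C: np.ndarray) -> float:
    return s + float(np.sum(K * s * C / (1.0 + K * s)))


def solve_equilibrium(system: BindingSystem, rel_tol: float = 1e-10) -> EquilibriumState:
    """Solve the competitive binding equilibrium of a system.

    Parameters
    ----------
    system : BindingSystem
    rel_tol : float
        Relative tolerance on the site-conservation residual, in (0, 1e-3].

    Returns
    -------
    EquilibriumState
        Per-ligand bound/free amounts (pmol), binding ratios, free sites.

    Notes
    -----
    A denatured target yields zero specific binding for every ligand; any
    ligand with a ``nonspecific_fraction`` keeps that fraction bound
    regardless of site occupancy (and regardless of denaturation).
    """
    if not (0 < rel_tol <= 1e-3):
        raise ValidationError("rel_tol must be in (0, 1e-3]")
    vol_l = system.volume * 1e-3
    s_tot = system.total_sites / _PMOL / vol_l  # mol/L

    ids = [lig.id for lig in system.ligands]
    K = np.array([lig.K for lig in system.ligands], dtype=float)
    C = np.array([lig.total_conc for lig in system.ligands], dtype=float)
    fns = np.array([lig.nonspecific_fraction for lig in system.ligands], dtype=float)
    totals = C * vol_l * _PMOL  # pmol

    if system.target.denatured or s_tot == 0.0 or len(ids) == 0:
        s_free = 0.0 if system.target.denatured else s_tot
        bound_specific = np.zeros_like(C)
    else:
        s_free = _solve_free_sites(s_tot, K, C, rel_tol)
        bound_specific = K * s_free * C / (1.0 + K * s_free) * vol_l * _PMOL

    bound = bound_specific + fns * totals
    bound = np.minimum(bound, totals)
    free = totals - bound
    with np.errstate(invalid="ignore", divide="ignore"):
        br = np.where(totals > 0, bound / np.where(totals > 0, totals, 1.0), 0.0)
    n_fs = s_free * vol_l * _PMOL if not system.target.denatured else system.total_sites

    return EquilibriumState(
        free_site_conc=float(s_free),
        bound=dict(zip(ids, map(float, bound))),
        free=dict(zip(ids, map(float, free))),
        BR=dict(zip(ids, map(float, br))),
        N_FS=float(n_fs),
        bound_specific=dict(zip(ids, map(float, bound_specific))),
    )


def _solve_free_sites(s_tot: float, K: np.ndarray, C: np.ndarray, rel_tol: float) -> float:
    """Root of the site closure on [0, s_tot], robust in the stiff regime."""

    def f(s: float) -> float:
        return _site_closure(s, K, C) - s_tot

    if f(s_tot) <= 0:  # no ligand consumes sites
        return s_tot

    lo, hi = 0.0, s_tot
    # In the tight-binding regime (K*s_tot >> 1) the root can sit many decades
    # below s_tot; pre-bracket on a log grid so brentq converges quickly.
    if np.max(K) * s_tot > 1e6:
        grid = s_tot * np.logspace(-40.0, 0.0, 161)
        vals = np.array([f(s) for s in grid])
        idx = np.searchsorted(vals > 0, True)
        if idx == 0:
            return float(grid[0])  # root below grid floor; free sites ~ 0
        lo, hi = float(grid[idx - 1]), float(grid[idx])

    try:
        root = brentq(f, lo, hi, xtol=max(lo * 1e-15, 1e-280), rtol=8.9e-16, maxiter=300)
    except ValueError as exc:  # pragma: no cover - defensive
        raise SolverError(f"failed to bracket free sites in [{lo}, {hi}]: {exc}") from None

    # Newton polish: f'(s) = 1 + sum K*C/(1+K*s)^2, strictly positive.
    s = float(root)
    for _ in range(4):
        fp = 1.0 + float(np.sum(K * C / (1.0 + K * s) ** 2))
        step = f(s) / fp
        s_new = s - step
        if s_new <= 0:
            break
        s = s_new
        if abs(step) <= abs(s) * 1e-16:
            break

    if abs(f(s)) > rel_tol * s_tot:
        raise SolverError(
            f"site conservation residual {abs(f(s)):.3e} exceeds rel_tol*{s_tot:.3e}"
        )
    return s


def single_ligand_closed_form(K: float, total_conc: float, sites: float, volume: float) -> float:
    """Bound amount (pmol) for one ligand, via the binding quadratic.

    Oracle for the iterative solver.  With ``L`` and ``S`` the total ligand
    and site concentrations and ``Kd = 1/K``, the bound concentration is the
    physical root of ``x**2 - (L + S + Kd) x + L S = 0``, evaluated in the
    numerically stable form ``x = 2 L S / (b + sqrt(b^2 - 4 L S))`` with
    ``b = L + S + Kd`` (avoids catastrophic cancellation in the tight-binding
    limit, where ``x -> min(L, S)``).

    Parameters
    ----------
    K : float
        Association constant, M^-1.
    total_conc : float
        Total ligand concentration, mol/L.
    sites : float
        Total sites, pmol.
    volume : float
        System volume, mL.
    """
    if not (np.isfinite(K) and K > 0):
        raise ValidationError("K must be finite and > 0")
    if total_conc < 0 or sites < 0 or volume <= 0:
        raise ValidationError("non-negative concentrations/sites and positive volume required")
    vol_l = volume * 1e-3
    L = total_conc
    S = sites / _PMOL / vol_l
    if L == 0.0 or S == 0.0:
        return 0.0
    kd = 1.0 / K
    b = L + S + kd
    disc = b * b - 4.0 * L * S
    x = 2.0 * L * S / (b + math.sqrt(max(disc, 0.0)))
    return x * vol_l * _PMOL
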