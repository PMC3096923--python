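"""Synthetic screening scenarios emulating the biotin/streptavidin model
system.

Everything the estimators and planners consume - mixtures, true affinities,
calibrations, peak tables - can be generated here with a sealed ground truth,
so the whole pipeline is testable without any instrument data.

The emulated system: biotin-derivative candidate ligands competing with an
exogenous biotinylated reference for the biotin sites of streptavidin-coated
paramagnetic particles.  Binding is femtomolar-Kd tight (dissociation
constants below 200 fM); the reference is assigned K_d = 100 fM and candidate
constants scale by their true relative affinities.  LC-MS responses are
linear with nonzero intercepts spanning a ~17-fold slope range; recovery
ratios sit in 0.4-1.0.

Mixture preparation modes:

* ``pooled``   - exact molar fractions (pooling of individual compounds);
* ``pcs_single`` - one candidate of interest from a parallel combinatorial
  synthesis, with approximate content (default 50% by convention);
* ``spsag``    - simultaneous addition of groups: candidate fractions track
  the input amine fractions, perturbed by a per-amine yield jitter
  (log-normal, CV 15% by default), plus optional nonspecific by-products.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .equilibrium import (
    BindingSystem,
    LigandSpecies,
    TargetPreparation,
    solve_equilibrium,
)
from .measurement import (
    LinearResponse,
    PeakTable,
    ProcessingProtocol,
    RecoveryProfile,
    save_calibrations,
    simulate_peak_table,
)

__all__ = [
    "MixtureSpec",
    "PMFSSpec",
    "ScenarioTruth",
    "make_spsag_mixture",
    "make_pooled_mixture",
    "make_pcs_single_mixture",
    "table_fixtures",
    "TableFixtures",
    "generate_scenario",
    "write_scenario_bundle",
    "REFERENCE_KD_M",
]

#: reference-ligand dissociation constant used for simulation truths (100 fM,
#: within the sub-200-fM regime of the model system)
REFERENCE_KD_M = 1e-13

PREPARATIONS = ("pooled", "pcs_single", "spsag")


@dataclass(frozen=True)
class MixtureSpec:
    """Composition of one mixture sample.

    ``components`` maps ligand id -> (molar fraction, role); fractions sum
    to 1.  ``nominal_total_content`` is the mass fraction of ligands of
    interest in the dry mixture (metadata for content-based planning).
    """

    components: dict[str, tuple[float, str]]
    preparation: str = "pooled"
    nominal_total_content: float = 1.0

    def __post_init__(self) -> None:
        if self.preparation not in PREPARATIONS:
            raise ValueError(f"preparation must be one of {PREPARATIONS}")
        total = sum(frac for frac, _ in self.components.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"molar fractions must sum to 1, got {total}")
        if self.preparation == "pcs_single":
            n_cand = sum(1 for _, role in self.components.values() if role == "candidate")
            if n_cand != 1:
                raise ValueError("pcs_single mixtures have exactly one candidate of interest")

    def fraction(self, ligand_id: str) -> float:
        return self.components[ligand_id][0]

    def candidates(self) -> list[str]:
        return [lid for lid, (_, role) in self.components.items() if role == "candidate"]


@dataclass(frozen=True)
class PMFSSpec:
    """A processed-mixture-for-screening: mixture plus spiked reference.

    ``total_candidate_conc`` is the expected total molar concentration of
    the mixture's candidates in the binding system (mol/L) and
    ``reference_conc_system`` the reference concentration there; the PMFS
    itself is more concentrated by system_volume/pmfs_volume (the reference
    stock convention is 200 uM in the PMFS for a 2.0 mL system).
    """

    mixture: MixtureSpec
    reference_id: str
    total_candidate_conc: float
    reference_conc_system: float
    pmfs_volume: float = 40.0

    def __post_init__(self) -> None:
        if self.reference_id in self.mixture.components:
            raise ValueError("the reference ligand must not be a member of the mixture")
        if self.total_candidate_conc < 0 or self.reference_conc_system <= 0:
            raise ValueError("concentrations must be positive")


@dataclass(frozen=True)
class ScenarioTruth:
    """Sealed simulation truth for one generated scenario."""

    true_ratios: dict[str, float]
    reference_K: float
    concentrations: dict[str, float]
    noise_cv: float
    seed: int
    site_density: float
    suspension_volume: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def make_pooled_mixture(fractions: dict[str, float], nonspecific: dict[str, float] | None = None,
                        nominal_total_content: float = 1.0) -> MixtureSpec:
    """Pooling of individual compounds: exact fractions, optional
    nonspecific members (all fractions together must sum to 1)."""
    comps = {lid: (frac, "candidate") for lid, frac in fractions.items()}
    for lid, frac in (nonspecific or {}).items():
        comps[lid] = (frac, "nonspecific")
    return MixtureSpec(components=comps, preparation="pooled",
                       nominal_total_content=nominal_total_content)


def make_pcs_single_mixture(candidate_id: str, content: float = 0.5,
                            secondary: dict[str, float] | None = None) -> MixtureSpec:
    """A single-candidate mixture from parallel combinatorial synthesis.

    ``content`` is the candidate's (approximate) fraction, by convention 50%
    unless calibrated; the remainder is secondary components whose affinity
    is never estimated."""
    secondary = dict(secondary or {})
    rest = 1.0 - content - sum(secondary.values())
    comps = {candidate_id: (content, "candidate")}
    for lid, frac in secondary.items():
        comps[lid] = (frac, "nonspecific")
    if rest > 1e-12:
        comps["secondary"] = (rest, "nonspecific")
    return MixtureSpec(components=comps, preparation="pcs_single",
                       nominal_total_content=content)


def make_spsag_mixture(
    amine_fractions: dict[str, float],
    yields: dict[str, float] | None = None,
    yield_jitter_cv: float = 0.0,
    rng: np.random.Generator | int | None = None,
    byproducts: dict[str, float] | None = None,
    nominal_total_content: float = 0.4,
) -> MixtureSpec:
    """Simultaneous-addition-of-groups mixture: candidate fractions track the
    input amine fractions times per-amine relative yields.

    ``amine_fractions`` maps candidate ligand id -> amine molar fraction
    (positive, summing to 1).  ``yields`` are relative acylation yields
    (default 1.0); ``yield_jitter_cv`` adds log-normal jitter to them,
    reproducing the deviations between nominal and realized molar ratios.
    ``byproducts`` adds nonspecific components as fractions *of the final
    mixture* (candidates are scaled down accordingly).
    """
    if not amine_fractions:
        raise ValueError("amine_fractions must not be empty")
    fracs = np.array(list(amine_fractions.values()), dtype=float)
    if np.any(fracs <= 0):
        raise ValueError("amine fractions must be positive")
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("amine fractions must sum to 1")
    ids = list(amine_fractions)
    y = np.array([(yields or {}).get(lid, 1.0) for lid in ids], dtype=float)
    if yield_jitter_cv > 0:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        sigma = np.sqrt(np.log1p(yield_jitter_cv**2))
        y = y * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(ids))
    eff = fracs * y
    eff = eff / eff.sum()

    byproducts = dict(byproducts or {})
    bp_total = sum(byproducts.values())
    if bp_total >= 1.0:
        raise ValueError("byproduct fractions must sum to < 1")
    comps = {lid: (float(f * (1.0 - bp_total)), "candidate") for lid, f in zip(ids, eff)}
    for lid, frac in byproducts.items():
        comps[lid] = (frac, "nonspecific")
    return MixtureSpec(components=comps, preparation="spsag",
                       nominal_total_content=nominal_total_content)


# --------------------------------------------------------------------------
# Calibrations and affinity truths of the biotin model system
# --------------------------------------------------------------------------

_SINGLE_CANDIDATE_CALIBRATIONS: dict[str, tuple[float, float, float, float, int]] = {
    # ligand: slope, intercept, RR, r2, mz   (linear_upper 30 pmol throughout)
    "BCHA": (862.1, 322.1, 0.47, 0.998, 326),
    "BMPL": (279.8, 143.4, 1.00, 0.998, 314),
    "BDETA": (116.9, 59.9, 0.57, 0.994, 332),
    "BME": (49.2, 24.2, 0.82, 0.992, 259),
}

# Multi-ligand set: published only qualitatively (BBZA intercept below zero,
# BNEDA the lowest slope of the five, BCHA comparable to BDEDA and higher than
# the rest).  The numbers below are synthetic, chosen to satisfy those
# orderings at the same scale as the single-candidate set.
_MULTI_CANDIDATE_CALIBRATIONS: dict[str, tuple[float, float, float, float, int]] = {
    "BCHA": (862.1, 322.1, 0.47, 0.998, 326),
    "BDEDA": (820.0, 290.0, 0.62, 0.997, 584),
    "BBZA": (420.0, -55.0, 0.55, 0.996, 348),
    "BNEDA": (150.0, 48.0, 0.45, 0.995, 427),
    "BPDEDA": (510.0, 170.0, 0.70, 0.997, 731),
}

#: relative affinities vs the single-candidate reference (homogeneous-assay
#: values used as simulation truths)
TRUE_RATIOS_BMPL: dict[str, float] = {"BCHA": 3.68, "BME": 1.90, "BDETA": 0.45}

#: relative affinities vs the multi-candidate reference
TRUE_RATIOS_BPDEDA: dict[str, float] = {"BDEDA": 1.3, "BBZA": 0.6, "BCHA": 1.3, "BNEDA": 2.0}


@dataclass(frozen=True)
class TableFixtures:
    """Calibrations and affinity truths of the biotin model system."""

    responses: dict[str, LinearResponse]
    recovery: RecoveryProfile
    mz: dict[str, int]
    true_ratios_bmpl: dict[str, float] = field(default_factory=lambda: dict(TRUE_RATIOS_BMPL))
    true_ratios_bpdeda: dict[str, float] = field(
        default_factory=lambda: dict(TRUE_RATIOS_BPDEDA)
    )

    def response(self, ligand_id: str) -> LinearResponse:
        return self.responses[ligand_id]

    def truth(self, ligand_id: str, scale: str = "BMPL") -> float:
        table = self.true_ratios_bmpl if scale == "BMPL" else self.true_ratios_bpdeda
        return table[ligand_id]


def table_fixtures(which: str = "single") -> TableFixtures:
    """Calibration parameters and simulation truths.

    ``which='single'`` returns the published single-candidate set (BCHA,
    BMPL, BDETA, BME); ``'multi'`` the five-ligand set around the BPDEDA
    reference (synthetic calibrations consistent with the published
    orderings); ``'all'`` merges both.
    """
    if which == "single":
        raw = dict(_SINGLE_CANDIDATE_CALIBRATIONS)
    elif which == "multi":
        raw = dict(_MULTI_CANDIDATE_CALIBRATIONS)
    elif which == "all":
        raw = {**_MULTI_CANDIDATE_CALIBRATIONS, **_SINGLE_CANDIDATE_CALIBRATIONS}
    else:
        raise ValueError("which must be 'single', 'multi' or 'all'")
    responses = {
        lid: LinearResponse(slope=s, intercept=i, linear_upper=30.0, r_squared=r2)
        for lid, (s, i, rr, r2, mz) in raw.items()
    }
    recovery = RecoveryProfile(RR={lid: rr for lid, (_, _, rr, _, _) in raw.items()})
    mz = {lid: m for lid, (_, _, _, _, m) in raw.items()}
    return TableFixtures(responses=responses, recovery=recovery, mz=mz)


# --------------------------------------------------------------------------
# Scenario generation
# --------------------------------------------------------------------------


def _default_geometry(multi: bool) -> tuple[float, TargetPreparation]:
    """Standard system geometry: 2.0 mL with 50 uL suspension for
    single-candidate work, 4.0 mL with 200 uL for multi-ligand work; site
    density 4.2 pmol/uL (the titrated capacity)."""
    if multi:
        return 4.0, TargetPreparation(suspension_volume=200.0, site_density=4.2)
    return 2.0, TargetPreparation(suspension_volume=50.0, site_density=4.2)


def build_binding_system(
    spec: PMFSSpec,
    truth_ratios: dict[str, float],
    system_volume: float,
    target: TargetPreparation,
    reference_K: float = 1.0 / REFERENCE_KD_M,
    nonspecific_K: float = 1e6,
    nonspecific_fraction: float = 0.02,
    mz: dict[str, int] | None = None,
) -> BindingSystem:
    """Assemble a binding system from a PMFS specification and truths.

    Candidate concentrations split ``total_candidate_conc`` by the mixture's
    molar fractions (renormalized over candidates); nonspecific members get a
    tiny association constant plus a small occupancy-independent bound
    fraction (so they survive a denatured-target control unchanged).
    """
    mz = mz or {}
    cand_ids = spec.mixture.candidates()
    cand_total_frac = sum(spec.mixture.fraction(lid) for lid in cand_ids)
    ligands = [
        LigandSpecies(
            id=spec.reference_id,
            role="reference",
            K=reference_K,
            total_conc=spec.reference_conc_system,
            mz=mz.get(spec.reference_id),
        )
    ]
    for lid, (frac, role) in spec.mixture.components.items():
        if role == "candidate":
            conc = spec.total_candidate_conc * frac / cand_total_frac
            K = reference_K * truth_ratios[lid]
            ligands.append(
                LigandSpecies(id=lid, role="candidate", K=K, total_conc=conc, mz=mz.get(lid))
            )
        else:
            conc = spec.total_candidate_conc * frac / max(cand_total_frac, 1e-300)
            ligands.append(
                LigandSpecies(
                    id=lid,
                    role="nonspecific",
                    K=nonspecific_K,
                    total_conc=conc,
                    mz=mz.get(lid),
                    nonspecific_fraction=nonspecific_fraction,
                )
            )
    return BindingSystem(volume=system_volume, target=target, ligands=tuple(ligands))


def generate_scenario(
    spec: PMFSSpec,
    seed: int,
    truth_ratios: dict[str, float] | None = None,
    fixtures: TableFixtures | None = None,
    system_volume: float | None = None,
    target: TargetPreparation | None = None,
    protocol: ProcessingProtocol | None = None,
    noise_cv: float = 0.10,
    duplicates: int = 2,
    reference_K: float = 1.0 / REFERENCE_KD_M,
) -> tuple[BindingSystem, ScenarioTruth, PeakTable]:
    """Generate one estimator-ready scenario: system, sealed truth, peaks.

    Deterministic given ``seed``.  Defaults emulate the model system: 40 uL
    PMFS into 2.0 mL (single candidate, 50 uL suspension) or 4.0 mL
    (multiple candidates, 200 uL suspension) at 4.2 pmol sites/uL, extract
    concentrated into 40 uL, 5 uL injections, duplicate analyses with 10%
    per-injection CV.
    """
    multi = len(spec.mixture.candidates()) > 1
    if fixtures is None:
        fixtures = table_fixtures("multi" if multi else "single")
    if truth_ratios is None:
        truth_ratios = fixtures.true_ratios_bpdeda if multi else fixtures.true_ratios_bmpl
    if system_volume is None or target is None:
        default_volume, default_target = _default_geometry(multi)
        system_volume = system_volume or default_volume
        target = target or default_target
    if protocol is None:
        protocol = ProcessingProtocol(
            system_volume=system_volume,
            extract_volume=40.0,
            injection_volume=5.0,
            pmfs_volume=spec.pmfs_volume,
        )

    system = build_binding_system(
        spec, truth_ratios, system_volume, target, reference_K=reference_K, mz=fixtures.mz
    )
    state = solve_equilibrium(system)
    rng = np.random.default_rng(seed)
    table = simulate_peak_table(
        state,
        system,
        protocol,
        fixtures.responses,
        fixtures.recovery,
        noise_cv=noise_cv,
        rng=rng,
        duplicates=duplicates,
    )
    truth = ScenarioTruth(
        true_ratios={lid: truth_ratios[lid] for lid in spec.mixture.candidates()},
        reference_K=reference_K,
        concentrations={lig.id: lig.total_conc for lig in system.ligands},
        noise_cv=noise_cv,
        seed=seed,
        site_density=target.site_density,
        suspension_volume=target.suspension_volume,
    )
    return system, truth, table


def write_scenario_bundle(
    directory,
    spec: PMFSSpec,
    seed: int,
    **kwargs,
) -> dict[str, Path]:
    """Generate a scenario and write its on-disk bundle.

    Layout: ``peaks.csv`` and ``calibrations.csv`` (estimator-facing) plus
    ``truth/truth.json`` (sealed, separate directory) and ``config.yaml``.
    """
    import yaml

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    multi = len(spec.mixture.candidates()) > 1
    fixtures = kwargs.pop("fixtures", None) or table_fixtures("multi" if multi else "single")
    system, truth, table = generate_scenario(spec, seed, fixtures=fixtures, **kwargs)

    paths = {
        "peaks": directory / "peaks.csv",
        "calibrations": directory / "calibrations.csv",
        "config": directory / "config.yaml",
        "truth": directory / "truth" / "truth.json",
    }
    table.to_csv(paths["peaks"])
    save_calibrations(paths["calibrations"], fixtures.responses, fixtures.recovery)
    config = {
        "reference_id": spec.reference_id,
        "protocol": {
            "system_volume": table.protocol.system_volume,
            "extract_volume": table.protocol.extract_volume,
            "injection_volume": table.protocol.injection_volume,
            "pmfs_volume": table.protocol.pmfs_volume,
        },
        "seed": seed,
        "peak_table": "peaks.csv",
        "calibrations": "calibrations.csv",
    }
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    paths["truth"].parent.mkdir(exist_ok=True)
    paths["truth"].write_text(truth.to_json())
    return paths
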