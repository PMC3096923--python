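"""Assay-design planners: target sizing and PMFS composition optimization.

Two ways to size the target (particle suspension):

* *parameter-dependent*: from each ligand's calibration alone, chain the
  minimum injected quantity that clears the five-times-intercept rule back
  through the extract, the recovery ratio and the site density to a minimum
  suspension volume; sum over same-site ligands and apply a safety factor.
* *experimental*: titrate the target volume, fit each ligand's extract area
  against it, and solve for the volume at which the area first clears the
  five-times-intercept threshold; the maximum over ligands is the optimized
  quantity.

Two ways to optimize the PMFS composition ratio:

* *fine*: escalate the candidate (or reference) concentration stepwise,
  compute the dilute-form estimate at every step without validity gating,
  and call the run stable once consecutive relative changes stay inside a
  plateau band while the prerequisites hold.
* *rough*: escalate exponentially (default 4-fold) and stop at the first
  composition whose prerequisites all hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import AffinityEstimate, RelativeAffinityModel
from .measurement import LinearResponse, PeakTable, ProcessingProtocol

__all__ = [
    "LigandPlanParams",
    "TargetSizing",
    "OptimizationTrajectory",
    "RoughOptimizationResult",
    "min_target_parameter_approach",
    "min_target_experimental",
    "fine_optimize",
    "rough_optimize",
    "choose_escalation_axis",
]


class PlanningError(ValueError):
    pass


@dataclass(frozen=True)
class LigandPlanParams:
    """Per-ligand inputs to the parameter-dependent sizing chain."""

    response: LinearResponse
    RR: float
    expected_content: float = 1.0

    def __post_init__(self) -> None:
        if self.RR <= 0:
            raise PlanningError("recovery ratio must be > 0")
        if not 0 < self.expected_content <= 1:
            raise PlanningError("expected_content must be in (0, 1]")


@dataclass(frozen=True)
class TargetSizing:
    """Output of the parameter-dependent sizing chain.

    Per-ligand columns (pmol / uL): minimum injected quantity, minimum
    quantity in the whole extract, minimum bound amount, minimum target
    suspension volume.  ``summed_min_target_volume`` adds the per-ligand
    volumes of all same-site ligands; ``practical_target_volume`` applies the
    safety factor.
    """

    per_ligand: pd.DataFrame
    summed_min_target_volume: float
    practical_target_volume: float
    safety_factor: float
    site_density: float
    rounding: str = "none"

    def report(self) -> str:
        lines = [
            f"Target sizing (site density {self.site_density} pmol/uL,"
            f" rounding policy {self.rounding!r})",
            self.per_ligand.to_string(float_format=lambda v: f"{v:.2f}"),
            f"summed minimum target volume: {self.summed_min_target_volume:.1f} uL",
            f"practical volume ({self.safety_factor:g}x safety): "
            f"{self.practical_target_volume:.1f} uL",
        ]
        return "\n".join(lines)


def _round_stage(value: float, decimals: int, policy: str) -> float:
    if policy == "table":
        # decimal half-up, as a printed table would round
        shift = 10.0**decimals
        return float(np.floor(value * shift + 0.5) / shift)
    return value


def min_target_parameter_approach(
    params: dict[str, LigandPlanParams],
    protocol: ProcessingProtocol,
    site_density: float = 4.0,
    intercept_floor: float = 0.5,
    safety_factor: float = 2.0,
    rounding: str = "none",
) -> TargetSizing:
    """Parameter-dependent minimum target quantity, per ligand and summed.

    Chain per ligand (positive intercept ``i``, slope ``s``):

    * ``q_inj  = 4 * i / s``  - the smallest injected quantity whose area
      ``s*q + i`` reaches ``5 * i``; when ``i <= 0`` every area clears the
      threshold and ``q_inj`` falls back to ``intercept_floor`` (pmol).
    * ``q_extract = q_inj * extract_volume / injection_volume``
    * ``q_bound   = q_extract / RR``
    * ``v_target  = q_bound / site_density``  (uL of suspension)

    ``rounding='table'`` rounds each stage half-up to one decimal before the
    next, emulating how a printed sizing table chains rounded cells;
    ``'none'`` carries full precision.
    """
    if site_density <= 0:
        raise PlanningError("site_density must be > 0")
    if rounding not in ("none", "table"):
        raise PlanningError("rounding must be 'none' or 'table'")
    rows = {}
    for lid, par in params.items():
        s = par.response.slope
        i = par.response.intercept
        if s <= 0:
            raise PlanningError(f"zero/negative slope for {lid}")
        q_inj = 4.0 * i / s if i > 0 else intercept_floor
        q_inj = _round_stage(q_inj, 1, rounding)
        q_extract = q_inj * protocol.extract_volume / protocol.injection_volume
        q_extract = _round_stage(q_extract, 1, rounding)
        q_bound = q_extract / par.RR
        q_bound = _round_stage(q_bound, 1, rounding)
        v_target = q_bound / site_density
        v_target = _round_stage(v_target, 1, rounding)
        rows[lid] = {
            "min_quantity_injected": q_inj,
            "min_quantity_extract": q_extract,
            "min_bound": q_bound,
            "min_target_volume": v_target,
        }
    frame = pd.DataFrame(rows).T
    summed = float(frame["min_target_volume"].sum())
    return TargetSizing(
        per_ligand=frame,
        summed_min_target_volume=summed,
        practical_target_volume=safety_factor * summed,
        safety_factor=safety_factor,
        site_density=site_density,
        rounding=rounding,
    )


@dataclass(frozen=True)
class ExperimentalSizing:
    """Per-ligand threshold target volumes from a titration series."""

    per_ligand_minimum: dict[str, float]
    optimized_volume: float
    unbracketed: tuple[str, ...] = ()
    at_lower_boundary: tuple[str, ...] = ()


def min_target_experimental(
    series: list[tuple[float, PeakTable]],
    responses: dict[str, LinearResponse],
    area_multiple: float = 5.0,
    extrapolate: bool = False,
) -> ExperimentalSizing:
    """Experimental minimum target volume per ligand, and the optimized
    (maximum) one.

    ``series`` pairs a target volume (any consistent unit, e.g. mL of
    suspension) with the resulting peak table.  Extract areas are fitted
    linearly against volume per ligand and the fit is solved for
    ``area = area_multiple * |intercept_of_response|``.
    """
    if len(series) < 3:
        raise PlanningError("need at least 3 target volumes spanning the threshold region")
    volumes = np.array([v for v, _ in series], dtype=float)
    if np.ptp(volumes) == 0:
        raise PlanningError("target volumes are all identical")

    ligands = [
        lid
        for lid in series[0][1].ligand_ids()
        if lid in responses and series[0][1].get(lid, "extract") is not None
    ]
    minima: dict[str, float] = {}
    unbracketed: list[str] = []
    boundary: list[str] = []
    for lid in ligands:
        areas = np.array([table.area(lid, "extract") for _, table in series])
        thresh = area_multiple * abs(responses[lid].intercept)
        fit = stats.linregress(volumes, areas)
        if fit.slope <= 0:
            raise PlanningError(f"extract area of {lid} does not grow with target volume")
        v_min = (thresh - fit.intercept) / fit.slope
        if areas.min() >= thresh:
            # already above threshold everywhere tested
            minima[lid] = float(volumes.min())
            boundary.append(lid)
            continue
        if v_min > volumes.max():
            if not extrapolate:
                raise PlanningError(
                    f"threshold for {lid} not bracketed by the tested volumes "
                    f"(predicted {v_min:.3g} > max {volumes.max():.3g})"
                )
            unbracketed.append(lid)
        minima[lid] = float(max(v_min, 0.0))
    return ExperimentalSizing(
        per_ligand_minimum=minima,
        optimized_volume=float(max(minima.values())),
        unbracketed=tuple(unbracketed),
        at_lower_boundary=tuple(boundary),
    )


@dataclass(frozen=True)
class OptimizationTrajectory:
    """A fine-optimization run: the dilute-form estimate at every step.

    ``stable_from`` is the first step index from which consecutive relative
    changes stay below the plateau tolerance for at least ``plateau_len``
    transitions while the prerequisites hold; ``stable_value`` averages the
    estimates from that step on.
    """

    steps: list[dict] = field(default_factory=list)
    stable_from: int | None = None
    stable_value: float | None = None
    plateau_rel_tol: float = 0.10
    plateau_len: int = 2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "composition": s["composition"],
                    "estimate": s["estimate"].ratio,
                    "valid": s["estimate"].valid,
                    "BR_X": s["estimate"].diagnostics["BR_X"],
                    "BR_A": s["estimate"].diagnostics["BR_A"],
                }
                for s in self.steps
            ]
        )

    def plot(self, ax=None):
        """Estimate and candidate binding ratio against composition
        (log-x).  Requires matplotlib."""
        import matplotlib.pyplot as plt

        frame = self.to_frame()
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(frame["composition"], frame["estimate"], "o-", label="K_X/K_A (dilute form)")
        ax.set_xscale("log")
        ax.set_xlabel("composition (candidate concentration scale)")
        ax.set_ylabel("relative affinity")
        if self.stable_value is not None:
            ax.axhline(self.stable_value, ls="--", color="grey", label="stable value")
        ax2 = ax.twinx()
        ax2.plot(frame["composition"], frame["BR_X"], "s--", color="C3", label="BR_X")
        ax2.set_ylabel("binding ratio")
        ax.legend(loc="best")
        return ax


def fine_optimize(
    feed,
    schedule,
    estimator_factory,
    plateau_rel_tol: float = 0.10,
    plateau_len: int = 2,
) -> OptimizationTrajectory:
    """Stepwise composition escalation with plateau detection.

    Parameters
    ----------
    feed : callable
        ``feed(composition) -> PeakTable`` for one composition value.
    schedule : sequence of float
        Strictly increasing composition values, at least 4.
    estimator_factory : callable
        ``estimator_factory(peak_table) -> RelativeAffinityModel`` bound to
        the pair of interest; the dilute-form estimate is computed at every
        step without validity gating.
    """
    schedule = list(schedule)
    if len(schedule) < 4:
        raise PlanningError("schedule must have at least 4 points")
    if any(b <= a for a, b in zip(schedule, schedule[1:])):
        raise PlanningError("schedule must be strictly increasing")

    steps: list[dict] = []
    for comp in schedule:
        table = feed(comp)
        model = estimator_factory(table)
        if len(model.candidate_ids) != 1:
            raise PlanningError("fine_optimize follows exactly one candidate")
        est = model.estimate_pair(model.candidate_ids[0], "eq6")
        steps.append({"composition": comp, "estimate": est})

    values = np.array([s["estimate"].ratio for s in steps])
    valid = np.array([s["estimate"].valid for s in steps])
    rel_change = np.abs(np.diff(values)) / np.abs(values[:-1])

    # a plateau is plateau_len consecutive steps (plateau_len - 1 transitions)
    # whose relative changes stay inside the band while prerequisites hold
    stable_from: int | None = None
    for i in range(len(steps) - plateau_len + 1):
        window = rel_change[i : i + plateau_len - 1]
        if np.all(window < plateau_rel_tol) and np.all(valid[i : i + plateau_len]):
            stable_from = i
            break
    stable_value = float(values[stable_from:].mean()) if stable_from is not None else None
    return OptimizationTrajectory(
        steps=steps,
        stable_from=stable_from,
        stable_value=stable_value,
        plateau_rel_tol=plateau_rel_tol,
        plateau_len=plateau_len,
    )


@dataclass(frozen=True)
class RoughOptimizationResult:
    """Outcome of an exponential-escalation search."""

    composition: float | None
    estimate: AffinityEstimate | None
    attempts: list[dict] = field(default_factory=list)

    @property
    def succeeded(self) -> bool:
        return self.composition is not None


def rough_optimize(
    feed,
    estimator_factory,
    initial_composition: float,
    escalation_factor: float = 4.0,
    max_steps: int = 5,
) -> RoughOptimizationResult:
    """Exponential composition escalation until the prerequisites hold.

    Returns the first composition whose prerequisite report is valid, with
    its estimate; on exhaustion, a failed result carrying every attempt's
    diagnostics.
    """
    if escalation_factor <= 1:
        raise PlanningError("escalation_factor must be > 1")
    if max_steps < 1:
        raise PlanningError("max_steps must be >= 1")
    comp = initial_composition
    attempts: list[dict] = []
    for _ in range(max_steps):
        table = feed(comp)
        model = estimator_factory(table)
        if len(model.candidate_ids) != 1:
            raise PlanningError("rough_optimize follows exactly one candidate")
        est = model.estimate_pair(model.candidate_ids[0], "eq6")
        attempts.append(
            {"composition": comp, "estimate": est, "failures": est.prerequisites.failures()}
        )
        if est.valid:
            return RoughOptimizationResult(composition=comp, estimate=est, attempts=attempts)
        comp *= escalation_factor
    return RoughOptimizationResult(composition=None, estimate=None, attempts=attempts)


def choose_escalation_axis(pilot_estimate: AffinityEstimate, threshold: float = 3.0) -> str:
    """Which composition axis to escalate, from a pilot estimate.

    A candidate much stronger than the reference (pilot ratio above
    ``threshold``) calls for escalating the *reference*; otherwise the
    mixture content is escalated.  A pilot exactly at the threshold
    escalates the mixture (tie-break toward the cheaper axis).
    """
    return "reference" if pilot_estimate.ratio > threshold else "mixture"
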