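"""Relative-affinity estimators from peak areas, with prerequisite validation.

For a candidate ligand X and the exogenous reference ligand A sharing one
binding site, mass action gives K_X / K_A = (bound_X / free_X) * (free_A /
bound_A); the unoccupied-site term cancels.  Expressing amounts through peak
areas, with x = A_BX / (RR_X * CR) and a = A_BA / (RR_A * CR) the bound
amounts on the total-measurement area scale, the depletion-corrected form is

    K_X / K_A = [x / (A_TX - x)] * [(A_TA - a) / a]          (ratio form)

and when both binding ratios are below ~10% the bound terms are negligible
against the totals, leaving the dilute form in which CR cancels entirely:

    K_X / K_A = (A_BX * RR_A * A_TA) / (A_BA * RR_X * A_TX)  (dilute form)

The dilute form is the workhorse of mixture screening (no knowledge of CR or
absolute amounts needed); its validity rests on four prerequisites: (a) same
binding site, (b) all four areas within their linear ranges, (c) all four
areas at least five times the absolute intercept of their channel, (d) both
binding ratios below 10%.  These are evaluated in that order.

Note the exact relation  dilute = ratio_form * (1 - BR_X) / (1 - BR_A):
for a high-affinity candidate (BR_X > BR_A) the dilute form UNDER-estimates,
and converges to the truth from below as the candidate concentration rises.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .measurement import (
    LinearResponse,
    PeakTable,
    RecoveryProfile,
)

__all__ = [
    "PrerequisiteReport",
    "AffinityEstimate",
    "estimated_binding_ratio",
    "relative_affinity_eq5",
    "relative_affinity_eq6",
    "validate_prerequisites",
    "judge_binding_site",
    "RelativeAffinityModel",
    "AffinityResults",
]


class EstimationError(ValueError):
    pass


class DepletionError(EstimationError):
    """Raised when the inferred free amount of a ligand is non-positive."""


@dataclass(frozen=True)
class PrerequisiteReport:
    """Outcome of the four validity prerequisites for one candidate/reference
    pair.

    ``same_site`` is a tri-state: 'supported' / 'refuted' / 'untested'
    (untested counts as satisfied: site identity can only be judged, not
    optimized).  The per-(ligand, kind) flags cover the linear-range and
    five-times-intercept rules; ``br_below_limit`` covers the binding-ratio
    rule.  ``valid`` is the overall conjunction.
    """

    same_site: str = "untested"
    in_linear_range: dict = field(default_factory=dict)
    above_intercept_multiple: dict = field(default_factory=dict)
    br_below_limit: dict = field(default_factory=dict)
    area_multiple: float = 5.0
    br_limit: float = 0.10
    implausible_br: tuple = ()

    def __post_init__(self) -> None:
        if self.same_site not in ("supported", "refuted", "untested"):
            raise EstimationError(f"bad same_site state {self.same_site!r}")

    @property
    def valid(self) -> bool:
        return (
            self.same_site != "refuted"
            and all(self.in_linear_range.values())
            and all(self.above_intercept_multiple.values())
            and all(self.br_below_limit.values())
            and bool(self.in_linear_range)
        )

    def failures(self) -> list[str]:
        out = []
        if self.same_site == "refuted":
            out.append("same_site refuted")
        out += [f"linear range: {k}" for k, v in self.in_linear_range.items() if not v]
        out += [
            f"area < {self.area_multiple}x|intercept|: {k}"
            for k, v in self.above_intercept_multiple.items()
            if not v
        ]
        out += [f"BR >= {self.br_limit:.0%}: {k}" for k, v in self.br_below_limit.items() if not v]
        return out


@dataclass(frozen=True)
class AffinityEstimate:
    """A relative affinity K_X/K_A with its validity evidence."""

    candidate_id: str
    reference_id: str
    ratio: float
    method: str  # 'eq6' (dilute) or 'eq5' (depletion-corrected)
    prerequisites: PrerequisiteReport
    diagnostics: dict = field(default_factory=dict)

    @property
    def valid(self) -> bool:
        return self.prerequisites.valid


def estimated_binding_ratio(
    A_B: float,
    A_T: float,
    RR: float,
    CR: float,
    dilution_correction: float = 1.0,
) -> float:
    """Binding ratio from areas: BR = A_B * dilution_correction / (RR * CR * A_T).

    Under the system-scale dilution convention ``dilution_correction`` is 1.
    Values above 1 are physically implausible (noise near validity
    boundaries can produce them) and are returned as-is; callers flag them.
    """
    if A_T <= 0:
        raise EstimationError("total-measurement area A_T must be > 0 to define BR")
    if RR <= 0 or CR <= 0:
        raise EstimationError("RR and CR must be > 0")
    if A_B < 0:
        raise EstimationError("A_B must be >= 0")
    return A_B * dilution_correction / (RR * CR * A_T)


def relative_affinity_eq6(
    A_TA: float, A_TX: float, A_BA: float, A_BX: float, RR_A: float, RR_X: float
) -> float:
    """Dilute-regime relative affinity (CR cancels; it is not an argument).

    K_X/K_A = (A_BX * RR_A * A_TA) / (A_BA * RR_X * A_TX).
    """
    for name, val in (("A_TA", A_TA), ("A_TX", A_TX), ("A_BA", A_BA), ("A_BX", A_BX)):
        if val <= 0:
            raise EstimationError(f"{name} must be > 0, got {val}")
    if RR_A <= 0 or RR_X <= 0:
        raise EstimationError("recovery ratios must be > 0")
    return (A_BX * RR_A * A_TA) / (A_BA * RR_X * A_TX)


def relative_affinity_eq5(
    A_TA: float,
    A_TX: float,
    A_BA: float,
    A_BX: float,
    RR_A: float,
    RR_X: float,
    CR: float,
) -> float:
    """Depletion-corrected relative affinity, valid at any binding ratio
    (prerequisites (a)-(c) still required).

    With x = A_BX/(RR_X*CR) and a = A_BA/(RR_A*CR):
    K_X/K_A = [x / (A_TX - x)] * [(A_TA - a) / a].
    """
    if CR <= 0:
        raise EstimationError("CR must be > 0")
    if RR_A <= 0 or RR_X <= 0:
        raise EstimationError("recovery ratios must be > 0")
    if A_BA <= 0 or A_BX <= 0:
        raise EstimationError("bound areas must be > 0")
    x = A_BX / (RR_X * CR)
    a = A_BA / (RR_A * CR)
    free_x = A_TX - x
    free_a = A_TA - a
    if free_x <= 0:
        raise DepletionError(
            f"candidate free amount non-positive (A_TX={A_TX}, bound term={x:.4g})"
        )
    if free_a <= 0:
        raise DepletionError(
            f"reference free amount non-positive (A_TA={A_TA}, bound term={a:.4g})"
        )
    return (x / free_x) * (free_a / a)


def validate_prerequisites(
    peak_table: PeakTable,
    responses: dict[str, LinearResponse],
    recovery: RecoveryProfile,
    reference_id: str,
    candidate_id: str,
    same_site_evidence: str = "untested",
    area_multiple: float = 5.0,
    br_limit: float = 0.10,
    dilution_correction: float = 1.0,
) -> PrerequisiteReport:
    """Evaluate the four validity prerequisites for one pair.

    Peak-area rules (linear range, five-times-intercept) are judged before
    the binding-ratio rule, matching the prescribed order.  Thresholds are
    configurable; defaults are the published 5x and 10% rules.
    """
    missing = [
        (lid, kind)
        for lid in (candidate_id, reference_id)
        for kind in ("pmfs", "extract")
        if peak_table.get(lid, kind) is None
    ]
    if missing:
        raise EstimationError(f"peak table missing records for: {missing}")

    in_range: dict[tuple[str, str], bool] = {}
    above: dict[tuple[str, str], bool] = {}
    for lid in (candidate_id, reference_id):
        resp = responses[lid]
        for kind in ("pmfs", "extract"):
            area = peak_table.area(lid, kind)
            in_range[(lid, kind)] = resp.area_in_linear_range(area)
            above[(lid, kind)] = area >= area_multiple * abs(resp.intercept)

    CR = peak_table.protocol.CR
    br: dict[str, float] = {}
    for lid in (candidate_id, reference_id):
        br[lid] = estimated_binding_ratio(
            peak_table.area(lid, "extract"),
            peak_table.area(lid, "pmfs"),
            recovery[lid],
            CR,
            dilution_correction,
        )
    br_ok = {lid: val < br_limit for lid, val in br.items()}
    implausible = tuple(lid for lid, val in br.items() if val > 1.0)

    return PrerequisiteReport(
        same_site=same_site_evidence,
        in_linear_range=in_range,
        above_intercept_multiple=above,
        br_below_limit=br_ok,
        area_multiple=area_multiple,
        br_limit=br_limit,
        implausible_br=implausible,
    )


def judge_binding_site(
    baseline: PeakTable,
    with_excess_competitor: PeakTable,
    denatured_control: PeakTable,
    recovery: RecoveryProfile,
    reduction_threshold: float = 0.40,
    nonspecific_change: float = 0.10,
    denatured_detect: float = 0.10,
    dilution_correction: float = 1.0,
) -> dict[str, str]:
    """Classify each ligand's binding as specific / nonspecific / indeterminate.

    A ligand is *specific* when an excess of the natural competitor reduces
    its binding ratio by at least ``reduction_threshold`` AND it shows no
    detectable binding to the denatured target (BR below ``denatured_detect``
    of baseline).  It is *nonspecific* when the competitor changes its BR by
    less than ``nonspecific_change`` (relative) AND its binding to the
    denatured target is unchanged.  Anything else is indeterminate.
    """
    ids = set(baseline.ligand_ids())
    for table, name in ((with_excess_competitor, "competitor"), (denatured_control, "denatured")):
        other = {
            lid for lid in table.ligand_ids() if table.get(lid, "extract") is not None
        } & ids
        if {lid for lid in ids if baseline.get(lid, "extract") is not None} - set(
            table.ligand_ids()
        ):
            raise EstimationError(f"{name} table does not share the baseline ligand set")

    def br_map(table: PeakTable) -> dict[str, float]:
        out = {}
        for lid in table.ligand_ids():
            rec_b = table.get(lid, "extract")
            rec_t = table.get(lid, "pmfs")
            if rec_b is None or rec_t is None or lid not in recovery:
                continue
            out[lid] = estimated_binding_ratio(
                rec_b.area, rec_t.area, recovery[lid], table.protocol.CR, dilution_correction
            )
        return out

    base = br_map(baseline)
    comp = br_map(with_excess_competitor)
    denat = br_map(denatured_control)

    verdicts: dict[str, str] = {}
    for lid, br0 in base.items():
        if lid not in comp or lid not in denat or br0 <= 0:
            verdicts[lid] = "indeterminate"
            continue
        reduction = 1.0 - comp[lid] / br0
        denat_frac = denat[lid] / br0
        if reduction >= reduction_threshold and denat_frac <= denatured_detect:
            verdicts[lid] = "specific"
        elif abs(reduction) < nonspecific_change and abs(denat_frac - 1.0) < nonspecific_change:
            verdicts[lid] = "nonspecific"
        else:
            verdicts[lid] = "indeterminate"
    return verdicts


class RelativeAffinityModel:
    """Relative affinities of candidate ligands in a mixture, from one peak
    table.

    Parameters
    ----------
    peak_table : PeakTable
        Areas for every ligand of interest in both the PMFS and the
        concentrated extract.
    responses : dict of LinearResponse
        Per-ligand linear calibrations.
    recovery : RecoveryProfile
        Per-ligand overall recovery ratios.
    reference_id : str
        The exogenous reference ligand; all affinities are reported
        relative to it.
    candidate_ids : sequence of str, optional
        Defaults to every ligand in the table (other than the reference)
        that has both a calibration and both measurement kinds.
    same_site : dict or str, optional
        Per-candidate same-site evidence ('supported'/'refuted'/'untested').

    Examples
    --------
    >>> model = RelativeAffinityModel(table, responses, recovery, "BMPL")
    >>> res = model.fit()
    >>> print(res.summary())            # doctest: +SKIP
    """

    def __init__(
        self,
        peak_table: PeakTable,
        responses: dict[str, LinearResponse],
        recovery: RecoveryProfile,
        reference_id: str,
        candidate_ids=None,
        same_site=None,
        area_multiple: float = 5.0,
        br_limit: float = 0.10,
        dilution_correction: float = 1.0,
    ) -> None:
        if peak_table.get(reference_id, "pmfs") is None or (
            peak_table.get(reference_id, "extract") is None
        ):
            raise EstimationError(
                f"reference ligand {reference_id!r} missing from the peak table"
            )
        self.peak_table = peak_table
        self.responses = responses
        self.recovery = recovery
        self.reference_id = reference_id
        if candidate_ids is None:
            candidate_ids = [
                lid
                for lid in peak_table.ligand_ids()
                if lid != reference_id
                and lid in responses
                and lid in recovery
                and peak_table.get(lid, "pmfs") is not None
                and peak_table.get(lid, "extract") is not None
            ]
        self.candidate_ids = list(candidate_ids)
        if isinstance(same_site, str) or same_site is None:
            same_site = {lid: (same_site or "untested") for lid in self.candidate_ids}
        self.same_site = same_site
        self.area_multiple = area_multiple
        self.br_limit = br_limit
        self.dilution_correction = dilution_correction

    @classmethod
    def from_csv(
        cls, peak_csv, calibration_csv, protocol, reference_id: str, **kwargs
    ) -> "RelativeAffinityModel":
        from .measurement import load_calibrations

        table = PeakTable.from_csv(peak_csv, protocol)
        responses, recovery = load_calibrations(calibration_csv)
        model = cls(table, responses, recovery, reference_id, **kwargs)
        model._input_checksums = {
            "peak_table": _file_sha256(peak_csv),
            "calibrations": _file_sha256(calibration_csv),
        }
        return model

    def estimate_pair(self, candidate_id: str, method: str = "eq6") -> AffinityEstimate:
        """Estimate one candidate's relative affinity, with its report.

        The dilute-form estimate is always computed, even when invalid (the
        fine optimizer tracks it across the validity boundary); validity is
        carried on the report.
        """
        table = self.peak_table
        ref, cand = self.reference_id, candidate_id
        report = validate_prerequisites(
            table,
            self.responses,
            self.recovery,
            ref,
            cand,
            same_site_evidence=self.same_site.get(cand, "untested"),
            area_multiple=self.area_multiple,
            br_limit=self.br_limit,
            dilution_correction=self.dilution_correction,
        )
        A_TA = table.area(ref, "pmfs")
        A_BA = table.area(ref, "extract")
        A_TX = table.area(cand, "pmfs")
        A_BX = table.area(cand, "extract")
        RR_A = self.recovery[ref]
        RR_X = self.recovery[cand]
        CR = table.protocol.CR
        if method == "eq6":
            ratio = relative_affinity_eq6(A_TA, A_TX, A_BA, A_BX, RR_A, RR_X)
        elif method == "eq5":
            ratio = relative_affinity_eq5(A_TA, A_TX, A_BA, A_BX, RR_A, RR_X, CR)
        else:
            raise EstimationError(f"unknown method {method!r}")
        br_x = estimated_binding_ratio(A_BX, A_TX, RR_X, CR, self.dilution_correction)
        br_a = estimated_binding_ratio(A_BA, A_TA, RR_A, CR, self.dilution_correction)
        diag = {
            "BR_X": br_x,
            "BR_A": br_a,
            "area_over_intercept": {
                (lid, kind): table.area(lid, kind)
                / abs(self.responses[lid].intercept)
                if self.responses[lid].intercept != 0
                else np.inf
                for lid in (cand, ref)
                for kind in ("pmfs", "extract")
            },
        }
        return AffinityEstimate(
            candidate_id=cand,
            reference_id=ref,
            ratio=ratio,
            method=method,
            prerequisites=report,
            diagnostics=diag,
        )

    def fit(self, method: str = "eq6") -> "AffinityResults":
        """Estimate every candidate's relative affinity.

        ``method='auto'`` uses the depletion-corrected form whenever a
        binding ratio violates the dilute-regime limit and the dilute form
        otherwise.
        """
        estimates = []
        for cand in self.candidate_ids:
            if method == "auto":
                probe = self.estimate_pair(cand, "eq6")
                use = "eq6" if all(probe.prerequisites.br_below_limit.values()) else "eq5"
                estimates.append(self.estimate_pair(cand, use))
            else:
                estimates.append(self.estimate_pair(cand, method))
        return AffinityResults(self, estimates)


class AffinityResults:
    """Estimates, diagnostics and reports from a fitted
    :class:`RelativeAffinityModel`."""

    def __init__(self, model: RelativeAffinityModel, estimates: list[AffinityEstimate]):
        self.model = model
        self.estimates = estimates

    @property
    def ratios(self) -> dict[str, float]:
        return {est.candidate_id: est.ratio for est in self.estimates}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for est in self.estimates:
            rows.append(
                {
                    "candidate_id": est.candidate_id,
                    "reference_id": est.reference_id,
                    "relative_affinity": est.ratio,
                    "method": est.method,
                    "valid": est.valid,
                    "BR_candidate": est.diagnostics["BR_X"],
                    "BR_reference": est.diagnostics["BR_A"],
                    "failures": "; ".join(est.prerequisites.failures()),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        frame = self.to_frame()
        lines = [
            "Relative affinity estimates (K_X / K_A)",
            f"  reference ligand: {self.model.reference_id}"
            f"   CR: {self.model.peak_table.protocol.CR:.1f}"
            f"   thresholds: {self.model.area_multiple:.0f}x|intercept|,"
            f" BR < {self.model.br_limit:.0%}",
            "-" * 78,
            f"{'candidate':<12}{'ratio':>8}{'method':>8}{'valid':>7}"
            f"{'BR_X':>8}{'BR_A':>8}  failures",
        ]
        for _, row in frame.iterrows():
            lines.append(
                f"{row.candidate_id:<12}{row.relative_affinity:>8.3f}{row.method:>8}"
                f"{str(row.valid):>7}{row.BR_candidate:>8.3f}{row.BR_reference:>8.3f}"
                f"  {row.failures}"
            )
        lines.append("-" * 78)
        return "\n".join(lines)

    def report_metadata(self) -> dict:
        meta = {
            "reference_id": self.model.reference_id,
            "thresholds": {
                "area_multiple": self.model.area_multiple,
                "br_limit": self.model.br_limit,
            },
            "peak_table_sha256": self.model.peak_table.checksum(),
        }
        meta.update(getattr(self.model, "_input_checksums", {}))
        return meta

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None):
        payload = {
            "metadata": self.report_metadata(),
            "estimates": [
                {
                    "candidate_id": est.candidate_id,
                    "reference_id": est.reference_id,
                    "relative_affinity": est.ratio,
                    "method": est.method,
                    "valid": est.valid,
                    "prerequisites": {
                        "same_site": est.prerequisites.same_site,
                        "failures": est.prerequisites.failures(),
                    },
                    "diagnostics": {
                        "BR_X": est.diagnostics["BR_X"],
                        "BR_A": est.diagnostics["BR_A"],
                    },
                }
                for est in self.estimates
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
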