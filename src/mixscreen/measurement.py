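"""Forward model and inversion of the measurement chain.

After equilibrium binding, target-ligand complexes are pulled down
magnetically, bound ligands are extracted into a small solvent volume
(concentrated by the factor CR = system volume / extract volume) and both the
spiked mixture (PMFS) and the concentrated extract are analyzed by LC-MS in
selected-ion-monitoring mode.  Peak areas respond linearly to the loaded
quantity up to a linear-range ceiling:

    area = slope * quantity + intercept        (quantity <= linear_upper)

Quantities are in pmol loaded per injection.  Each ligand also has an overall
recovery ratio RR: the fraction of its bound amount that survives the whole
pull-down / extraction / concentration process.

Dilution convention: PMFS ("total") measurements are interpreted at the
binding-system concentration scale, i.e. the PMFS is diluted by
V_system / V_PMFS before injection.  Under the standard protocol
(V_PMFS = V_extract = 40 uL) that factor equals CR, which is the only
convention making the binding-ratio formula A_B / (RR * CR * A_T) exact; the
``dilution`` field on each record lets deviating protocols be corrected.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LinearResponse",
    "ProcessingProtocol",
    "RecoveryProfile",
    "PeakRecord",
    "PeakTable",
    "predict_area",
    "quantify",
    "fit_linear_response",
    "simulate_peak_table",
    "recovery_ratio",
]

PEAK_COLUMNS = ["ligand_id", "kind", "mz", "rt_min", "dilution", "area", "replicate"]
CALIBRATION_COLUMNS = ["ligand_id", "slope", "intercept", "linear_upper", "r2", "RR"]

MEASUREMENT_KINDS = ("pmfs", "extract")


class QuantificationError(ValueError):
    pass


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class LinearResponse:
    """Linear peak-area response of one SIM channel.

    slope in area units per pmol (> 0), intercept in area units (may be
    negative), linear_upper in pmol.
    """

    slope: float
    intercept: float
    linear_upper: float = 30.0
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope) and self.slope > 0):
            raise CalibrationError("slope must be finite and > 0")
        if not (np.isfinite(self.linear_upper) and self.linear_upper > 0):
            raise CalibrationError("linear_upper must be finite and > 0")

    @property
    def area_upper(self) -> float:
        """Largest area still on the linear branch."""
        return self.slope * self.linear_upper + self.intercept

    def in_linear_range(self, quantity: float) -> bool:
        return 0.0 <= quantity <= self.linear_upper

    def area_in_linear_range(self, area: float) -> bool:
        # strict: a saturated channel reports exactly the ceiling area
        return area < self.area_upper


@dataclass(frozen=True)
class ProcessingProtocol:
    """Volumes of the pull-down / extraction / analysis chain.

    system_volume in mL; extract, injection and PMFS volumes in uL.
    ``pmfs_dilution`` is the factor by which the PMFS is diluted before
    direct analysis; ``None`` selects the system-concentration convention
    (dilute by 1000 * system_volume / pmfs_volume).
    """

    system_volume: float = 2.0
    extract_volume: float = 40.0
    injection_volume: float = 5.0
    pmfs_volume: float = 40.0
    pmfs_dilution: float | None = None

    def __post_init__(self) -> None:
        for name in ("system_volume", "extract_volume", "injection_volume", "pmfs_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.pmfs_dilution is not None and self.pmfs_dilution <= 0:
            raise ValueError("pmfs_dilution must be > 0")

    @property
    def CR(self) -> float:
        """Concentration ratio: system volume over extract volume."""
        return 1000.0 * self.system_volume / self.extract_volume

    @property
    def effective_pmfs_dilution(self) -> float:
        if self.pmfs_dilution is not None:
            return self.pmfs_dilution
        return 1000.0 * self.system_volume / self.pmfs_volume


@dataclass(frozen=True)
class RecoveryProfile:
    """Per-ligand overall recovery ratios (fractions in (0, 1.05])."""

    RR: dict[str, float]

    def __post_init__(self) -> None:
        for lig, rr in self.RR.items():
            if not (0.0 < rr <= 1.05):
                raise CalibrationError(f"recovery ratio for {lig!r} out of (0, 1.05]: {rr}")

    def __getitem__(self, ligand_id: str) -> float:
        return self.RR[ligand_id]

    def __contains__(self, ligand_id: str) -> bool:
        return ligand_id in self.RR

    def relative(self, candidate_id: str, reference_id: str) -> float:
        """RR_X / RR_A."""
        return self.RR[candidate_id] / self.RR[reference_id]


@dataclass(frozen=True)
class PeakRecord:
    """One detected component in one measurement.

    ``kind`` is ``"pmfs"`` (direct analysis of the diluted mixture; houses
    the A_T areas) or ``"extract"`` (concentrated extract of bound ligands;
    houses the A_B areas).  ``dilution`` is the factor from the
    binding-system concentration scale to the injected solution.
    """

    ligand_id: str
    kind: str
    area: float
    mz: int | None = None
    retention_time: float | None = None
    dilution: float = 1.0
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.kind not in MEASUREMENT_KINDS:
            raise ValueError(f"kind must be one of {MEASUREMENT_KINDS}, got {self.kind!r}")
        if self.area < 0:
            raise ValueError("area must be >= 0")
        if self.dilution <= 0:
            raise ValueError("dilution must be > 0")


@dataclass(frozen=True)
class PeakTable:
    """All peak areas from one binding system, plus its protocol."""

    records: tuple[PeakRecord, ...]
    protocol: ProcessingProtocol = field(default_factory=ProcessingProtocol)

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.ligand_id, rec.kind)
            if key in seen:
                raise ValueError(f"duplicate record for {key}")
            seen.add(key)

    def area(self, ligand_id: str, kind: str) -> float:
        for rec in self.records:
            if rec.ligand_id == ligand_id and rec.kind == kind:
                return rec.area
        raise KeyError((ligand_id, kind))

    def get(self, ligand_id: str, kind: str) -> PeakRecord | None:
        for rec in self.records:
            if rec.ligand_id == ligand_id and rec.kind == kind:
                return rec
        return None

    def ligand_ids(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.ligand_id not in out:
                out.append(rec.ligand_id)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "ligand_id": r.ligand_id,
                "kind": r.kind,
                "mz": r.mz,
                "rt_min": r.retention_time,
                "dilution": r.dilution,
                "area": r.area,
                "replicate": r.replicate,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=PEAK_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, protocol: ProcessingProtocol) -> "PeakTable":
        missing = [c for c in ("ligand_id", "kind", "area") if c not in frame.columns]
        if missing:
            raise ValueError(f"peak table missing columns: {missing}")
        records = []
        for _, row in frame.iterrows():
            mz = row.get("mz")
            rt = row.get("rt_min")
            records.append(
                PeakRecord(
                    ligand_id=str(row["ligand_id"]),
                    kind=str(row["kind"]),
                    area=float(row["area"]),
                    mz=None if pd.isna(mz) else int(mz),
                    retention_time=None if pd.isna(rt) else float(rt),
                    dilution=float(row.get("dilution", 1.0)),
                    replicate=int(row.get("replicate", 1)),
                )
            )
        return cls(records=tuple(records), protocol=protocol)

    @classmethod
    def from_csv(cls, path, protocol: ProcessingProtocol) -> "PeakTable":
        return cls.from_frame(pd.read_csv(path), protocol)

    def checksum(self) -> str:
        import hashlib

        buf = io.StringIO()
        self.to_frame().to_csv(buf, index=False)
        return hashlib.sha256(buf.getvalue().encode()).hexdigest()


def _noise_factor(noise_cv: float, rng: np.random.Generator) -> float:
    """Multiplicative log-normal noise with unit mean and the given CV."""
    if noise_cv == 0.0:
        return 1.0
    sigma = math.sqrt(math.log1p(noise_cv**2))
    return float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))


def predict_area(
    response: LinearResponse,
    quantity: float,
    noise_cv: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Expected peak area for a loaded quantity (pmol), optionally noisy.

    Quantities above ``linear_upper`` saturate: the area returned is the
    linear-ceiling area (callers probing beyond range get a flag from
    ``response.in_linear_range``, not an error, because the composition
    optimizers intentionally cross the boundary).
    """
    if quantity < 0:
        raise QuantificationError("quantity must be >= 0")
    q = min(quantity, response.linear_upper)
    mean = response.slope * q + response.intercept
    if noise_cv == 0.0:
        return mean
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return max(mean * _noise_factor(noise_cv, rng), 0.0)


def quantify(response: LinearResponse, area: float, neglect_intercept: bool = False) -> float:
    """Invert the linear response: loaded quantity in pmol.

    With ``neglect_intercept`` (the dilute-regime convention used by the
    ratio estimators) the quantity is simply ``area / slope``; otherwise the
    intercept is subtracted, and an area below the intercept is an error.
    """
    if neglect_intercept:
        return area / response.slope
    if area < response.intercept:
        raise QuantificationError(
            f"area {area} below intercept {response.intercept}; cannot invert"
        )
    return (area - response.intercept) / response.slope


def fit_linear_response(
    pairs,
    residual_band: float = 3.0,
) -> LinearResponse:
    """Ordinary least squares fit of areas vs loaded quantities.

    Parameters
    ----------
    pairs : sequence of (quantity, area)
        At least 3 points spanning a nonzero quantity range.  Quantities may
        be pure-compound pmol or PMFS amounts in arbitrary units (both
        calibration routes are standard; a mixture-based library rarely has
        purified counterparts).
    residual_band : float
        ``linear_upper`` is the largest quantity whose residual is within
        ``residual_band`` times the residual standard deviation.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise CalibrationError("need at least 3 (quantity, area) pairs")
    q, a = arr[:, 0], arr[:, 1]
    if np.ptp(q) == 0:
        raise CalibrationError("degenerate design: all quantities identical")
    res = stats.linregress(q, a)
    resid = a - (res.slope * q + res.intercept)
    sd = float(np.std(resid, ddof=2)) if len(q) > 2 else 0.0
    ok = np.abs(resid) <= residual_band * sd if sd > 0 else np.ones_like(q, dtype=bool)
    upper = float(np.max(q[ok])) if ok.any() else float(np.max(q))
    return LinearResponse(
        slope=float(res.slope),
        intercept=float(res.intercept),
        linear_upper=upper,
        r_squared=float(res.rvalue**2),
    )


@dataclass(frozen=True)
class ContaminantPeak:
    """A spurious component (e.g. leached from the particles) on some SIM
    channel.  Resolved from ligands of interest by retention time, so it adds
    a separate record rather than inflating a ligand's area."""

    label: str
    kind: str
    area: float
    mz: int | None = None
    retention_time: float | None = None


def simulate_peak_table(
    state,
    system,
    protocol: ProcessingProtocol,
    responses: dict[str, LinearResponse],
    recovery: RecoveryProfile,
    noise_cv: float = 0.1,
    rng: np.random.Generator | int | None = None,
    duplicates: int = 2,
    contaminants: tuple[ContaminantPeak, ...] = (),
    extract_background: dict[str, float] | None = None,
    retention_times: dict[str, float] | None = None,
) -> PeakTable:
    """Forward-simulate the LC-MS peak table of one binding system.

    For ligand ``i`` the extract injection carries
    ``bound_i * RR_i * injection_volume / extract_volume`` pmol and the PMFS
    injection (diluted to the system concentration scale) carries
    ``total_conc_i * injection_volume`` pmol.  Per-injection multiplicative
    noise with CV ``noise_cv`` is applied and the mean over ``duplicates``
    injections is recorded, mirroring duplicate analyses.

    ``extract_background`` adds a fixed spurious area on a ligand's extract
    channel (an unresolved co-eluting interference); ``contaminants`` add
    retention-time-resolved spurious records.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if duplicates < 1:
        raise ValueError("duplicates must be >= 1")
    background = extract_background or {}
    rts = retention_times or {}

    records: list[PeakRecord] = []
    for lig in system.ligands:
        if lig.id not in responses or lig.id not in recovery:
            if getattr(lig, "role", "candidate") == "nonspecific":
                continue  # not every by-product is quantifiable on a SIM channel
            missing = "linear response" if lig.id not in responses else "recovery ratio"
            raise CalibrationError(f"no {missing} calibrated for ligand {lig.id!r}")
        resp = responses[lig.id]
        rr = recovery[lig.id]

        q_extract = (
            state.bound[lig.id] * rr * protocol.injection_volume / protocol.extract_volume
        )
        q_pmfs = lig.total_conc * 1e6 * protocol.injection_volume  # pmol at system scale

        for kind, q in (("pmfs", q_pmfs), ("extract", q_extract)):
            areas = [predict_area(resp, q, noise_cv, rng) for _ in range(duplicates)]
            area = float(np.mean(areas))
            if kind == "extract":
                area += background.get(lig.id, 0.0)
            dilution = (
                protocol.effective_pmfs_dilution
                * protocol.pmfs_volume
                / (1000.0 * protocol.system_volume)
                if kind == "pmfs"
                else 1.0
            )
            records.append(
                PeakRecord(
                    ligand_id=lig.id,
                    kind=kind,
                    area=area,
                    mz=lig.mz,
                    retention_time=rts.get(lig.id),
                    dilution=dilution,
                    replicate=duplicates,
                )
            )

    for cont in contaminants:
        records.append(
            PeakRecord(
                ligand_id=cont.label,
                kind=cont.kind,
                area=cont.area,
                mz=cont.mz,
                retention_time=cont.retention_time,
                replicate=duplicates,
            )
        )
    return PeakTable(records=tuple(records), protocol=protocol)


def recovery_ratio(
    extract_area: float,
    reference_mixture_area: float,
    CR_correction: float,
    response: LinearResponse | None = None,
) -> float:
    """Overall recovery ratio from a saturation-binding calibration run.

    The calibration mixture is bound quantitatively (target in large excess),
    so after correcting the extract area for the concentration factor the
    ratio to the mixture's own area is the fraction surviving the whole
    pull-down / extraction / concentration chain:

        RR = extract_area / (CR_correction * reference_mixture_area)

    If a ``response`` is given, both areas must satisfy the five-times-
    intercept rule and lie within the linear range (the calibration protocol
    requires it).
    """
    if reference_mixture_area <= 0 or CR_correction <= 0:
        raise CalibrationError("reference area and CR correction must be > 0")
    if response is not None:
        thresh = 5.0 * abs(response.intercept)
        for name, area in (("extract", extract_area), ("mixture", reference_mixture_area)):
            if area < thresh:
                raise CalibrationError(
                    f"{name} area {area:.1f} below five times |intercept| ({thresh:.1f})"
                )
            if not response.area_in_linear_range(area):
                raise CalibrationError(f"{name} area {area:.1f} above the linear range")
    return extract_area / (CR_correction * reference_mixture_area)


def load_calibrations(path) -> tuple[dict[str, LinearResponse], RecoveryProfile]:
    """Read a calibration CSV (columns ligand_id, slope, intercept,
    linear_upper, r2, RR) into response and recovery maps."""
    frame = pd.read_csv(path)
    missing = [c for c in ("ligand_id", "slope", "intercept", "RR") if c not in frame.columns]
    if missing:
        raise CalibrationError(f"calibration table missing columns: {missing}")
    responses: dict[str, LinearResponse] = {}
    rr: dict[str, float] = {}
    for _, row in frame.iterrows():
        lid = str(row["ligand_id"])
        responses[lid] = LinearResponse(
            slope=float(row["slope"]),
            intercept=float(row["intercept"]),
            linear_upper=float(row.get("linear_upper", 30.0)),
            r_squared=None if pd.isna(row.get("r2")) else float(row["r2"]),
        )
        rr[lid] = float(row["RR"])
    return responses, RecoveryProfile(RR=rr)


def save_calibrations(path, responses: dict[str, LinearResponse], recovery: RecoveryProfile) -> None:
    rows = []
    for lid, resp in responses.items():
        rows.append(
            {
                "ligand_id": lid,
                "slope": resp.slope,
                "intercept": resp.intercept,
                "linear_upper": resp.linear_upper,
                "r2": resp.r_squared,
                "RR": recovery[lid],
            }
        )
    pd.DataFrame(rows, columns=CALIBRATION_COLUMNS).to_csv(path, index=False)
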