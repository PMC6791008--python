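"""qPCR quantification: standard curves, telomere T/S ratio, TREC/KREC copies.

Implements the arithmetic of two assays:

* **Monochrome multiplex telomere assay** — telomere (TEL) and beta-globin
  single-copy gene (BG) signals are each interpolated on a standard curve of
  reference DNA (1:2 serial dilutions, 21 ng down to 0.1640625 ng/well).
  T is the nanograms of reference DNA matching the sample's telomere signal,
  S the nanograms matching its beta-globin signal; relative telomere length
  is the dimensionless ratio T/S.

* **Duplex TREC/KREC assay** — T-cell receptor excision circles and
  K-deleting recombination excision circles are quantified on copy-number
  standard curves from the same plate and normalized to copies per ml of
  blood.

Triplicate quality control: a replicate group is rejected when the
coefficient of variation of its interpolated quantities exceeds 15 %
(strictly; CV = 15.0 % passes).  Rejected groups yield flagged-invalid
results, never silent numbers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    AssayFailureError,
    ConfigurationError,
    ExtrapolationWarning,
    InsufficientReplicatesError,
    InsufficientStandardsError,
    PlateContaminationError,
    PlateFormatError,
)

VALID_TARGETS = ("TEL", "BG", "TREC", "KREC", "REF")
VALID_ROLES = ("standard", "sample", "ntc", "internal_control")

#: default replicate-CV acceptance threshold (percent)
CV_THRESHOLD_PCT = 15.0
#: NTC wells with Cq below this are treated as contamination
NTC_CONTAMINATION_CQ = 38.0

#: the 8-point 1:2 reference-DNA dilution ladder, ng/well (21 ng halved 7x)
TELOMERE_STANDARD_LADDER_NG = tuple(21.0 / 2**k for k in range(8))


@dataclass(frozen=True)
class Well:
    """One physical well of a qPCR plate."""

    well_id: str
    target: str
    role: str
    replicate_group: str
    known_quantity: float | None  # ng (TEL/BG) or copies (TREC/KREC); None for samples/ntc
    cq: float  # NaN = no amplification

    def __post_init__(self) -> None:
        if self.target not in VALID_TARGETS:
            raise PlateFormatError(f"unknown target {self.target!r}; expected one of {VALID_TARGETS}")
        if self.role not in VALID_ROLES:
            raise PlateFormatError(f"unknown role {self.role!r}; expected one of {VALID_ROLES}")
        if self.role == "standard" and (self.known_quantity is None or self.known_quantity <= 0):
            raise PlateFormatError(f"standard well {self.well_id} must carry known_quantity > 0")
        if self.role == "ntc" and self.known_quantity is not None:
            raise PlateFormatError(f"ntc well {self.well_id} must not carry a quantity")


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares log-linear calibration Cq = intercept + slope*log10(q)."""

    target: str
    slope: float  # cycles per log10 quantity; < 0 for a working assay
    intercept: float  # cycles at quantity 1
    r2: float
    efficiency_pct: float
    quantity_range: tuple[float, float] = (np.nan, np.nan)  # min/max standard quantity


@dataclass(frozen=True)
class ReplicateQC:
    replicate_group: str
    n: int
    mean: float
    sd: float
    cv_pct: float
    accepted: bool


@dataclass(frozen=True)
class TSResult:
    """Relative telomere length of one sample with its replicate QC."""

    sample_id: str
    t_ng: float  # ng of reference DNA matching the telomere signal
    s_ng: float  # ng matching the beta-globin signal
    ts_ratio: float  # NaN when invalid
    qc_t: ReplicateQC
    qc_s: ReplicateQC
    valid: bool


@dataclass(frozen=True)
class ExcisionCircleResult:
    """TREC/KREC output of one sample, expressed as copies/ml of blood.

    A failed replicate group yields ``None`` (absent, not zero) and a reason.
    """

    sample_id: str
    trec_copies_per_ml: float | None
    krec_copies_per_ml: float | None
    qc_trec: ReplicateQC
    qc_krec: ReplicateQC
    reasons: dict = field(default_factory=dict)


@dataclass(frozen=True)
class BloodNormalization:
    """Scale copies/reaction to copies/ml of blood.

    ``copies_per_ml = copies_per_reaction * cells_per_ml / cells_per_reaction``.
    """

    cells_per_ml: float
    cells_per_reaction: float

    def __post_init__(self) -> None:
        if not (self.cells_per_ml > 0 and self.cells_per_reaction > 0):
            raise ConfigurationError("blood normalization factors must be > 0")

    @property
    def factor(self) -> float:
        return self.cells_per_ml / self.cells_per_reaction


class QpcrPlate:
    """A collection of wells with target/role accessors and CSV round-trip."""

    COLUMNS = ("well", "target", "role", "replicate_group", "quantity_ng_or_copies", "cq")

    def __init__(self, wells: Iterable[Well]):
        self.wells: list[Well] = list(wells)

    def __len__(self) -> int:
        return len(self.wells)

    def standards(self, target: str) -> list[Well]:
        return [w for w in self.wells if w.role == "standard" and w.target == target]

    def sample_wells(self, target: str, sample_id: str) -> list[Well]:
        return [
            w
            for w in self.wells
            if w.role == "sample" and w.target == target and w.replicate_group == sample_id
        ]

    def ntc_wells(self, target: str | None = None) -> list[Well]:
        return [w for w in self.wells if w.role == "ntc" and (target is None or w.target == target)]

    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for w in self.wells:
            if w.role == "sample":
                seen.setdefault(w.replicate_group, None)
        return list(seen)

    def targets(self) -> set[str]:
        return {w.target for w in self.wells}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "well": w.well_id,
                    "target": w.target,
                    "role": w.role,
                    "replicate_group": w.replicate_group,
                    "quantity_ng_or_copies": w.known_quantity,
                    "cq": w.cq,
                }
                for w in self.wells
            ],
            columns=list(self.COLUMNS),
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "QpcrPlate":
        missing = [c for c in cls.COLUMNS if c not in df.columns]
        if missing:
            raise PlateFormatError(f"plate table missing column(s): {', '.join(missing)}")
        wells = []
        for _, row in df.iterrows():
            qty = row["quantity_ng_or_copies"]
            wells.append(
                Well(
                    well_id=str(row["well"]),
                    target=str(row["target"]),
                    role=str(row["role"]),
                    replicate_group=str(row["replicate_group"]),
                    known_quantity=None if pd.isna(qty) else float(qty),
                    cq=float(row["cq"]) if not pd.isna(row["cq"]) else math.nan,
                )
            )
        return cls(wells)

    @classmethod
    def from_csv(cls, path: str | Path) -> "QpcrPlate":
        return cls.from_frame(pd.read_csv(path))


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency in percent, ``100*(10**(-1/slope) - 1)``.

    A slope of -3.3219 (= -1/log10(2)) means perfect per-cycle doubling,
    i.e. 100 %.
    """
    if not slope < 0:
        raise AssayFailureError(f"standard-curve slope must be negative, got {slope}")
    return 100.0 * (10.0 ** (-1.0 / slope) - 1.0)


def fit_standard_curve(standards: Sequence[Well], target: str | None = None) -> StandardCurve:
    """Ordinary least squares of Cq on log10(known quantity).

    Requires >= 3 distinct dilution points with finite Cq.  A fitted slope
    >= 0 indicates assay failure and raises.
    """
    wells = [w for w in standards if w.role == "standard"]
    if target is not None:
        wells = [w for w in wells if w.target == target]
    if not wells:
        raise InsufficientStandardsError("no standard wells supplied")
    tgt = target or wells[0].target
    if any(w.target != tgt for w in wells):
        raise PlateFormatError("standards mix multiple targets; pass target= explicitly")
    q = np.array([w.known_quantity for w in wells], dtype=float)
    cq = np.array([w.cq for w in wells], dtype=float)
    if not np.all(np.isfinite(cq)):
        raise InsufficientStandardsError(f"{tgt}: non-finite Cq among standards")
    if np.unique(q).size < 3:
        raise InsufficientStandardsError(
            f"{tgt}: need >=3 distinct dilution points, got {np.unique(q).size}"
        )
    res = sps.linregress(np.log10(q), cq)
    slope, intercept = float(res.slope), float(res.intercept)
    if slope >= 0:
        raise AssayFailureError(f"{tgt}: fitted slope {slope:.3f} >= 0; assay failed")
    return StandardCurve(
        target=tgt,
        slope=slope,
        intercept=intercept,
        r2=float(res.rvalue**2),
        efficiency_pct=efficiency_from_slope(slope),
        quantity_range=(float(q.min()), float(q.max())),
    )


def interpolate_quantity(curve: StandardCurve, cq: float) -> float:
    """Invert the calibration: quantity = 10**((cq - intercept)/slope).

    Emits :class:`ExtrapolationWarning` when the result lies more than one
    log10 outside the fitted standard range.
    """
    q = 10.0 ** ((cq - curve.intercept) / curve.slope)
    lo, hi = curve.quantity_range
    if np.isfinite(lo) and np.isfinite(hi) and hi > 0:
        if q < lo / 10.0 or q > hi * 10.0:
            warnings.warn(
                f"{curve.target}: quantity {q:.3g} extrapolates >1 log10 beyond "
                f"standards [{lo:.3g}, {hi:.3g}]",
                ExtrapolationWarning,
                stacklevel=2,
            )
    return q


def replicate_qc(
    values: Sequence[float],
    replicate_group: str = "",
    threshold_pct: float = CV_THRESHOLD_PCT,
) -> ReplicateQC:
    """CV-based acceptance of a replicate group of interpolated quantities.

    CV uses the sample (n-1) standard deviation.  Rejection is strict:
    CV > threshold rejects, CV == threshold passes.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise InsufficientReplicatesError(
            f"replicate group {replicate_group!r}: need >=2 values, got {vals.size}"
        )
    if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
        raise InsufficientReplicatesError(
            f"replicate group {replicate_group!r}: quantities must be finite and > 0"
        )
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    cv = 100.0 * sd / mean
    return ReplicateQC(
        replicate_group=replicate_group,
        n=int(vals.size),
        mean=mean,
        sd=sd,
        cv_pct=cv,
        accepted=bool(cv <= threshold_pct),
    )


def check_ntc(plate: QpcrPlate, cutoff_cq: float = NTC_CONTAMINATION_CQ) -> None:
    """Raise if any no-template control amplified below the contamination cutoff."""
    for w in plate.ntc_wells():
        if np.isfinite(w.cq) and w.cq < cutoff_cq:
            raise PlateContaminationError(
                f"NTC well {w.well_id} ({w.target}) amplified at Cq {w.cq:.2f} < {cutoff_cq}"
            )


def _interpolated_replicates(plate: QpcrPlate, curve: StandardCurve, sample_id: str) -> list[float]:
    wells = plate.sample_wells(curve.target, sample_id)
    if not wells:
        raise PlateFormatError(f"no {curve.target} sample wells for {sample_id!r}")
    return [interpolate_quantity(curve, w.cq) for w in wells]


def compute_ts_ratio(
    plate: QpcrPlate,
    sample_id: str,
    cv_threshold_pct: float = CV_THRESHOLD_PCT,
    ntc_cutoff_cq: float = NTC_CONTAMINATION_CQ,
) -> TSResult:
    """Relative telomere length T/S for one sample from a telomere plate.

    T and S are the medians of the accepted triplicate interpolations on the
    TEL and BG standard curves.  If either replicate group fails CV
    acceptance the result is flagged invalid (``ts_ratio`` = NaN), not
    raised.
    """
    for tgt in ("TEL", "BG"):
        if tgt not in plate.targets():
            raise PlateFormatError(f"telomere plate missing target {tgt}")
    check_ntc(plate, ntc_cutoff_cq)
    curves = {tgt: fit_standard_curve(plate.standards(tgt), tgt) for tgt in ("TEL", "BG")}
    quantities = {
        tgt: _interpolated_replicates(plate, curves[tgt], sample_id) for tgt in ("TEL", "BG")
    }
    qc_t = replicate_qc(quantities["TEL"], f"{sample_id}:TEL", cv_threshold_pct)
    qc_s = replicate_qc(quantities["BG"], f"{sample_id}:BG", cv_threshold_pct)
    t_ng = float(np.median(quantities["TEL"]))
    s_ng = float(np.median(quantities["BG"]))
    valid = qc_t.accepted and qc_s.accepted
    return TSResult(
        sample_id=sample_id,
        t_ng=t_ng,
        s_ng=s_ng,
        ts_ratio=t_ng / s_ng if valid else math.nan,
        qc_t=qc_t,
        qc_s=qc_s,
        valid=valid,
    )


def quantify_excision_circles(
    plate: QpcrPlate,
    sample_id: str,
    blood_norm: BloodNormalization,
    cv_threshold_pct: float = CV_THRESHOLD_PCT,
    ntc_cutoff_cq: float = NTC_CONTAMINATION_CQ,
) -> ExcisionCircleResult:
    """TREC and KREC copies/ml of blood for one sample from a duplex plate.

    copies/ml = median accepted copies-per-reaction x cells_per_ml /
    cells_per_reaction.  A target whose replicate group fails QC reports an
    absent value (``None``) with a reason, never zero.
    """
    if blood_norm is None:
        raise ConfigurationError("blood normalization factors are required")
    for tgt in ("TREC", "KREC"):
        if tgt not in plate.targets():
            raise PlateFormatError(f"duplex plate missing target {tgt}")
    check_ntc(plate, ntc_cutoff_cq)
    values: dict[str, float | None] = {}
    qcs: dict[str, ReplicateQC] = {}
    reasons: dict[str, str] = {}
    for tgt in ("TREC", "KREC"):
        curve = fit_standard_curve(plate.standards(tgt), tgt)
        reps = _interpolated_replicates(plate, curve, sample_id)
        qc = replicate_qc(reps, f"{sample_id}:{tgt}", cv_threshold_pct)
        qcs[tgt] = qc
        if qc.accepted:
            values[tgt] = float(np.median(reps)) * blood_norm.factor
        else:
            values[tgt] = None
            reasons[tgt] = f"replicate CV {qc.cv_pct:.1f}% > {cv_threshold_pct}%"
    return ExcisionCircleResult(
        sample_id=sample_id,
        trec_copies_per_ml=values["TREC"],
        krec_copies_per_ml=values["KREC"],
        qc_trec=qcs["TREC"],
        qc_krec=qcs["KREC"],
        reasons=reasons,
    )


def plate_run_qc(plate: QpcrPlate) -> dict:
    """Run-level QC report: per-target slope, intercept, r², efficiency."""
    report = {}
    for tgt in sorted(plate.targets()):
        std = plate.standards(tgt)
        if len(std) >= 3:
            c = fit_standard_curve(std, tgt)
            report[tgt] = {
                "slope": c.slope,
                "intercept": c.intercept,
                "r2": c.r2,
                "efficiency_pct": c.efficiency_pct,
            }
    return report
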