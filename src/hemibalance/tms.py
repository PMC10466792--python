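"""Corticospinal-excitability asymmetry metrics from resting motor thresholds.

LI(RMT) = (RMT_AH - RMT_UH) / (RMT_AH + RMT_UH): positive values mean a higher
threshold (lower excitability) on the affected side, i.e. excitability is
lateralised to the unaffected hemisphere. The equivalent ratio R = RMT_AH /
RMT_UH and its one-month change d(R) = R2 - R1 stratify patients by which
hemisphere's excitability changed more during recovery: d(R) > 0 the
unaffected, d(R) < 0 the affected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .records import RMT_CEILING, TmsRecord, ValidationError, validate_tms

AH_DOMINANT = "AH_dominant"
UH_DOMINANT = "UH_dominant"


@dataclass
class RmtLaterality:
    subject_id: str
    timepoint: str
    li_rmt: float
    r_ratio: float


@dataclass
class DominanceGroup:
    subject_id: str
    d_r: float
    group: str | None   # AH_dominant (d_r < 0), UH_dominant (d_r > 0), None if 0


def _check_rmt(value: float, name: str) -> None:
    if not 0 < value <= RMT_CEILING:
        raise ValidationError(f"{name}={value} outside (0, {RMT_CEILING}] %MSO")


def li_rmt(rmt_ah: float, rmt_uh: float) -> float:
    """Laterality index of the resting motor threshold, in (-1, 1)."""
    _check_rmt(rmt_ah, "rmt_ah")
    _check_rmt(rmt_uh, "rmt_uh")
    return (rmt_ah - rmt_uh) / (rmt_ah + rmt_uh)


def r_ratio(rmt_ah: float, rmt_uh: float) -> float:
    """Interhemispheric threshold ratio R = RMT_AH / RMT_UH."""
    _check_rmt(rmt_ah, "rmt_ah")
    _check_rmt(rmt_uh, "rmt_uh")
    return rmt_ah / rmt_uh


def rmt_laterality(record: TmsRecord) -> RmtLaterality:
    """LI and ratio for one validated TMS record. The 110 %MSO no-MEP
    imputation feeds the formulas exactly like a measured threshold."""
    validate_tms(record)
    li = li_rmt(record.rmt_ah, record.rmt_uh)
    r = r_ratio(record.rmt_ah, record.rmt_uh)
    # algebraic identity linking the two parameterisations
    assert abs(li - (r - 1.0) / (r + 1.0)) < 1e-12
    return RmtLaterality(subject_id=record.subject_id,
                         timepoint=record.timepoint, li_rmt=li, r_ratio=r)


def classify_dominance(r1: float, r2: float,
                       subject_id: str = "") -> DominanceGroup:
    """Assign a subject to the hemisphere whose excitability changed more.

    d(R) = R2 - R1; a strictly positive value assigns the unaffected-dominant
    group, strictly negative the affected-dominant group. Exactly zero has no
    defined group: the subject is excluded from subgroup analyses.
    """
    d_r = r2 - r1
    if d_r > 0:
        group = UH_DOMINANT
    elif d_r < 0:
        group = AH_DOMINANT
    else:
        group = None
        warnings.warn(
            f"subject {subject_id or '?'}: d(R) is exactly 0; excluded from "
            "dominance subgroup analyses", stacklevel=2)
    return DominanceGroup(subject_id=subject_id, d_r=d_r, group=group)
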