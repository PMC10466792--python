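"""fNIRS activation laterality indices and the per-subject metric set.

LI(dHBO) = (dHBO_AH - dHBO_UH) / (|dHBO_AH| + |dHBO_UH|), bounded in [-1, 1];
the absolute values in the denominator keep it defined when the two activation
changes have opposite signs. Positive values mean activation lateralised to
the affected hemisphere, -1/+1 complete unaffected/affected dominance. The
index is computed for M1, SMA, PMC and the combined M1+SMA+PMC region (the
unweighted mean of the three ROI-level activations per hemisphere).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .preprocess import RoiActivation
from .records import HemibalanceError, ROIS, SubjectRecord
from .tms import RmtLaterality


class UndefinedLIError(HemibalanceError):
    """Both activation values are exactly zero: LI has no defined value."""


class JoinError(HemibalanceError):
    """Inputs to assemble() disagree on subject or timepoint."""


LI_METRICS = ("li_rmt", "li_m1", "li_sma", "li_pmc", "li_combined")


@dataclass
class LateralitySet:
    """All laterality metrics for one subject at one timepoint."""

    subject_id: str
    timepoint: str
    li_rmt: float | None = None
    li_m1: float | None = None
    li_sma: float | None = None
    li_pmc: float | None = None
    li_combined: float | None = None


def li_hbo(delta_ah: float, delta_uh: float) -> float:
    """Activation laterality index; errors if both inputs are exactly zero."""
    denom = abs(delta_ah) + abs(delta_uh)
    if denom == 0:
        raise UndefinedLIError("both dHBO values are zero; LI undefined")
    value = (delta_ah - delta_uh) / denom
    # |numerator| <= |a| + |b| guarantees the bound
    assert -1.0 <= value <= 1.0
    return value


def li_combined(activation: RoiActivation) -> float:
    """LI of the combined M1+SMA+PMC region: li_hbo of the across-ROI means."""
    for roi in ROIS:
        for hemi in ("AH", "UH"):
            if (roi, hemi) not in activation.values:
                raise KeyError(f"missing ROI value ({roi}, {hemi})")
    mean_ah = float(np.mean([activation.values[(r, "AH")] for r in ROIS]))
    mean_uh = float(np.mean([activation.values[(r, "UH")] for r in ROIS]))
    return li_hbo(mean_ah, mean_uh)


def assemble(subject: SubjectRecord,
             activation: RoiActivation | None,
             rmt: RmtLaterality | None,
             timepoint: str | None = None) -> LateralitySet:
    """Join the fNIRS and TMS laterality metrics of one subject/timepoint.

    A missing ROI leaves that LI (and the combined LI) as None; the others
    stay intact. Subject/timepoint mismatches raise :class:`JoinError`.
    """
    sources = [s for s in (activation, rmt) if s is not None]
    if not sources:
        raise JoinError("assemble() needs at least one of activation and rmt")
    tp = timepoint or sources[0].timepoint
    for s in sources:
        if s.subject_id != subject.subject_id:
            raise JoinError(
                f"subject mismatch: {s.subject_id} vs {subject.subject_id}")
        if s.timepoint != tp:
            raise JoinError(
                f"timepoint mismatch for {subject.subject_id}: "
                f"{s.timepoint} vs {tp}")
    out = LateralitySet(subject_id=subject.subject_id, timepoint=tp)
    if rmt is not None:
        out.li_rmt = rmt.li_rmt
    if activation is not None:
        for roi, attr in (("M1", "li_m1"), ("SMA", "li_sma"), ("PMC", "li_pmc")):
            pair = (activation.values.get((roi, "AH")),
                    activation.values.get((roi, "UH")))
            if pair[0] is not None and pair[1] is not None:
                setattr(out, attr, li_hbo(*pair))
        if all((r, h) in activation.values for r in ROIS for h in ("AH", "UH")):
            out.li_combined = li_combined(activation)
    return out


def laterality_frame(sets: Iterable[LateralitySet]) -> pd.DataFrame:
    """Long table (subject_id, timepoint, li_*) from laterality sets."""
    rows = [{
        "subject_id": s.subject_id, "timepoint": s.timepoint,
        **{m: getattr(s, m) for m in LI_METRICS},
    } for s in sets]
    return pd.DataFrame(rows, columns=["subject_id", "timepoint", *LI_METRICS])


def write_laterality(sets: Iterable[LateralitySet], path: str | Path) -> None:
    laterality_frame(sets).to_csv(path, index=False)


def read_laterality(path: str | Path) -> list[LateralitySet]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        kwargs = {m: (None if pd.isna(row[m]) else float(row[m]))
                  for m in LI_METRICS}
        out.append(LateralitySet(subject_id=str(row["subject_id"]),
                                 timepoint=str(row["timepoint"]), **kwargs))
    return out
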