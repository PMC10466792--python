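"""End-to-end orchestration: recordings + TMS + scores -> analysis report."""

from __future__ import annotations

import pandas as pd

from .laterality import LI_METRICS, LateralitySet, assemble, laterality_frame
from .preprocess import PipelineConfig, RoiActivation, preprocess_recording
from .records import AnalysisError, SubjectRecord, TmsRecord
from .simulate import Study
from .stats import (
    AnalysisReport,
    correlation_matrix,
    mean_split_groups,
    paired_change,
    subgroup_correlations,
)
from .tms import DominanceGroup, classify_dominance, rmt_laterality


def dominance_from_tms(tms_records: list[TmsRecord]) -> list[DominanceGroup]:
    """d(R)-based hemispheric-dominance assignment per subject."""
    ratios: dict[str, dict[str, float]] = {}
    for rec in tms_records:
        ratios.setdefault(rec.subject_id, {})[rec.timepoint] = \
            rmt_laterality(rec).r_ratio
    out = []
    for sid, r in ratios.items():
        if "T1" in r and "T2" in r:
            out.append(classify_dominance(r["T1"], r["T2"], subject_id=sid))
    return out


def laterality_sets(subjects: list[SubjectRecord],
                    tms_records: list[TmsRecord],
                    activations: dict[tuple[str, str], RoiActivation],
                    ) -> list[LateralitySet]:
    """Assemble one LateralitySet per subject/timepoint from the modalities."""
    by_subject = {s.subject_id: s for s in subjects}
    tms_by_key = {(r.subject_id, r.timepoint): r for r in tms_records}
    sets = []
    keys = sorted(set(tms_by_key) | set(activations),
                  key=lambda k: (int(k[0]) if k[0].isdigit() else k[0], k[1]))
    for sid, tp in keys:
        if sid not in by_subject:
            raise AnalysisError(f"no subject record for id {sid}")
        tms = tms_by_key.get((sid, tp))
        act = activations.get((sid, tp))
        rmt = rmt_laterality(tms) if tms is not None else None
        sets.append(assemble(by_subject[sid], act, rmt, timepoint=tp))
    return sets


def wide_table(subjects: list[SubjectRecord],
               sets: list[LateralitySet]) -> pd.DataFrame:
    """One row per subject: clinical scores plus li_*_t1/li_*_t2 columns."""
    long = laterality_frame(sets)
    wide = long.pivot(index="subject_id", columns="timepoint",
                      values=list(LI_METRICS))
    wide.columns = [f"{metric}_{tp.lower()}" for metric, tp in wide.columns]
    wide = wide.reset_index()
    clin = pd.DataFrame([{
        "subject_id": s.subject_id,
        "fma_ue_t1": s.fma_ue_t1, "fma_ue_t2": s.fma_ue_t2,
        "fma_d_t1": s.fma_d_t1, "fma_d_t2": s.fma_d_t2,
        "fma_p_t1": s.fma_p_t1, "fma_p_t2": s.fma_p_t2,
    } for s in subjects])
    wide["subject_id"] = wide["subject_id"].astype(str)
    clin["subject_id"] = clin["subject_id"].astype(str)
    return clin.merge(wide, on="subject_id", how="outer")


def analyze_table(df: pd.DataFrame,
                  dominance: list[DominanceGroup] | None = None,
                  ) -> AnalysisReport:
    """Run the full statistical battery on a wide per-subject table."""
    report = AnalysisReport()
    for var in ("fma_ue", "fma_d", "fma_p"):
        c1, c2 = f"{var}_t1", f"{var}_t2"
        if c1 in df.columns and c2 in df.columns \
                and df[c1].notna().sum() >= 3 and df[c2].notna().sum() >= 3:
            report.paired.append(paired_change(df[c1], df[c2], variable=var))
    report.correlations = correlation_matrix(df)
    try:
        report.mean_split = mean_split_groups(df)
    except AnalysisError:
        report.mean_split = None
    if dominance:
        report.subgroups = subgroup_correlations(dominance, df)
    return report


def truth_activations(study: Study) -> dict[tuple[str, str], RoiActivation]:
    """ROI activations taken directly from the generating truth (bypasses the
    raw signal chain; used for score-level simulations)."""
    out = {}
    for t in study.truth:
        for tp in ("T1", "T2"):
            out[(t.subject_id, tp)] = RoiActivation(
                subject_id=t.subject_id, timepoint=tp,
                values=dict(t.amplitudes[tp]),
                n_channels={k: 1 for k in t.amplitudes[tp]})
    return out


def pipeline_activations(study: Study,
                         config: PipelineConfig | None = None,
                         ) -> dict[tuple[str, str], RoiActivation]:
    """ROI activations recovered from the raw recordings via the full chain."""
    config = config or PipelineConfig()
    by_subject = {s.subject_id: s for s in study.subjects}
    out = {}
    for (sid, tp), rec in study.recordings.items():
        out[(sid, tp)] = preprocess_recording(
            rec, by_subject[sid], config, study.config.paradigm)
    return out


def analyze_study(study: Study, from_raw: bool | None = None,
                  pipeline_config: PipelineConfig | None = None,
                  ) -> AnalysisReport:
    """Full analysis of a synthetic study.

    ``from_raw=True`` runs the fNIRS signal chain on the raw recordings;
    ``False`` uses the generating truth activations. Default: raw if the
    study carries recordings.
    """
    if from_raw is None:
        from_raw = bool(study.recordings)
    activations = (pipeline_activations(study, pipeline_config) if from_raw
                   else truth_activations(study))
    sets = laterality_sets(study.subjects, study.tms_records, activations)
    df = wide_table(study.subjects, sets)
    dominance = dominance_from_tms(study.tms_records)
    return analyze_table(df, dominance)
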