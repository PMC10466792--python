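"""Domain records and file I/O for a multimodal stroke motor-recovery study.

The study combines three measurement modalities per patient and timepoint:

* a clinical table (demographics, lesion side, Barthel Index, upper-extremity
  Fugl-Meyer scores FMA-UE with distal/proximal sub-scores FMA-d / FMA-p),
* task-block fNIRS recordings (two-wavelength raw intensities over a 26-channel
  bilateral sensorimotor montage), and
* TMS resting motor thresholds (RMT, %MSO) of both hemispheres.

This module defines the record types, their validation rules, and plain-text
readers/writers: cohort CSV, montage JSON, TMS CSV, and a two-file recording
container (YAML metadata sidecar + long-format CSV intensity table).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

TIMEPOINTS = ("T1", "T2")
ROIS = ("M1", "SMA", "PMC")
HEMISPHERES = ("L", "R")
WAVELENGTHS_NM = (730.0, 850.0)
N_CHANNELS = 26
N_SOURCES = 14
N_DETECTORS = 8
FMA_UE_MAX = 66
RMT_CEILING = 110.0  # %MSO assigned when no MEP can be elicited

COHORT_COLUMNS = (
    "subject_id", "sex", "age", "stroke_type", "affected_hemisphere",
    "stroke_duration_days", "barthel",
    "fma_ue_t1", "fma_ue_t2", "fma_d_t1", "fma_d_t2", "fma_p_t1", "fma_p_t2",
)
# FMA columns beyond the baseline total are optional at read time; operations
# needing them fail late with a named-field error.
COHORT_REQUIRED = COHORT_COLUMNS[:8]


class HemibalanceError(Exception):
    """Base class for all package errors."""


class FormatError(HemibalanceError):
    """A file does not follow the documented container format."""


class ValidationError(HemibalanceError):
    """A record violates a domain invariant."""


class ParadigmError(HemibalanceError):
    """Task marks are inconsistent with the block paradigm."""


class MontageError(HemibalanceError):
    """The channel montage violates its invariants."""


class DataError(HemibalanceError):
    """Signal data are unusable (e.g. non-positive intensities)."""


class ConfigurationError(HemibalanceError):
    """Invalid analysis parameters."""


class MissingRoiError(HemibalanceError):
    """No usable channel remains for a required ROI/hemisphere."""


class AnalysisError(HemibalanceError):
    """A statistical analysis cannot be carried out on these inputs."""


@dataclass(frozen=True)
class BlockParadigm:
    """Grasping-task block design: alternating task and rest blocks.

    Defaults follow the acquisition protocol: three 25 s task blocks
    separated by 30 s rests, with the 5 s immediately before each task
    onset used as the hemodynamic baseline.
    """

    n_blocks: int = 3
    task_s: float = 25.0
    rest_s: float = 30.0
    baseline_window_s: float = 5.0

    def __post_init__(self) -> None:
        for name in ("task_s", "rest_s", "baseline_window_s"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"BlockParadigm.{name} must be > 0")
        if self.n_blocks < 1:
            raise ValidationError("BlockParadigm.n_blocks must be >= 1")

    def duration_s(self) -> float:
        """Total recording length: leading rest then alternating task/rest."""
        return self.rest_s + self.n_blocks * (self.task_s + self.rest_s)


@dataclass
class SubjectRecord:
    """One patient's demographics, lesion side and clinical scores."""

    subject_id: str
    sex: str                      # {"F", "M"}
    age: int                      # years
    stroke_type: str              # {"infarction", "hemorrhage"}
    affected_hemisphere: str      # {"L", "R"}
    stroke_duration_days: int
    barthel: int | None = None    # Barthel Index, 0-100
    fma_ue_t1: float | None = None
    fma_ue_t2: float | None = None
    fma_d_t1: float | None = None
    fma_d_t2: float | None = None
    fma_p_t1: float | None = None
    fma_p_t2: float | None = None

    def fma(self, measure: str, timepoint: str) -> float:
        """Return a score, failing late with the field name if absent."""
        key = f"{measure}_{timepoint.lower()}"
        value = getattr(self, key)
        if value is None:
            raise ValidationError(
                f"subject {self.subject_id}: required score '{key}' is missing")
        return value

    def validate(self) -> "SubjectRecord":
        sid = self.subject_id
        if self.sex not in ("F", "M"):
            raise ValidationError(f"subject {sid}: sex must be F or M")
        if self.stroke_type not in ("infarction", "hemorrhage"):
            raise ValidationError(
                f"subject {sid}: stroke_type must be infarction or hemorrhage")
        if self.affected_hemisphere not in HEMISPHERES:
            raise ValidationError(
                f"subject {sid}: affected_hemisphere must be L or R")
        if self.stroke_duration_days < 0:
            raise ValidationError(f"subject {sid}: stroke duration < 0 days")
        if self.barthel is not None and not 0 <= self.barthel <= 100:
            raise ValidationError(f"subject {sid}: Barthel outside 0-100")
        if not 30 <= self.age <= 80:
            # inclusion criterion; tolerated with a warning
            warnings.warn(
                f"subject {sid}: age {self.age} outside the 30-80 inclusion range",
                stacklevel=2)
        for tp in ("t1", "t2"):
            ue = getattr(self, f"fma_ue_{tp}")
            d = getattr(self, f"fma_d_{tp}")
            p = getattr(self, f"fma_p_{tp}")
            if ue is not None and not 0 <= ue <= FMA_UE_MAX:
                raise ValidationError(
                    f"subject {sid}: fma_ue_{tp}={ue} outside 0-{FMA_UE_MAX}")
            if ue is not None and d is not None and p is not None:
                if abs((d + p) - ue) > 1e-9:
                    raise ValidationError(
                        f"subject {sid}: fma_d_{tp} + fma_p_{tp} != fma_ue_{tp}")
        return self


@dataclass
class TmsRecord:
    """Per-hemisphere resting motor threshold (%MSO) at one timepoint.

    A hemisphere where no MEP could be elicited carries the conventional
    ceiling value RMT = 110 %MSO with its ``mep_present`` flag cleared.
    """

    subject_id: str
    timepoint: str
    rmt_ah: float
    rmt_uh: float
    mep_present_ah: bool = True
    mep_present_uh: bool = True


def validate_tms(record: TmsRecord) -> TmsRecord:
    """Check RMT ranges and enforce the no-MEP ceiling convention."""
    sid, tp = record.subject_id, record.timepoint
    if tp not in TIMEPOINTS:
        raise ValidationError(f"TMS {sid}: timepoint must be one of {TIMEPOINTS}")
    for side in ("ah", "uh"):
        rmt = getattr(record, f"rmt_{side}")
        present = getattr(record, f"mep_present_{side}")
        if not 0 < rmt <= RMT_CEILING:
            raise ValidationError(
                f"TMS {sid}/{tp}: rmt_{side}={rmt} outside (0, {RMT_CEILING}]")
        if not present and rmt != RMT_CEILING:
            raise ValidationError(
                f"TMS {sid}/{tp}: mep_present_{side}=False requires "
                f"rmt_{side}={RMT_CEILING}, got {rmt}")
    return record


@dataclass(frozen=True)
class MontageChannel:
    channel_id: int
    source_id: int
    detector_id: int
    hemisphere: str          # {"L", "R"}
    roi: str                 # {"M1", "SMA", "PMC", "none"}
    separation_mm: float = 30.0


@dataclass
class Montage:
    """26-channel bilateral montage mapping channels to hemisphere and ROI."""

    channels: list[MontageChannel]

    def validate(self) -> "Montage":
        if len(self.channels) != N_CHANNELS:
            raise MontageError(
                f"montage must have exactly {N_CHANNELS} channels, "
                f"got {len(self.channels)}")
        ids = [c.channel_id for c in self.channels]
        if sorted(ids) != list(range(1, N_CHANNELS + 1)):
            raise MontageError("channel_id values must be 1..26 without gaps")
        for ch in self.channels:
            if not 1 <= ch.source_id <= N_SOURCES:
                raise MontageError(f"channel {ch.channel_id}: source_id outside 1..{N_SOURCES}")
            if not 1 <= ch.detector_id <= N_DETECTORS:
                raise MontageError(f"channel {ch.channel_id}: detector_id outside 1..{N_DETECTORS}")
            if ch.hemisphere not in HEMISPHERES:
                raise MontageError(f"channel {ch.channel_id}: hemisphere must be L or R")
            if ch.roi not in ROIS + ("none",):
                raise MontageError(f"channel {ch.channel_id}: unknown roi {ch.roi!r}")
            if ch.separation_mm <= 0:
                raise MontageError(f"channel {ch.channel_id}: separation must be > 0 mm")
        for roi in ROIS + ("none",):
            n_l = len(self.channel_indices(roi=roi, hemisphere="L"))
            n_r = len(self.channel_indices(roi=roi, hemisphere="R"))
            if roi in ROIS and (n_l == 0 or n_r == 0):
                raise MontageError(f"ROI {roi} must have >= 1 channel on each hemisphere")
            if n_l != n_r:
                raise MontageError(
                    f"ROI {roi} channel counts differ across the midline ({n_l} L vs {n_r} R)")
        return self

    def channel_indices(self, roi: str | None = None,
                        hemisphere: str | None = None) -> list[int]:
        """0-based positions (in montage order) matching the given ROI/side."""
        out = []
        for i, ch in enumerate(self.channels):
            if roi is not None and ch.roi != roi:
                continue
            if hemisphere is not None and ch.hemisphere != hemisphere:
                continue
            out.append(i)
        return out

    def separations_mm(self) -> np.ndarray:
        return np.array([c.separation_mm for c in self.channels], dtype=float)


def default_montage(separation_mm: float = 30.0) -> Montage:
    """Symmetric bilateral sensorimotor montage: per hemisphere 4 M1, 3 SMA,
    3 PMC and 3 unassigned channels (13 per side, 26 total)."""
    plan = ["M1"] * 4 + ["SMA"] * 3 + ["PMC"] * 3 + ["none"] * 3
    channels: list[MontageChannel] = []
    cid = 1
    for hemi, src0, det0 in (("L", 0, 0), ("R", 7, 4)):
        for k, roi in enumerate(plan):
            channels.append(MontageChannel(
                channel_id=cid,
                source_id=src0 + (k % 7) + 1,
                detector_id=det0 + (k % 4) + 1,
                hemisphere=hemi,
                roi=roi,
                separation_mm=separation_mm,
            ))
            cid += 1
    return Montage(channels).validate()


@dataclass
class FnirsRecording:
    """Raw two-wavelength detector intensities for one subject/timepoint.

    ``intensities`` has shape (n_channels, n_wavelengths, n_samples) and must
    be strictly positive wherever it feeds optical-density conversion.
    ``marks`` lists (block_index, task_onset_sample, task_offset_sample).
    """

    subject_id: str
    timepoint: str
    sampling_rate: float
    intensities: np.ndarray
    marks: list[tuple[int, int, int]]
    montage: Montage
    wavelengths_nm: tuple[float, float] = WAVELENGTHS_NM

    def validate(self, paradigm: BlockParadigm | None = None) -> "FnirsRecording":
        paradigm = paradigm or BlockParadigm()
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be > 0")
        self.montage.validate()
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 3 or arr.shape[0] != len(self.montage.channels) \
                or arr.shape[1] != len(self.wavelengths_nm):
            raise FormatError(
                "intensities must have shape (n_channels, n_wavelengths, n_samples) "
                f"matching the montage; got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise DataError("intensities contain non-finite values")
        if np.any(arr <= 0):
            ch, wl, t = np.argwhere(arr <= 0)[0]
            raise DataError(
                f"non-positive intensity at channel {self.montage.channels[ch].channel_id}, "
                f"wavelength index {wl}, sample {t}")
        if len(self.marks) != paradigm.n_blocks:
            raise ParadigmError(
                f"expected {paradigm.n_blocks} task marks, got {len(self.marks)}")
        task_n = self.sampling_rate * paradigm.task_s
        rest_n = self.sampling_rate * paradigm.rest_s
        marks = sorted(self.marks, key=lambda m: m[1])
        for k, (block, onset, offset) in enumerate(marks):
            if not 0 <= onset < offset <= arr.shape[2]:
                raise ParadigmError(f"mark {block}: samples outside the recording")
            if abs((offset - onset) - task_n) > 1.0:
                raise ParadigmError(
                    f"mark {block}: task length {offset - onset} samples, "
                    f"expected {task_n:.1f} +/- 1")
            if k > 0:
                gap = onset - marks[k - 1][2]
                if abs(gap - rest_n) > 1.0:
                    raise ParadigmError(
                        f"mark {block}: inter-task rest {gap} samples, "
                        f"expected {rest_n:.1f} +/- 1")
        return self

    @property
    def n_samples(self) -> int:
        return int(np.asarray(self.intensities).shape[2])


# ---------------------------------------------------------------------------
# cohort CSV


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)


def read_cohort(path: str | Path) -> list[SubjectRecord]:
    """Read the cohort clinical table (one row per patient)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"cohort file {path}: missing column(s) {', '.join(missing)}")
    records = []
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        try:
            rec = SubjectRecord(
                subject_id=sid,
                sex=str(row["sex"]).strip(),
                age=int(row["age"]),
                stroke_type=str(row["stroke_type"]).strip().lower(),
                affected_hemisphere=str(row["affected_hemisphere"]).strip().upper(),
                stroke_duration_days=int(row["stroke_duration_days"]),
                barthel=None if _opt_float(row.get("barthel")) is None
                else int(float(row["barthel"])),
                **{c: _opt_float(row.get(c)) for c in COHORT_COLUMNS[7:]},
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"cohort row {sid}: {exc}") from exc
        records.append(rec.validate())
    return records


def write_cohort(records: Iterable[SubjectRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({c: getattr(r, c) for c in COHORT_COLUMNS})
    pd.DataFrame(rows, columns=list(COHORT_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# TMS CSV

TMS_COLUMNS = ("subject_id", "timepoint", "rmt_ah", "rmt_uh",
               "mep_present_ah", "mep_present_uh")


def read_tms(path: str | Path) -> list[TmsRecord]:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in TMS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"TMS file {path}: missing column(s) {', '.join(missing)}")
    out = []
    for _, row in df.iterrows():
        rec = TmsRecord(
            subject_id=str(row["subject_id"]),
            timepoint=str(row["timepoint"]),
            rmt_ah=float(row["rmt_ah"]),
            rmt_uh=float(row["rmt_uh"]),
            mep_present_ah=str(row["mep_present_ah"]).strip().lower() == "true",
            mep_present_uh=str(row["mep_present_uh"]).strip().lower() == "true",
        )
        out.append(validate_tms(rec))
    return out


def write_tms(records: Iterable[TmsRecord], path: str | Path) -> None:
    rows = [{c: getattr(r, c) for c in TMS_COLUMNS} for r in records]
    pd.DataFrame(rows, columns=list(TMS_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# montage JSON


def read_montage(path: str | Path) -> Montage:
    with open(path) as fh:
        payload = json.load(fh)
    if "channels" not in payload:
        raise FormatError(f"montage file {path}: missing 'channels' key")
    channels = [MontageChannel(**ch) for ch in payload["channels"]]
    return Montage(channels).validate()


def write_montage(montage: Montage, path: str | Path) -> None:
    payload = {"channels": [dict(
        channel_id=ch.channel_id, source_id=ch.source_id,
        detector_id=ch.detector_id, hemisphere=ch.hemisphere,
        roi=ch.roi, separation_mm=ch.separation_mm)
        for ch in montage.channels]}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# recording container: YAML sidecar + long-format CSV


def write_recording(recording: FnirsRecording, basepath: str | Path) -> None:
    """Write ``<base>.meta.yaml`` + ``<base>.csv`` (channel/wavelength/time)."""
    base = Path(basepath)
    meta = {
        "subject_id": recording.subject_id,
        "timepoint": recording.timepoint,
        "sampling_rate_hz": float(recording.sampling_rate),
        "wavelengths_nm": [float(w) for w in recording.wavelengths_nm],
        "marks": [[int(b), int(on), int(off)] for b, on, off in recording.marks],
        "n_samples": recording.n_samples,
    }
    with open(base.with_suffix(".meta.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    arr = np.asarray(recording.intensities, dtype=float)
    n_ch, n_wl, n_t = arr.shape
    chan_ids = np.repeat([c.channel_id for c in recording.montage.channels], n_wl * n_t)
    wls = np.tile(np.repeat(recording.wavelengths_nm, n_t), n_ch)
    samples = np.tile(np.arange(n_t), n_ch * n_wl)
    df = pd.DataFrame({
        "channel_id": chan_ids,
        "wavelength_nm": wls,
        "sample": samples,
        "intensity": arr.reshape(-1),
    })
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(base.with_suffix(".csv"), index=False, float_format="%.17g")


def read_recording(basepath: str | Path, montage: Montage,
                   paradigm: BlockParadigm | None = None) -> FnirsRecording:
    """Read a recording written by :func:`write_recording`."""
    base = Path(basepath)
    meta_path = base.with_suffix(".meta.yaml")
    if not meta_path.exists():
        raise FormatError(f"missing metadata sidecar {meta_path}")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    for key in ("subject_id", "timepoint", "sampling_rate_hz",
                "wavelengths_nm", "marks", "n_samples"):
        if key not in meta:
            raise FormatError(f"{meta_path}: missing key '{key}'")
    df = pd.read_csv(base.with_suffix(".csv"), float_precision="round_trip")
    montage.validate()
    wavelengths = tuple(float(w) for w in meta["wavelengths_nm"])
    n_t = int(meta["n_samples"])
    n_ch = len(montage.channels)
    arr = np.empty((n_ch, len(wavelengths), n_t), dtype=float)
    arr.fill(np.nan)
    order = {c.channel_id: i for i, c in enumerate(montage.channels)}
    wl_order = {w: j for j, w in enumerate(wavelengths)}
    unknown = set(df["channel_id"].unique()) - set(order)
    if unknown:
        raise MontageError(f"recording channels {sorted(unknown)} not in montage")
    for (cid, wl), grp in df.groupby(["channel_id", "wavelength_nm"], sort=False):
        grp = grp.sort_values("sample")
        if len(grp) != n_t:
            raise FormatError(
                f"channel {cid} @ {wl} nm: {len(grp)} samples, expected {n_t}")
        arr[order[int(cid)], wl_order[float(wl)]] = grp["intensity"].to_numpy()
    if np.isnan(arr).any():
        raise FormatError("recording table does not cover every channel/wavelength")
    rec = FnirsRecording(
        subject_id=str(meta["subject_id"]),
        timepoint=str(meta["timepoint"]),
        sampling_rate=float(meta["sampling_rate_hz"]),
        intensities=arr,
        marks=[tuple(int(v) for v in m) for m in meta["marks"]],
        montage=montage,
        wavelengths_nm=wavelengths,
    )
    return rec.validate(paradigm)


def table1_cohort_path() -> Path:
    """Path of the bundled clinical table of the 31-patient cohort."""
    return Path(__file__).parent / "data" / "table1_cohort.csv"
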