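"""Synthetic multimodal studies with known ground truth.

Generates complete desk-scale studies — raw two-wavelength fNIRS recordings,
per-hemisphere TMS resting motor thresholds, and clinical scores — with a
planted lateralization-outcome structure, so the whole pipeline (signal chain,
laterality indices, statistical battery) can be exercised end to end and
checked against the generating truth.

The forward model mirrors the acquisition: a 26-channel bilateral montage at
11 Hz, 730/850 nm, three 25 s grasp blocks separated by 30 s rests. Each
channel's haemoglobin course is a canonical double-gamma HRF convolved with
the task boxcar, scaled by the channel ROI's true per-hemisphere amplitude;
the modified Beer-Lambert forward model maps it to optical density, and
physiological noise (cardiac ~1.1 Hz, respiratory ~0.25 Hz, Mayer waves,
drift, white noise, occasional motion spikes) is added before converting to
detector intensities.

Outcome scores follow
    FMA-UE(T2) = FMA-UE(T1) + gain - beta_rmt * LI-RMT(T1)
                 - beta_sma * LI-SMA(T1) [+ subgroup PMC coupling] + noise,
clipped to [0, 66], so the planted correlations between baseline laterality
and one-month outcome are negative, and a positive LI-PMC(T2) coupling exists
only inside the d(R) > 0 stratum.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .laterality import li_hbo
from .records import (
    BlockParadigm,
    FnirsRecording,
    Montage,
    RMT_CEILING,
    ROIS,
    SubjectRecord,
    TmsRecord,
    default_montage,
    write_cohort,
    write_montage,
    write_recording,
    write_tms,
)
from .preprocess import DEFAULT_EXTINCTION
from .tms import li_rmt as li_rmt_formula
from .tms import r_ratio as r_ratio_formula

_SEED_MOD = 2**31 - 1


@dataclass
class NoiseConfig:
    """Additive optical-density noise, amplitudes in OD units."""

    cardiac_hz: float = 1.1
    cardiac_od: float = 0.008
    respiratory_hz: float = 0.25
    respiratory_od: float = 0.006
    mayer_hz: float = 0.09
    mayer_od: float = 0.002
    drift_od: float = 0.01          # total linear drift over the recording
    white_od_sd: float = 0.003
    spike_rate_hz: float = 0.01     # expected motion spikes per second
    spike_od: float = 0.05

    def silent(self) -> "NoiseConfig":
        return NoiseConfig(cardiac_od=0.0, respiratory_od=0.0, mayer_od=0.0,
                           drift_od=0.0, white_od_sd=0.0, spike_rate_hz=0.0,
                           spike_od=0.0)


@dataclass
class EffectConfig:
    """Planted couplings between baseline laterality and outcome."""

    beta_rmt: float = 55.0          # FMA points per unit LI-RMT(T1)
    beta_sma: float = 18.0          # FMA points per unit LI-SMA(T1)
    beta_pmc_subgroup: float = 32.0  # d(R)>0 stratum only, per unit LI-PMC(T2)
    gain_mean: float = 6.0          # spontaneous one-month improvement
    gain_sd: float = 4.0
    score_noise_sd: float = 0.0     # extra outcome noise beyond gain_sd
    sma_rmt_rho: float = 0.0        # planted corr(LI-SMA(T1), LI-RMT asymmetry)

    def null(self) -> "EffectConfig":
        return EffectConfig(beta_rmt=0.0, beta_sma=0.0, beta_pmc_subgroup=0.0,
                            gain_mean=self.gain_mean, gain_sd=self.gain_sd,
                            score_noise_sd=self.score_noise_sd,
                            sma_rmt_rho=0.0)


@dataclass
class SimulationConfig:
    n_subjects: int = 31
    sampling_rate: float = 11.0
    wavelengths_nm: tuple[float, float] = (730.0, 850.0)
    paradigm: BlockParadigm = field(default_factory=BlockParadigm)
    # hemodynamics
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    hrf_undershoot_ratio: float = 1.0 / 6.0
    hbr_ratio: float = 1.0 / 3.0            # dHbR = -ratio * dHbO
    base_amplitude_um: dict[str, float] = field(
        default_factory=lambda: {"M1": 0.6, "SMA": 0.5, "PMC": 0.4})
    li_range: float = 0.8                   # true fNIRS LIs ~ U(-range, range)
    dpf: float = 6.0
    extinction: dict[float, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EXTINCTION))
    source_intensity: float = 1000.0
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    effects: EffectConfig = field(default_factory=EffectConfig)
    # TMS
    no_mep_frac_t1: float = 20 / 31
    no_mep_frac_t2: float = 19 / 31
    rmt_uh_mean: float = 50.0
    rmt_uh_sd: float = 6.0

    def validate(self) -> "SimulationConfig":
        assert self.n_subjects >= 1 and self.sampling_rate > 0
        assert all(a >= 0 for a in self.base_amplitude_um.values())
        assert 0 <= self.li_range <= 1
        assert 0 <= self.no_mep_frac_t1 <= 1 and 0 <= self.no_mep_frac_t2 <= 1
        return self


@dataclass
class SubjectTruth:
    """Generating values for one subject: the recovery oracle."""

    subject_id: str
    affected_hemisphere: str
    severity: float
    rmt: dict[str, tuple[float, float, bool]]    # tp -> (ah, uh, capped)
    li_rmt: dict[str, float]
    r_ratio: dict[str, float]
    d_r: float
    li_fnirs: dict[str, dict[str, float]]        # tp -> {roi or "combined": li}
    amplitudes: dict[str, dict[tuple[str, str], float]]  # tp -> (roi, AH/UH) -> uM
    fma: dict[str, float]

    def check_identities(self) -> None:
        """True LI values must obey the defining formulas exactly."""
        for tp, (ah, uh, _c) in self.rmt.items():
            assert abs(self.li_rmt[tp] - li_rmt_formula(ah, uh)) < 1e-12
            assert abs(self.r_ratio[tp] - r_ratio_formula(ah, uh)) < 1e-12
        for tp, amps in self.amplitudes.items():
            for roi in ROIS:
                if (amps[(roi, "AH")], amps[(roi, "UH")]) == (0.0, 0.0):
                    continue
                li = li_hbo(amps[(roi, "AH")], amps[(roi, "UH")])
                assert abs(li - self.li_fnirs[tp][roi]) < 1e-9
            mean_ah = float(np.mean([amps[(r, "AH")] for r in ROIS]))
            mean_uh = float(np.mean([amps[(r, "UH")] for r in ROIS]))
            if (mean_ah, mean_uh) != (0.0, 0.0):
                assert abs(li_hbo(mean_ah, mean_uh)
                           - self.li_fnirs[tp]["combined"]) < 1e-9


@dataclass
class Study:
    config: SimulationConfig
    montage: Montage
    subjects: list[SubjectRecord]
    tms_records: list[TmsRecord]
    truth: list[SubjectTruth]
    recordings: dict[tuple[str, str], FnirsRecording] = field(default_factory=dict)


def double_gamma_hrf(t: np.ndarray, peak_s: float = 6.0,
                     undershoot_s: float = 16.0,
                     undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic impulse response (unit area of the
    positive lobe before the undershoot is subtracted)."""
    from scipy.stats import gamma
    h = (gamma.pdf(t, peak_s, scale=1.0)
         - undershoot_ratio * gamma.pdf(t, undershoot_s, scale=1.0))
    return h


def task_response(n_samples: int, fs: float, marks, paradigm: BlockParadigm,
                  config: SimulationConfig | None = None) -> np.ndarray:
    """HRF-convolved task boxcar, normalised to unit plateau."""
    config = config or SimulationConfig()
    box = np.zeros(n_samples)
    for _b, onset, offset in marks:
        box[onset:offset] = 1.0
    t = np.arange(0, 32.0, 1.0 / fs)
    kernel = double_gamma_hrf(t, config.hrf_peak_s, config.hrf_undershoot_s,
                              config.hrf_undershoot_ratio) / fs
    resp = np.convolve(box, kernel)[:n_samples]
    # unit plateau: a sustained task tends to kernel area
    area = kernel.sum()
    return resp / area if area != 0 else resp


def expected_delta_hbo_factor(config: SimulationConfig | None = None,
                              filtered: bool = False) -> float:
    """Expected measured dHBO per unit plateau amplitude under the paradigm.

    Numerically integrates the same HRF-convolved block waveform the generator
    emits: block-averages the three epochs and takes the task-window mean
    minus the pre-onset baseline mean. The canonical HRF's slow rise makes
    this factor ~0.84 (~0.83 through the analysis band-pass), the systematic
    shape factor linking plateau amplitude to the task-minus-baseline measure.
    """
    config = config or SimulationConfig()
    fs = config.sampling_rate
    paradigm = config.paradigm
    n_t = int(round(paradigm.duration_s() * fs))
    marks = paradigm_marks(paradigm, fs)
    resp = task_response(n_t, fs, marks, paradigm, config)
    if filtered:
        from .preprocess import OpticalDensitySeries, bandpass
        wrapped = OpticalDensitySeries(
            data=resp[np.newaxis, np.newaxis, :], sampling_rate=fs,
            wavelengths_nm=config.wavelengths_nm,
            separations_mm=np.array([30.0]))
        resp = bandpass(wrapped).data[0, 0]
    n_base = int(round(paradigm.baseline_window_s * fs))
    n_task = int(round(paradigm.task_s * fs))
    epochs = [resp[on - n_base:on + n_task] for _b, on, _off in marks]
    mean = np.mean(epochs, axis=0)
    return float(mean[n_base:].mean() - mean[:n_base].mean())


def paradigm_marks(paradigm: BlockParadigm, fs: float) -> list[tuple[int, int, int]]:
    """(block, onset, offset) sample marks: leading rest, then task/rest."""
    marks = []
    task_n = int(round(paradigm.task_s * fs))
    for b in range(paradigm.n_blocks):
        onset_s = paradigm.rest_s + b * (paradigm.task_s + paradigm.rest_s)
        onset = int(round(onset_s * fs))
        marks.append((b + 1, onset, onset + task_n))
    return marks


def _sub_rng(seed: int, *keys: int) -> np.random.Generator:
    derived = seed % _SEED_MOD
    for k in keys:
        derived = (derived * 1_000_003 + k + 1) % _SEED_MOD
    return np.random.default_rng(derived)


def simulate_truth(config: SimulationConfig, seed: int) -> list[SubjectTruth]:
    """Draw the per-subject generating quantities (no raw signals yet)."""
    config.validate()
    rng = _sub_rng(seed, 0)
    n = config.n_subjects
    eff = config.effects
    severity = rng.uniform(0.0, 1.0, size=n)
    order = np.argsort(-severity)             # most severe first
    n_cap1 = int(round(config.no_mep_frac_t1 * n))
    n_cap2 = int(round(config.no_mep_frac_t2 * n))
    capped_t1 = set(order[:n_cap1])
    capped_t2 = set(order[:n_cap2])           # recovery: the least severe regain MEP
    truths: list[SubjectTruth] = []
    for i in range(n):
        sid = str(i + 1)
        ah_side = "L" if rng.random() < 0.5 else "R"
        uh1 = float(np.clip(rng.normal(config.rmt_uh_mean, config.rmt_uh_sd),
                            35.0, 70.0))
        uh2 = float(np.clip(uh1 + rng.normal(-1.0, 2.0), 35.0, 70.0))
        asym1 = max(0.0, rng.normal(0.10 + 0.25 * severity[i], 0.08))
        asym2 = max(0.0, asym1 + rng.normal(-0.05, 0.10))
        rmt_vals: dict[str, tuple[float, float, bool]] = {}
        for tp, uh, asym, capped in (("T1", uh1, asym1, i in capped_t1),
                                     ("T2", uh2, asym2, i in capped_t2)):
            ah = RMT_CEILING if capped else float(
                np.clip(uh * (1.0 + asym), uh, RMT_CEILING - 2.0))
            rmt_vals[tp] = (ah, uh, capped)
        li_rmt_true = {tp: li_rmt_formula(v[0], v[1]) for tp, v in rmt_vals.items()}
        r_true = {tp: r_ratio_formula(v[0], v[1]) for tp, v in rmt_vals.items()}
        d_r = r_true["T2"] - r_true["T1"]
        # true activation laterality; LI-SMA(T1) optionally coupled to the
        # T1 RMT asymmetry through a Gaussian copula
        li_fnirs: dict[str, dict[str, float]] = {}
        amplitudes: dict[str, dict[tuple[str, str], float]] = {}
        for tp in ("T1", "T2"):
            lis = {}
            for roi in ROIS:
                if roi == "SMA" and tp == "T1" and eff.sma_rmt_rho != 0.0:
                    z_rmt = (li_rmt_true["T1"] - 0.2) / 0.2
                    z = (eff.sma_rmt_rho * z_rmt
                         + np.sqrt(1 - eff.sma_rmt_rho ** 2) * rng.normal())
                    u = 2.0 * float(np.clip((z + 3) / 6, 0.0, 1.0)) - 1.0
                    lis[roi] = u * config.li_range
                else:
                    lis[roi] = float(rng.uniform(-config.li_range,
                                                 config.li_range))
            amps = {}
            for roi in ROIS:
                base = config.base_amplitude_um[roi]
                amps[(roi, "AH")] = base * (1.0 + lis[roi])
                amps[(roi, "UH")] = base * (1.0 - lis[roi])
            mean_ah = float(np.mean([amps[(r, "AH")] for r in ROIS]))
            mean_uh = float(np.mean([amps[(r, "UH")] for r in ROIS]))
            # degenerate all-zero amplitudes (silent-cortex configs) carry no
            # defined laterality
            lis["combined"] = (li_hbo(mean_ah, mean_uh)
                               if (mean_ah, mean_uh) != (0.0, 0.0) else 0.0)
            li_fnirs[tp] = lis
            amplitudes[tp] = amps
        truths.append(SubjectTruth(
            subject_id=sid, affected_hemisphere=ah_side,
            severity=float(severity[i]), rmt=rmt_vals, li_rmt=li_rmt_true,
            r_ratio=r_true, d_r=d_r, li_fnirs=li_fnirs,
            amplitudes=amplitudes, fma={}))
    simulate_scores(truths, config, seed)
    return truths


def simulate_scores(truths: list[SubjectTruth], config: SimulationConfig,
                    seed: int) -> None:
    """Fill the FMA fields of each truth record with planted-effect scores."""
    rng = _sub_rng(seed, 1)
    eff = config.effects
    distal_frac = 0.35
    # centre the couplings on the cohort means so the planted correlations
    # leave the mean one-month gain (spontaneous recovery) untouched
    mean_li_rmt = float(np.mean([t.li_rmt["T1"] for t in truths]))
    mean_li_sma = float(np.mean([t.li_fnirs["T1"]["SMA"] for t in truths]))
    pmc_pos = [t.li_fnirs["T2"]["PMC"] for t in truths if t.d_r > 0]
    mean_li_pmc = float(np.mean(pmc_pos)) if pmc_pos else 0.0
    for t in truths:
        ue1 = float(np.clip(np.round(rng.normal(22.0, 16.0)), 0, 64))
        gain = rng.normal(eff.gain_mean, eff.gain_sd)
        gain -= eff.beta_rmt * (t.li_rmt["T1"] - mean_li_rmt)
        gain -= eff.beta_sma * (t.li_fnirs["T1"]["SMA"] - mean_li_sma)
        if t.d_r > 0:
            gain += eff.beta_pmc_subgroup * (t.li_fnirs["T2"]["PMC"]
                                             - mean_li_pmc)
        if eff.score_noise_sd > 0:
            gain += rng.normal(0.0, eff.score_noise_sd)
        ue2 = float(np.clip(np.round(ue1 + gain), 0, 66))
        d1 = float(np.round(distal_frac * ue1))
        d2 = float(np.round(distal_frac * ue2))
        t.fma = {"fma_ue_t1": ue1, "fma_ue_t2": ue2,
                 "fma_d_t1": d1, "fma_d_t2": d2,
                 "fma_p_t1": ue1 - d1, "fma_p_t2": ue2 - d2}


def simulate_tms(truth: SubjectTruth) -> tuple[TmsRecord, TmsRecord]:
    """TMS record pair (T1, T2) from a subject's generating values."""
    out = []
    for tp in ("T1", "T2"):
        ah, uh, capped = truth.rmt[tp]
        out.append(TmsRecord(subject_id=truth.subject_id, timepoint=tp,
                             rmt_ah=ah, rmt_uh=uh,
                             mep_present_ah=not capped, mep_present_uh=True))
    return out[0], out[1]


def subject_record(truth: SubjectTruth, config: SimulationConfig,
                   seed: int) -> SubjectRecord:
    """Demographics drawn to resemble a subacute stroke cohort."""
    rng = _sub_rng(seed, 2, int(truth.subject_id))
    return SubjectRecord(
        subject_id=truth.subject_id,
        sex="M" if rng.random() < 22 / 31 else "F",
        age=int(np.clip(np.round(rng.normal(65.0, 10.0)), 30, 80)),
        stroke_type="hemorrhage" if rng.random() < 5 / 31 else "infarction",
        affected_hemisphere=truth.affected_hemisphere,
        stroke_duration_days=int(np.clip(np.round(rng.lognormal(4.2, 0.9)),
                                         7, 450)),
        barthel=int(np.clip(np.round(rng.normal(53, 18) / 5) * 5, 0, 100)),
        **truth.fma,
    ).validate()


def simulate_recording(truth: SubjectTruth, timepoint: str,
                       config: SimulationConfig, seed: int,
                       montage: Montage | None = None,
                       noise: NoiseConfig | None = None) -> FnirsRecording:
    """Raw two-wavelength intensities for one subject/timepoint."""
    config.validate()
    montage = montage or default_montage()
    noise = noise if noise is not None else config.noise
    fs = config.sampling_rate
    paradigm = config.paradigm
    n_t = int(round(paradigm.duration_s() * fs))
    marks = paradigm_marks(paradigm, fs)
    resp = task_response(n_t, fs, marks, paradigm, config)
    rng = _sub_rng(seed, 3, int(truth.subject_id),
                   0 if timepoint == "T1" else 1)
    t = np.arange(n_t) / fs
    amps = truth.amplitudes[timepoint]
    ah_side = truth.affected_hemisphere
    eps = np.array([config.extinction[float(w)] for w in config.wavelengths_nm])
    n_ch = len(montage.channels)
    intensities = np.empty((n_ch, len(config.wavelengths_nm), n_t))
    for c, ch in enumerate(montage.channels):
        if ch.roi in ROIS:
            hemi_label = "AH" if ch.hemisphere == ah_side else "UH"
            amp = amps[(ch.roi, hemi_label)]
        else:
            amp = 0.0
        hbo = amp * resp
        hbr = -config.hbr_ratio * hbo
        path = ch.separation_mm / 10.0 * config.dpf * 1e-6
        for w in range(len(config.wavelengths_nm)):
            od = (eps[w, 0] * hbo + eps[w, 1] * hbr) * path
            od = od + _noise_trace(t, n_t, fs, noise, rng)
            intensities[c, w] = config.source_intensity * 10.0 ** (-od)
    rec = FnirsRecording(
        subject_id=truth.subject_id, timepoint=timepoint, sampling_rate=fs,
        intensities=intensities, marks=marks, montage=montage,
        wavelengths_nm=tuple(float(w) for w in config.wavelengths_nm))
    return rec.validate(paradigm)


def _noise_trace(t: np.ndarray, n_t: int, fs: float, noise: NoiseConfig,
                 rng: np.random.Generator) -> np.ndarray:
    od = np.zeros(n_t)
    for hz, amp in ((noise.cardiac_hz, noise.cardiac_od),
                    (noise.respiratory_hz, noise.respiratory_od),
                    (noise.mayer_hz, noise.mayer_od)):
        if amp > 0:
            od += amp * np.sin(2 * np.pi * hz * t + rng.uniform(0, 2 * np.pi))
    if noise.drift_od > 0:
        od += rng.normal(0.0, noise.drift_od) * (t / t[-1] if n_t > 1 else t)
    if noise.white_od_sd > 0:
        od += rng.normal(0.0, noise.white_od_sd, size=n_t)
    if noise.spike_rate_hz > 0 and noise.spike_od > 0:
        n_spikes = rng.poisson(noise.spike_rate_hz * n_t / fs)
        for _ in range(n_spikes):
            pos = rng.integers(0, n_t)
            width = rng.integers(2, 6)
            mag = rng.normal(0.0, noise.spike_od)
            hi = min(n_t, pos + width)
            od[pos:hi] += mag
    return od


def simulate_study(config: SimulationConfig | None = None, seed: int = 0,
                   include_recordings: bool = True) -> Study:
    """A complete synthetic study; recordings can be skipped for score-level
    simulations where the true laterality values are used directly."""
    config = (config or SimulationConfig()).validate()
    montage = default_montage()
    truths = simulate_truth(config, seed)
    for t in truths:
        t.check_identities()
    subjects = [subject_record(t, config, seed) for t in truths]
    tms_records = [rec for t in truths for rec in simulate_tms(t)]
    recordings: dict[tuple[str, str], FnirsRecording] = {}
    if include_recordings:
        for t in truths:
            for tp in ("T1", "T2"):
                recordings[(t.subject_id, tp)] = simulate_recording(
                    t, tp, config, seed, montage)
    return Study(config=config, montage=montage, subjects=subjects,
                 tms_records=tms_records, truth=truths, recordings=recordings)


def truth_to_dict(truth: SubjectTruth) -> dict:
    d = asdict(truth)
    # JSON-safe keys for the amplitude mapping
    d["amplitudes"] = {tp: {f"{roi}_{hemi}": v for (roi, hemi), v in amps.items()}
                       for tp, amps in truth.amplitudes.items()}
    return d


def write_study(study: Study, out_dir: str | Path) -> None:
    """Write every container of a study in the package's own formats."""
    out = Path(out_dir)
    (out / "recordings").mkdir(parents=True, exist_ok=True)
    write_cohort(study.subjects, out / "cohort.csv")
    write_tms(study.tms_records, out / "tms.csv")
    write_montage(study.montage, out / "montage.json")
    for (sid, tp), rec in study.recordings.items():
        write_recording(rec, out / "recordings" / f"sub{sid}_{tp}")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump({"config_n_subjects": study.config.n_subjects,
                   "subjects": [truth_to_dict(t) for t in study.truth]},
                  fh, indent=1, sort_keys=True)
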