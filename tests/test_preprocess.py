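"""Signal chain: optical density, artifacts, filtering, Beer-Lambert,
block averaging, dHBO extraction and ROI labelling."""

import dataclasses

import numpy as np
import pytest
from scipy import signal as sps

from hemibalance.preprocess import (
    BlockWaveform,
    HboSeries,
    OpticalDensitySeries,
    PipelineConfig,
    bandpass,
    beer_lambert,
    block_average,
    correct_artifacts,
    delta_hbo,
    extinction_matrix,
    preprocess_recording,
    roi_activation,
    to_optical_density,
)
from hemibalance.records import (
    BlockParadigm,
    ConfigurationError,
    DataError,
    MissingRoiError,
    ParadigmError,
    SubjectRecord,
)
from hemibalance.simulate import (
    NoiseConfig,
    SimulationConfig,
    expected_delta_hbo_factor,
    paradigm_marks,
    simulate_recording,
    simulate_truth,
    task_response,
)

from conftest import make_recording

FS = 11.0


def od_series(data, fs=FS):
    n_ch = data.shape[0]
    return OpticalDensitySeries(data=np.asarray(data, float), sampling_rate=fs,
                                wavelengths_nm=(730.0, 850.0),
                                separations_mm=np.full(n_ch, 30.0))


class TestOpticalDensity:
    def test_constant_channel_is_zero(self, montage):
        n_t = int(round(BlockParadigm().duration_s() * FS))
        rec = make_recording(np.full((26, 2, n_t), 7.3), montage)
        od = to_optical_density(rec)
        assert np.allclose(od.data, 0.0)

    def test_tenth_of_reference_gives_unit_od(self, montage):
        n_t = int(round(BlockParadigm().duration_s() * FS))
        data = np.full((26, 2, n_t), 2.0)
        # one dipped sample at exactly ref/10: b = (n-1) a / (10 n - 1)
        a = 2.0
        b = (n_t - 1) * a / (10 * n_t - 1)
        data[0, 0, -1] = b
        od = to_optical_density(make_recording(data, montage))
        assert od.data[0, 0, -1] == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self, montage):
        """Multiplying a whole channel by a constant leaves dOD unchanged."""
        rng = np.random.default_rng(0)
        n_t = int(round(BlockParadigm().duration_s() * FS))
        data = rng.uniform(500, 1500, (26, 2, n_t))
        od1 = to_optical_density(make_recording(data, montage))
        scaled = data.copy()
        scaled[5] *= 3.7
        od2 = to_optical_density(make_recording(scaled, montage))
        assert np.allclose(od1.data, od2.data, atol=1e-12)

    def test_non_positive_rejected(self, montage):
        n_t = int(round(BlockParadigm().duration_s() * FS))
        data = np.ones((26, 2, n_t))
        data[3, 0, 7] = -1.0
        rec = make_recording(np.ones((26, 2, n_t)), montage)
        rec.intensities = data
        with pytest.raises(DataError):
            to_optical_density(rec)


class TestArtifactCorrection:
    def test_clean_sinusoid_unchanged(self):
        t = np.arange(0, 60, 1 / FS)
        x = np.sin(2 * np.pi * 0.05 * t)
        od = od_series(np.tile(x, (26, 2, 1)))
        out = correct_artifacts(od)
        assert np.allclose(out.data, od.data)
        assert out.n_corrected.sum() == 0

    def test_spike_interpolated(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 60, 1 / FS)
        x = np.sin(2 * np.pi * 0.05 * t) + rng.normal(0, 0.05, t.size)
        sd = x.std()
        data = np.tile(x, (26, 2, 1))
        data[0, :, 300:303] += 10 * sd
        out = correct_artifacts(od_series(data))
        assert out.n_corrected[0] > 0
        assert np.abs(out.data[0]).max() < 3 * sd

    def test_all_spike_channel_excluded(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 0.01, 660)
        data = np.tile(x, (26, 2, 1))
        # channel 4: mostly huge jumps
        data[4, :, :] = np.where(np.arange(660) % 2 == 0, 5.0, -5.0)
        data[4, :, :500] += rng.normal(0, 3.0, 500)
        cfg = PipelineConfig(artifact_threshold=3.0)
        with pytest.warns(UserWarning, match="excluded"):
            out = correct_artifacts(od_series(data), cfg)
        assert 4 in out.bad_channels


class TestBandpass:
    @pytest.mark.parametrize("freq,bound,kind", [
        (0.05, 0.7, "ge"),    # passband tone survives
        (1.1, 0.1, "le"),     # cardiac tone suppressed
        (0.25, 0.1, "le"),    # respiratory tone suppressed
    ])
    def test_tone_amplitudes(self, freq, bound, kind):
        t = np.arange(0, 600, 1 / FS)
        x = np.sin(2 * np.pi * freq * t)
        od = od_series(np.tile(x, (1, 2, 1)))
        y = bandpass(od).data[0, 0]
        n = len(y) // 4
        amp = np.abs(y[n:-n]).max()
        assert (amp >= bound) if kind == "ge" else (amp <= bound)

    def test_attenuation_specs_db(self):
        """>= 20 dB suppression at 1.1 and 0.25 Hz, <= 3 dB loss at 0.05 Hz,
        for the zero-phase (forward-backward) response."""
        sos = sps.butter(3, [0.01, 0.1], btype="bandpass", fs=FS, output="sos")
        _w, h = sps.sosfreqz(sos, worN=[0.05, 0.25, 1.1], fs=FS)
        db = 40 * np.log10(np.abs(h))   # doubled: filter applied twice
        assert db[0] >= -3.0
        assert db[1] <= -20.0
        assert db[2] <= -20.0

    def test_dc_removed(self):
        od = od_series(np.full((1, 2, 2145), 5.0))
        y = bandpass(od).data
        assert np.abs(y).mean() < 1e-3

    def test_band_above_nyquist_rejected(self):
        od = od_series(np.zeros((1, 2, 100)), fs=0.15)
        with pytest.raises(ConfigurationError, match="Nyquist"):
            bandpass(od, 0.01, 0.1)


class TestBeerLambert:
    def test_zero_od_gives_zero_concentration(self):
        hbo = beer_lambert(od_series(np.zeros((26, 2, 50))))
        assert np.allclose(hbo.data, 0.0)
        assert np.allclose(hbo.hbr, 0.0)

    def test_forward_then_invert_machine_precision(self):
        """Concentrations planted through the forward model are recovered."""
        rng = np.random.default_rng(7)
        cfg = PipelineConfig()
        n_ch, n_t = 26, 120
        hbo_true = rng.normal(0, 1.0, (n_ch, n_t))
        hbr_true = rng.normal(0, 0.5, (n_ch, n_t))
        E = extinction_matrix((730.0, 850.0), cfg.extinction)
        sep_cm, dpf = 3.0, cfg.dpf
        od = np.empty((n_ch, 2, n_t))
        for w in range(2):
            od[:, w, :] = (E[w, 0] * hbo_true + E[w, 1] * hbr_true) \
                * sep_cm * dpf * 1e-6
        out = beer_lambert(od_series(od))
        np.testing.assert_allclose(out.data, hbo_true, rtol=1e-10, atol=1e-10)
        np.testing.assert_allclose(out.hbr, hbr_true, rtol=1e-10, atol=1e-10)

    def test_doubling_dpf_halves_concentration(self):
        rng = np.random.default_rng(8)
        od = od_series(rng.normal(0, 0.01, (26, 2, 40)))
        c1 = beer_lambert(od, dpf=6.0).data
        c2 = beer_lambert(od, dpf=12.0).data
        np.testing.assert_allclose(c2, c1 / 2.0, rtol=1e-12)

    def test_singular_extinction_rejected(self):
        with pytest.raises(ConfigurationError, match="singular"):
            extinction_matrix((730.0, 850.0),
                              {730.0: (1.0, 2.0), 850.0: (2.0, 4.0)})


def hbo_series(data, fs=FS):
    return HboSeries(data=np.asarray(data, float), sampling_rate=fs)


class TestBlockAverage:
    def setup_method(self):
        self.paradigm = BlockParadigm()
        self.marks = paradigm_marks(self.paradigm, FS)
        self.n_t = int(round(self.paradigm.duration_s() * FS))

    def test_identical_epochs_reproduced(self):
        period = int(round((self.paradigm.task_s + self.paradigm.rest_s) * FS))
        x = np.sin(2 * np.pi * np.arange(self.n_t) / period)  # period-locked
        wave = block_average(hbo_series(np.tile(x, (26, 1))),
                             self.paradigm, self.marks)
        n_base = wave.n_baseline
        lo = self.marks[0][1] - n_base
        hi = self.marks[0][1] + int(round(self.paradigm.task_s * FS))
        np.testing.assert_allclose(wave.data[0], x[lo:hi], atol=1e-9)

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(5)
        data = rng.normal(0, 1, (26, self.n_t))
        wave = block_average(hbo_series(data), self.paradigm, self.marks)
        n_base, n_task = wave.n_baseline, int(round(self.paradigm.task_s * FS))
        manual = np.mean([data[:, on - n_base:on + n_task]
                          for _b, on, _off in self.marks], axis=0)
        np.testing.assert_allclose(wave.data, manual)

    def test_epoch_out_of_bounds_rejected(self):
        marks = [(b, on - 400, off - 400) for b, on, off in self.marks]
        with pytest.raises(ParadigmError, match="block 1"):
            block_average(hbo_series(np.zeros((26, self.n_t))),
                          self.paradigm, marks)


class TestDeltaHbo:
    def test_flat_waveform_zero(self):
        wave = BlockWaveform(np.full((26, 330), 2.0), FS, n_baseline=55)
        assert np.allclose(delta_hbo(wave), 0.0)

    def test_unit_plateau(self):
        data = np.zeros((26, 330))
        data[:, 55:] = 1.0
        wave = BlockWaveform(data, FS, n_baseline=55)
        np.testing.assert_allclose(delta_hbo(wave), 1.0)

    def test_hrf_waveform_matches_integration_oracle(self):
        """Measured dHBO of the HRF-convolved boxcar equals the numerically
        integrated task-minus-baseline expectation (unfiltered chain)."""
        cfg = SimulationConfig()
        paradigm = cfg.paradigm
        marks = paradigm_marks(paradigm, FS)
        n_t = int(round(paradigm.duration_s() * FS))
        resp = 0.8 * task_response(n_t, FS, marks, paradigm, cfg)
        wave = block_average(hbo_series(np.tile(resp, (26, 1))),
                             paradigm, marks)
        expected = 0.8 * expected_delta_hbo_factor(cfg)
        np.testing.assert_allclose(delta_hbo(wave), expected, rtol=1e-9)
        # the shape factor keeps the measure within 25% of the plateau
        assert abs(delta_hbo(wave)[0] - 0.8) / 0.8 < 0.25


def _subject(side="R"):
    return SubjectRecord("s1", "M", 60, "infarction", side, 30, 60)


class TestRoiActivation:
    def test_label_mapping(self, montage):
        """With a right-sided lesion, left-hemisphere channels report as the
        unaffected hemisphere."""
        delta = np.zeros(26)
        left_m1 = montage.channel_indices(roi="M1", hemisphere="L")
        delta[left_m1] = 0.8
        act = roi_activation(delta, montage, _subject("R"))
        assert act.values[("M1", "UH")] == pytest.approx(0.8)
        assert act.values[("M1", "AH")] == pytest.approx(0.0)

    def test_single_channel_roi(self, montage):
        rng = np.random.default_rng(4)
        delta = rng.normal(0, 1, 26)
        pmc_left = montage.channel_indices(roi="PMC", hemisphere="L")
        bad = set(pmc_left[1:])   # leave one usable channel
        act = roi_activation(delta, montage, _subject("R"), bad_channels=bad)
        assert act.values[("PMC", "UH")] == pytest.approx(delta[pmc_left[0]])
        assert act.n_channels[("PMC", "UH")] == 1

    def test_flip_is_involution(self, montage):
        rng = np.random.default_rng(6)
        delta = rng.normal(0, 1, 26)
        a = roi_activation(delta, montage, _subject("R"))
        b = roi_activation(delta, montage, _subject("L"))
        for roi in ("M1", "SMA", "PMC"):
            assert a.values[(roi, "AH")] == b.values[(roi, "UH")]
            assert a.values[(roi, "UH")] == b.values[(roi, "AH")]

    def test_all_channels_bad_raises(self, montage):
        bad = set(montage.channel_indices(roi="SMA", hemisphere="L"))
        with pytest.raises(MissingRoiError, match="SMA"):
            roi_activation(np.zeros(26), montage, _subject("R"),
                           bad_channels=bad)


class TestPipelineProperties:
    def test_end_to_end_linearity(self, montage, silent_noise):
        """Scaling planted amplitudes by k scales every dHBO by k (within 2%)."""
        cfg = SimulationConfig(n_subjects=1)
        truth = simulate_truth(cfg, seed=21)[0]
        sub = _subject(truth.affected_hemisphere)
        sub = SubjectRecord(truth.subject_id, "M", 60, "infarction",
                            truth.affected_hemisphere, 30, 60)
        base = {}
        for k in (1.0, 0.5, 2.0):
            scaled_cfg = SimulationConfig(
                n_subjects=1,
                base_amplitude_um={r: k * v for r, v
                                   in cfg.base_amplitude_um.items()})
            t2 = simulate_truth(scaled_cfg, seed=21)[0]
            rec = simulate_recording(t2, "T1", scaled_cfg, seed=21,
                                     montage=montage, noise=silent_noise)
            act = preprocess_recording(rec, sub)
            if k == 1.0:
                base = dict(act.values)
            else:
                for key, v in act.values.items():
                    assert v == pytest.approx(k * base[key], rel=0.02)

    def test_noise_free_ordering_recovered(self, montage, silent_noise):
        """The planted AH/UH ordering survives the whole chain in 50/50 runs."""
        hits = 0
        for seed in range(50):
            cfg = SimulationConfig(n_subjects=1)
            truth = simulate_truth(cfg, seed=seed)[0]
            sub = SubjectRecord(truth.subject_id, "M", 60, "infarction",
                                truth.affected_hemisphere, 30, 60)
            rec = simulate_recording(truth, "T1", cfg, seed=seed,
                                     montage=montage, noise=silent_noise)
            act = preprocess_recording(rec, sub)
            ok = all(
                np.sign(act.values[(r, "AH")] - act.values[(r, "UH")])
                == np.sign(truth.amplitudes["T1"][(r, "AH")]
                           - truth.amplitudes["T1"][(r, "UH")])
                for r in ("M1", "SMA", "PMC"))
            hits += ok
        assert hits == 50

    def test_physiological_tones_filtered_out(self, montage, silent_noise):
        """Cardiac + respiratory tones at 5x the signal's OD amplitude move
        dHBO by < 10%."""
        cfg = SimulationConfig(n_subjects=1)
        truth = simulate_truth(cfg, seed=33)[0]
        sub = SubjectRecord(truth.subject_id, "M", 60, "infarction",
                            truth.affected_hemisphere, 30, 60)
        # signal OD scale: max amplitude ~1 uM through the forward model
        signal_od = 1058.0 * 1.0 * 1e-6 * 3.0 * 6.0
        tones = NoiseConfig(cardiac_od=5 * signal_od,
                            respiratory_od=5 * signal_od,
                            mayer_od=0.0, drift_od=0.0, white_od_sd=0.0,
                            spike_rate_hz=0.0, spike_od=0.0)
        clean = preprocess_recording(
            simulate_recording(truth, "T1", cfg, seed=33, montage=montage,
                               noise=silent_noise), sub)
        noisy = preprocess_recording(
            simulate_recording(truth, "T1", cfg, seed=33, montage=montage,
                               noise=tones), sub)
        for key, v in clean.values.items():
            assert noisy.values[key] == pytest.approx(v, rel=0.10)
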