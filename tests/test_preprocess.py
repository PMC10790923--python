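import numpy as np
import pytest
from dataclasses import replace
from scipy import signal as sps

from nirspain.montage import default_montage
from nirspain.preprocess import (
    MotionSegment,
    PreprocessError,
    StageOrderError,
    apply_bandpass,
    apply_cbsi,
    apply_motion_correction,
    cbsi,
    chebyshev_bandpass,
    chebyshev_bandpass_sos,
    correct_motion,
    detect_motion_segments,
    hemodynamics_from_od,
    hr_from_ecg,
    mbll_forward,
    mbll_inverse,
    process_recording,
)
from nirspain.synth import SimulationConfig, simulate_session, synthesize_ecg


class TestMbll:
    def test_zero_od_zero_concentration(self):
        hbo, hbr = mbll_inverse(np.zeros((2, 5)), separation_cm=3.0)
        assert np.all(hbo == 0) and np.all(hbr == 0)

    def test_forward_then_inverse_identity(self, rng):
        hbo_in = rng.normal(0, 1, 50)
        hbr_in = rng.normal(0, 0.3, 50)
        od = mbll_forward(hbo_in, hbr_in, separation_cm=3.82)
        hbo, hbr = mbll_inverse(od, separation_cm=3.82)
        assert np.allclose(hbo, hbo_in, atol=1e-10)
        assert np.allclose(hbr, hbr_in, atol=1e-10)

    def test_identity_coefficients(self):
        od = np.array([[1.0, 2.0], [3.0, 4.0]])
        hbo, hbr = mbll_inverse(od, separation_cm=1.0, dpf=1.0, extinction=np.eye(2))
        assert np.allclose(hbo, od[0]) and np.allclose(hbr, od[1])

    def test_singular_extinction_rejected(self):
        with pytest.raises(PreprocessError, match="singular"):
            mbll_inverse(np.zeros((2, 3)), 3.0, extinction=np.ones((2, 2)))

    def test_wavelength_count_checked(self):
        with pytest.raises(PreprocessError, match="2 wavelengths"):
            mbll_inverse(np.zeros((3, 4)), 3.0)


def _driven_amplitude(freq, n_s=1200.0, fs=10.0, passes=1):
    """Amplitude of the driven-frequency component after filtering."""
    t = np.arange(int(n_s * fs)) / fs
    x = np.sin(2 * np.pi * freq * t)
    y = x
    for _ in range(passes):
        y = chebyshev_bandpass(y, sample_rate=fs)
    mid = slice(len(t) // 3, 2 * len(t) // 3)
    ref = np.exp(2j * np.pi * freq * t[mid])
    return 2 * np.abs(np.mean(y[mid] * np.conj(ref)))


class TestChebyshevBandpass:
    def test_dc_rejected(self):
        out = chebyshev_bandpass(np.ones(6000))
        assert np.abs(out[1000:-1000]).max() < 1e-6

    def test_passband_gain_near_unity(self):
        assert 0.9 <= _driven_amplitude(0.05) <= 1.0

    def test_1hz_strongly_attenuated(self):
        assert _driven_amplitude(1.0) < 0.01

    def test_stopband_attenuation_40db(self):
        sos = chebyshev_bandpass_sos()
        _, h = sps.sosfreqz(sos, worN=np.array([1e-4, 1.0]), fs=10.0)
        # forward-backward application squares the response
        assert np.all(20 * np.log10(np.abs(h) ** 2 + 1e-300) < -40.0)

    def test_double_filtering_composes(self):
        a1 = _driven_amplitude(0.05, passes=1)
        a2 = _driven_amplitude(0.05, passes=2)
        assert a2 == pytest.approx(a1**2, rel=0.02)

    def test_inverted_band_rejected(self):
        with pytest.raises(PreprocessError):
            chebyshev_bandpass(np.zeros(100), band=(0.09, 0.01))


class TestMotionDetection:
    fs = 10.0

    def _accel(self, n_s, bursts, amp=0.5, rate=512.0):
        n = int(n_s * rate)
        a = np.zeros((3, n))
        a[2] = 1.0
        t = np.arange(n) / rate
        for s, e in bursts:
            m = (t >= s) & (t < e)
            a[:, m] += amp * np.sin(2 * np.pi * 5 * t[m])
        return a

    def test_flat_accel_no_segments(self, rng):
        fnirs = rng.normal(0, 1, (1, 600))
        segs = detect_motion_segments(self._accel(60, []), fnirs)
        assert segs == []

    def test_accel_burst_without_fnirs_change(self):
        fnirs = np.zeros((1, 600))
        segs = detect_motion_segments(self._accel(60, [(20, 22)]), fnirs)
        assert segs == []

    def test_step_inside_burst_detected_once(self, rng):
        n = 600
        fnirs = rng.normal(0, 0.05, (1, n))
        fnirs[0, 100:115] += 5.0  # 10.0-11.5 s step
        segs = detect_motion_segments(self._accel(60, [(10.0, 11.5)]), fnirs)
        assert len(segs) == 1
        seg = segs[0]
        assert 9.0 <= seg.start_s <= 10.0
        assert 11.5 <= seg.end_s <= 12.5

    def test_empty_stream_rejected(self):
        with pytest.raises(PreprocessError, match="empty"):
            detect_motion_segments(np.zeros((3, 0)), np.zeros((1, 10)))


class TestCorrectMotion:
    def test_empty_segments_identity(self, rng):
        x = rng.normal(0, 1, 100)
        assert np.array_equal(correct_motion(x, []), x)

    def test_step_artifact_rmse_reduced(self, rng):
        clean = rng.normal(0, 0.1, 600)
        dirty = clean.copy()
        dirty[200:240] += 10.0
        seg = [MotionSegment(channel=0, start_s=20.0, end_s=24.0)]
        fixed = correct_motion(dirty, seg)
        rmse_before = np.sqrt(np.mean((dirty - clean) ** 2))
        rmse_after = np.sqrt(np.mean((fixed - clean) ** 2))
        assert rmse_after <= rmse_before / 5.0
        # untouched outside the segment
        assert np.array_equal(fixed[:200], dirty[:200])
        assert np.array_equal(fixed[240:], dirty[240:])

    def test_edge_discontinuity_reduced(self, rng):
        clean = np.zeros(600)
        dirty = clean + rng.normal(0, 0.01, 600)
        dirty[200:240] += 8.0
        fixed = correct_motion(dirty, [MotionSegment(0, 20.0, 24.0)])
        jump = lambda x, i: abs(x[i] - x[i - 1])
        assert jump(fixed, 200) < jump(dirty, 200)
        assert jump(fixed, 240) < jump(dirty, 240)

    def test_segment_at_series_end_uses_backward_baseline(self, rng):
        x = rng.normal(0, 0.1, 100)
        out = correct_motion(x, [MotionSegment(0, 8.0, 10.0)])
        assert np.isfinite(out).all()
        assert np.allclose(out[80:], np.mean(x[60:80]))

    def test_overlapping_segments_rejected(self):
        with pytest.raises(PreprocessError, match="overlap"):
            correct_motion(np.zeros(100), [MotionSegment(0, 1.0, 3.0),
                                           MotionSegment(0, 2.0, 4.0)])


class TestCbsi:
    def test_alpha_one_identity(self, rng):
        hbo = rng.normal(0, 1, 200)
        hbo_c, _ = cbsi(hbo, -hbo)
        assert np.allclose(hbo_c, hbo)

    def test_perfect_anticorrelation(self, rng):
        hbo = rng.normal(0, 1.0, (8, 300))
        hbr = rng.normal(0, 0.4, (8, 300))
        hbo_c, hbr_c = cbsi(hbo, hbr)
        for ch in range(8):
            r = np.corrcoef(hbo_c[ch], hbr_c[ch])[0, 1]
            assert abs(r + 1.0) < 1e-9

    def test_hand_computed_pair(self):
        hbo_c, _ = cbsi(np.array([1.0, 2.0, 3.0]), np.array([3.0, 1.0, 2.0]))
        assert np.allclose(hbo_c, [-1.0, 0.5, 0.5])

    def test_zero_variance_channel_named(self):
        with pytest.raises(PreprocessError, match="channel 1"):
            cbsi(np.array([[1.0, 2.0], [1.0, 1.0]]), np.array([[1.0, 0.0], [0.5, 0.2]]))


class TestHrFromEcg:
    def test_recovers_constant_60_bpm(self, rng):
        ecg = synthesize_ecg(np.full(600, 60.0), 10.0, rng)
        hr = hr_from_ecg(ecg)
        assert abs(np.median(hr[50:-50]) - 60.0) <= 1.0

    def test_missing_beat_interpolated(self, rng):
        ecg = synthesize_ecg(np.full(600, 60.0), 10.0, rng)
        # blank out one beat (~30 s in) to create an implausible 2-s RR gap
        ecg[int(29.6 * 250):int(30.6 * 250)] = 0.0
        hr = hr_from_ecg(ecg)
        assert np.isfinite(hr).all()
        assert abs(np.median(hr[50:-50]) - 60.0) <= 1.5

    def test_flatline_rejected(self):
        with pytest.raises(PreprocessError):
            hr_from_ecg(np.zeros(250 * 20))

    def test_short_record_rejected(self):
        with pytest.raises(PreprocessError, match="10 s"):
            hr_from_ecg(np.zeros(250 * 5))


class TestStageOrder:
    def _fresh(self, rng):
        od = rng.normal(0, 0.01, (2, 2, 400))
        return hemodynamics_from_od(od, [3.0, 3.0])

    def test_cbsi_requires_prior_stages(self, rng):
        hs = self._fresh(rng)
        with pytest.raises(StageOrderError):
            apply_cbsi(hs)

    def test_motion_correction_must_precede_filter(self, rng):
        hs = self._fresh(rng)
        apply_bandpass(hs)
        with pytest.raises(StageOrderError):
            apply_motion_correction(hs, np.zeros((3, 400 * 51)), accel_rate=512.0)

    def test_full_pipeline_sets_flags(self, processed_hard_pain):
        # process_recording runs all four stages; CBSI anti-correlation is the
        # observable signature of the final stage
        ps = processed_hard_pain
        assert ps.hbo.shape[0] == 8


def test_end_to_end_activation_recovery(default_config):
    """The pipeline recovers the in-band activation at default SNR."""
    corrs = []
    for p, cond in ((0, "hard"), (1, "easy")):
        rec, gt = simulate_session(default_config, p, cond)
        ps = process_recording(rec)
        clean_f = chebyshev_bandpass(gt.clean_hbo)
        g = slice(900, 2700)
        corrs += [np.corrcoef(ps.hbo[ch, g], clean_f[ch, g])[0, 1] for ch in range(8)]
    assert np.mean(corrs) >= 0.7
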