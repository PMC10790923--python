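import numpy as np
import pytest
from itertools import combinations

from nirspain.features import (
    CHANNEL_PAIRS,
    FeatureError,
    EpochFeatureTable,
    ProcessedSession,
    assemble_features,
    extract_session_features,
    hbo_stats,
    hr_stats,
    pearson_conn,
    wavelet_coherence,
    window_bounds,
    window_series,
)


class TestWindowing:
    def test_180s_game_yields_23_epochs(self):
        assert len(window_bounds(1800, 10.0)) == 23

    def test_exact_single_window(self):
        assert len(window_bounds(80, 10.0)) == 1

    def test_short_partial_dropped(self):
        # 19 s: two full windows, the trailing 3 s partial is below the 4-s floor
        assert len(window_bounds(190, 10.0)) == 2

    def test_sub_minimum_series_warns_and_returns_none(self):
        with pytest.warns(UserWarning, match="no windows"):
            assert window_bounds(30, 10.0) == []

    def test_window_series_records_start_times(self):
        wins = window_series(np.arange(200), 10.0)
        assert [w[0] for w in wins] == [0.0, 8.0, 16.0]
        assert len(wins[-1][1]) == 40


class TestHboStats:
    def test_constant_window(self):
        # 81 samples span exactly 8 s; trapezoidal AUC of a constant is 8c
        mean, peak, sk, var, auc = hbo_stats(np.full(81, 2.5), 10.0)
        assert (mean, peak, sk, var) == (2.5, 2.5, 0.0, 0.0)
        assert auc == pytest.approx(8 * 2.5)

    def test_hand_computed_ramp(self):
        mean, peak, sk, var, auc = hbo_stats(np.arange(10.0), 1.0)
        assert mean == 4.5
        assert peak == 9.0
        assert sk == pytest.approx(0.0, abs=1e-12)
        assert var == pytest.approx(9.16667, abs=1e-4)
        assert auc == pytest.approx(40.5)

    def test_symmetric_window_zero_skew(self):
        w = np.concatenate([np.arange(5.0), np.arange(5.0)[::-1]])
        assert hbo_stats(w, 10.0)[2] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_samples(self):
        with pytest.raises(FeatureError):
            hbo_stats([1.0, 2.0])


class TestHrStats:
    def test_constant_60(self):
        assert hr_stats(np.full(80, 60.0)) == (60.0, 60.0, 60.0, 60.0, 0.0, 0.0)

    def test_hand_computed(self):
        avg, med, mx, mn, rng_, sd = hr_stats([58.0, 60.0, 62.0, 64.0])
        assert (avg, med, mx, mn, rng_) == (61.0, 61.0, 64.0, 58.0, 6.0)
        assert sd == pytest.approx(np.sqrt(20.0 / 3.0))

    def test_single_sample_rejected(self):
        with pytest.raises(FeatureError):
            hr_stats([60.0])


class TestPearson:
    def test_perfect_positive_and_negative(self):
        x = np.arange(10.0)
        assert pearson_conn(x, 2 * x) == pytest.approx(1.0)
        assert pearson_conn(x, -x + 3) == pytest.approx(-1.0)

    def test_hand_computed(self):
        assert pearson_conn([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_affine_invariance(self, rng):
        x = rng.normal(0, 1, 80)
        y = rng.normal(0, 1, 80)
        r = pearson_conn(x, y)
        assert pearson_conn(3.0 * x + 5.0, y) == pytest.approx(r, abs=1e-12)

    def test_matches_direct_covariance_formula(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, 60)
            y = rng.normal(0, 1, 60)
            direct = np.cov(x, y)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
            assert pearson_conn(x, y) == pytest.approx(direct, abs=1e-12)

    def test_zero_variance_warns_nan(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            assert np.isnan(pearson_conn(np.ones(10), np.arange(10.0)))


class TestWaveletCoherence:
    def test_self_coherence_is_one(self, rng):
        x = rng.normal(0, 1, 600)
        assert wavelet_coherence(x, x) >= 0.99

    def test_small_delay_preserves_coherence(self, rng):
        x = rng.normal(0, 1, 601)
        assert wavelet_coherence(x[:-1], x[1:]) >= 0.95

    def test_independent_noise_low_on_average(self, rng):
        vals = []
        for _ in range(100):
            vals.append(wavelet_coherence(rng.normal(0, 1, 300), rng.normal(0, 1, 300)))
        assert np.mean(vals) < 0.5

    def test_self_beats_noise(self, rng):
        for _ in range(5):
            x = rng.normal(0, 1, 400)
            assert wavelet_coherence(x, x) >= wavelet_coherence(x, rng.normal(0, 1, 400))

    def test_band_outside_nyquist_rejected(self, rng):
        with pytest.raises(FeatureError):
            wavelet_coherence(rng.normal(0, 1, 100), rng.normal(0, 1, 100), band=(0.1, 6.0))


def make_processed(rng, pid="P01", condition="easy", game=(90.0, 270.0), n_s=285.0,
                   immersion=None):
    n = int(n_s * 10)
    return ProcessedSession(
        participant_id=pid,
        condition=condition,
        hbo=rng.normal(0, 0.3, (8, n)),
        hr=rng.normal(70, 3, n),
        sample_rate=10.0,
        game_interval=game,
        immersion_interval=immersion,
    )


class TestAssembly:
    def test_pair_count_matches_combinatorics(self):
        assert len(CHANNEL_PAIRS) == len(list(combinations(range(8), 2))) == 28

    def test_table_structure(self, rng):
        ps = make_processed(rng)
        table = assemble_features([ps])
        assert len(table.fnirs_columns) == 96
        assert len(table.hr_columns) == 6
        assert len(table.df) == 23
        assert set(table.df["demand"]) == {"Easy"}

    def test_windows_outside_game_excluded(self, rng):
        ps = make_processed(rng)
        df = extract_session_features(ps)
        assert df["window_start_s"].min() >= 90.0
        assert df["window_start_s"].max() < 270.0

    def test_all_missing_channel_named(self, rng):
        ps = make_processed(rng)
        ps.hbo[4] = np.nan
        with pytest.raises(FeatureError, match="channel 5"):
            extract_session_features(ps)

    def test_extraction_is_pure(self, rng):
        ps = make_processed(rng)
        a = extract_session_features(ps)
        b = extract_session_features(ps)
        assert a.equals(b)

    def test_missing_label_rejected(self, rng):
        ps = make_processed(rng)
        df = extract_session_features(ps)
        df.loc[0, "demand"] = None
        with pytest.raises(FeatureError, match="labels"):
            EpochFeatureTable(df)
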