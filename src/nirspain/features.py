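"""8-s window feature extraction.

From each game's preprocessed signals the pipeline computes, per consecutive
non-overlapping 8-s window (a final partial window is kept when >= 4 s, so a
180-s game yields 23 epochs):

* per-channel HbO statistics: mean, peak, skew, variance, AUC (40 columns);
* connectivity for each of the 28 unordered channel pairs: Pearson
  correlation and band-averaged wavelet coherence (56 columns);
* heart-rate statistics: average, median, maximum, minimum, range, sd.

Wavelet coherence is computed on the whole game-length series with an
analytic Morlet wavelet (omega0 = 6, 12 voices per octave, FFT convolution),
smoothed over time (boxcar spanning three scale lengths) and scale
(0.6-octave boxcar), then the time-scale map is averaged inside each window over the
0.08-0.3125 Hz band outside the cone of influence. Computing coherence inside
an isolated 8-s window could not resolve 0.08 Hz at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.fft import fft, ifft, next_fast_len
from scipy.ndimage import uniform_filter1d
from scipy.stats import skew as _skew

COHERENCE_BAND_HZ = (0.08, 0.3125)
WINDOW_S = 8.0
MIN_PARTIAL_S = 4.0

HBO_STATS = ("mean", "peak", "skew", "variance", "auc")
HR_STATS = ("average", "median", "maximum", "minimum", "range", "std")
CHANNEL_PAIRS = tuple(combinations(range(8), 2))  # 28 unordered pairs


class FeatureError(ValueError):
    pass


# --- windowing -------------------------------------------------------------

def window_bounds(n_samples, sample_rate, window_s=WINDOW_S, min_partial_s=MIN_PARTIAL_S):
    """Start/stop sample indices of consecutive non-overlapping windows.

    The trailing partial window is retained when it spans at least
    ``min_partial_s`` seconds.
    """
    w = int(round(window_s * sample_rate))
    min_n = int(round(min_partial_s * sample_rate))
    bounds = []
    for start in range(0, n_samples, w):
        stop = min(start + w, n_samples)
        if stop - start >= min_n:
            bounds.append((start, stop))
    if not bounds:
        warnings.warn(f"series of {n_samples} samples shorter than {min_partial_s} s: no windows")
    return bounds


def window_series(series, sample_rate, window_s=WINDOW_S, min_partial_s=MIN_PARTIAL_S):
    """Split a 1-D series into windows; returns [(start_s, window_array), ...]."""
    x = np.asarray(series, float)
    return [(start / sample_rate, x[start:stop])
            for start, stop in window_bounds(len(x), sample_rate, window_s, min_partial_s)]


# --- per-window statistics -------------------------------------------------

def hbo_stats(window, sample_rate=10.0):
    """(mean, peak, skew, variance, auc) of one HbO window.

    Skew is the adjusted Fisher-Pearson sample skewness (0 for zero-variance
    windows), variance is the unbiased sample variance, and AUC is the signed
    trapezoidal integral over time in seconds (uM*s).
    """
    w = np.asarray(window, float)
    if w.size < 3:
        raise FeatureError("hbo_stats needs >= 3 samples")
    var = float(np.var(w, ddof=1))
    sk = 0.0 if var == 0 else float(_skew(w, bias=False))
    return (
        float(np.mean(w)),
        float(np.max(w)),
        sk,
        var,
        float(np.trapezoid(w, dx=1.0 / sample_rate)),
    )


def hr_stats(window):
    """(average, median, maximum, minimum, range, std) of a heart-rate window."""
    w = np.asarray(window, float)
    if w.size < 2:
        raise FeatureError("hr_stats needs >= 2 samples")
    return (
        float(np.mean(w)),
        float(np.median(w)),
        float(np.max(w)),
        float(np.min(w)),
        float(np.max(w) - np.min(w)),
        float(np.std(w, ddof=1)),
    )


def pearson_conn(x, y):
    """Pearson correlation of two equal-length windows (nan if degenerate)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise FeatureError("windows must have equal length")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero-variance input to pearson_conn: emitting nan")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


# --- wavelet coherence -----------------------------------------------------

_OMEGA0 = 6.0
_FOURIER_FACTOR = (4 * np.pi) / (_OMEGA0 + np.sqrt(2.0 + _OMEGA0**2))  # scale -> period


def morlet_scales(sample_rate, f_min=0.04, f_max=0.5, voices=12):
    """Geometric scale grid (seconds) covering [f_min, f_max]."""
    s_min = 1.0 / (_FOURIER_FACTOR * f_max)
    n = int(np.ceil(voices * np.log2(f_max / f_min))) + 1
    return s_min * 2.0 ** (np.arange(n) / voices)


def morlet_cwt(x, sample_rate, scales):
    """Analytic Morlet (omega0=6) CWT via FFT; returns (n_scales, n) complex."""
    x = np.asarray(x, float)
    n = len(x)
    npad = next_fast_len(2 * n)
    xh = fft(x - x.mean(), npad)
    omega = 2 * np.pi * np.fft.fftfreq(npad, d=1.0 / sample_rate)
    W = np.empty((len(scales), n), dtype=complex)
    dt = 1.0 / sample_rate
    for i, s in enumerate(scales):
        psi_hat = (np.pi ** -0.25) * np.sqrt(2 * np.pi * s / dt) \
            * np.exp(-0.5 * (s * omega - _OMEGA0) ** 2) * (omega > 0)
        W[i] = ifft(xh * psi_hat)[:n]
    return W


#: time-smoothing boxcar length in units of the wavelet scale; three scale
#: lengths give enough independent coefficients that unrelated signals do not
#: masquerade as coherent, while leaving self-coherence at 1
TIME_SMOOTH_SCALES = 3.0


def _smooth(A, scales, sample_rate, voices=12, scale_octaves=0.6):
    """Smoothing operator S: boxcar in time (3 x scale) and scale (0.6 oct)."""
    nsc = max(int(round(scale_octaves * voices)), 1)

    def smooth_real(M):
        out = np.empty_like(M)
        for i, s in enumerate(scales):
            win = max(int(round(TIME_SMOOTH_SCALES * s * sample_rate)), 3)
            out[i] = uniform_filter1d(M[i], win, mode="nearest")
        return uniform_filter1d(out, nsc, axis=0, mode="nearest")

    if np.iscomplexobj(A):
        return smooth_real(A.real) + 1j * smooth_real(A.imag)
    return smooth_real(A)


def coherence_map(x, y, sample_rate, scales=None, Wx=None, Wy=None):
    """Smoothed wavelet-coherence map R^2 in [0, 1].

    Returns ``(R2, freqs, valid)`` where ``valid`` masks the cone of
    influence (e-folding time sqrt(2)*scale from either edge). ``Wx``/``Wy``
    allow reusing precomputed transforms of the same scale grid.
    """
    if scales is None:
        scales = morlet_scales(sample_rate)
    if Wx is None:
        Wx = morlet_cwt(x, sample_rate, scales)
    if Wy is None:
        Wy = morlet_cwt(y, sample_rate, scales)
    inv_s = 1.0 / scales[:, None]
    Sxy = _smooth(Wx * np.conj(Wy) * inv_s, scales, sample_rate)
    Sxx = _smooth(np.abs(Wx) ** 2 * inv_s, scales, sample_rate)
    Syy = _smooth(np.abs(Wy) ** 2 * inv_s, scales, sample_rate)
    R2 = np.abs(Sxy) ** 2 / (Sxx * Syy + 1e-300)
    R2 = np.clip(R2.real, 0.0, 1.0)
    n = R2.shape[1]
    t = np.arange(n) / sample_rate
    coi = np.sqrt(2.0) * scales[:, None]  # e-folding time per scale, seconds
    valid = (t[None, :] >= coi) & (t[None, :] <= t[-1] - coi)
    freqs = 1.0 / (_FOURIER_FACTOR * scales)
    return R2, freqs, valid


def wavelet_coherence(x, y, band=COHERENCE_BAND_HZ, sample_rate=10.0):
    """Mean smoothed wavelet coherence of two series over a frequency band."""
    lo, hi = band
    if not (0.0 < lo < hi < sample_rate / 2):
        raise FeatureError(f"band {band} outside (0, Nyquist)")
    R2, freqs, valid = coherence_map(np.asarray(x, float), np.asarray(y, float), sample_rate)
    in_band = (freqs >= lo) & (freqs <= hi)
    mask = valid[in_band]
    vals = R2[in_band]
    if mask.any():
        return float(vals[mask].mean())
    return float(vals.mean())  # series too short for any out-of-cone cell


# --- assembling the epoch table -------------------------------------------

@dataclass
class ProcessedSession:
    """Preprocessed signals of one session, ready for feature extraction."""

    participant_id: str
    condition: str
    hbo: np.ndarray  # (8, n) CBSI-corrected HbO, uM
    hr: np.ndarray  # (n,) bpm on the fNIRS time base
    sample_rate: float
    game_interval: tuple[float, float] | None  # seconds, half-open
    immersion_interval: tuple[float, float] | None = None

    @property
    def demand(self) -> str:
        return "Hard" if self.condition.startswith("hard") else "Easy"

    @property
    def pain(self) -> str:
        return "pain" if self.condition.endswith("_pain") else "no_pain"


def fnirs_feature_columns(n_channels=8):
    stat_cols = [f"ch{c + 1}_{s}" for c in range(n_channels) for s in HBO_STATS]
    pair_cols = []
    for a, b in combinations(range(n_channels), 2):
        pair_cols.append(f"pearson_ch{a + 1}_ch{b + 1}")
    for a, b in combinations(range(n_channels), 2):
        pair_cols.append(f"wcoh_ch{a + 1}_ch{b + 1}")
    return stat_cols + pair_cols


def hr_feature_columns():
    return [f"hr_{s}" for s in HR_STATS]


@dataclass
class EpochFeatureTable:
    """One row per (participant, condition, 8-s window)."""

    df: pd.DataFrame

    LABEL_COLS = ("participant_id", "condition", "demand", "pain", "window_start_s")

    def __post_init__(self):
        fcols = self.fnirs_columns
        if len(fcols) != 96:
            raise FeatureError(f"expected 96 fNIRS feature columns, found {len(fcols)}")
        if len(self.hr_columns) != 6:
            raise FeatureError("expected 6 HR feature columns")
        if self.df[list(self.LABEL_COLS)].isna().any().any():
            raise FeatureError("missing labels in feature table")

    @property
    def fnirs_columns(self):
        return [c for c in fnirs_feature_columns() if c in self.df.columns]

    @property
    def hr_columns(self):
        return [c for c in hr_feature_columns() if c in self.df.columns]

    def to_csv(self, path):
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path):
        return cls(pd.read_csv(path))


def extract_session_features(ps: ProcessedSession, window_s=WINDOW_S,
                             min_partial_s=MIN_PARTIAL_S, band=COHERENCE_BAND_HZ,
                             max_duration_s=None) -> pd.DataFrame:
    """Windowed feature rows for one session's game interval.

    ``max_duration_s`` truncates the analysed game segment (used by the
    pain/no-pain duration matching).
    """
    fs = ps.sample_rate
    g0, g1 = ps.game_interval
    if max_duration_s is not None:
        g1 = min(g1, g0 + max_duration_s)
    i0, i1 = int(round(g0 * fs)), int(round(g1 * fs))
    seg = ps.hbo[:, i0:i1]
    n_ch = seg.shape[0]
    for ch in range(n_ch):
        if np.isnan(seg[ch]).all():
            raise FeatureError(f"channel {ch + 1} is all-missing")
    hrseg = np.asarray(ps.hr, float)[i0:i1]
    bounds = window_bounds(seg.shape[1], fs, window_s, min_partial_s)

    scales = morlet_scales(fs)
    Ws = [morlet_cwt(seg[ch], fs, scales) for ch in range(n_ch)]
    inv_s = 1.0 / scales[:, None]
    autos = [_smooth(np.abs(W) ** 2 * inv_s, scales, fs) for W in Ws]
    n_seg = seg.shape[1]
    t_seg = np.arange(n_seg) / fs
    coi = np.sqrt(2.0) * scales[:, None]
    valid = (t_seg[None, :] >= coi) & (t_seg[None, :] <= t_seg[-1] - coi)
    freqs = 1.0 / (_FOURIER_FACTOR * scales)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    pair_R2 = {}
    for a, b in combinations(range(n_ch), 2):
        Sxy = _smooth(Ws[a] * np.conj(Ws[b]) * inv_s, scales, fs)
        R2 = np.clip((np.abs(Sxy) ** 2 / (autos[a] * autos[b] + 1e-300)).real, 0.0, 1.0)
        pair_R2[(a, b)] = R2[in_band]
    band_valid = valid[in_band]
    rows = []
    for start, stop in bounds:
        row = {
            "participant_id": ps.participant_id,
            "condition": ps.condition,
            "demand": ps.demand,
            "pain": ps.pain,
            "window_start_s": g0 + start / fs,
        }
        for ch in range(n_ch):
            stats = hbo_stats(seg[ch, start:stop], fs)
            for name, val in zip(HBO_STATS, stats):
                row[f"ch{ch + 1}_{name}"] = val
        for a, b in combinations(range(n_ch), 2):
            row[f"pearson_ch{a + 1}_ch{b + 1}"] = pearson_conn(seg[a, start:stop], seg[b, start:stop])
        for a, b in combinations(range(n_ch), 2):
            win_R2 = pair_R2[(a, b)][:, start:stop]
            win_valid = band_valid[:, start:stop]
            row[f"wcoh_ch{a + 1}_ch{b + 1}"] = float(
                win_R2[win_valid].mean() if win_valid.any() else win_R2.mean()
            )
        for name, val in zip(HR_STATS, hr_stats(hrseg[start:stop])):
            row[f"hr_{name}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def assemble_features(processed_sessions, window_s=WINDOW_S, min_partial_s=MIN_PARTIAL_S,
                      band=COHERENCE_BAND_HZ) -> EpochFeatureTable:
    """EpochFeatureTable over the game sessions of a cohort.

    Sessions without a game interval (rest baselines, no-game cold pressor)
    are not windowed here; only in-game epochs enter classification.
    """
    frames = []
    for ps in processed_sessions:
        if ps.game_interval is None:
            continue
        frames.append(extract_session_features(ps, window_s, min_partial_s, band))
    if not frames:
        raise FeatureError("no game sessions to extract features from")
    return EpochFeatureTable(pd.concat(frames, ignore_index=True))
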