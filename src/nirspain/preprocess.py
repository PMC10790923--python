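"""Raw-stream preprocessing.

Optical density -> haemoglobin pipeline, in the enforced order:

1. mBLL inversion: per channel, the two-wavelength modified Beer-Lambert
   system is solved per sample for (dHbO, dHbR) in uM.
2. Accelerometer-gated motion correction: segments where the accelerometer
   moving standard deviation (MSD) and the fNIRS MSD jointly exceed their
   thresholds are reconstructed by interpolation between pre/post baselines.
   Correction precedes filtering: a narrow band-pass smears a step artifact
   into a transient lasting on the order of the pass band's longest period
   (~100 s), after which no local reconstruction can remove it.
3. Band-pass: 6th-order Chebyshev type-I (0.5 dB ripple), pass band
   0.01-0.09 Hz, applied forward-backward (zero phase).
4. CBSI: HbO/HbR are recombined so they are perfectly anti-correlated,
   suppressing motion-related common-mode noise; only HbO is used downstream.

ECG is reduced to a uniform heart-rate series (bpm) by band-pass + adaptive
threshold R-peak detection with physiological RR gating.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

# Molar extinction coefficients in uM^-1 cm^-1 (HbO, HbR), interpolated at the
# device wavelengths from a standard compiled haemoglobin absorption spectrum.
EXTINCTION_UM_CM = {
    761.0: (5.91e-4, 1.539e-3),
    847.0: (1.044e-3, 7.00e-4),
}

DEFAULT_DPF = 6.0  # differential pathlength factor; configurable, dimensionless


class PreprocessError(ValueError):
    pass


class StageOrderError(PreprocessError):
    """A pipeline stage was invoked out of order."""


def extinction_matrix(wavelengths=(847.0, 761.0)) -> np.ndarray:
    """2x2 matrix E with E[i] = (eps_HbO, eps_HbR) at wavelengths[i]."""
    return np.array([EXTINCTION_UM_CM[float(w)] for w in wavelengths])


def mbll_forward(hbo, hbr, separation_cm, dpf=DEFAULT_DPF, wavelengths=(847.0, 761.0)) -> np.ndarray:
    """Forward modified Beer-Lambert law: concentrations (uM) -> dOD (2, n)."""
    E = extinction_matrix(wavelengths)
    conc = np.vstack([np.asarray(hbo, float), np.asarray(hbr, float)])
    return (E @ conc) * separation_cm * dpf


def mbll_inverse(od, separation_cm, dpf=DEFAULT_DPF, extinction=None, wavelengths=(847.0, 761.0)):
    """Invert the two-wavelength mBLL system per sample.

    Parameters
    ----------
    od : (2, n) array of optical-density change, one row per wavelength.
    separation_cm : source-detector separation in cm.
    dpf : differential pathlength factor.
    extinction : optional explicit 2x2 coefficient matrix (uM^-1 cm^-1);
        defaults to the packaged table at ``wavelengths``.

    Returns
    -------
    (hbo, hbr) : concentration change in uM, each of length n.
    """
    od = np.atleast_2d(np.asarray(od, float))
    if od.shape[0] != 2:
        raise PreprocessError(f"expected 2 wavelengths, got {od.shape[0]}")
    if separation_cm <= 0:
        raise PreprocessError("separation must be > 0")
    E = extinction_matrix(wavelengths) if extinction is None else np.asarray(extinction, float)
    if abs(np.linalg.det(E)) < 1e-12:
        raise PreprocessError("extinction matrix is singular")
    conc = np.linalg.solve(E, od / (separation_cm * dpf))
    return conc[0], conc[1]


# --- band-pass filtering ---------------------------------------------------

def chebyshev_bandpass_sos(order=6, band=(0.01, 0.09), sample_rate=10.0, ripple_db=0.5):
    lo, hi = band
    if not (0 < lo < hi < sample_rate / 2):
        raise PreprocessError(f"band edges {band} invalid for rate {sample_rate}")
    return signal.cheby1(order, ripple_db, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")


def chebyshev_bandpass(series, order=6, band=(0.01, 0.09), sample_rate=10.0, ripple_db=0.5):
    """Zero-phase Chebyshev type-I band-pass along the last axis."""
    sos = chebyshev_bandpass_sos(order, band, sample_rate, ripple_db)
    return signal.sosfiltfilt(sos, np.asarray(series, float), axis=-1)


# --- motion artifacts ------------------------------------------------------

@dataclass(frozen=True)
class MotionSegment:
    """An interval flagged by joint accelerometer + fNIRS MSD exceedance."""

    channel: int | str  # 0-based channel index, or "all"
    start_s: float
    end_s: float
    trigger: str = "accel+fnirs"

    def __post_init__(self):
        if self.end_s <= self.start_s:
            raise PreprocessError("motion segment must have end > start")


def moving_std(x, win_samples: int) -> np.ndarray:
    """Centred moving standard deviation with edge replication."""
    x = np.asarray(x, float)
    m = uniform_filter1d(x, win_samples, mode="nearest", axis=-1)
    m2 = uniform_filter1d(x * x, win_samples, mode="nearest", axis=-1)
    return np.sqrt(np.maximum(m2 - m * m, 0.0))


def accel_magnitude_at(accel, accel_rate, out_rate, n_out) -> np.ndarray:
    """Gravity-removed windowed-RMS acceleration magnitude resampled to out_rate."""
    accel = np.asarray(accel, float)
    mag = np.linalg.norm(accel, axis=0)
    mag = mag - np.median(mag)
    edges = np.round(np.arange(n_out + 1) * accel_rate / out_rate).astype(int)
    edges = np.clip(edges, 0, len(mag))
    sq = mag * mag
    csum = np.concatenate([[0.0], np.cumsum(sq)])
    counts = np.maximum(np.diff(edges), 1)
    return np.sqrt(np.diff(csum[edges]) / counts)


def _runs_above(mask: np.ndarray):
    """Start/stop sample indices of True runs in a boolean mask."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return idx.reshape(-1, 2)


def merge_segments(runs, min_gap: float):
    """Merge (start, end) second intervals separated by less than min_gap."""
    if not runs:
        return []
    runs = sorted(runs)
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] < min_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(r) for r in merged]


def detect_motion_segments(
    accel,
    fnirs,
    accel_rate=512.0,
    fnirs_rate=10.0,
    accel_msd_win_s=1.0,
    fnirs_msd_win_s=2.0,
    accel_thresh=None,
    fnirs_thresh=None,
    merge_gap_s=1.0,
) -> list[MotionSegment]:
    """Mark intervals where accelerometer and fNIRS MSD jointly spike.

    The accelerometer is reduced to a gravity-removed RMS magnitude on the
    fNIRS time base; both streams are summarised by a moving standard
    deviation. A sample is flagged on a channel only when *both* MSDs exceed
    their thresholds (default: session mean + 2 sd of each MSD trace), and
    flagged runs closer than ``merge_gap_s`` are merged.
    """
    fnirs = np.atleast_2d(np.asarray(fnirs, float))
    if fnirs.size == 0 or np.asarray(accel).size == 0:
        raise PreprocessError("empty stream")
    n = fnirs.shape[1]
    amag = accel_magnitude_at(accel, accel_rate, fnirs_rate, n)
    a_msd = moving_std(amag, max(int(accel_msd_win_s * fnirs_rate), 2))
    f_msd = moving_std(fnirs, max(int(fnirs_msd_win_s * fnirs_rate), 2))
    for thr in (accel_thresh, fnirs_thresh):
        if thr is not None and np.any(np.atleast_1d(thr) <= 0):
            raise PreprocessError("thresholds must be > 0")
    # session-adaptive defaults; exactly quiescent streams yield 0, and the
    # strict > comparison then flags nothing
    if accel_thresh is None:
        accel_thresh = a_msd.mean() + 2.0 * a_msd.std()
    if fnirs_thresh is None:
        fnirs_thresh = f_msd.mean(axis=-1) + 2.0 * f_msd.std(axis=-1)
    fnirs_thresh = np.broadcast_to(np.atleast_1d(fnirs_thresh), (fnirs.shape[0],))
    a_mask = a_msd > accel_thresh
    segments = []
    for ch in range(fnirs.shape[0]):
        mask = a_mask & (f_msd[ch] > fnirs_thresh[ch])
        runs = [(s / fnirs_rate, e / fnirs_rate) for s, e in _runs_above(mask)]
        for s, e in merge_segments(runs, merge_gap_s):
            segments.append(MotionSegment(channel=ch, start_s=s, end_s=e))
    return segments


def correct_motion(series, segments, sample_rate=10.0, baseline_s=2.0) -> np.ndarray:
    """Reconstruct flagged segments by baseline-to-baseline interpolation.

    Outside the segments the series is returned unchanged. Inside, samples are
    replaced by a straight line between the mean of a ``baseline_s`` window
    before the segment and one after it; at the series edges only the
    available side is used (constant extrapolation).
    """
    x = np.atleast_2d(np.asarray(series, float)).copy()
    squeeze = np.asarray(series).ndim == 1
    n = x.shape[1]
    nb = max(int(baseline_s * sample_rate), 1)
    per_channel: dict[int, list] = {}
    for seg in segments:
        chans = range(x.shape[0]) if seg.channel == "all" else [int(seg.channel)]
        for ch in chans:
            per_channel.setdefault(ch, []).append(seg)
    for ch, segs in per_channel.items():
        segs = sorted(segs, key=lambda s: s.start_s)
        for a, b in zip(segs, segs[1:]):
            if b.start_s < a.end_s:
                raise PreprocessError(
                    f"overlapping unmerged segments on channel {ch}: "
                    f"[{a.start_s}, {a.end_s}) and [{b.start_s}, {b.end_s})"
                )
        for seg in segs:
            i0 = max(int(round(seg.start_s * sample_rate)), 0)
            i1 = min(int(round(seg.end_s * sample_rate)), n)
            if i1 <= i0:
                continue
            pre = x[ch, max(i0 - nb, 0):i0]
            post = x[ch, i1:i1 + nb]
            if pre.size == 0 and post.size == 0:
                continue  # segment spans the whole series; nothing to anchor on
            b0 = pre.mean() if pre.size else post.mean()
            b1 = post.mean() if post.size else pre.mean()
            x[ch, i0:i1] = np.linspace(b0, b1, i1 - i0)
    return x[0] if squeeze else x


# --- CBSI ------------------------------------------------------------------

def cbsi(hbo, hbr):
    """Correlation-based signal improvement.

    Per channel, with alpha = sd(hbo)/sd(hbr):
        hbo' = (hbo - alpha * hbr) / 2,   hbr' = -hbo' / alpha
    which makes corr(hbo', hbr') exactly -1 and cancels common-mode noise.
    """
    hbo = np.atleast_2d(np.asarray(hbo, float))
    hbr = np.atleast_2d(np.asarray(hbr, float))
    if hbo.shape != hbr.shape:
        raise PreprocessError("hbo and hbr must have equal shape")
    sd_o = hbo.std(axis=-1)
    sd_r = hbr.std(axis=-1)
    for ch in range(hbo.shape[0]):
        if sd_o[ch] == 0 or sd_r[ch] == 0:
            raise PreprocessError(f"zero-variance channel {ch} in CBSI")
    alpha = (sd_o / sd_r)[:, None]
    hbo_c = (hbo - alpha * hbr) / 2.0
    hbr_c = -hbo_c / alpha
    if np.asarray(hbo).ndim == 1:
        return hbo_c[0], hbr_c[0]
    return hbo_c, hbr_c


# --- heart rate from ECG ---------------------------------------------------

def hr_from_ecg(ecg, ecg_rate=250.0, out_rate=10.0, rr_bounds_s=(0.3, 2.0)):
    """Heart-rate series (bpm) from raw ECG via R-peak detection.

    Band-pass (5-15 Hz) emphasises the QRS complex; peaks are picked with an
    adaptive threshold (40% of the 99th percentile) and a 0.3-s refractory
    distance. RR intervals outside ``rr_bounds_s`` are discarded and the
    instantaneous rate 60/RR is interpolated to a uniform ``out_rate`` grid.
    """
    ecg = np.asarray(ecg, float)
    if len(ecg) < 10 * ecg_rate:
        raise PreprocessError("ECG shorter than 10 s")
    if ecg.std() < 1e-12:
        raise PreprocessError("no detectable R peaks (flat ECG)")
    sos = signal.butter(3, [5.0, 15.0], btype="bandpass", fs=ecg_rate, output="sos")
    filt = signal.sosfiltfilt(sos, ecg)
    height = 0.4 * np.percentile(np.abs(filt), 99)
    peaks, _ = signal.find_peaks(filt, height=height, distance=int(0.3 * ecg_rate))
    if len(peaks) < 3:
        raise PreprocessError("no detectable R peaks")
    beat_t = peaks / ecg_rate
    rr = np.diff(beat_t)
    ok = (rr >= rr_bounds_s[0]) & (rr <= rr_bounds_s[1])
    if not ok.any():
        raise PreprocessError("no physiologically plausible RR intervals")
    t_mid = (beat_t[:-1] + beat_t[1:]) / 2.0
    hr_inst = 60.0 / rr[ok]
    t_ok = t_mid[ok]
    t_out = np.arange(int(np.floor(len(ecg) / ecg_rate * out_rate))) / out_rate
    return np.interp(t_out, t_ok, hr_inst)


# --- staged container ------------------------------------------------------

@dataclass
class HemodynamicSeries:
    """Per-channel HbO/HbR concentration change with stage provenance."""

    hbo: np.ndarray  # (channels, samples), uM
    hbr: np.ndarray
    sample_rate: float = 10.0
    flags: dict = field(default_factory=lambda: {
        "mbll": False, "filtered": False, "motion_corrected": False, "cbsi": False,
    })

    def __post_init__(self):
        self.hbo = np.atleast_2d(np.asarray(self.hbo, float))
        self.hbr = np.atleast_2d(np.asarray(self.hbr, float))
        if self.hbo.shape != self.hbr.shape:
            raise PreprocessError("hbo/hbr must be equal length")

    def _require(self, *stages):
        for s in stages:
            if not self.flags[s]:
                raise StageOrderError(f"stage order violated: {s!r} has not been applied")


def hemodynamics_from_od(od, separations_cm, dpf=DEFAULT_DPF, sample_rate=10.0,
                         wavelengths=(847.0, 761.0)) -> HemodynamicSeries:
    """Stage 1: mBLL inversion of an (channels, 2, samples) OD array."""
    od = np.asarray(od, float)
    hbo = np.empty((od.shape[0], od.shape[2]))
    hbr = np.empty_like(hbo)
    for ch in range(od.shape[0]):
        hbo[ch], hbr[ch] = mbll_inverse(od[ch], separations_cm[ch], dpf, wavelengths=wavelengths)
    hs = HemodynamicSeries(hbo, hbr, sample_rate)
    hs.flags["mbll"] = True
    return hs


def apply_motion_correction(hs: HemodynamicSeries, accel, accel_rate=512.0, **kwargs):
    """Stage 2: accelerometer-gated artifact detection + reconstruction.

    Must run on the unfiltered concentrations: the band-pass would smear a
    step artifact into a transient spanning the pass band's longest period.
    """
    hs._require("mbll")
    if hs.flags["filtered"]:
        raise StageOrderError("motion correction must precede band-pass filtering")
    segments = detect_motion_segments(accel, hs.hbo, accel_rate=accel_rate,
                                      fnirs_rate=hs.sample_rate, **kwargs)
    hs.hbo = correct_motion(hs.hbo, segments, hs.sample_rate)
    hs.hbr = correct_motion(hs.hbr, segments, hs.sample_rate)
    hs.flags["motion_corrected"] = True
    return hs, segments


def apply_bandpass(hs: HemodynamicSeries, **kwargs) -> HemodynamicSeries:
    """Stage 3: zero-phase band-pass of both chromophores."""
    hs._require("mbll")
    hs.hbo = chebyshev_bandpass(hs.hbo, sample_rate=hs.sample_rate, **kwargs)
    hs.hbr = chebyshev_bandpass(hs.hbr, sample_rate=hs.sample_rate, **kwargs)
    hs.flags["filtered"] = True
    return hs


def apply_cbsi(hs: HemodynamicSeries) -> HemodynamicSeries:
    """Stage 4: CBSI; requires the full preceding chain."""
    hs._require("mbll", "motion_corrected", "filtered")
    hs.hbo, hs.hbr = cbsi(hs.hbo, hs.hbr)
    hs.flags["cbsi"] = True
    return hs


def preprocess_session(rec, montage=None, dpf=DEFAULT_DPF, motion_kwargs=None):
    """Full pipeline for one session.

    Returns ``(HemodynamicSeries, hr_bpm, segments)`` where ``hr_bpm`` is the
    session's heart-rate series on the fNIRS time base (precomputed HR is used
    when present, otherwise derived from ECG).
    """
    from nirspain.montage import default_montage

    if montage is None:
        montage = default_montage()
    seps = [c.separation for c in montage]
    hs = hemodynamics_from_od(rec.fnirs_od, seps, dpf=dpf, sample_rate=rec.fnirs_rate,
                              wavelengths=rec.wavelengths)
    hs, segments = apply_motion_correction(hs, rec.accel, accel_rate=rec.accel_rate,
                                           **(motion_kwargs or {}))
    apply_bandpass(hs)
    apply_cbsi(hs)
    if rec.hr is not None:
        n = hs.hbo.shape[1]
        t_out = np.arange(n) / hs.sample_rate
        t_in = np.arange(len(rec.hr)) / rec.hr_rate
        hr = np.interp(t_out, t_in, rec.hr)
    else:
        hr = hr_from_ecg(rec.ecg, rec.ecg_rate, out_rate=hs.sample_rate)
        n = hs.hbo.shape[1]
        if len(hr) < n:
            hr = np.pad(hr, (0, n - len(hr)), mode="edge")
        hr = hr[:n]
    return hs, hr, segments


def process_recording(rec, montage=None, dpf=DEFAULT_DPF, motion_kwargs=None):
    """Run the full pipeline and package the result for feature extraction."""
    from nirspain.features import ProcessedSession

    hs, hr, _segments = preprocess_session(rec, montage=montage, dpf=dpf,
                                           motion_kwargs=motion_kwargs)
    return ProcessedSession(
        participant_id=rec.participant_id,
        condition=rec.condition,
        hbo=hs.hbo,
        hr=hr,
        sample_rate=hs.sample_rate,
        game_interval=rec.event_interval("game"),
        immersion_interval=rec.event_interval("immersion"),
    )
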