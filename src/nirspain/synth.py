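"""Synthetic cohort generator with known ground truth.

Emulates the study design: 20 participants, each playing a ~180-s racing game
at Easy and Hard demand, with and without cold-pressor pain, plus a resting
baseline and a no-game cold-pressor session. Each session carries the
statistical structure the downstream analysis assumes:

* demand-dependent cortical activation — a sustained boxcar plus randomly
  timed game-event responses, both convolved with a canonical double-gamma
  HRF peaking at ~7 s;
* physiological oscillations (cardiac, respiratory, Mayer waves), white
  noise, and slow drift;
* anti-correlated HbO/HbR (HbR = -ratio * HbO + independent noise);
* optical density built by the *forward* modified Beer-Lambert law, so the
  preprocessing stage can invert it;
* motion artifacts injected into the OD only inside accelerometer bursts;
* a heart-rate series elevated by game demand and by cold-pressor immersion;
* immersion (pain-tolerance) durations drawn from a right-censored log-normal
  calibrated so the censored means match the behavioural targets
  (22.5 s no-game, 48.5 s Easy, 74.07 s Hard; 180-s cap).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import json

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from nirspain.preprocess import mbll_forward, DEFAULT_DPF
from nirspain.session import SessionRecording, GAME_CONDITIONS, write_recording
from nirspain.montage import default_montage


class SimulationError(ValueError):
    pass


# --- configuration ---------------------------------------------------------

@dataclass(frozen=True)
class NoiseConfig:
    cardiac_hz: float = 1.1
    resp_hz: float = 0.25
    mayer_hz: float = 0.1
    cardiac_amp: float = 0.08  # uM
    resp_amp: float = 0.15
    mayer_amp: float = 0.3
    white_sd: float = 0.3
    drift_slope: float = 0.1  # uM per minute (sd of the random linear drift)


@dataclass(frozen=True)
class ArtifactConfig:
    rate_per_min: float = 2.0
    step_amp_um: float = 8.0  # HbO-equivalent OD step amplitude
    accel_burst_g: float = 0.5
    min_dur_s: float = 0.5
    max_dur_s: float = 2.0


@dataclass(frozen=True)
class ToleranceConfig:
    """Behavioural pain-tolerance calibration targets (censored mean, sd, cap)."""

    baseline_mean_s: float = 22.5
    baseline_sd_s: float = 9.75
    easy_mean_s: float = 48.5
    easy_sd_s: float = 35.73
    hard_mean_s: float = 74.07
    hard_sd_s: float = 64.11
    cap_s: float = 180.0


@dataclass(frozen=True)
class SimulationConfig:
    n_participants: int = 20
    demand_effect: float = 0.3  # uM HbO amplitude gain, Hard vs Easy
    base_activation: float = 0.5  # uM Easy-demand activation amplitude
    pain_effect_hr: float = 5.0  # bpm shift during immersion
    demand_effect_hr: float = 2.0  # bpm shift, Hard vs Easy, during the game
    hrf_peak_time: float = 7.0  # s
    hbr_ratio: float = 1.0 / 3.0  # HbR = -ratio * HbO + noise
    event_rate_per_min: float = 4.0  # in-game activation events
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    artifact: ArtifactConfig = field(default_factory=ArtifactConfig)
    tolerance: ToleranceConfig = field(default_factory=ToleranceConfig)
    baseline_s: float = 90.0
    game_s: float = 180.0
    post_s: float = 15.0
    fnirs_rate: float = 10.0
    accel_rate: float = 512.0
    seed: int = 0

    def __post_init__(self):
        if self.hrf_peak_time <= 0:
            raise SimulationError("hrf_peak_time must be > 0")
        if self.tolerance.cap_s <= 0:
            raise SimulationError("tolerance cap must be > 0")

    def null(self) -> "SimulationConfig":
        """A copy with all demand and pain effects removed."""
        return replace(self, demand_effect=0.0, demand_effect_hr=0.0, pain_effect_hr=0.0)


@dataclass
class GroundTruth:
    participant_id: str
    condition: str
    activation_amplitude: float  # uM, per-session event/boxcar amplitude scale
    clean_hbo: np.ndarray  # (channels, samples) activation without noise
    artifact_segments: list  # [(start_s, end_s), ...]
    immersion_duration_s: float | None
    hr_baseline_bpm: float


# --- canonical HRF ---------------------------------------------------------

def canonical_hrf(peak_time=7.0, sample_rate=10.0, duration_s=30.0, undershoot_ratio=1.0 / 6.0):
    """Double-gamma haemodynamic response kernel with unit peak amplitude.

    The positive lobe is a gamma density with its mode at ``peak_time``; the
    undershoot is a wider gamma peaking at 2.3x that latency, scaled to
    ``undershoot_ratio`` of the peak. Support is ``duration_s`` seconds.
    """
    if peak_time <= 0:
        raise SimulationError("peak_time must be > 0")
    if sample_rate <= 0:
        raise SimulationError("sample_rate must be > 0")
    t = np.arange(int(round(duration_s * sample_rate))) / sample_rate
    shape1, shape2 = 6.0, 12.0
    scale1 = peak_time / (shape1 - 1.0)
    scale2 = 2.3 * peak_time / (shape2 - 1.0)

    def gamma_lobe(shape, scale):
        g = t ** (shape - 1.0) * np.exp(-t / scale)
        return g / g.max()

    h = gamma_lobe(shape1, scale1) - undershoot_ratio * gamma_lobe(shape2, scale2)
    return h / h.max()


# --- censored tolerance model ---------------------------------------------

@dataclass(frozen=True)
class ToleranceModel:
    """Log-normal immersion-duration model, right-censored at ``cap_s``."""

    mu: float
    sigma: float
    cap_s: float

    def censored_mean(self) -> float:
        return _censored_lognormal_mean(self.mu, self.sigma, self.cap_s)

    def censor_probability(self) -> float:
        return float(1.0 - norm.cdf((np.log(self.cap_s) - self.mu) / self.sigma))

    def sample(self, n, rng) -> np.ndarray:
        return np.minimum(rng.lognormal(self.mu, self.sigma, size=n), self.cap_s)


def _censored_lognormal_mean(mu, sigma, cap):
    z = (np.log(cap) - mu) / sigma
    return float(np.exp(mu + sigma**2 / 2.0) * norm.cdf(z - sigma) + cap * (1.0 - norm.cdf(z)))


def calibrate_truncated_mean(target_mean_s, sd_s, cap_s=180.0) -> ToleranceModel:
    """Solve for a right-censored log-normal whose censored mean hits the target.

    The log-scale spread is fixed from the target coefficient of variation
    (sigma^2 = ln(1 + (sd/mean)^2)) and the location ``mu`` is solved
    numerically so the *censored* mean equals ``target_mean_s``.
    """
    if not (0.0 < target_mean_s < cap_s):
        raise SimulationError(f"target mean {target_mean_s} infeasible for cap {cap_s}")
    if sd_s <= 0:
        raise SimulationError("sd must be > 0")
    sigma = float(np.sqrt(np.log1p((sd_s / target_mean_s) ** 2)))
    f = lambda mu: _censored_lognormal_mean(mu, sigma, cap_s) - target_mean_s
    lo, hi = np.log(target_mean_s) - 10.0, np.log(cap_s) + 20.0
    mu = brentq(f, lo, hi, xtol=1e-10)
    model = ToleranceModel(mu=mu, sigma=sigma, cap_s=cap_s)
    assert abs(model.censored_mean() - target_mean_s) < 0.5
    return model


def tolerance_models(cfg: ToleranceConfig):
    """Calibrated models for the no-game, Easy and Hard conditions."""
    return {
        "baseline": calibrate_truncated_mean(cfg.baseline_mean_s, cfg.baseline_sd_s, cfg.cap_s),
        "easy": calibrate_truncated_mean(cfg.easy_mean_s, cfg.easy_sd_s, cfg.cap_s),
        "hard": calibrate_truncated_mean(cfg.hard_mean_s, cfg.hard_sd_s, cfg.cap_s),
    }


# --- per-session synthesis -------------------------------------------------

#: relative activation gain per channel (frontal channels respond more
#: strongly than central-parietal ones)
CHANNEL_GAIN = np.array([1.0, 0.9, 0.95, 0.9, 0.6, 0.55, 0.6, 0.55])


def _session_rng(config: SimulationConfig, participant_index: int, condition: str):
    cond_idx = ("baseline", "cpt_only", "easy", "hard", "easy_pain", "hard_pain").index(condition)
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(participant_index, cond_idx))
    return np.random.default_rng(ss)


def _smooth_mask(mask, sample_rate, tau_s=3.0):
    """Soften binary on/off transitions with a causal exponential kernel."""
    k = np.exp(-np.arange(int(5 * tau_s * sample_rate)) / (tau_s * sample_rate))
    k /= k.sum()
    return np.convolve(mask, k)[: len(mask)]


def simulate_session(config: SimulationConfig, participant_index: int, condition: str,
                     rng=None, with_ecg: bool = False,
                     immersion_s: float | None = None):
    """Generate one (SessionRecording, GroundTruth) pair.

    ``participant_index`` selects the participant-level random stream so a
    fixed config seed reproduces the session bit-for-bit regardless of which
    other sessions are generated.
    """
    if condition not in GAME_CONDITIONS + ("baseline", "cpt_only"):
        raise SimulationError(f"unknown condition {condition!r}")
    if rng is None:
        rng = _session_rng(config, participant_index, condition)
    fs = config.fnirs_rate
    tol = tolerance_models(config.tolerance)

    # participant-stable quantities are drawn from a dedicated stream so every
    # condition of one participant shares them
    prng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed,
                                                        spawn_key=(participant_index, 99)))
    participant_gain = prng.lognormal(0.0, 0.2)
    hr_baseline = prng.normal(70.0, 5.0)

    is_game = condition in GAME_CONDITIONS
    if is_game:
        total_s = config.baseline_s + config.game_s + config.post_s
        game = (config.baseline_s, config.baseline_s + config.game_s)
    elif condition == "baseline":
        total_s = config.baseline_s
        game = None
    else:  # cpt_only
        total_s = 30.0 + config.tolerance.cap_s + 30.0
        game = None
    n = int(round(total_s * fs))
    t = np.arange(n) / fs

    events = []
    demand = "hard" if condition.startswith("hard") else ("easy" if condition.startswith("easy") else None)
    immersion = None
    if condition in ("easy_pain", "hard_pain"):
        dur = immersion_s if immersion_s is not None else float(tol[demand].sample(1, rng)[0])
        dur = min(dur, config.game_s)
        immersion = (game[0], game[0] + dur)
        events.append(("immersion", *immersion))
    elif condition == "cpt_only":
        dur = immersion_s if immersion_s is not None else float(tol["baseline"].sample(1, rng)[0])
        immersion = (30.0, 30.0 + dur)
        events.append(("immersion", *immersion))
    if is_game:
        events.insert(0, ("game", *game))
        events.insert(0, ("baseline", 0.0, config.baseline_s))
    elif condition == "baseline":
        events.append(("baseline", 0.0, total_s))

    # --- activation ground truth ------------------------------------------
    hrf = canonical_hrf(config.hrf_peak_time, fs)
    clean = np.zeros((8, n))
    amplitude = 0.0
    if is_game:
        amplitude = (config.base_activation +
                     (config.demand_effect if demand == "hard" else 0.0)) * participant_gain
        stim = np.zeros(n)
        g0, g1 = int(game[0] * fs), int(game[1] * fs)
        stim[g0:g1] = 1.0
        n_events = rng.poisson(config.event_rate_per_min * config.game_s / 60.0)
        impulses = np.zeros(n)
        for et in np.sort(rng.uniform(game[0], game[1] - 10.0, size=n_events)):
            impulses[int(et * fs)] += rng.lognormal(0.0, 0.3)
        # sustained component plateaus at 0.5x amplitude; each game event adds
        # a unit-peak HRF response scaled by 0.8x amplitude
        drive = (0.5 * np.convolve(stim, hrf)[:n] / hrf.sum()
                 + 0.8 * np.convolve(impulses, hrf)[:n])
        clean = amplitude * CHANNEL_GAIN[:, None] * drive[None, :]

    # --- physiological noise ----------------------------------------------
    nz = config.noise
    hbo = clean.copy()
    for ch in range(8):
        osc = (nz.cardiac_amp * np.sin(2 * np.pi * nz.cardiac_hz * t + rng.uniform(0, 2 * np.pi))
               + nz.resp_amp * np.sin(2 * np.pi * nz.resp_hz * t + rng.uniform(0, 2 * np.pi))
               + nz.mayer_amp * np.sin(2 * np.pi * nz.mayer_hz * t + rng.uniform(0, 2 * np.pi)))
        drift = rng.normal(0.0, nz.drift_slope) * t / 60.0
        hbo[ch] += osc + drift + rng.normal(0.0, nz.white_sd, size=n)
    hbr = -config.hbr_ratio * hbo + rng.normal(0.0, 0.3 * nz.white_sd, size=(8, n))

    # --- forward mBLL to optical density ----------------------------------
    montage = default_montage()
    od = np.empty((8, 2, n))
    for ch in range(8):
        od[ch] = mbll_forward(hbo[ch], hbr[ch], montage[ch].separation, DEFAULT_DPF)

    # --- motion artifacts + accelerometer ----------------------------------
    art = config.artifact
    n_acc = int(round(total_s * config.accel_rate))
    t_acc = np.arange(n_acc) / config.accel_rate
    accel = rng.normal(0.0, 0.01, size=(3, n_acc))
    accel[2] += 1.0  # gravity
    artifact_segments = []
    n_art = rng.poisson(art.rate_per_min * total_s / 60.0) if art.rate_per_min > 0 else 0
    starts = np.sort(rng.uniform(2.0, total_s - art.max_dur_s - 2.0, size=n_art))
    for s in starts:
        d = rng.uniform(art.min_dur_s, art.max_dur_s)
        if artifact_segments and s < artifact_segments[-1][1] + 2.0:
            continue  # keep bursts separated
        seg = (float(s), float(s + d))
        artifact_segments.append(seg)
        i0, i1 = int(seg[0] * fs), int(seg[1] * fs)
        sign = rng.choice([-1.0, 1.0])
        step_um = sign * art.step_amp_um
        for ch in range(8):
            jitter = rng.uniform(0.8, 1.2)
            od_step = mbll_forward(np.full(i1 - i0, step_um * jitter), np.zeros(i1 - i0),
                                   montage[ch].separation, DEFAULT_DPF)
            od[ch, :, i0:i1] += od_step
        a0, a1 = int(seg[0] * config.accel_rate), int(seg[1] * config.accel_rate)
        burst = art.accel_burst_g * np.sin(2 * np.pi * 5.0 * t_acc[a0:a1])
        accel[:, a0:a1] += burst * rng.uniform(0.5, 1.0, size=(3, 1)) \
            + rng.normal(0.0, art.accel_burst_g / 3.0, size=(3, a1 - a0))

    # --- heart rate ---------------------------------------------------------
    hr = np.full(n, hr_baseline)
    hr += 1.5 * np.sin(2 * np.pi * 0.01 * t + rng.uniform(0, 2 * np.pi))
    if is_game:
        gmask = np.zeros(n)
        gmask[int(game[0] * fs):int(game[1] * fs)] = 1.0
        hr += (3.0 + (config.demand_effect_hr if demand == "hard" else 0.0)) * _smooth_mask(gmask, fs)
    if immersion is not None:
        imask = np.zeros(n)
        imask[int(immersion[0] * fs):int(immersion[1] * fs)] = 1.0
        hr += config.pain_effect_hr * _smooth_mask(imask, fs)
    hr += _smooth_mask(rng.normal(0.0, 2.0, size=n), fs, tau_s=1.0) * 3.0

    ecg = synthesize_ecg(hr, fs, rng) if with_ecg else None
    rec = SessionRecording(
        participant_id=f"P{participant_index + 1:02d}",
        condition=condition,
        fnirs_od=od,
        accel=accel,
        events=events,
        ecg=ecg,
        hr=None if with_ecg else hr,
        hr_rate=fs,
        fnirs_rate=fs,
        accel_rate=config.accel_rate,
    )
    truth = GroundTruth(
        participant_id=rec.participant_id,
        condition=condition,
        activation_amplitude=float(amplitude),
        clean_hbo=clean,
        artifact_segments=artifact_segments,
        immersion_duration_s=None if immersion is None else immersion[1] - immersion[0],
        hr_baseline_bpm=float(hr_baseline),
    )
    return rec, truth


def synthesize_ecg(hr_bpm, hr_rate, rng, ecg_rate=250.0):
    """Simple R-wave template train following an instantaneous-rate series."""
    dur = len(hr_bpm) / hr_rate
    t_hr = np.arange(len(hr_bpm)) / hr_rate
    beats = []
    t_beat = 0.3
    while t_beat < dur:
        beats.append(t_beat)
        bpm = np.interp(t_beat, t_hr, hr_bpm)
        t_beat += 60.0 / bpm
    n = int(dur * ecg_rate)
    t = np.arange(n) / ecg_rate
    ecg = rng.normal(0.0, 0.02, size=n)
    for b in beats:
        ecg += np.exp(-0.5 * ((t - b) / 0.012) ** 2)  # narrow R spike
        ecg -= 0.12 * np.exp(-0.5 * ((t - b - 0.16) / 0.05) ** 2)  # T-ish wave
    return ecg


# --- cohort ----------------------------------------------------------------

_ORDERS = [  # counterbalanced 4-condition presentation orders (Latin square)
    ("easy", "easy_pain", "hard", "hard_pain"),
    ("easy_pain", "hard", "hard_pain", "easy"),
    ("hard", "hard_pain", "easy", "easy_pain"),
    ("hard_pain", "easy", "easy_pain", "hard"),
]


@dataclass
class Cohort:
    config: SimulationConfig
    sessions: list  # [(SessionRecording, GroundTruth), ...]

    def recordings(self, conditions=None):
        return [r for r, _ in self.sessions if conditions is None or r.condition in conditions]

    def __len__(self):
        return len(self.sessions)


def simulate_cohort(config: SimulationConfig, include_rest: bool = True,
                    game_conditions=None) -> Cohort:
    """All sessions for ``config.n_participants`` participants.

    Each participant contributes the four game conditions in a counterbalanced
    order plus, when ``include_rest``, a resting baseline and a no-game
    cold-pressor session. ``game_conditions`` restricts the game sessions to a
    subset (e.g. only Easy/Hard without pain) for reduced designs.
    """
    sessions = []
    for p in range(config.n_participants):
        order = _ORDERS[p % len(_ORDERS)]
        if game_conditions is not None:
            order = tuple(c for c in order if c in game_conditions)
        conds = (("baseline", "cpt_only") if include_rest else ()) + order
        for cond in conds:
            sessions.append(simulate_session(config, p, cond))
    return Cohort(config=config, sessions=sessions)


def write_cohort(cohort: Cohort, outdir, fnirs_format: str = "csv") -> Path:
    """Write every session as a directory plus a ground-truth summary JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = []
    for rec, gt in cohort.sessions:
        write_recording(rec, outdir / f"{rec.participant_id}_{rec.condition}", fnirs_format)
        truth.append({
            "participant_id": gt.participant_id,
            "condition": gt.condition,
            "activation_amplitude_um": gt.activation_amplitude,
            "artifact_segments_s": gt.artifact_segments,
            "immersion_duration_s": gt.immersion_duration_s,
            "hr_baseline_bpm": gt.hr_baseline_bpm,
        })
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return outdir
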