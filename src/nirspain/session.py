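"""Session container and on-disk formats.

A session is one participant-condition recording: continuous fNIRS optical
density (8 channels x 2 wavelengths at 10 Hz), 3-axis accelerometer (512 Hz),
and ECG (250 Hz) and/or a precomputed heart-rate series, plus an event table.

On disk a session is a directory:

    meta.json        participant, condition, sampling rates, fNIRS format
    fnirs.csv        (or fnirs.snirf) time + ch{i}_wl{nm} columns
    accel.csv        time, ax, ay, az  (g)
    ecg.csv          time, ecg  (mV)      [optional]
    hr.csv           time, bpm            [optional]
    events.json      [{label, start_s, end_s}, ...]   half-open [start, end)

CSV files use one header line, comma separation, a time column in seconds from
the stream origin, and fixed 6-decimal formatting, so write -> read round-trips
bit-exactly for data quantised to 6 decimals. SNIRF (HDF5) round-trips within
float tolerance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from nirspain.montage import WAVELENGTHS_NM

FNIRS_RATE = 10.0
ACCEL_RATE = 512.0
ECG_RATE = 250.0

GAME_CONDITIONS = ("easy", "hard", "easy_pain", "hard_pain")
CONDITIONS = GAME_CONDITIONS + ("baseline", "cpt_only")

CSV_FLOAT_FMT = "%.6f"
_RATE_RTOL = 0.01


class SessionError(ValueError):
    """Missing stream, malformed file, or inconsistent metadata."""


@dataclass
class SessionRecording:
    participant_id: str
    condition: str
    fnirs_od: np.ndarray  # (8 channels, 2 wavelengths, n) at 10 Hz
    accel: np.ndarray  # (3, m) at 512 Hz, g
    events: list[tuple[str, float, float]]
    ecg: np.ndarray | None = None  # 250 Hz, mV
    hr: np.ndarray | None = None  # bpm
    hr_rate: float = FNIRS_RATE
    fnirs_rate: float = FNIRS_RATE
    accel_rate: float = ACCEL_RATE
    ecg_rate: float = ECG_RATE
    wavelengths: tuple[float, float] = field(default=WAVELENGTHS_NM)

    def __post_init__(self):
        self.fnirs_od = np.asarray(self.fnirs_od, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        if self.condition not in CONDITIONS:
            raise SessionError(f"unknown condition {self.condition!r}")
        if self.fnirs_od.ndim != 3 or self.fnirs_od.shape[1] != 2:
            raise SessionError("fnirs_od must have shape (channels, 2 wavelengths, samples)")
        if self.accel.ndim != 2 or self.accel.shape[0] != 3:
            raise SessionError("accel must have shape (3, samples)")
        if self.ecg is None and self.hr is None:
            raise SessionError("at least one of ecg/hr must be present")
        dur = self.duration_s
        for label, start, end in self.events:
            if not (0.0 <= start < end <= dur + 1e-6):
                raise SessionError(f"event {label!r} [{start}, {end}) outside recording (0, {dur:.1f})")
        game = self.event_interval("game")
        if game is not None and game[1] - game[0] > 185.0:
            raise SessionError("game interval longer than 185 s")

    @property
    def n_channels(self) -> int:
        return self.fnirs_od.shape[0]

    @property
    def duration_s(self) -> float:
        return self.fnirs_od.shape[2] / self.fnirs_rate

    def event_interval(self, label: str) -> tuple[float, float] | None:
        for lab, start, end in self.events:
            if lab == label:
                return (start, end)
        return None

    @property
    def demand(self) -> str | None:
        if self.condition.startswith("easy"):
            return "Easy"
        if self.condition.startswith("hard"):
            return "Hard"
        return None

    @property
    def pain(self) -> bool:
        return self.condition.endswith("_pain") or self.condition == "cpt_only"


def _check_time_axis(t: np.ndarray, rate: float, name: str) -> None:
    if len(t) > 1:
        dt = np.median(np.diff(t))
        if abs(dt * rate - 1.0) > _RATE_RTOL:
            raise SessionError(
                f"{name}: timestamp spacing {dt:.6f} s inconsistent with "
                f"declared rate {rate} Hz"
            )


def _fnirs_columns(n_channels: int, wavelengths) -> list[str]:
    return [f"ch{c + 1}_wl{int(wl)}" for c in range(n_channels) for wl in wavelengths]


def _write_csv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FMT)


def write_recording(rec: SessionRecording, path, fnirs_format: str = "csv") -> Path:
    """Write a session directory; returns the directory path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "participant_id": rec.participant_id,
        "condition": rec.condition,
        "fnirs_rate": rec.fnirs_rate,
        "accel_rate": rec.accel_rate,
        "ecg_rate": rec.ecg_rate,
        "hr_rate": rec.hr_rate,
        "wavelengths": list(rec.wavelengths),
        "fnirs_format": fnirs_format,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    events = [{"label": l, "start_s": s, "end_s": e} for l, s, e in rec.events]
    (path / "events.json").write_text(json.dumps(events, indent=1))

    n = rec.fnirs_od.shape[2]
    t = np.arange(n) / rec.fnirs_rate
    flat = rec.fnirs_od.reshape(rec.n_channels * 2, n).T  # ch-major, wl-minor
    if fnirs_format == "csv":
        df = pd.DataFrame(flat, columns=_fnirs_columns(rec.n_channels, rec.wavelengths))
        df.insert(0, "time", t)
        _write_csv(path / "fnirs.csv", df)
    elif fnirs_format == "snirf":
        _write_snirf(path / "fnirs.snirf", rec, t, flat)
    else:
        raise SessionError(f"unknown fnirs_format {fnirs_format!r}")

    ta = np.arange(rec.accel.shape[1]) / rec.accel_rate
    _write_csv(path / "accel.csv", pd.DataFrame({"time": ta, "ax": rec.accel[0], "ay": rec.accel[1], "az": rec.accel[2]}))
    if rec.ecg is not None:
        te = np.arange(len(rec.ecg)) / rec.ecg_rate
        _write_csv(path / "ecg.csv", pd.DataFrame({"time": te, "ecg": rec.ecg}))
    if rec.hr is not None:
        th = np.arange(len(rec.hr)) / rec.hr_rate
        _write_csv(path / "hr.csv", pd.DataFrame({"time": th, "bpm": rec.hr}))
    return path


def read_recording(path) -> SessionRecording:
    """Read a session directory written by :func:`write_recording`."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise SessionError(f"missing meta.json in {path}")
    meta = json.loads(meta_path.read_text())
    events_path = path / "events.json"
    if not events_path.exists():
        raise SessionError(f"missing events.json in {path}")
    events = [(d["label"], float(d["start_s"]), float(d["end_s"])) for d in json.loads(events_path.read_text())]

    wavelengths = tuple(meta.get("wavelengths", WAVELENGTHS_NM))
    fnirs_rate = float(meta.get("fnirs_rate", FNIRS_RATE))
    fmt = meta.get("fnirs_format", "csv")
    if fmt == "csv":
        fpath = path / "fnirs.csv"
        if not fpath.exists():
            raise SessionError("missing stream: fnirs (fnirs.csv)")
        df = pd.read_csv(fpath)
        _check_time_axis(df["time"].to_numpy(), fnirs_rate, "fnirs")
        cols = _fnirs_columns((df.shape[1] - 1) // 2, wavelengths)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SessionError(f"fnirs.csv missing columns {missing}")
        flat = df[cols].to_numpy().T
        od = flat.reshape(len(cols) // 2, 2, -1)
    elif fmt == "snirf":
        fpath = path / "fnirs.snirf"
        if not fpath.exists():
            raise SessionError("missing stream: fnirs (fnirs.snirf)")
        od, fnirs_rate, wavelengths = _read_snirf(fpath)
    else:
        raise SessionError(f"unknown fnirs_format {fmt!r}")

    apath = path / "accel.csv"
    if not apath.exists():
        raise SessionError("missing stream: accel (accel.csv)")
    adf = pd.read_csv(apath)
    accel_rate = float(meta.get("accel_rate", ACCEL_RATE))
    _check_time_axis(adf["time"].to_numpy(), accel_rate, "accel")
    accel = adf[["ax", "ay", "az"]].to_numpy().T

    ecg = hr = None
    if (path / "ecg.csv").exists():
        edf = pd.read_csv(path / "ecg.csv")
        _check_time_axis(edf["time"].to_numpy(), float(meta.get("ecg_rate", ECG_RATE)), "ecg")
        ecg = edf["ecg"].to_numpy()
    if (path / "hr.csv").exists():
        hdf = pd.read_csv(path / "hr.csv")
        _check_time_axis(hdf["time"].to_numpy(), float(meta.get("hr_rate", FNIRS_RATE)), "hr")
        hr = hdf["bpm"].to_numpy()
    if ecg is None and hr is None:
        raise SessionError("missing stream: ecg or hr (need at least one)")

    return SessionRecording(
        participant_id=meta["participant_id"],
        condition=meta["condition"],
        fnirs_od=od,
        accel=accel,
        events=events,
        ecg=ecg,
        hr=hr,
        hr_rate=float(meta.get("hr_rate", FNIRS_RATE)),
        fnirs_rate=fnirs_rate,
        accel_rate=accel_rate,
        ecg_rate=float(meta.get("ecg_rate", ECG_RATE)),
        wavelengths=wavelengths,
    )


# --- minimal SNIRF (HDF5) support -----------------------------------------

def _write_snirf(fpath: Path, rec: SessionRecording, t: np.ndarray, flat: np.ndarray) -> None:
    with h5py.File(fpath, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        data = nirs.create_group("data1")
        data.create_dataset("dataTimeSeries", data=flat)
        data.create_dataset("time", data=t)
        for i in range(flat.shape[1]):
            ch, wl = divmod(i, 2)
            ml = data.create_group(f"measurementList{i + 1}")
            ml.create_dataset("sourceIndex", data=np.int32(ch + 1))
            ml.create_dataset("detectorIndex", data=np.int32(ch + 1))
            ml.create_dataset("wavelengthIndex", data=np.int32(wl + 1))
            ml.create_dataset("dataType", data=np.int32(1))
            ml.create_dataset("dataTypeIndex", data=np.int32(1))
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths, dtype=float))


def _read_snirf(fpath: Path):
    with h5py.File(fpath, "r") as f:
        data = f["nirs/data1"]
        flat = data["dataTimeSeries"][()]
        t = data["time"][()]
        wavelengths = tuple(f["nirs/probe/wavelengths"][()])
        n_meas = flat.shape[1]
        wl_index = np.zeros(n_meas, dtype=int)
        for i in range(n_meas):
            ml = data.get(f"measurementList{i + 1}")
            if ml is None or "wavelengthIndex" not in ml:
                raise SessionError(f"SNIRF measurementList{i + 1} missing wavelength index")
            wl_index[i] = int(ml["wavelengthIndex"][()])
    if set(wl_index) != {1, 2}:
        raise SessionError("SNIRF file does not contain both wavelength indices")
    if len(t) > 1:
        rate = 1.0 / float(np.median(np.diff(t)))
    else:
        rate = FNIRS_RATE
    _check_time_axis(t, rate, "fnirs")
    od = flat.T.reshape(n_meas // 2, 2, -1)
    return od, rate, wavelengths
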