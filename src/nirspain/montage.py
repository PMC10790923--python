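"""Montage definitions and optode geometry.

The default montage is a sparse midline layout: two sources (Fz, CPz), each
paired with four detectors over prefrontal and central-parietal cortex, giving
eight channels sampled at two near-infrared wavelengths (847 and 761 nm).
Optode positions are MNI coordinates in mm; source-detector separations are
reported in cm.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

WAVELENGTHS_NM = (847.0, 761.0)

#: tolerance (cm) for the strict separation-vs-coordinates invariant
SEPARATION_TOL_CM = 0.005
#: looser tolerance (cm) used when cross-checking a file's stored separation
#: column, which may carry independent rounding
STORED_SEPARATION_TOL_CM = 0.025


class MontageError(ValueError):
    """Malformed or inconsistent montage definition."""


@dataclass(frozen=True)
class MontageChannel:
    """One source-detector pair of the fNIRS montage."""

    channel_id: int
    source_label: str
    detector_label: str
    source_mni: np.ndarray  # mm
    detector_mni: np.ndarray  # mm
    separation: float  # cm, recomputed from the coordinates
    wavelengths: tuple[float, float] = field(default=WAVELENGTHS_NM)

    def __post_init__(self):
        object.__setattr__(self, "source_mni", np.asarray(self.source_mni, dtype=float))
        object.__setattr__(self, "detector_mni", np.asarray(self.detector_mni, dtype=float))
        if self.separation <= 0:
            raise MontageError(f"channel {self.channel_id}: separation must be > 0")
        d = optode_distance(self.source_mni, self.detector_mni)
        if abs(d - self.separation) > SEPARATION_TOL_CM:
            raise MontageError(
                f"channel {self.channel_id}: separation {self.separation:.3f} cm "
                f"does not match coordinates ({d:.3f} cm)"
            )


def optode_distance(source_mni, detector_mni) -> float:
    """Euclidean source-detector distance in cm from MNI coordinates in mm."""
    a = np.asarray(source_mni, dtype=float)
    b = np.asarray(detector_mni, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("optode coordinates must be finite")
    if a.shape != (3,) or b.shape != (3,):
        raise ValueError("optode coordinates must be 3-vectors")
    return float(np.linalg.norm(a - b)) / 10.0


def display_distance(distance_cm: float) -> float:
    """Round a separation for display: half-even to 2 decimals."""
    return float(np.round(distance_cm, 2))


_REQUIRED_COLS = [
    "channel_id",
    "source_label",
    "detector_label",
    "source_x",
    "source_y",
    "source_z",
    "detector_x",
    "detector_y",
    "detector_z",
]


def load_montage(path, n_channels: int = 8) -> list[MontageChannel]:
    """Read a TSV montage table into a validated list of channels.

    The file carries one row per channel with the optode labels and MNI
    coordinates (mm); an optional ``separation_cm`` column is cross-checked
    against the distance recomputed from the coordinates.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise MontageError(f"cannot parse montage table {path}: {exc}") from exc
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise MontageError(f"montage table missing columns: {missing}")
    channels = []
    for i, row in df.iterrows():
        coords = row[["source_x", "source_y", "source_z", "detector_x", "detector_y", "detector_z"]]
        try:
            coords = coords.astype(float).to_numpy()
            cid = int(row["channel_id"])
        except (TypeError, ValueError) as exc:
            raise MontageError(f"montage row {i + 1}: non-numeric value ({exc})") from exc
        src, det = coords[:3], coords[3:]
        sep = optode_distance(src, det)
        if "separation_cm" in df.columns and np.isfinite(row["separation_cm"]):
            stored = float(row["separation_cm"])
            if abs(stored - sep) > STORED_SEPARATION_TOL_CM:
                raise MontageError(
                    f"montage row {i + 1}: stored separation {stored} cm inconsistent "
                    f"with coordinates ({sep:.3f} cm)"
                )
        channels.append(
            MontageChannel(
                channel_id=cid,
                source_label=str(row["source_label"]),
                detector_label=str(row["detector_label"]),
                source_mni=src,
                detector_mni=det,
                separation=sep,
            )
        )
    ids = [c.channel_id for c in channels]
    if len(set(ids)) != len(ids):
        raise MontageError("duplicate channel_id in montage table")
    if len(channels) != n_channels:
        raise MontageError(f"expected {n_channels} channels, found {len(channels)}")
    n_sources = len({c.source_label for c in channels})
    if n_sources != 2:
        raise MontageError(f"expected exactly 2 distinct sources, found {n_sources}")
    return channels


def default_montage() -> list[MontageChannel]:
    """The packaged 8-channel midline montage (Fz and CPz sources)."""
    ref = importlib.resources.files("nirspain").joinpath("data/montage_midline.tsv")
    with importlib.resources.as_file(ref) as p:
        return load_montage(p)


def printed_separations(path=None) -> pd.DataFrame:
    """Stored (as-printed) and recomputed separations, for cross-checking."""
    if path is None:
        ref = importlib.resources.files("nirspain").joinpath("data/montage_midline.tsv")
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    src = df[["source_x", "source_y", "source_z"]].to_numpy(float)
    det = df[["detector_x", "detector_y", "detector_z"]].to_numpy(float)
    recomputed = np.linalg.norm(src - det, axis=1) / 10.0
    return pd.DataFrame(
        {
            "channel_id": df["channel_id"],
            "stored_cm": df.get("separation_cm"),
            "recomputed_cm": np.round(recomputed, 2),
        }
    )
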