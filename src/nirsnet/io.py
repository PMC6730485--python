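"""File formats, the prefrontal montage fixture, and pipeline configuration.

The default montage reconstructs a 20-channel prefrontal layout from
8 emitters and 7 detectors arranged in two parallel rows 3.0 cm apart, with
FpZ as the reference landmark at the origin.  Only the stated counts and
the 2.5-3.0 cm emitter-detector separations are constrained; the exact
pairing is a plausible reconstruction (the published configuration is
available only as a schematic).

Recordings travel as wide TSV (a time column plus one column per
channel x wavelength), event schedules as onset/duration/condition TSV,
matrices as labeled square TSV, and everything else as JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .activation import EventSchedule, HRFParams
from .optics import (
    DEFAULT_FILTER_ORDER,
    DEFAULT_HIGH_CUT_HZ,
    DEFAULT_LOW_CUT_HZ,
    DEFAULT_WAVELENGTHS_NM,
)

DEFAULT_FS_HZ = 7.81


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Channel:
    name: str
    emitter: str
    detector: str
    midpoint: tuple[float, float]
    separation_cm: float


@dataclass
class Montage:
    """Emitter/detector geometry in a flat 2-D head-schematic frame (cm),
    origin at the reference landmark."""

    emitters: dict[str, tuple[float, float]]
    detectors: dict[str, tuple[float, float]]
    channels: list[Channel]
    reference: str = "FpZ"

    def __post_init__(self) -> None:
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("duplicate channel names in montage")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def coordinates(self) -> np.ndarray:
        """(n_channels, 2) channel midpoints."""
        return np.array([c.midpoint for c in self.channels])

    def to_json(self) -> str:
        return json.dumps(
            {
                "reference": self.reference,
                "emitters": self.emitters,
                "detectors": self.detectors,
                "channels": [dataclasses.asdict(c) for c in self.channels],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "Montage":
        d = json.loads(text)
        channels = [
            Channel(
                name=c["name"],
                emitter=c["emitter"],
                detector=c["detector"],
                midpoint=tuple(c["midpoint"]),
                separation_cm=c["separation_cm"],
            )
            for c in d["channels"]
        ]
        return cls(
            emitters={k: tuple(v) for k, v in d["emitters"].items()},
            detectors={k: tuple(v) for k, v in d["detectors"].items()},
            channels=channels,
            reference=d["reference"],
        )


def default_montage(separation_cm: float = 3.0) -> Montage:
    """20-channel prefrontal fixture: 8 emitters, 7 detectors, two rows.

    Row layout (x increases to the subject's left, units cm)::

        upper row (y = +s):  E1  D1  E2  D2  E3  D3  E4
        lower row (y =  0):  D4  E5  D5  E6  D6  E7  D7  E8

    Channels are the 13 horizontally adjacent pairs plus the 7 vertical
    pairs, every pair separated by exactly ``separation_cm``.  Channel
    numbering is 1-based.
    """
    s = separation_cm
    upper = ["E1", "D1", "E2", "D2", "E3", "D3", "E4"]
    lower = ["D4", "E5", "D5", "E6", "D6", "E7", "D7", "E8"]
    pos: dict[str, tuple[float, float]] = {}
    for i, name in enumerate(upper):
        pos[name] = (i * s, s)
    for i, name in enumerate(lower):
        pos[name] = (i * s, 0.0)
    # center the reference (FpZ) below the middle of the array
    cx = (7 * s) / 2.0
    pos = {k: (round(x - cx, 6), y) for k, (x, y) in pos.items()}
    emitters = {k: v for k, v in pos.items() if k.startswith("E")}
    detectors = {k: v for k, v in pos.items() if k.startswith("D")}

    pairs: list[tuple[str, str]] = []
    for row in (upper, lower):
        pairs += list(zip(row, row[1:]))
    for i in range(7):  # vertical pairs share the same x index
        pairs.append((upper[i], lower[i]))

    channels = []
    for k, (a, b) in enumerate(pairs, start=1):
        em, det = (a, b) if a.startswith("E") else (b, a)
        (x1, y1), (x2, y2) = pos[em], pos[det]
        sep = float(np.hypot(x1 - x2, y1 - y2))
        if not (2.5 <= sep <= 3.0 + 1e-9):
            raise ValueError(f"channel {k} separation {sep} cm outside [2.5, 3.0]")
        channels.append(
            Channel(
                name=f"CH{k:02d}",
                emitter=em,
                detector=det,
                midpoint=((x1 + x2) / 2, (y1 + y2) / 2),
                separation_cm=sep,
            )
        )
    assert len(channels) == 20
    return Montage(emitters=emitters, detectors=detectors, channels=channels)


# ---------------------------------------------------------------------------
# Raw recording container + TSV dialect
# ---------------------------------------------------------------------------


@dataclass
class RawRecording:
    """Two-wavelength intensity series per channel plus segment markers."""

    intensity: np.ndarray  # (n_samples, n_channels, 2)
    fs: float
    channels: list[str]
    wavelengths_nm: tuple[float, float] = DEFAULT_WAVELENGTHS_NM
    segments: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3 or self.intensity.shape[2] != 2:
            raise ValueError("intensity must have shape (n_samples, n_channels, 2)")
        if self.intensity.shape[1] != len(self.channels):
            raise ValueError("channel label count does not match intensity array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def segment_slice(self, name: str) -> slice:
        t0, t1 = self.segments[name]
        return slice(int(round(t0 * self.fs)), int(round(t1 * self.fs)))


def _wl_tag(wl: float) -> str:
    return f"{int(round(wl))}"


def save_recording(rec: RawRecording, path: str | Path) -> None:
    cols = {"time": rec.time}
    for j, ch in enumerate(rec.channels):
        for k, wl in enumerate(rec.wavelengths_nm):
            cols[f"{ch}_{_wl_tag(wl)}"] = rec.intensity[:, j, k]
    df = pd.DataFrame(cols)
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    sidecar = {
        "fs": rec.fs,
        "wavelengths_nm": list(rec.wavelengths_nm),
        "segments": {k: list(v) for k, v in rec.segments.items()},
        "channels": rec.channels,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_recording(
    path: str | Path,
    montage: Montage | None = None,
    fs: float | None = None,
) -> RawRecording:
    """Read a wide-TSV recording, validating time axis and channel labels.

    Channel labels are matched against ``montage`` when given; missing
    channels are reported by name.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "time" not in df.columns:
        raise ValueError(f"{path}: missing required 'time' column")
    t = df["time"].to_numpy()
    dup = np.flatnonzero(np.diff(t) <= 0)
    if dup.size:
        raise ValueError(
            f"{path}: time column not strictly increasing at row {int(dup[0]) + 1}"
        )
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    if fs is None:
        fs = meta.get("fs", 1.0 / np.median(np.diff(t)))
    wls = tuple(meta.get("wavelengths_nm", DEFAULT_WAVELENGTHS_NM))
    # infer channel names from columns
    chan_names: list[str] = []
    for col in df.columns:
        if col == "time":
            continue
        base = col.rsplit("_", 1)[0]
        if base not in chan_names:
            chan_names.append(base)
    if montage is not None:
        missing = [c for c in montage.channel_names if c not in chan_names]
        if missing:
            raise ValueError(
                f"{path}: channels missing from file: {', '.join(missing)}"
            )
        chan_names = montage.channel_names
    arr = np.empty((len(df), len(chan_names), 2))
    for j, ch in enumerate(chan_names):
        for k, wl in enumerate(wls):
            col = f"{ch}_{_wl_tag(wl)}"
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col}")
            arr[:, j, k] = df[col].to_numpy()
    segments = {k: tuple(v) for k, v in meta.get("segments", {}).items()}
    return RawRecording(
        intensity=arr, fs=float(fs), channels=chan_names, wavelengths_nm=wls, segments=segments
    )


def save_events(schedule: EventSchedule, path: str | Path) -> None:
    schedule.to_frame().to_csv(path, sep="\t", index=False)
    meta = {"segments": {k: list(v) for k, v in schedule.segments.items()}}
    p = Path(path)
    p.with_suffix(p.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_events(path: str | Path) -> EventSchedule:
    p = Path(path)
    df = pd.read_csv(p, sep="\t")
    sidecar = p.with_suffix(p.suffix + ".json")
    segments = {}
    if sidecar.exists():
        segments = {
            k: tuple(v) for k, v in json.loads(sidecar.read_text())["segments"].items()
        }
    return EventSchedule.from_frame(df, segments=segments)


def save_matrix(values: np.ndarray, labels: list[str], path: str | Path) -> None:
    pd.DataFrame(values, index=labels, columns=labels).to_csv(path, sep="\t")


def load_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), list(df.columns)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters; defaults follow the study settings
    (7.81 Hz sampling, 0.026/0.15 Hz 4th-order band-pass, fixed threshold
    0.8, sparsity grid 0.5-0.9 step 0.05, alpha 0.01)."""

    fs: float = DEFAULT_FS_HZ
    low_cut: float = DEFAULT_LOW_CUT_HZ
    high_cut: float = DEFAULT_HIGH_CUT_HZ
    filter_order: int = DEFAULT_FILTER_ORDER
    hrf_peak_time: float = 6.0
    hrf_undershoot_time: float = 16.0
    hrf_undershoot_ratio: float = 1.0 / 6.0
    fixed_threshold: float = 0.8
    sparsity_min: float = 0.5
    sparsity_max: float = 0.9
    sparsity_step: float = 0.05
    alpha: float = 0.01
    seed: int = 0
    n_per_group: int = 3
    groups: tuple[str, ...] = ("HC", "MCI-0")
    chromophore: str = "hbo"
    n_nulls: int = 100
    input_dir: str | None = None
    output_dir: str = "nirsnet_out"

    def hrf_params(self) -> HRFParams:
        return HRFParams(
            peak_time=self.hrf_peak_time,
            undershoot_time=self.hrf_undershoot_time,
            undershoot_ratio=self.hrf_undershoot_ratio,
        )

    def sparsity_grid(self) -> np.ndarray:
        n = int(round((self.sparsity_max - self.sparsity_min) / self.sparsity_step)) + 1
        return np.round(self.sparsity_min + self.sparsity_step * np.arange(n), 10)

    def validate(self) -> None:
        if not (0 < self.low_cut < self.high_cut < self.fs / 2):
            raise ValueError(
                f"filter cutoffs invalid: need 0 < {self.low_cut} < {self.high_cut} "
                f"< fs/2 = {self.fs / 2}"
            )
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        grid = self.sparsity_grid()
        if np.any(grid <= 0) or np.any(grid > 1):
            raise ValueError("sparsity grid must lie within (0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = list(self.groups)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "groups" in d:
            d["groups"] = tuple(d["groups"])
        return cls(**d)
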