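"""Conversion of raw fNIRS light intensities to hemoglobin concentration
changes, and band-pass filtering of the resulting series.

The modified Beer-Lambert law (MBLL) relates the optical-density change at a
wavelength to the underlying chromophore concentration changes::

    dOD(lambda) = [eps_HbO(lambda) * dHbO + eps_HbR(lambda) * dHbR] * d * DPF(lambda)

where ``eps`` are molar extinction coefficients, ``d`` the emitter-detector
separation and ``DPF`` the differential pathlength factor.  With measurements
at two wavelengths (760 and 850 nm) the 2x2 system is solved per time point
for (dHbO, dHbR).

Physiological nuisance components (cardiac ~1 Hz, respiration ~0.25 Hz,
Mayer waves ~0.1 Hz, slow drifts) are removed with a 4th-order Butterworth
band-pass between 0.026 and 0.15 Hz; the low cut is 1/38 Hz, the period of
one task trial, so the evoked response itself is preserved.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

DEFAULT_WAVELENGTHS_NM = (760.0, 850.0)

# Molar extinction coefficients for HbO2 and Hb (1 / (M * cm)), from the
# standard compiled tabulation (S. Prahl, Oregon Medical Laser Center).
# Rows: wavelength (760, 850 nm); columns: (HbO, HbR).
DEFAULT_EXTINCTION = np.array(
    [
        [586.00, 1548.52],
        [1058.00, 691.32],
    ]
)

DEFAULT_DPF = (6.0, 6.0)
DEFAULT_DISTANCE_CM = 3.0

#: Band edges of the physiological-noise filter (Hz).  The high-pass cut is
#: 1/38 Hz, the reciprocal of the longest trial period.
DEFAULT_LOW_CUT_HZ = 0.026
DEFAULT_HIGH_CUT_HZ = 0.15
DEFAULT_FILTER_ORDER = 4


@dataclass(frozen=True)
class OpticalGeometry:
    """Geometry and optical constants entering the MBLL.

    Parameters
    ----------
    distance_cm
        Emitter-detector separation in cm.  Must lie in [2.5, 5.0]:
        separations above 5 cm yield noisy, unstable signals and are
        rejected.
    dpf
        Differential pathlength factor per wavelength (dimensionless).
    wavelengths_nm
        The two measurement wavelengths.
    extinction
        2x2 molar extinction matrix, rows indexed by wavelength, columns
        by chromophore (HbO, HbR), in 1/(M*cm).
    """

    distance_cm: float = DEFAULT_DISTANCE_CM
    dpf: tuple[float, float] = DEFAULT_DPF
    wavelengths_nm: tuple[float, float] = DEFAULT_WAVELENGTHS_NM
    extinction: np.ndarray = field(default_factory=lambda: DEFAULT_EXTINCTION.copy())

    def __post_init__(self) -> None:
        if not (2.5 <= self.distance_cm <= 5.0):
            raise ValueError(
                f"emitter-detector distance {self.distance_cm} cm outside the "
                "accepted range [2.5, 5.0] cm"
            )
        ext = np.asarray(self.extinction, dtype=float)
        if ext.shape != (2, 2):
            raise ValueError("extinction must be a 2x2 matrix (wavelength x chromophore)")
        if np.linalg.cond(ext) > 1e12:
            raise ValueError("extinction matrix is singular or near-singular")
        object.__setattr__(self, "extinction", ext)

    @property
    def pathlength_matrix(self) -> np.ndarray:
        """Effective 2x2 system matrix M with dOD = M @ (dHbO, dHbR) in uM.

        Includes the 1e-6 factor converting uM to M.
        """
        dpf = np.asarray(self.dpf, dtype=float)[:, None]
        return self.extinction * self.distance_cm * dpf * 1e-6

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["extinction"] = self.extinction.tolist()
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "OpticalGeometry":
        d = json.loads(text)
        d["dpf"] = tuple(d["dpf"])
        d["wavelengths_nm"] = tuple(d["wavelengths_nm"])
        d["extinction"] = np.asarray(d["extinction"], dtype=float)
        return cls(**d)


@dataclass
class HemoglobinSeries:
    """Per-channel dHbO / dHbR concentration-change time series (uM)."""

    hbo: np.ndarray  # (n_samples, n_channels)
    hbr: np.ndarray
    fs: float
    channels: list[str]
    filtered: bool = False
    filter_params: dict | None = None

    def __post_init__(self) -> None:
        self.hbo = np.atleast_2d(np.asarray(self.hbo, dtype=float))
        self.hbr = np.atleast_2d(np.asarray(self.hbr, dtype=float))
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("hbo and hbr must have identical shapes")
        if not (np.all(np.isfinite(self.hbo)) and np.all(np.isfinite(self.hbr))):
            raise ValueError("hemoglobin series contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[1]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def select(self, chromophore: str = "hbo") -> np.ndarray:
        if chromophore not in ("hbo", "hbr"):
            raise ValueError("chromophore must be 'hbo' or 'hbr'")
        return self.hbo if chromophore == "hbo" else self.hbr


def optical_density(
    intensity: np.ndarray,
    baseline: slice | tuple[int, int] | None = None,
    channels: Sequence[str] | None = None,
) -> np.ndarray:
    """Convert light intensity to optical-density change.

    dOD(t) = -log10(I(t) / I0) with I0 the mean intensity over the
    baseline window (the whole series when ``baseline`` is None), so the
    mean dOD over the baseline window is approximately zero.

    Parameters
    ----------
    intensity
        Array (n_samples, ...) of strictly positive intensities.  Trailing
        axes (channels, wavelengths) are preserved.
    baseline
        Sample window used for I0, as a slice or (start, stop) tuple.
    channels
        Optional channel labels used in diagnostics.
    """
    intensity = np.asarray(intensity, dtype=float)
    if baseline is None:
        baseline = slice(None)
    elif isinstance(baseline, tuple):
        baseline = slice(*baseline)
    bad = ~(intensity > 0)
    if np.any(bad):
        bad_ch = sorted(set(np.argwhere(bad)[:, 1])) if intensity.ndim > 1 else [0]
        labels = (
            [channels[i] for i in bad_ch]
            if channels is not None
            else [str(i) for i in bad_ch]
        )
        raise ValueError(
            "non-positive intensity in channel(s) "
            + ", ".join(labels)
            + "; cannot take optical density"
        )
    i0 = intensity[baseline].mean(axis=0)
    return -np.log10(intensity / i0)


def forward_optical_density(
    hbo: np.ndarray, hbr: np.ndarray, geometry: OpticalGeometry | None = None
) -> np.ndarray:
    """Forward MBLL: concentration changes (uM) -> dOD at both wavelengths.

    Returns an array with one extra trailing axis of length 2 (wavelength).
    """
    if geometry is None:
        geometry = OpticalGeometry()
    conc = np.stack([np.asarray(hbo, float), np.asarray(hbr, float)], axis=-1)
    return conc @ geometry.pathlength_matrix.T


def mbll_convert(
    od: np.ndarray,
    geometry: OpticalGeometry | None = None,
    fs: float = 7.81,
    channels: Sequence[str] | None = None,
) -> HemoglobinSeries:
    """Invert the MBLL: dOD at two wavelengths -> (dHbO, dHbR) in uM.

    Parameters
    ----------
    od
        Array (n_samples, n_channels, 2) of optical-density changes, the
        trailing axis ordered like ``geometry.wavelengths_nm``.
    """
    if geometry is None:
        geometry = OpticalGeometry()
    od = np.asarray(od, dtype=float)
    if od.ndim == 2:  # single channel
        od = od[:, None, :]
    if od.shape[-1] != 2:
        raise ValueError("expected optical density at exactly two wavelengths")
    inv = np.linalg.inv(geometry.pathlength_matrix)
    conc = od @ inv.T
    n_ch = conc.shape[1]
    if channels is None:
        channels = [f"CH{i + 1:02d}" for i in range(n_ch)]
    return HemoglobinSeries(
        hbo=conc[..., 0], hbr=conc[..., 1], fs=fs, channels=list(channels)
    )


def _butter_sos(order: int, cut: float, fs: float, btype: str) -> np.ndarray:
    return signal.butter(order, cut, btype=btype, fs=fs, output="sos")


def bandpass_filter(
    x: np.ndarray,
    fs: float,
    low_cut: float = DEFAULT_LOW_CUT_HZ,
    high_cut: float = DEFAULT_HIGH_CUT_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass, realized as cascaded low- and
    high-pass sections of the stated order.

    Both sections are applied forward-backward (``sosfiltfilt``), so the
    filter is zero-phase and the effective magnitude response is squared;
    the output has the same length as the input.
    """
    if not (0 < low_cut < high_cut < fs / 2):
        raise ValueError(
            f"require 0 < low_cut < high_cut < fs/2, got low_cut={low_cut}, "
            f"high_cut={high_cut} with fs={fs} (Nyquist {fs / 2})"
        )
    x = np.asarray(x, dtype=float)
    lo = _butter_sos(order, high_cut, fs, "lowpass")
    hi = _butter_sos(order, low_cut, fs, "highpass")
    y = signal.sosfiltfilt(lo, x, axis=0)
    y = signal.sosfiltfilt(hi, y, axis=0)
    return y


def filter_hemoglobin(
    series: HemoglobinSeries,
    low_cut: float = DEFAULT_LOW_CUT_HZ,
    high_cut: float = DEFAULT_HIGH_CUT_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> HemoglobinSeries:
    """Apply the physiological band-pass to both chromophores."""
    params = {"low_cut": low_cut, "high_cut": high_cut, "order": order}
    return HemoglobinSeries(
        hbo=bandpass_filter(series.hbo, series.fs, low_cut, high_cut, order),
        hbr=bandpass_filter(series.hbr, series.fs, low_cut, high_cut, order),
        fs=series.fs,
        channels=list(series.channels),
        filtered=True,
        filter_params=params,
    )
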