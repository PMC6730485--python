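"""Task activation analysis for the working-memory block paradigm.

Each trial of the paradigm is a 24-s task block (8 s encoding, 14 s
retention, 2 s probe) followed by 14 s of rest, with a 2-s ready cue at the
end of the preceding rest.  The designed hemodynamic response function
(dHRF) is a canonical double-gamma HRF convolved with a unit boxcar over
each 24-s task block.  Channel activation is estimated by regressing the
measured dHbO on the dHRF with iteratively reweighted least squares using
bisquare weights (robust to motion/physiological outliers), and summarized
as a t-value per channel; t-values are interpolated over the optode plane
into a min-max normalized activation map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate
from scipy.stats import gamma as gamma_dist
from scipy.stats import t as t_dist
import statsmodels.api as sm

TASK_CONDITIONS = ("encode", "retain", "probe")


@dataclass(frozen=True)
class EventEntry:
    onset: float
    duration: float
    condition: str

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass
class EventSchedule:
    """Onsets/durations of trial phases plus segment markers.

    ``segments`` maps segment names ('resting', 'task', 'post_rest') to
    (start, stop) times in seconds.
    """

    entries: list[EventEntry]
    segments: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: (e.onset, e.condition))
        for e in self.entries:
            if e.onset < 0 or e.duration < 0:
                raise ValueError(f"negative onset/duration in entry {e}")
        # entries of the same condition must not overlap
        by_cond: dict[str, list[EventEntry]] = {}
        for e in self.entries:
            by_cond.setdefault(e.condition, []).append(e)
        for cond, ents in by_cond.items():
            for a, b in zip(ents, ents[1:]):
                if b.onset < a.offset - 1e-9:
                    raise ValueError(f"overlapping '{cond}' entries at {b.onset} s")

    @property
    def duration(self) -> float:
        stops = [e.offset for e in self.entries]
        stops += [s[1] for s in self.segments.values()]
        return max(stops) if stops else 0.0

    def task_blocks(self) -> list[tuple[float, float]]:
        """(onset, duration) of each contiguous task block (encode..probe)."""
        encodes = [e for e in self.entries if e.condition == "encode"]
        blocks = []
        for enc in encodes:
            end = enc.offset
            for cond in ("retain", "probe"):
                nxt = [
                    e
                    for e in self.entries
                    if e.condition == cond and abs(e.onset - end) < 1e-9
                ]
                if nxt:
                    end = nxt[0].offset
            blocks.append((enc.onset, end - enc.onset))
        return blocks

    def task_onsets(self) -> np.ndarray:
        return np.array([b[0] for b in self.task_blocks()])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.onset, e.duration, e.condition) for e in self.entries],
            columns=["onset", "duration", "condition"],
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, segments: dict[str, tuple[float, float]] | None = None
    ) -> "EventSchedule":
        entries = [
            EventEntry(float(r.onset), float(r.duration), str(r.condition))
            for r in df.itertuples()
        ]
        return cls(entries=entries, segments=segments or {})


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma HRF shape parameters (seconds)."""

    peak_time: float = 6.0
    undershoot_time: float = 16.0
    undershoot_ratio: float = 1.0 / 6.0
    length: float = 32.0


def double_gamma_hrf(t: np.ndarray, params: HRFParams | None = None) -> np.ndarray:
    """Evaluate the double-gamma HRF kernel on a time grid.

    Gamma densities with unit scale and shape ``peak_time + 1`` peak exactly
    at ``peak_time`` (mode of a Gamma(k, 1) is k - 1).
    """
    if params is None:
        params = HRFParams()
    t = np.asarray(t, dtype=float)
    peak = gamma_dist.pdf(t, params.peak_time + 1.0)
    under = gamma_dist.pdf(t, params.undershoot_time + 1.0)
    h = peak - params.undershoot_ratio * under
    return h


@dataclass
class DesignRegressor:
    """Sampled dHRF regressor (a.u., peak normalized to 1) plus provenance."""

    values: np.ndarray
    fs: float
    hrf_params: HRFParams
    boxcar: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("regressor contains non-finite values")


def build_dhrf(
    schedule: EventSchedule,
    fs: float,
    hrf_params: HRFParams | None = None,
    allow_empty: bool = False,
) -> DesignRegressor:
    """Designed hemodynamic response: HRF (*) task boxcar, sampled at fs.

    The boxcar is 1 over each task block (encoding through probe, 24 s in
    the default paradigm) and 0 elsewhere; the convolution is normalized so
    the regressor peak is 1, making the regression slope directly
    interpretable as an evoked amplitude in uM.
    """
    if hrf_params is None:
        hrf_params = HRFParams()
    blocks = schedule.task_blocks()
    if not blocks and not allow_empty:
        raise ValueError("schedule contains no task blocks")
    n = int(round(schedule.duration * fs))
    boxcar = np.zeros(n)
    for onset, dur in blocks:
        i0 = int(round(onset * fs))
        i1 = int(round((onset + dur) * fs))
        boxcar[i0:i1] = 1.0
    kernel = double_gamma_hrf(np.arange(0.0, hrf_params.length, 1.0 / fs), hrf_params)
    values = np.convolve(boxcar, kernel)[:n] / fs
    peak = np.abs(values).max()
    if peak > 0:
        values = values / peak
    return DesignRegressor(values=values, fs=fs, hrf_params=hrf_params, boxcar=boxcar)


@dataclass(frozen=True)
class GLMResult:
    beta: float
    se: float
    t: float
    intercept: float
    df_resid: float


#: Bisquare tuning constant of the robust fit (95% Gaussian efficiency).
BISQUARE_C = 4.685


def robust_glm(y: np.ndarray, x: DesignRegressor | np.ndarray) -> GLMResult:
    """Robust fit of y = b0 + beta * x by IRLS with bisquare weights.

    Returns the slope, its robust standard error, and t = beta / SE.  The
    iteration stops on a coefficient change below 1e-8 or 50 iterations.
    """
    xv = x.values if isinstance(x, DesignRegressor) else np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.shape != xv.shape:
        raise ValueError("y and regressor must be aligned")
    if y.size < 20:
        raise ValueError("need at least 10 samples per regression term")
    if np.ptp(xv) == 0:
        raise ValueError("constant regressor: slope undefined")
    exog = sm.add_constant(xv)
    model = sm.RLM(y, exog, M=sm.robust.norms.TukeyBiweight(c=BISQUARE_C))
    res = model.fit(maxiter=50, tol=1e-8)
    beta = float(res.params[1])
    se = float(res.bse[1])
    t = beta / se if se > 0 else np.nan
    return GLMResult(
        beta=beta, se=se, t=t, intercept=float(res.params[0]), df_resid=float(res.df_resid)
    )


@dataclass
class BlockAverage:
    """Trial-averaged response: point-wise mean +/- SD across epochs."""

    time: np.ndarray  # seconds relative to task onset
    mean: np.ndarray
    sd: np.ndarray
    n_epochs: int
    sd_defined: bool


def block_average(
    y: np.ndarray,
    schedule: EventSchedule,
    fs: float,
    window: float = 38.0,
    baseline: float = 2.0,
) -> BlockAverage:
    """Epoch y around each task onset over [-baseline, window] and average.

    Each epoch is corrected by subtracting its pre-onset mean; the default
    window spans one full 38-s trial.
    """
    y = np.asarray(y, dtype=float)
    onsets = schedule.task_onsets()
    nb = int(round(baseline * fs))
    nw = int(round(window * fs))
    epochs = []
    for onset in onsets:
        i = int(round(onset * fs))
        if i - nb < 0 or i + nw > y.shape[0]:
            continue
        ep = y[i - nb : i + nw].astype(float)
        base = ep[:nb].mean(axis=0) if nb > 0 else 0.0
        epochs.append(ep - base)
    if not epochs:
        raise ValueError("no complete epochs fit within the series")
    arr = np.stack(epochs)
    sd_defined = arr.shape[0] >= 2
    if not sd_defined:
        warnings.warn("fewer than 2 epochs: SD undefined", stacklevel=2)
    sd = arr.std(axis=0, ddof=1) if sd_defined else np.full(arr.shape[1:], np.nan)
    time = (np.arange(-nb, nw)) / fs
    return BlockAverage(
        time=time, mean=arr.mean(axis=0), sd=sd, n_epochs=arr.shape[0], sd_defined=sd_defined
    )


@dataclass
class ActivationResult:
    """Per-channel activation statistics from the robust dHRF fit."""

    table: pd.DataFrame  # channel, beta, se, t, active
    alpha: float

    @property
    def t_values(self) -> np.ndarray:
        return self.table["t"].to_numpy()


def estimate_activation(
    hbo: np.ndarray,
    regressor: DesignRegressor,
    channels: list[str] | None = None,
    alpha: float = 0.01,
) -> ActivationResult:
    """Robust GLM per channel; a channel is active when its t exceeds the
    upper-tail critical value of the t distribution at ``alpha``."""
    hbo = np.atleast_2d(np.asarray(hbo, dtype=float))
    n_ch = hbo.shape[1]
    if channels is None:
        channels = [f"CH{i + 1:02d}" for i in range(n_ch)]
    rows = []
    for i in range(n_ch):
        r = robust_glm(hbo[:, i], regressor)
        crit = t_dist.ppf(1 - alpha, r.df_resid)
        rows.append((channels[i], r.beta, r.se, r.t, bool(r.t > crit)))
    table = pd.DataFrame(rows, columns=["channel", "beta", "se", "t", "active"])
    return ActivationResult(table=table, alpha=alpha)


@dataclass
class TMap:
    """Min-max normalized activation map over the optode plane."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    values: np.ndarray  # (ny, nx) in [0, 1]
    node_values: np.ndarray  # normalized values at channel coordinates
    coords: np.ndarray  # (n_channels, 2)


def t_map(
    t_values: np.ndarray,
    coords: np.ndarray,
    grid_step: float = 0.25,
    pad: float = 1.0,
) -> TMap:
    """Interpolate per-channel t-values over the 2-D montage plane.

    A thin-plate-spline radial basis interpolant passes exactly through the
    channel values; the map is then min-max normalized to [0, 1].  When all
    t-values are equal (no spread) the map is all zeros by convention.
    """
    t_values = np.asarray(t_values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] != t_values.shape[0]:
        raise ValueError("one coordinate pair required per channel")
    xs = np.arange(coords[:, 0].min() - pad, coords[:, 0].max() + pad + grid_step, grid_step)
    ys = np.arange(coords[:, 1].min() - pad, coords[:, 1].max() + pad + grid_step, grid_step)
    gx, gy = np.meshgrid(xs, ys)
    spread = np.ptp(t_values)
    if spread == 0:
        vals = np.zeros_like(gx)
        nodes = np.zeros_like(t_values)
    else:
        rbf = interpolate.RBFInterpolator(coords, t_values, kernel="thin_plate_spline")
        flat = rbf(np.column_stack([gx.ravel(), gy.ravel()]))
        lo, hi = t_values.min(), t_values.max()
        vals = np.clip((flat.reshape(gx.shape) - lo) / (hi - lo), 0.0, 1.0)
        nodes = (t_values - lo) / (hi - lo)
    return TMap(grid_x=gx, grid_y=gy, values=vals, node_values=nodes, coords=coords)
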