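"""Synthetic fNIRS cohort generator with known ground truth.

Forward model per subject, per channel (all concentrations in uM):

    dHbO(t) = A_i * dHRF(t) + background_i(t) + noise_i(t)
    dHbR(t) = -dHbO_evoked(t) / 3 + independent background/noise at 1/3 scale

* ``A_i`` is the group activation amplitude on active channels (with
  modest between-subject variability), 0 elsewhere.
* ``background`` is spatially correlated pink-ish noise: white noise mixed
  through a matrix square root of the group's latent correlation matrix,
  then smoothed into the analysis pass band, so the measured channel
  correlations converge to the latent matrix.
* ``noise`` carries cardiac (~1.1 Hz), respiration (~0.25 Hz), Mayer-wave
  (~0.1 Hz) sinusoids with random phases, a low-frequency random-walk
  drift, and white noise -- all bands the 0.026-0.15 Hz filter removes.

The concentrations are pushed through the forward Beer-Lambert model to
two-wavelength light intensities, so the whole analysis chain (optical
density -> MBLL inversion -> filtering -> activation/connectivity/graphs)
can be exercised end-to-end without any real recording.

The default paradigm is a 4-min resting state, nine 38-s working-memory
trials (2-s ready cue in the preceding rest, 8-s encoding, 14-s retention,
2-s probe, 14-s rest), and a 30-s post-rest: 612 s in total.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .activation import EventEntry, EventSchedule, HRFParams, build_dhrf
from .io import DEFAULT_FS_HZ, Montage, RawRecording, default_montage
from .optics import bandpass_filter, forward_optical_density, OpticalGeometry

RESTING_S = 240.0
TRIAL_TASK_S = 24.0
TRIAL_REST_S = 14.0
TRIAL_S = TRIAL_TASK_S + TRIAL_REST_S
N_TRIALS = 9
POST_REST_S = 30.0

#: 1-based channels reported as task-active in the reference analysis
#: (4, 5, 9, 14, 16, 19) plus the dorsolateral channels 1-2; stored 0-based.
DEFAULT_ACTIVE_CHANNELS = (0, 1, 3, 4, 8, 13, 15, 18)


@dataclass(frozen=True)
class NoiseSpec:
    """Physiological + instrumental noise amplitudes (uM) and frequencies (Hz)."""

    cardiac: tuple[float, float] = (1.1, 0.20)  # (freq, amplitude)
    respiration: tuple[float, float] = (0.25, 0.10)
    mayer: tuple[float, float] = (0.10, 0.05)
    drift: float = 0.05  # random-walk scale, uM / sqrt(s)
    white: float = 0.03  # white-noise SD, uM

    def __post_init__(self) -> None:
        for name in ("cardiac", "respiration", "mayer"):
            f, a = getattr(self, name)
            if f <= 0:
                raise ValueError(f"{name} frequency must be positive")
            if a < 0:
                raise ValueError(f"{name} amplitude must be non-negative")
        if self.drift < 0 or self.white < 0:
            raise ValueError("drift and white scales must be non-negative")

    @property
    def max_frequency(self) -> float:
        return max(self.cardiac[0], self.respiration[0], self.mayer[0])

    def is_silent(self) -> bool:
        return (
            self.cardiac[1] == 0
            and self.respiration[1] == 0
            and self.mayer[1] == 0
            and self.drift == 0
            and self.white == 0
        )

    @classmethod
    def silent(cls) -> "NoiseSpec":
        return cls(cardiac=(1.1, 0.0), respiration=(0.25, 0.0), mayer=(0.1, 0.0), drift=0.0, white=0.0)


def _check_correlation(mat: np.ndarray) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("latent_connectivity must be square")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("latent_connectivity must be symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-10):
        raise ValueError("latent_connectivity must have unit diagonal")
    w = np.linalg.eigvalsh(mat)
    if w.min() < -1e-8:
        raise ValueError(
            f"latent_connectivity is not positive semi-definite (min eig {w.min():.3g})"
        )
    return mat


@dataclass
class GroupProfile:
    """Ground-truth generative settings for one subject group."""

    label: str
    activation_amplitude: float  # evoked dHbO peak on active channels, uM
    active_channels: tuple[int, ...]
    latent_connectivity: np.ndarray
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    background_sd: float = 0.20  # SD of the correlated background, uM
    subject_cv: float = 0.08  # between-subject amplitude variability

    def __post_init__(self) -> None:
        if self.activation_amplitude < 0:
            raise ValueError("activation_amplitude must be non-negative")
        self.latent_connectivity = _check_correlation(self.latent_connectivity)
        if self.background_sd < 0:
            raise ValueError("background_sd must be non-negative")


@dataclass
class GroundTruth:
    """Everything that determines the noiseless signal component."""

    amplitudes: np.ndarray  # per-channel true evoked peak, uM
    latent_connectivity: np.ndarray
    regressor: np.ndarray  # the dHRF used for the evoked component
    seed: int


def uniform_connectivity(n: int, r: float) -> np.ndarray:
    """Constant off-diagonal correlation r (PSD for r >= -1/(n-1))."""
    m = np.full((n, n), float(r))
    np.fill_diagonal(m, 1.0)
    return m


def degraded_connectivity(
    n: int,
    strength: float,
    coupling: dict[int, float] | None = None,
) -> np.ndarray:
    """Correlation structure with a coupled core and degraded channels.

    Fully coupled channel pairs correlate at ``strength``; each channel
    listed in ``coupling`` has every one of its pairs reduced to the given
    level instead (a pair of two degraded channels takes the lower level).
    Channel-wise decoupling is what degrades network efficiency under
    proportional thresholding: the strongest edges concentrate among the
    coupled core, so a degraded channel stays isolated until the edge
    budget exceeds the number of pairs ranked above its own, and the
    ordering of coupling levels fixes the order in which degraded channels
    rejoin the network as the sparsity level rises.
    """
    m = np.full((n, n), float(strength))
    for ch, level in sorted((coupling or {}).items(), key=lambda kv: -kv[1]):
        m[ch, :] = level
        m[:, ch] = level
    np.fill_diagonal(m, 1.0)
    return _check_correlation(m)


def default_profiles(n_channels: int = 20) -> list[GroupProfile]:
    """Study-condition group profiles, ordered HC > MCI-1 > MCI-2 > MCI-0
    in evoked amplitude, overall connectivity strength, and network
    integration (progressively more decoupled channels)."""
    settings = [
        # label, amplitude (uM), coupled strength, per-channel coupling
        ("HC", 0.40, 0.60, {}),
        ("MCI-1", 0.30, 0.55, {19: 0.02}),
        ("MCI-2", 0.20, 0.45, {8: 0.10, 9: 0.02}),  # channels 9, 10
        ("MCI-0", 0.10, 0.35, {7: 0.10, 8: 0.02, 9: 0.0}),  # channels 8-10
    ]
    return [
        GroupProfile(
            label=label,
            activation_amplitude=amp,
            active_channels=DEFAULT_ACTIVE_CHANNELS,
            latent_connectivity=degraded_connectivity(n_channels, strength, coupling),
        )
        for label, amp, strength, coupling in settings
    ]


def make_default_schedule() -> EventSchedule:
    """The working-memory block paradigm: 240-s resting state, nine 38-s
    trials (24-s task + 14-s rest, ready cue in the last 2 s of the
    preceding rest), then 30 s of post-rest."""
    entries: list[EventEntry] = []
    task_start = RESTING_S
    for k in range(N_TRIALS):
        t0 = task_start + k * TRIAL_S
        entries.append(EventEntry(t0 - 2.0, 2.0, "ready"))
        entries.append(EventEntry(t0, 8.0, "encode"))
        entries.append(EventEntry(t0 + 8.0, 14.0, "retain"))
        entries.append(EventEntry(t0 + 22.0, 2.0, "probe"))
        entries.append(EventEntry(t0 + 24.0, TRIAL_REST_S, "rest"))
    task_end = task_start + N_TRIALS * TRIAL_S
    segments = {
        "resting": (0.0, RESTING_S),
        "task": (task_start, task_end),
        "post_rest": (task_end, task_end + POST_REST_S),
    }
    return EventSchedule(entries=entries, segments=segments)


def _matrix_sqrt(corr: np.ndarray) -> np.ndarray:
    """Spectral square root; tolerates semi-definite matrices."""
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def _correlated_background(
    rng: np.random.Generator, n: int, corr: np.ndarray, sd: float, fs: float
) -> np.ndarray:
    """White noise mixed through sqrt(corr), smoothed into the pass band,
    rescaled by a common factor so the marginal SD is ``sd``."""
    if sd == 0:
        return np.zeros((n, corr.shape[0]))
    z = rng.standard_normal((n, corr.shape[0]))
    bg = z @ _matrix_sqrt(corr).T
    # smooth into (roughly) the analysis band; a common filter across
    # channels leaves the cross-channel correlation structure intact
    bg = bandpass_filter(bg, fs, low_cut=0.015, high_cut=0.2, order=2)
    scale = bg.std()
    if scale > 0:
        bg = bg * (sd / scale)
    return bg


def _physiological_noise(
    rng: np.random.Generator, n: int, n_ch: int, spec: NoiseSpec, fs: float
) -> np.ndarray:
    t = np.arange(n)[:, None] / fs
    out = np.zeros((n, n_ch))
    for f, a in (spec.cardiac, spec.respiration, spec.mayer):
        if a > 0:
            phases = rng.uniform(0, 2 * np.pi, size=n_ch)
            out += a * np.sin(2 * np.pi * f * t + phases)
    if spec.drift > 0:
        steps = rng.standard_normal((n, n_ch)) * (spec.drift / np.sqrt(fs))
        out += np.cumsum(steps, axis=0)
    if spec.white > 0:
        out += spec.white * rng.standard_normal((n, n_ch))
    return out


def simulate_subject(
    profile: GroupProfile,
    montage: Montage | None = None,
    schedule: EventSchedule | None = None,
    fs: float = DEFAULT_FS_HZ,
    seed: int = 0,
    geometry: OpticalGeometry | None = None,
    hrf_params: HRFParams | None = None,
) -> tuple[RawRecording, GroundTruth]:
    """Simulate one subject's two-wavelength recording plus its ground truth.

    Identical (profile, seed) pairs yield bit-identical recordings.
    """
    if montage is None:
        montage = default_montage()
    if schedule is None:
        schedule = make_default_schedule()
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    if fs <= 2 * profile.noise.max_frequency and not profile.noise.is_silent():
        raise ValueError(
            f"fs = {fs} Hz cannot represent noise up to "
            f"{profile.noise.max_frequency} Hz"
        )
    if not schedule.entries:
        raise ValueError("empty event schedule")
    n_ch = montage.n_channels
    if profile.latent_connectivity.shape[0] != n_ch:
        raise ValueError(
            "latent_connectivity dimension does not match montage channel count"
        )
    if geometry is None:
        geometry = OpticalGeometry()

    rng = np.random.default_rng(seed)
    n = int(round(schedule.duration * fs))

    # resting-only schedules are legitimate (background/noise simulation)
    regressor = build_dhrf(schedule, fs, hrf_params, allow_empty=True).values
    amps = np.zeros(n_ch)
    jitter = rng.standard_normal(n_ch)
    for i in profile.active_channels:
        amps[i] = max(
            0.0, profile.activation_amplitude * (1.0 + profile.subject_cv * jitter[i])
        )
    evoked = regressor[:, None] * amps[None, :]

    bg = _correlated_background(
        rng, n, profile.latent_connectivity, profile.background_sd, fs
    )
    noise = _physiological_noise(rng, n, n_ch, profile.noise, fs)
    hbo = evoked + bg + noise

    bg_r = _correlated_background(
        rng, n, profile.latent_connectivity, profile.background_sd / 3.0, fs
    )
    noise_r = (
        _physiological_noise(rng, n, n_ch, profile.noise, fs) / 3.0
        if not profile.noise.is_silent()
        else np.zeros((n, n_ch))
    )
    hbr = -evoked / 3.0 + bg_r + noise_r

    od = forward_optical_density(hbo, hbr, geometry)
    intensity = 10.0 ** (-od)  # I0 = 1
    rec = RawRecording(
        intensity=intensity,
        fs=fs,
        channels=montage.channel_names,
        wavelengths_nm=geometry.wavelengths_nm,
        segments=dict(schedule.segments),
    )
    truth = GroundTruth(
        amplitudes=amps,
        latent_connectivity=profile.latent_connectivity.copy(),
        regressor=regressor,
        seed=seed,
    )
    return rec, truth


def derive_subject_seed(master_seed: int, label: str, index: int) -> int:
    """Deterministic, stream-independent per-subject seed."""
    h = hashlib.sha256(f"{master_seed}:{label}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class Cohort:
    """Simulated cohort: per group, a list of (recording, truth) pairs."""

    groups: dict[str, list[tuple[RawRecording, GroundTruth]]]
    master_seed: int

    def manifest(self) -> dict:
        return {
            "master_seed": self.master_seed,
            "groups": {
                label: [
                    {"subject": i, "seed": truth.seed}
                    for i, (_, truth) in enumerate(subs)
                ]
                for label, subs in self.groups.items()
            },
        }

    @property
    def n_subjects(self) -> int:
        return sum(len(v) for v in self.groups.values())


def simulate_cohort(
    profiles: list[GroupProfile],
    n_per_group: int,
    montage: Montage | None = None,
    schedule: EventSchedule | None = None,
    fs: float = DEFAULT_FS_HZ,
    seed: int = 0,
    **kwargs,
) -> Cohort:
    """Simulate ``n_per_group`` independent subjects for each group profile.

    Per-subject seeds are derived deterministically from the master seed,
    group label, and subject index, so streams never collide.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    labels = [p.label for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate group labels in cohort")
    groups: dict[str, list[tuple[RawRecording, GroundTruth]]] = {}
    for profile in profiles:
        subs = []
        for i in range(n_per_group):
            s = derive_subject_seed(seed, profile.label, i)
            subs.append(
                simulate_subject(
                    profile, montage=montage, schedule=schedule, fs=fs, seed=s, **kwargs
                )
            )
        groups[profile.label] = subs
    return Cohort(groups=groups, master_seed=seed)
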