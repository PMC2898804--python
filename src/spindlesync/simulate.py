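"""Ground-truth spindle simulation and sensor-level rendering.

Two source systems generate each simulated spindle, mirroring the two
thalamo-cortical projection systems hypothesized to underlie the
EEG-visible versus MEG-visible components of the oscillation:

* a **matrix** system — a diffuse, spatially smooth, everywhere-in-phase
  10-15 Hz oscillation spanning the whole cortical surface (one common
  frequency and phase per spindle, Hann envelope, smooth strictly
  positive spatial gain map), and
* a **core** system — several focal patches (geodesic discs of ~15 mm
  radius) whose frequencies, phases, and active sub-intervals are drawn
  independently, so the foci shift over the course of a single spindle.

Spindle durations are drawn from a Beta(0.273, 0.460) distribution
rescaled to [483, 1123] ms, whose mean and standard deviation are 721 ms
and 235 ms — the only distribution of that family matching all three
printed moments of the empirical duration distribution.  On top of the
spindle systems, every source carries stationary 1/f background noise,
and every channel white sensor noise appropriate to its kind.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .geometry import ChannelKind, Modality, SensorArray, SourceSpace
from .forward import GainMatrix

__all__ = [
    "DURATION_BETA",
    "DURATION_RANGE_S",
    "CorePatch",
    "SpindleEvent",
    "GeneratorConfig",
    "SourceActivity",
    "Annotation",
    "Recording",
    "sample_spindle_events",
    "sample_durations",
    "matrix_gain_map",
    "synthesize_matrix_activity",
    "synthesize_core_activity",
    "synthesize_background",
    "render_recording",
    "empty_room_recording",
    "filter_recording",
    "extract_epochs",
]

#: Beta shape parameters of the spindle-duration law
DURATION_BETA = (0.273, 0.460)
#: support of the duration law, seconds
DURATION_RANGE_S = (0.483, 1.123)
#: spindle oscillation band, Hz
SPINDLE_BAND = (10.0, 15.0)


@dataclass(frozen=True)
class CorePatch:
    center_source_index: int
    radius: float
    frequency: float
    phase: float
    onset_lag: float
    offset_lead: float
    amplitude: float


@dataclass(frozen=True)
class SpindleEvent:
    onset: float
    duration: float
    matrix_frequency: float
    matrix_phase: float
    core_patches: tuple[CorePatch, ...] = ()

    def __post_init__(self) -> None:
        lo, hi = DURATION_RANGE_S
        if not (lo - 1e-9 <= self.duration <= hi + 1e-9):
            raise ValueError(f"duration {self.duration:.3f} s outside [{lo}, {hi}] s")
        freqs = [self.matrix_frequency] + [p.frequency for p in self.core_patches]
        if any(not (SPINDLE_BAND[0] <= f <= SPINDLE_BAND[1]) for f in freqs):
            raise ValueError("all spindle frequencies must lie in [10, 15] Hz")
        if any(p.radius <= 0 for p in self.core_patches):
            raise ValueError("core patch radius must be > 0")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the simulated recordings.

    Amplitudes are per-source dipole moments in A*m; sensor noise is the
    white per-sample standard deviation in each channel kind's units.
    """

    n_subjects: int = 7
    spindles_per_subject: int = 12
    matrix_amplitude: float = 26e-9
    matrix_gain_map_smoothness: int = 2
    n_core_patches_per_spindle: tuple[int, int] = (3, 6)
    core_amplitude: float = 10e-9
    core_patch_radius: float = 0.010
    core_tangential_threshold: float = 0.35
    background_amplitude: float = 1e-9
    sensor_noise_sd: dict = field(
        default_factory=lambda: {
            "EEG": 3.5e-6,   # V
            "MAG": 5.0e-14,  # T
            "GRAD1": 4.0e-12,  # T/m
            "GRAD2": 4.0e-12,
        }
    )
    sampling_rate: float = 500.0
    record_duration: float = 120.0
    quiet_epochs_per_subject: int = 100
    quiet_epoch_duration: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate not in (500.0, 600.0):
            raise ValueError("sampling_rate must be 500 or 600 Hz")
        for name in ("matrix_amplitude", "core_amplitude", "background_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SourceActivity:
    """Dipole moment along the local surface normal, per source and sample."""

    values: np.ndarray  # (n_sources, n_samples), A*m
    sampling_rate: float
    first_sample: int = 0
    ground_truth: tuple[SpindleEvent, ...] = ()

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("source activity must be finite")


@dataclass(frozen=True)
class Annotation:
    label: str  # "spindle" | "quiet_epoch"
    onset: float
    duration: float

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass
class Recording:
    values: np.ndarray  # (n_channels, n_samples), channel units
    sampling_rate: float
    array: SensorArray
    annotations: list[Annotation] = field(default_factory=list)
    provenance: str = "simulated"  # "simulated" | "empty_room"
    events: tuple[SpindleEvent, ...] = ()

    def __post_init__(self) -> None:
        T = self.values.shape[1] / self.sampling_rate
        for ann in self.annotations:
            if ann.onset < 0 or ann.offset > T + 1e-9:
                raise ValueError(f"annotation {ann} outside record bounds")

    @property
    def duration(self) -> float:
        return self.values.shape[1] / self.sampling_rate

    def sample_slice(self, ann: Annotation) -> slice:
        i0 = int(round(ann.onset * self.sampling_rate))
        i1 = int(round(ann.offset * self.sampling_rate))
        return slice(i0, i1)


# ---------------------------------------------------------------------------
# Event sampling
# ---------------------------------------------------------------------------

def sample_durations(n: int, rng: np.random.Generator) -> np.ndarray:
    """Spindle durations in seconds: rescaled Beta(0.273, 0.460)."""
    lo, hi = DURATION_RANGE_S
    return lo + (hi - lo) * rng.beta(*DURATION_BETA, size=n)


def _core_center_pool(source_space: SourceSpace, config: GeneratorConfig) -> np.ndarray:
    """Candidate core-patch centers: the tangentially oriented sources.

    The focal (core-system) generators are modelled as sulcal-wall
    patches — sources whose surface normal is nearly tangential to the
    radial direction — the population MEG is selectively sensitive to.
    Falls back to the most tangential decile when the threshold leaves
    too small a pool.
    """
    u = source_space.positions / np.linalg.norm(
        source_space.positions, axis=1, keepdims=True
    )
    radiality = np.abs(np.sum(source_space.orientations * u, axis=1))
    pool = np.flatnonzero(radiality < config.core_tangential_threshold)
    if pool.size < 20:
        pool = np.argsort(radiality)[: max(20, source_space.n_sources // 10)]
    return np.sort(pool)


def sample_spindle_events(
    config: GeneratorConfig,
    source_space: SourceSpace,
    seed: int | None = None,
) -> list[SpindleEvent]:
    """Draw non-overlapping spindle events for one subject's record."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    center_pool = _core_center_pool(source_space, config)
    k = config.spindles_per_subject
    durations = sample_durations(k, rng)
    total = durations.sum()
    # margin at both record ends and between consecutive events
    margin = 0.5
    slack = config.record_duration - total - margin * (k + 1)
    if slack < 0:
        raise ValueError(
            f"cannot fit {k} spindles in a {config.record_duration:.0f} s record"
        )
    gaps = rng.dirichlet(np.ones(k + 1)) * slack
    onsets = []
    t = 0.0
    for i in range(k):
        t += gaps[i] + margin
        onsets.append(t)
        t += durations[i]
    lo_p, hi_p = config.n_core_patches_per_spindle
    events = []
    for onset, dur in zip(onsets, durations):
        n_patch = int(rng.integers(lo_p, hi_p + 1))
        patches = []
        for _ in range(n_patch):
            lag = rng.uniform(0.0, 0.3) * dur
            lead = rng.uniform(0.0, 0.3) * dur
            patches.append(
                CorePatch(
                    center_source_index=int(rng.choice(center_pool)),
                    radius=config.core_patch_radius,
                    frequency=rng.uniform(*SPINDLE_BAND),
                    phase=rng.uniform(0.0, 2.0 * np.pi),
                    onset_lag=lag,
                    offset_lead=lead,
                    amplitude=config.core_amplitude,
                )
            )
        events.append(
            SpindleEvent(
                onset=float(onset),
                duration=float(dur),
                matrix_frequency=float(rng.uniform(*SPINDLE_BAND)),
                matrix_phase=float(rng.uniform(0.0, 2.0 * np.pi)),
                core_patches=tuple(patches),
            )
        )
    return events


# ---------------------------------------------------------------------------
# Source activity synthesis
# ---------------------------------------------------------------------------

def _real_sph_harm_basis(points: np.ndarray, degree: int) -> np.ndarray:
    """Low-order solid-harmonic basis on unit vectors (constant + x,y,z + ...)."""
    x, y, z = points.T
    cols = [np.ones_like(x)]
    if degree >= 1:
        cols += [x, y, z]
    if degree >= 2:
        cols += [x * y, y * z, x * z, x**2 - y**2, 3 * z**2 - 1]
    if degree >= 3:
        cols += [x * (x**2 - 3 * y**2), z * (x**2 - y**2), x * y * z]
    return np.column_stack(cols)


def matrix_gain_map(source_space: SourceSpace, config: GeneratorConfig) -> np.ndarray:
    """Smooth strictly positive spatial gain of the diffuse matrix system.

    A fixed function of the generator seed and source positions, so the
    map is identical for every spindle of a subject.
    """
    rng = np.random.default_rng(config.seed + 104729)
    unit = source_space.positions / np.linalg.norm(
        source_space.positions, axis=1, keepdims=True
    )
    basis = _real_sph_harm_basis(unit, config.matrix_gain_map_smoothness)
    coef = rng.standard_normal(basis.shape[1])
    coef[0] = 0.0
    f = basis @ coef
    f = f / max(np.std(f), 1e-12)
    return np.exp(0.4 * f)  # strictly positive, smooth, same sign everywhere


def _event_times(event: SpindleEvent, config: GeneratorConfig) -> np.ndarray:
    n = int(round(event.duration * config.sampling_rate))
    return event.onset + np.arange(n) / config.sampling_rate


def synthesize_matrix_activity(
    event: SpindleEvent,
    source_space: SourceSpace,
    config: GeneratorConfig,
) -> SourceActivity:
    """Diffuse synchronous oscillation: one waveform, positive spatial map."""
    t = _event_times(event, config)
    env = np.hanning(t.size)
    wave = (
        config.matrix_amplitude
        * env
        * np.sin(2.0 * np.pi * event.matrix_frequency * (t - event.onset) + event.matrix_phase)
    )
    g = matrix_gain_map(source_space, config)
    values = g[:, None] * wave[None, :]
    return SourceActivity(
        values=values,
        sampling_rate=config.sampling_rate,
        first_sample=int(round(event.onset * config.sampling_rate)),
        ground_truth=(event,),
    )


def patch_members(source_space: SourceSpace, patch: CorePatch) -> np.ndarray:
    """Indices of sources within the patch's geodesic disc."""
    pos = source_space.positions
    center = pos[patch.center_source_index]
    r_center = np.linalg.norm(center)
    u = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    cosang = np.clip(u @ (center / r_center), -1.0, 1.0)
    geodesic = r_center * np.arccos(cosang)
    return np.flatnonzero(geodesic <= patch.radius)


def synthesize_core_activity(
    event: SpindleEvent,
    source_space: SourceSpace,
    config: GeneratorConfig,
) -> SourceActivity:
    """Focal asynchronous patches, each with its own waveform and support."""
    if not event.core_patches:
        raise ValueError("event has no core patches")
    t = _event_times(event, config)
    values = np.zeros((source_space.n_sources, t.size))
    max_extent = np.pi * np.linalg.norm(source_space.positions, axis=1).max() / 2
    for patch in event.core_patches:
        if patch.radius > max_extent:
            raise ValueError("patch radius exceeds hemisphere extent")
        t0 = event.onset + patch.onset_lag
        t1 = event.offset - patch.offset_lead
        active = (t >= t0) & (t <= t1)
        if not np.any(active):
            continue
        ta = t[active]
        env = np.hanning(ta.size)
        wave = (
            patch.amplitude
            * env
            * np.sin(2.0 * np.pi * patch.frequency * (ta - t0) + patch.phase)
        )
        members = patch_members(source_space, patch)
        values[np.ix_(members, np.flatnonzero(active))] += wave[None, :]
    return SourceActivity(
        values=values,
        sampling_rate=config.sampling_rate,
        first_sample=int(round(event.onset * config.sampling_rate)),
        ground_truth=(event,),
    )


def one_over_f_noise(
    n_series: int, n_samples: int, rng: np.random.Generator, fs: float
) -> np.ndarray:
    """Stationary noise with power spectral density ~ 1/f, unit variance.

    The 1/f shaping is flattened below 1 Hz (spontaneous activity has a
    low-frequency cutoff and recordings are high-passed), which also
    keeps independent draws decorrelated over finite records.
    """
    white = rng.standard_normal((n_series, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    shaping[0] = 0.0  # no DC
    spec *= shaping
    out = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = out.std(axis=1, keepdims=True)
    return out / np.where(sd > 0, sd, 1.0)


def synthesize_background(
    n_samples: int,
    source_space: SourceSpace,
    config: GeneratorConfig,
    seed: int | None = None,
) -> SourceActivity:
    """Spatially independent 1/f-shaped noise dipoles at every source."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if config.background_amplitude == 0:
        values = np.zeros((source_space.n_sources, n_samples))
    else:
        values = config.background_amplitude * one_over_f_noise(
            source_space.n_sources, n_samples, rng, config.sampling_rate
        )
    return SourceActivity(values=values, sampling_rate=config.sampling_rate)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _sensor_noise(
    array: SensorArray, n_samples: int, config: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    sds = np.array([config.sensor_noise_sd[ch.kind.value] for ch in array.channels])
    return sds[:, None] * rng.standard_normal((len(array), n_samples))


def _quiet_epoch_annotations(
    events: tuple[SpindleEvent, ...], config: GeneratorConfig
) -> list[Annotation]:
    """Non-overlapping quiet epochs placed in the event-free gaps."""
    dur = config.quiet_epoch_duration
    guard = 0.1
    edges = [0.0]
    for ev in sorted(events, key=lambda e: e.onset):
        edges.append(ev.onset - guard)
        edges.append(ev.offset + guard)
    edges.append(config.record_duration)
    epochs: list[Annotation] = []
    for lo, hi in zip(edges[::2], edges[1::2]):
        t = lo
        while t + dur <= hi and len(epochs) < config.quiet_epochs_per_subject:
            epochs.append(Annotation("quiet_epoch", round(t, 6), dur))
            t += dur
    if len(epochs) < config.quiet_epochs_per_subject:
        raise ValueError(
            f"only {len(epochs)} quiet epochs fit; lengthen record_duration"
        )
    return epochs


def render_recording(
    activities: list[SourceActivity],
    gain: GainMatrix,
    source_space: SourceSpace,
    config: GeneratorConfig,
    seed: int | None = None,
    n_samples: int | None = None,
) -> Recording:
    """Project source activity to sensors and add white channel noise.

    ``x = G_n s + noise`` with ``G_n`` the gain collapsed onto the local
    surface normals.  Spindle annotations are carried over from the
    activities' ground-truth events; quiet epochs are inserted in the
    event-free gaps.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if n_samples is None:
        n_samples = int(round(config.record_duration * config.sampling_rate))
    arr = _array_of(gain)
    Gn = gain.along_normals(source_space)
    x = np.zeros((Gn.shape[0], n_samples))
    events: list[SpindleEvent] = []
    for act in activities:
        if act.values.shape[0] != source_space.n_sources:
            raise ValueError("activity/source-space dimension mismatch")
        i0 = act.first_sample
        i1 = i0 + act.values.shape[1]
        if i1 > n_samples:
            raise ValueError("activity extends past the record end")
        x[:, i0:i1] += Gn @ act.values
        events.extend(act.ground_truth)
    noise = _sensor_noise(arr, n_samples, config, rng)
    annotations = [Annotation("spindle", ev.onset, ev.duration) for ev in events]
    annotations += _quiet_epoch_annotations(tuple(events), config)
    return Recording(
        values=x + noise,
        sampling_rate=config.sampling_rate,
        array=arr,
        annotations=annotations,
        provenance="simulated",
        events=tuple(sorted(events, key=lambda e: e.onset)),
    )


def _array_of(gain: GainMatrix) -> SensorArray:
    if not hasattr(gain, "_array"):
        raise ValueError("gain has no attached sensor array; use attach_array")
    return gain._array  # type: ignore[attr-defined]


def attach_array(gain: GainMatrix, array: SensorArray) -> GainMatrix:
    """Associate the sensor array with its gain for rendering."""
    if array.names != gain.channel_order:
        raise ValueError("array channels do not match gain channel order")
    gain._array = array  # type: ignore[attr-defined]
    return gain


def empty_room_recording(
    array: SensorArray,
    config: GeneratorConfig,
    n_samples: int,
    seed: int | None = None,
) -> Recording:
    """Sensor noise only — the instrumentation/environment noise estimate.

    Only meaningful for MEG: an EEG 'empty room' has no physical analog
    (electrodes need a scalp), so EEG requests are refused.
    """
    if array.modality == Modality.EEG:
        raise ValueError("EEG has no empty-room analog")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return Recording(
        values=_sensor_noise(array, n_samples, config, rng),
        sampling_rate=config.sampling_rate,
        array=array,
        annotations=[],
        provenance="empty_room",
    )


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

_FILTERS = {
    "lowpass40": dict(N=4, Wn=40.0, btype="lowpass"),
    "band10_15": dict(N=4, Wn=(10.0, 15.0), btype="bandpass"),
}


def filter_recording(rec: Recording, kind: str) -> Recording:
    """Zero-phase (forward-backward) Butterworth filtering."""
    if kind not in _FILTERS:
        raise ValueError(f"unknown filter kind {kind!r}")
    spec = _FILTERS[kind]
    upper = spec["Wn"] if np.isscalar(spec["Wn"]) else spec["Wn"][1]
    if rec.sampling_rate <= 2 * upper:
        raise ValueError("sampling rate must exceed twice the filter's upper edge")
    sos = signal.butter(spec["N"], spec["Wn"], btype=spec["btype"], fs=rec.sampling_rate, output="sos")
    # forward-backward doubles order; require a record several times the
    # filter's effective impulse-response length
    padlen = 3 * (2 * sos.shape[0] + 1) * 10
    if rec.values.shape[1] <= padlen:
        raise ValueError("record too short for zero-phase filtering edge effects")
    filtered = signal.sosfiltfilt(sos, rec.values, axis=1)
    return replace(rec, values=filtered, annotations=list(rec.annotations))


def extract_epochs(rec: Recording, label: str) -> list[np.ndarray]:
    """Channel x time segments for every annotation with the given label."""
    return [rec.values[:, rec.sample_slice(a)] for a in rec.annotations if a.label == label]
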