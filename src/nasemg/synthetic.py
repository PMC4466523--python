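"""Ground-truth scenario generator for the nasality pipeline.

A *scenario* emulates the paired acquisition the analysis assumes: the same
nonsense-word utterances produced twice by a speaker — once in an EMG
session (5-channel surface EMG at 600 Hz plus 8 kHz audio) and once in an
RT-MRI session (14 frames/s image sequences plus 16 kHz audio) — with a
smooth monotone time warp between the two sessions.  Every stage of the
pipeline can therefore be scored against known truth: the velum-aperture
pulses, the nasal intervals, the warp, and the per-frame airway areas.

The EMG model is deliberately phenomenological: Gaussian baseline noise
plus Hann-enveloped band-limited (60–200 Hz) stochastic bursts whose
envelopes start ``burst_lead`` seconds before each nasal-interval onset
(and, by default, before each offset, for the closing movement), mixed
across channels by a crosstalk matrix.  It reproduces the *statistical*
structure the classifier exploits — activity anticipating nasal intervals,
contaminated by crosstalk and noise — without claiming a physiological
motor-unit model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.signal

from .datatypes import AudioSignal, EMGRecording, ImageSequence, VelumCurve

__all__ = [
    "Event",
    "MRIGeometry",
    "PiecewiseLinearWarp",
    "ScenarioConfig",
    "Scenario",
    "make_schedule",
    "make_velum_curve",
    "make_emg",
    "burst_windows",
    "make_base_audio",
    "make_warped_audio",
    "make_mri_stack",
    "make_scenario",
]

#: SAMPA labels of the five European Portuguese nasal vowels, cycled over
#: the schedule so per-vowel result grouping has something to group by.
NASAL_VOWELS = ("6~", "e~", "i~", "o~", "u~")


@dataclass
class Event:
    """One schedule entry: a syllable whose vowel may open the velum."""

    onset_time: float
    kind: str  # "nasal" | "oral"
    open_duration: float
    vowel: str = "6~"

    def __post_init__(self) -> None:
        if self.kind not in ("nasal", "oral"):
            raise ValueError("event kind must be 'nasal' or 'oral'")
        if self.open_duration <= 0:
            raise ValueError("open_duration must be positive")
        if self.onset_time < 0:
            raise ValueError("onset_time must be non-negative")


@dataclass
class MRIGeometry:
    """Toy image geometry: a bright tissue background with a dark airway
    region inside a rectangular ROI whose area tracks the velum curve."""

    height: int = 64
    width: int = 64
    roi: tuple = (16, 48, 16, 48)  # (row0, row1, col0, col1), half-open
    min_area: int = 40
    max_area: int = 400
    background: float = 0.8
    airway: float = 0.1
    noise_sd: float = 0.02

    def roi_mask(self) -> np.ndarray:
        m = np.zeros((self.height, self.width), dtype=bool)
        r0, r1, c0, c1 = self.roi
        m[r0:r1, c0:c1] = True
        return m


class PiecewiseLinearWarp:
    """Strictly monotone piecewise-linear time map defined by knots.

    Linear continuation beyond the first/last knot.  ``inverse()`` swaps
    the knot coordinates.
    """

    def __init__(self, knots):
        knots = np.asarray(knots, dtype=np.float64)
        if knots.ndim != 2 or knots.shape[1] != 2 or len(knots) < 2:
            raise ValueError("warp needs >= 2 (u, t) knots")
        if np.any(np.diff(knots[:, 0]) <= 0) or np.any(np.diff(knots[:, 1]) <= 0):
            raise ValueError("warp knots must be strictly increasing in both axes")
        self.knots = knots

    @classmethod
    def identity(cls, duration: float = 1.0) -> "PiecewiseLinearWarp":
        return cls([[0.0, 0.0], [duration, duration]])

    @classmethod
    def affine(cls, factor: float, duration: float = 1.0) -> "PiecewiseLinearWarp":
        if factor <= 0:
            raise ValueError("affine warp factor must be positive")
        return cls([[0.0, 0.0], [duration, factor * duration]])

    def __call__(self, u):
        u = np.asarray(u, dtype=np.float64)
        x, y = self.knots[:, 0], self.knots[:, 1]
        out = np.interp(u, x, y)
        # linear extrapolation at both ends
        lo = u < x[0]
        hi = u > x[-1]
        if np.any(lo):
            s = (y[1] - y[0]) / (x[1] - x[0])
            out = np.where(lo, y[0] + s * (u - x[0]), out)
        if np.any(hi):
            s = (y[-1] - y[-2]) / (x[-1] - x[-2])
            out = np.where(hi, y[-1] + s * (u - x[-1]), out)
        return out if out.ndim else float(out)

    def inverse(self) -> "PiecewiseLinearWarp":
        return PiecewiseLinearWarp(self.knots[:, ::-1])


def _as_warp(warp_params, duration: float) -> PiecewiseLinearWarp:
    """Accept a warp object, knot list, ('affine', a) pair, or None."""
    if warp_params is None:
        return PiecewiseLinearWarp.identity(duration)
    if isinstance(warp_params, PiecewiseLinearWarp):
        return warp_params
    if (
        isinstance(warp_params, (tuple, list))
        and len(warp_params) == 2
        and warp_params[0] == "affine"
    ):
        return PiecewiseLinearWarp.affine(float(warp_params[1]), duration)
    return PiecewiseLinearWarp(warp_params)


@dataclass
class ScenarioConfig:
    """Generation parameters; the defaults are the package's reference
    study conditions (sampling rates of the acquisition being emulated,
    five EMG channels, 0.10 s activation lead, burst SNR 4)."""

    n_utterances: int = 8
    vowel_schedule: list = None  # type: ignore[assignment]
    emg_rate: float = 600.0
    mri_fps: float = 14.0
    audio_rate_mri: float = 16000.0
    audio_rate_emg: float = 8000.0
    n_channels: int = 5
    burst_lead: float = 0.10
    burst_duration: float = 0.40
    bursts_at_closing: bool = True
    burst_snr: float = 4.0
    noise_rms: float = 1.0
    channel_gains: tuple = None  # type: ignore[assignment]
    crosstalk: np.ndarray = None  # type: ignore[assignment]
    warp_params: object = None
    mri_geometry: MRIGeometry = field(default_factory=MRIGeometry)
    tail: float = 0.6  # silence after the last event, s
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("emg_rate", "mri_fps", "audio_rate_mri", "audio_rate_emg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.burst_lead < 0:
            raise ValueError("burst_lead must be non-negative")
        if self.burst_snr < 0:
            raise ValueError("burst_snr must be non-negative")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if self.vowel_schedule is None:
            self.vowel_schedule = make_schedule(self.n_utterances)
        if self.channel_gains is None:
            # mid channels slightly hotter, mimicking electrode placement
            if self.n_channels == 5:
                self.channel_gains = (0.7, 1.0, 1.0, 1.0, 0.7)
            else:
                self.channel_gains = tuple([1.0] * self.n_channels)
        if self.crosstalk is None:
            self.crosstalk = default_crosstalk(self.n_channels)
        self.crosstalk = np.asarray(self.crosstalk, dtype=np.float64)
        if self.crosstalk.shape != (self.n_channels, self.n_channels):
            raise ValueError("crosstalk must be n_channels x n_channels")
        if not np.all(np.isfinite(self.crosstalk)):
            raise ValueError("crosstalk weights must be finite")

    @property
    def duration(self) -> float:
        last = max(e.onset_time + e.open_duration for e in self.vowel_schedule)
        return last + self.tail


def default_crosstalk(n: int) -> np.ndarray:
    """Identity mixing plus mild leakage into first and second neighbours."""
    m = np.eye(n)
    for i in range(n):
        for j in range(n):
            d = abs(i - j)
            if d == 1:
                m[i, j] = 0.15
            elif d == 2:
                m[i, j] = 0.05
    return m


def make_schedule(
    n_utterances: int,
    period: float = 1.4,
    open_duration: float = 0.8,
    start: float = 0.7,
    nasal_fraction: float = 1.0,
) -> list:
    """Regular schedule of utterances; each carries one of the five nasal
    vowels (cycled) unless diluted by ``nasal_fraction`` < 1, in which case
    every ``1/(1-nasal_fraction)``-th event is oral."""
    if n_utterances < 1:
        raise ValueError("need at least one utterance")
    events = []
    for k in range(n_utterances):
        kind = "nasal"
        if nasal_fraction < 1.0:
            stride = max(2, int(round(1.0 / max(1e-9, 1.0 - nasal_fraction))))
            if k % stride == stride - 1:
                kind = "oral"
        events.append(
            Event(
                onset_time=start + k * period,
                kind=kind,
                open_duration=open_duration,
                vowel=NASAL_VOWELS[k % len(NASAL_VOWELS)] if kind == "nasal" else "a",
            )
        )
    return events


def _pulse_values(schedule, times: np.ndarray) -> np.ndarray:
    """Pointwise maximum of raised-cosine aperture pulses at ``times``."""
    out = np.zeros_like(np.asarray(times, dtype=np.float64))
    for ev in schedule:
        if ev.kind != "nasal":
            continue
        o, d = ev.onset_time, ev.open_duration
        m = (times >= o) & (times < o + d)
        pulse = 0.5 * (1.0 - np.cos(2.0 * np.pi * (times[m] - o) / d))
        out[m] = np.maximum(out[m], pulse)
    return out


def make_velum_curve(schedule, fps: float, duration: float) -> VelumCurve:
    """Velum-aperture curve: baseline 0 (closed port), one raised-cosine
    pulse of height 1 per nasal event; overlaps merge by pointwise maximum.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    for ev in schedule:
        if ev.onset_time + ev.open_duration > duration + 1e-9:
            raise ValueError(f"event at {ev.onset_time} s extends past duration")
    n = int(round(duration * fps))
    times = np.arange(n) / fps
    return VelumCurve(values=_pulse_values(schedule, times), rate=fps)


def nasal_intervals(schedule) -> list:
    """Merged [start, end) supports of the nasal pulses, sorted."""
    spans = sorted(
        (e.onset_time, e.onset_time + e.open_duration)
        for e in schedule
        if e.kind == "nasal"
    )
    merged: list = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def burst_windows(intervals, config: ScenarioConfig) -> list:
    """Half-open [start, end) envelope windows implied by the config.

    The opening burst starts ``burst_lead`` before the interval onset
    (activity anticipates the lowering movement).  The optional closing
    burst spans the raising movement, which completes at the interval
    offset, so its envelope is placed to end there.
    """
    wins = []
    for s, e in intervals:
        wins.append((s - config.burst_lead, s - config.burst_lead + config.burst_duration))
        if config.bursts_at_closing:
            wins.append((e - config.burst_duration, e))
    return wins


def _bandlimited_noise(n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """White noise shaped to the 60–200 Hz band (4th-order Butterworth,
    zero-phase), RMS-normalized."""
    white = rng.standard_normal(n)
    sos = scipy.signal.butter(4, [60.0, 200.0], btype="bandpass", fs=rate, output="sos")
    shaped = scipy.signal.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(shaped**2))
    return shaped / rms if rms > 0 else shaped


def make_emg(
    true_velum: VelumCurve,
    true_nasal_intervals,
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> EMGRecording:
    """Render the multi-channel EMG: per channel, Gaussian baseline noise
    plus Hann-enveloped band-limited bursts anchored to the nasal
    intervals, amplitude set so burst-RMS / noise-RMS = ``burst_snr`` times
    the channel gain; channels then mixed by the crosstalk matrix."""
    if config.burst_snr < 0:
        raise ValueError("burst_snr must be non-negative")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    duration = true_velum.duration
    for s, e in true_nasal_intervals:
        if e > duration + 1e-9:
            raise ValueError("nasal interval extends past the curve duration")
    n = int(round(duration * config.emg_rate))
    raw = np.empty((config.n_channels, n))
    wins = burst_windows(true_nasal_intervals, config)
    for c in range(config.n_channels):
        x = rng.standard_normal(n) * config.noise_rms
        if config.burst_snr > 0:
            target = config.burst_snr * config.channel_gains[c] * config.noise_rms
            for t0, t1 in wins:
                i0 = max(0, int(round(t0 * config.emg_rate)))
                i1 = min(n, int(round(t1 * config.emg_rate)))
                if i1 - i0 < 4:
                    continue
                carrier = _bandlimited_noise(i1 - i0, config.emg_rate, rng)
                env = scipy.signal.windows.hann(i1 - i0)
                seg = carrier * env
                rms = np.sqrt(np.mean(seg**2))
                if rms > 0:
                    x[i0:i1] += seg * (target / rms)
        raw[c] = x
    mixed = config.crosstalk @ raw
    meta = [
        {"id": c + 1, "configuration": "monopolar" if c + 1 in (1, 2) else "bipolar"}
        for c in range(config.n_channels)
    ]
    return EMGRecording(channels=mixed, rate=config.emg_rate, channel_meta=meta)


def make_base_audio(schedule, duration: float, rate: float = 16000.0) -> AudioSignal:
    """Concatenated tone-complex 'syllables', one per schedule event.

    Each event contributes a Hann-enveloped complex of three harmonics on
    an event-specific fundamental (cycled over a small set), giving the
    DTW stage distinct spectral/energy landmarks without speech synthesis.
    """
    f0s = (220.0, 290.0, 360.0, 440.0, 520.0)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    x = np.zeros(n)
    for k, ev in enumerate(schedule):
        f0 = f0s[k % len(f0s)]
        o, d = ev.onset_time, ev.open_duration
        m = (t >= o) & (t < o + d)
        u = (t[m] - o) / d
        env = 0.5 * (1.0 - np.cos(2.0 * np.pi * u))
        seg = np.zeros(m.sum())
        for h, amp in ((1, 1.0), (2, 0.5), (3, 0.25)):
            seg += amp * np.sin(2.0 * np.pi * h * f0 * (t[m] - o))
        x[m] += env * seg
    peak = np.max(np.abs(x))
    if peak > 0:
        x *= 0.8 / peak
    return AudioSignal(samples=x, rate=rate)


def make_warped_audio(
    base: AudioSignal,
    warp_params,
    rate_mri: float = 16000.0,
    rate_emg: float = 8000.0,
):
    """Render the two session audio tracks from one base waveform.

    ``audio_emg`` is the base resampled to the EMG-side rate.  ``audio_mri``
    is the base time-warped by the monotone map g: EMG-time → MRI-time and
    rendered at the MRI-side rate.  Returns (audio_mri, audio_emg,
    true_warp) where ``true_warp`` maps MRI-time → EMG-time (g⁻¹), for
    alignment-recovery tests.
    """
    if base.samples.size == 0:
        raise ValueError("base audio must be non-empty")
    g = _as_warp(warp_params, base.duration)
    from .align import resample_audio  # local import to avoid cycle

    audio_emg = resample_audio(base, rate_emg)
    dur_mri = float(g(base.duration))
    n_mri = int(round(dur_mri * rate_mri))
    tau = np.arange(n_mri) / rate_mri
    ginv = g.inverse()
    u = ginv(tau)  # EMG-session times to sample the base at
    base_t = np.arange(base.samples.size) / base.rate
    samples = np.interp(u, base_t, base.samples, left=0.0, right=0.0)
    audio_mri = AudioSignal(samples=samples, rate=rate_mri)
    return audio_mri, audio_emg, ginv


def make_mri_stack(
    true_velum: VelumCurve,
    geometry: MRIGeometry | None = None,
    rng: np.random.Generator | None = None,
):
    """Toy sagittal stack: bright background, dark airway region inside the
    ROI whose pixel count is an affine (hence monotone) function of the
    velum curve.  Returns (ImageSequence, true_areas)."""
    if geometry is None:
        geometry = MRIGeometry()
    if rng is None:
        rng = np.random.default_rng(0)
    g = geometry
    r0, r1, c0, c1 = g.roi
    if r1 > g.height or c1 > g.width or r0 < 0 or c0 < 0:
        raise ValueError("ROI must fit inside the image")
    rows, cols = np.mgrid[r0:r1, c0:c1]
    cy, cx = (r0 + r1 - 1) / 2.0, (c0 + c1 - 1) / 2.0
    dist = (rows - cy) ** 2 + (cols - cx) ** 2
    order = np.argsort(dist.ravel(), kind="stable")
    rr, cc = rows.ravel()[order], cols.ravel()[order]
    if g.max_area > rr.size:
        raise ValueError("max_area exceeds the ROI capacity")
    T = true_velum.values.size
    frames = np.empty((T, g.height, g.width))
    true_areas = np.empty(T, dtype=np.int64)
    for k in range(T):
        area = g.min_area + int(round(true_velum.values[k] * (g.max_area - g.min_area)))
        true_areas[k] = area
        img = np.full((g.height, g.width), g.background)
        img[rr[:area], cc[:area]] = g.airway
        img += rng.standard_normal(img.shape) * g.noise_sd
        frames[k] = np.clip(img, 0.0, 1.0)
    return ImageSequence(frames=frames, fps=true_velum.rate), true_areas


@dataclass
class Scenario:
    """One generated study condition with all ground truth attached."""

    config: ScenarioConfig
    true_velum: VelumCurve  # on the MRI clock
    true_nasal_intervals: list  # [start, end) on the EMG clock
    true_warp: PiecewiseLinearWarp  # MRI-time -> EMG-time
    emg: EMGRecording
    audio_mri: AudioSignal
    audio_emg: AudioSignal
    mri: ImageSequence
    true_areas: np.ndarray
    vowel_of_time: list = field(default_factory=list)  # (start, end, vowel)


def make_scenario(config: ScenarioConfig) -> Scenario:
    """Generate a full scenario from one seeded generator (bit-reproducible
    for identical (config, seed))."""
    rng = np.random.default_rng(config.seed)
    duration = config.duration
    intervals = nasal_intervals(config.vowel_schedule)
    if not intervals:
        raise ValueError("schedule contains no nasal events")

    # EMG-session timeline (canonical)
    velum_emg = make_velum_curve(config.vowel_schedule, config.emg_rate, duration)
    emg = make_emg(velum_emg, intervals, config, rng)
    base = make_base_audio(config.vowel_schedule, duration, config.audio_rate_mri)
    audio_mri, audio_emg, true_warp = make_warped_audio(
        base, config.warp_params, config.audio_rate_mri, config.audio_rate_emg
    )

    # MRI-session timeline: velum curve observed through the warp
    g = _as_warp(config.warp_params, duration)
    dur_mri = float(g(duration))
    n_mri = int(round(dur_mri * config.mri_fps))
    t_mri = np.arange(n_mri) / config.mri_fps
    values = _pulse_values(config.vowel_schedule, np.asarray(true_warp(t_mri)))
    true_velum = VelumCurve(values=values, rate=config.mri_fps)
    mri, true_areas = make_mri_stack(true_velum, config.mri_geometry, rng)

    vowels = [
        (e.onset_time, e.onset_time + e.open_duration, e.vowel)
        for e in config.vowel_schedule
        if e.kind == "nasal"
    ]
    return Scenario(
        config=config,
        true_velum=true_velum,
        true_nasal_intervals=intervals,
        true_warp=true_warp,
        emg=emg,
        audio_mri=audio_mri,
        audio_emg=audio_emg,
        mri=mri,
        true_areas=true_areas,
        vowel_of_time=vowels,
    )
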