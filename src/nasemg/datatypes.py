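"""Shared containers for the EMG / RT-MRI nasality pipeline.

All times are seconds (float64), intervals are half-open ``[start, end)``
and sample/frame indices are 0-based throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AudioSignal",
    "ImageSequence",
    "AreaCurve",
    "VelumCurve",
    "EMGRecording",
    "WarpPath",
    "BoundaryGeometry",
    "Zone",
    "ZoneLabels",
    "FrameIndex",
]


@dataclass
class AudioSignal:
    """A mono waveform with its sampling rate in Hz."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise ValueError("audio rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("audio samples must be 1-D")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("audio samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass
class ImageSequence:
    """Time-ordered stack of 2-D intensity frames (RT-MRI stand-in).

    ``frames`` has shape (T, H, W) with intensities in [0, 1];
    ``fps`` is the acquisition frame rate.
    """

    frames: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) stack with T >= 1")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("intensities must be finite")
        if self.frames.min() < 0 or self.frames.max() > 1:
            raise ValueError("intensities must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class AreaCurve:
    """Per-frame pixel counts of a segmented region, at the image frame rate."""

    areas: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas)
        if self.areas.ndim != 1:
            raise ValueError("areas must be 1-D")
        if np.any(self.areas < 0):
            raise ValueError("areas must be non-negative")
        if not np.all(self.areas == np.round(self.areas)):
            raise ValueError("areas must be integer pixel counts")
        self.areas = self.areas.astype(np.int64)
        if self.fps <= 0:
            raise ValueError("fps must be positive")


@dataclass
class VelumCurve:
    """Normalized velum-aperture signal x(n) in [0, 1].

    ``mean`` and ``sd`` are the sample mean and *population* standard
    deviation of ``values``; they drive the nasal threshold x̄ + σ/2.
    ``degenerate`` marks a constant source curve in which no nasality
    is detectable.
    """

    values: np.ndarray
    rate: float
    mean: float = field(default=None)  # type: ignore[assignment]
    sd: float = field(default=None)  # type: ignore[assignment]
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a non-empty 1-D array")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("values must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)
        if self.mean is None:
            self.mean = float(self.values.mean())
        if self.sd is None:
            self.sd = float(self.values.std())  # population SD

    @property
    def duration(self) -> float:
        return self.values.size / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.rate


@dataclass
class EMGRecording:
    """Multi-channel surface EMG.

    ``channels`` has shape (C, N); ``rate`` defaults to the 600 Hz of the
    acquisition hardware.  ``channel_meta`` carries id and electrode
    configuration per channel; ``marker_time`` is the sync marker.
    """

    channels: np.ndarray
    rate: float = 600.0
    channel_meta: list = field(default_factory=list)
    marker_time: float = 0.0
    preprocessed: bool = False
    zero_channels: tuple = ()

    def __post_init__(self) -> None:
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=np.float64))
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not self.channel_meta:
            self.channel_meta = [
                {"id": i + 1, "configuration": "bipolar"}
                for i in range(self.channels.shape[0])
            ]
        if len(self.channel_meta) != self.channels.shape[0]:
            raise ValueError("channel_meta length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


@dataclass
class WarpPath:
    """A DTW alignment path between two short-time feature timelines.

    ``pairs`` is a (K, 2) int array of (i, j) indices; it starts at (0, 0),
    ends at (N-1, M-1), and moves by steps in {(1,0), (0,1), (1,1)}.
    ``frame_hop`` converts indices to seconds.
    """

    pairs: np.ndarray
    frame_hop: float

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64)
        if self.pairs.ndim != 2 or self.pairs.shape[1] != 2 or len(self.pairs) == 0:
            raise ValueError("pairs must be a non-empty (K, 2) array")
        if self.frame_hop <= 0:
            raise ValueError("frame_hop must be positive")
        d = np.diff(self.pairs, axis=0)
        if len(d) and (d.min() < 0 or d.max() > 1 or np.any(d.sum(axis=1) == 0)):
            raise ValueError("path steps must be in {(1,0),(0,1),(1,1)}")
        if tuple(self.pairs[0]) != (0, 0):
            raise ValueError("path must start at (0, 0)")


@dataclass
class BoundaryGeometry:
    """Mirrored-angle construction that widens a nasal zone boundary.

    theta1 is the angle at the peak between the vertical axis and the
    segment to the x = x̄ crossing; the congruent triangle dropped from the
    crossing level to zero has horizontal cathetus ``v2``, the amount by
    which the boundary is pushed outward.
    """

    peak_time: float
    peak_level: float
    crossing_time: float
    crossing_level: float
    theta1: float
    theta2: float
    v2: float
    boundary_time: float


@dataclass
class Zone:
    start: float
    end: float
    label: str  # "nasal" | "non-nasal"
    geometry: tuple | None = None  # (rising BoundaryGeometry, falling ...) for nasal

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("zone must have positive duration")
        if self.label not in ("nasal", "non-nasal"):
            raise ValueError("label must be 'nasal' or 'non-nasal'")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class ZoneLabels:
    """Ordered non-overlapping zones covering a time span, plus the 0/1
    square wave sampled on the curve clock (1 = nasal)."""

    zones: list
    square_wave: np.ndarray
    rate: float
    span: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.square_wave = np.asarray(self.square_wave, dtype=np.int8)
        starts = [z.start for z in self.zones]
        if starts != sorted(starts):
            raise ValueError("zones must be sorted")
        for a, b in zip(self.zones, self.zones[1:]):
            if b.start < a.end - 1e-9:
                raise ValueError("zones must not overlap")

    def nasal_zones(self) -> list:
        return [z for z in self.zones if z.label == "nasal"]

    def label_at(self, t: float) -> str:
        for z in self.zones:
            if z.start <= t < z.end:
                return z.label
        # allow the exact right edge of the span
        if self.zones and abs(t - self.zones[-1].end) <= 1e-9:
            return self.zones[-1].label
        raise ValueError(f"time {t} s outside the labeled span")


@dataclass
class FrameIndex:
    """Half-open (start_sample, end_sample) frames on a sample clock."""

    frames: np.ndarray  # (K, 2) ints
    rate: float
    frame_length: float = 0.100
    frame_shift: float = 0.020

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64).reshape(-1, 2)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def start_times(self) -> np.ndarray:
        return self.frames[:, 0] / self.rate

    def midpoints(self) -> np.ndarray:
        return (self.frames[:, 0] + self.frames[:, 1]) / (2.0 * self.rate)
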