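"""Surface-EMG pre-processing and framing.

Pre-processing per channel: max-absolute normalization, rectification,
and a 12-point moving-average run forward and backward so the net filter
is exactly zero-phase (an even-length single-pass boxcar cannot be
zero-phase on the sample grid).  Classification frames are 100 ms long
with a 20 ms shift.
"""

from __future__ import annotations

import numpy as np

from .datatypes import EMGRecording, FrameIndex

__all__ = ["preprocess", "frame_signal"]

_MA_POINTS = 12


def _smooth(x: np.ndarray) -> np.ndarray:
    """12-tap boxcar applied forward then backward (net 23-tap symmetric
    response), with reflect padding trimmed after filtering."""
    k = np.ones(_MA_POINTS) / _MA_POINTS
    pad = _MA_POINTS
    xp = np.pad(x, pad, mode="reflect")
    fwd = np.convolve(xp, k, mode="full")[: xp.size]  # causal pass
    bwd = np.convolve(fwd[::-1], k, mode="full")[: xp.size][::-1]
    return bwd[pad:-pad]


def preprocess(rec: EMGRecording) -> EMGRecording:
    """Normalize, rectify and smooth every channel; all-zero channels are
    passed through unchanged and flagged in ``zero_channels``."""
    out = np.empty_like(rec.channels)
    zero = []
    for c in range(rec.n_channels):
        x = rec.channels[c]
        peak = np.max(np.abs(x)) if x.size else 0.0
        if peak == 0.0:
            zero.append(c)
            out[c] = x
            continue
        out[c] = _smooth(np.abs(x / peak))
    return EMGRecording(
        channels=out,
        rate=rec.rate,
        channel_meta=[dict(m) for m in rec.channel_meta],
        marker_time=rec.marker_time,
        preprocessed=True,
        zero_channels=tuple(zero),
    )


def frame_signal(
    n_samples: int,
    rate: float,
    frame_length: float = 0.100,
    frame_shift: float = 0.020,
) -> FrameIndex:
    """Half-open frames of round(frame_length·rate) samples every
    round(frame_shift·rate); the trailing partial frame is discarded."""
    if frame_shift <= 0 or frame_length < frame_shift:
        raise ValueError("need frame_length >= frame_shift > 0")
    L = int(round(frame_length * rate))
    S = int(round(frame_shift * rate))
    if n_samples < L:
        frames = np.empty((0, 2), dtype=np.int64)
    else:
        k = (n_samples - L) // S + 1
        starts = S * np.arange(k)
        frames = np.stack([starts, starts + L], axis=1)
    return FrameIndex(frames=frames, rate=rate, frame_length=frame_length, frame_shift=frame_shift)
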