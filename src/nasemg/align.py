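"""Cross-modal time alignment of the two recording sessions.

Each session produced an audio track alongside its primary modality (RT-MRI
images, surface EMG).  Both audio tracks are resampled to a common 12 kHz
rate, reduced to short-time log-energy envelopes (25 ms window, 10 ms hop),
and aligned by dynamic time warping with steps {(1,1), (1,0), (0,1)},
squared-difference local cost and a Sakoe–Chiba band.  The resulting path
is collapsed into a monotone time map used to carry the velum curve onto
the EMG sample clock.

DTW over envelopes rather than raw samples keeps the problem O((N/hop)²)
and phase-robust; energy landmarks (syllable onsets/offsets) are what the
two sessions genuinely share.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import scipy.signal
from numba import njit

from .datatypes import AudioSignal, VelumCurve, WarpPath

__all__ = [
    "resample_audio",
    "log_energy_features",
    "dtw_align",
    "path_time_map",
    "warp_curve",
    "COMMON_RATE",
]

COMMON_RATE = 12000.0
DTW_WINDOW = 0.025  # s
DTW_HOP = 0.010  # s
DB_FLOOR = -60.0


def resample_audio(a: AudioSignal, target_rate: float) -> AudioSignal:
    """Band-limited (polyphase) resampling; output length is
    round(len * target / rate)."""
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if a.samples.size == 0 or target_rate == a.rate:
        return AudioSignal(samples=a.samples.copy(), rate=target_rate)
    frac = Fraction(target_rate / a.rate).limit_denominator(10000)
    out = scipy.signal.resample_poly(a.samples, frac.numerator, frac.denominator)
    n_target = int(round(a.samples.size * target_rate / a.rate))
    if out.size > n_target:
        out = out[:n_target]
    elif out.size < n_target:
        out = np.pad(out, (0, n_target - out.size))
    return AudioSignal(samples=out, rate=target_rate)


def log_energy_features(
    a: AudioSignal, window: float = DTW_WINDOW, hop: float = DTW_HOP
) -> np.ndarray:
    """Short-time log energy in dB, floored at −60 dB relative to the
    track's peak frame energy."""
    L = int(round(window * a.rate))
    S = int(round(hop * a.rate))
    if a.samples.size < L:
        raise ValueError("signal shorter than one analysis window")
    n = (a.samples.size - L) // S + 1
    idx = np.arange(L)[None, :] + S * np.arange(n)[:, None]
    frames = a.samples[idx]
    e = np.mean(frames**2, axis=1)
    ref = e.max()
    if ref <= 0:
        return np.full(n, DB_FLOOR)
    db = 10.0 * np.log10(np.maximum(e / ref, 10 ** (DB_FLOOR / 10.0)))
    return db


@njit(cache=False)
def _dtw_band(x, y, w):  # pragma: no cover - exercised via dtw_align
    # Sakoe–Chiba band in normalized coordinates: cell (i, j) is inside
    # iff |i/(n-1) - j/(m-1)| <= w, an exactly transpose-symmetric region
    # (so the minimal cost is invariant under argument swap).
    n, m = x.size, y.size
    INF = 1e300
    D = np.full((n + 1, m + 1), INF)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        frac = (i - 1) / (n - 1) if n > 1 else 0.0
        if m > 1:
            j0 = max(1, int(np.ceil((frac - w) * (m - 1))) + 1)
            j1 = min(m, int(np.floor((frac + w) * (m - 1))) + 1)
        else:
            j0, j1 = 1, m
        for j in range(j0, j1 + 1):
            d = x[i - 1] - y[j - 1]
            c = d * d
            best = D[i - 1, j - 1]  # tie-break: prefer (1,1)
            if D[i - 1, j] < best:
                best = D[i - 1, j]  # then (1,0)
            if D[i, j - 1] < best:
                best = D[i, j - 1]  # then (0,1)
            D[i, j] = c + best
    # backtrack
    path = np.empty((n + m, 2), dtype=np.int64)
    k = 0
    i, j = n, m
    while i > 1 or j > 1:
        path[k, 0] = i - 1
        path[k, 1] = j - 1
        k += 1
        if i > 1 and j > 1:
            best = D[i - 1, j - 1]
            bi, bj = i - 1, j - 1
            if D[i - 1, j] < best:
                best = D[i - 1, j]
                bi, bj = i - 1, j
            if D[i, j - 1] < best:
                bi, bj = i, j - 1
            i, j = bi, bj
        elif i > 1:
            i -= 1
        else:
            j -= 1
    path[k, 0] = 0
    path[k, 1] = 0
    k += 1
    return D[n, m], path[:k][::-1]


def dtw_align(a: AudioSignal, b: AudioSignal, band_fraction: float = 0.10):
    """Align two audio tracks (any rates; both are brought to 12 kHz),
    returning the minimal-cost warp path over their log-energy timelines.

    The Sakoe–Chiba band is ``band_fraction`` of the longer feature
    length, widened if needed to keep the endpoints reachable.
    """
    fa = log_energy_features(resample_audio(a, COMMON_RATE))
    fb = log_energy_features(resample_audio(b, COMMON_RATE))
    w = max(band_fraction, 2.0 / max(min(fa.size, fb.size) - 1, 1))
    cost, pairs = _dtw_band(fa.astype(np.float64), fb.astype(np.float64), w)
    path = WarpPath(pairs=pairs, frame_hop=DTW_HOP)
    path.cost = float(cost)  # stashed for diagnostics/tests
    return path


def path_time_map(path: WarpPath):
    """Collapse a warp path into a single-valued monotone time map.

    Returns (t_a, t_b): for each feature index i on the first timeline the
    median matched index j on the second, in seconds, with monotonicity
    enforced by a running maximum.
    """
    pairs = path.pairs
    i_vals = np.unique(pairs[:, 0])
    t_a = i_vals * path.frame_hop
    j_med = np.array(
        [np.median(pairs[pairs[:, 0] == i, 1]) for i in i_vals], dtype=np.float64
    )
    j_med = np.maximum.accumulate(j_med)
    t_b = j_med * path.frame_hop
    return t_a, t_b


def warp_curve(
    v: VelumCurve,
    path: WarpPath,
    emg_rate: float = 600.0,
) -> VelumCurve:
    """Map a velum curve from the MRI clock onto the EMG sample clock.

    The path's first timeline is taken to be the MRI-side audio, the
    second the EMG-side audio.  The collapsed time map m: t_mri → t_emg is
    inverted by linear interpolation and composed with the curve, which is
    then sampled at ``emg_rate`` over the EMG-side audio span.  Linear
    interpolation keeps values inside the original range.
    """
    if len(path.pairs) == 0:
        raise ValueError("empty warp path")
    t_mri, t_emg = path_time_map(path)
    dur_emg = t_emg[-1] + path.frame_hop
    n = int(round(dur_emg * emg_rate))
    tau = np.arange(n) / emg_rate
    # invert m: for each EMG time, the MRI time it came from
    t_mri_of_tau = np.interp(tau, t_emg, t_mri)
    values = np.interp(t_mri_of_tau, v.times, v.values)
    return VelumCurve(values=values, rate=emg_rate)
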