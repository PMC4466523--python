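"""Nasal / non-nasal zone segmentation of the warped velum curve.

A normalized velum curve x(n) is thresholded at τ = x̄ + σ/2: samples at or
above τ are candidate nasal material.  Because the velum's lowering and
raising transitions also belong to the nasal gesture, each candidate run
is widened by a geometric construction: from the run's peak, the angle θ₁
to the adjacent x = x̄ crossing is mirrored (θ₂ = θ₁) in a congruent right
triangle dropped from the crossing level to zero, whose horizontal
cathetus

    v₂ = x̄ · |t_c − t_p| / (y_p − x̄)

pushes the boundary outward to t_c ± v₂.  Runs in which the velum stays
open for long use different peaks for the initial and end boundary (the
first and last local maximum of the run).
"""

from __future__ import annotations

import numpy as np

from .datatypes import BoundaryGeometry, VelumCurve, Zone, ZoneLabels

__all__ = [
    "compute_threshold",
    "extend_boundary",
    "detect_zones",
    "label_frames",
    "renormalize",
]


def compute_threshold(v: VelumCurve):
    """Return (x̄, τ) with τ = x̄ + σ/2; degenerate curves carry no
    detectable nasality."""
    if v.degenerate or v.sd == 0:
        raise ValueError("no nasality detectable in a degenerate (constant) curve")
    return v.mean, v.mean + v.sd / 2.0


def extend_boundary(peak, crossing, direction: str) -> float:
    """Extend a zone boundary outward from an x = x̄ crossing.

    Parameters
    ----------
    peak : (t_p, y_p) nearest local maximum of the run.
    crossing : (t_c, x̄) adjacent mean-level crossing.
    direction : "rising" (crossing precedes the peak; boundary moves
        earlier) or "falling" (crossing follows the peak; boundary moves
        later).

    Returns the boundary time t_b = t_c ± v₂ with
    v₂ = x̄·|t_c − t_p|/(y_p − x̄).
    """
    t_p, y_p = peak
    t_c, mean = crossing
    if direction not in ("rising", "falling"):
        raise ValueError("direction must be 'rising' or 'falling'")
    if y_p <= mean:
        raise ValueError("peak level must exceed the mean (no valid triangle)")
    if mean < 0:
        raise ValueError("mean level must be non-negative")
    if direction == "falling" and t_c < t_p:
        raise ValueError("falling crossing must not precede the peak")
    if direction == "rising" and t_c > t_p:
        raise ValueError("rising crossing must not follow the peak")
    v2 = mean * abs(t_c - t_p) / (y_p - mean)
    return t_c + v2 if direction == "falling" else t_c - v2


def _boundary_geometry(peak, crossing, direction: str, t_b: float) -> BoundaryGeometry:
    t_p, y_p = peak
    t_c, mean = crossing
    theta = float(np.arctan2(abs(t_c - t_p), y_p - mean))
    return BoundaryGeometry(
        peak_time=t_p,
        peak_level=y_p,
        crossing_time=t_c,
        crossing_level=mean,
        theta1=theta,
        theta2=theta,
        v2=abs(t_b - t_c),
        boundary_time=t_b,
    )


def _local_maxima(x: np.ndarray, prominence: float = 0.0) -> np.ndarray:
    """Indices of local maxima with at least the given prominence;
    plateaus contribute their midpoint.  The prominence floor keeps noise
    ripples from masquerading as velum peaks."""
    import scipy.signal

    if x.size < 3:
        return np.asarray([], dtype=np.int64)
    peaks, props = scipy.signal.find_peaks(
        x, prominence=prominence if prominence > 0 else None, plateau_size=0
    )
    if peaks.size and "left_edges" in props:
        peaks = (props["left_edges"] + props["right_edges"]) // 2
    return peaks.astype(np.int64)


def _crossing_time(x, times, mean, idx, side: str) -> float:
    """Sub-sample time where x crosses the mean level adjacent to a run.

    ``side`` = "left": search backwards from ``idx`` for the last upward
    crossing of the mean; "right": forwards for the next downward one.
    Falls back to the curve edge when the signal never returns below the
    mean."""
    n = x.size
    if side == "left":
        i = idx
        while i > 0 and x[i - 1] >= mean:
            i -= 1
        if i == 0:
            return times[0]
        # x[i-1] < mean <= x[i]
        f = (mean - x[i - 1]) / (x[i] - x[i - 1])
        return times[i - 1] + f * (times[i] - times[i - 1])
    i = idx
    while i < n - 1 and x[i + 1] >= mean:
        i += 1
    if i == n - 1:
        return times[-1]
    f = (x[i] - mean) / (x[i] - x[i + 1])
    return times[i] + f * (times[i + 1] - times[i])


def renormalize(v: VelumCurve) -> VelumCurve:
    """Min–max renormalize (used after warping, before thresholding)."""
    lo, hi = v.values.min(), v.values.max()
    if hi == lo:
        return VelumCurve(
            values=np.zeros_like(v.values), rate=v.rate, mean=0.0, sd=0.0, degenerate=True
        )
    return VelumCurve(values=(v.values - lo) / (hi - lo), rate=v.rate)


def detect_zones(v: VelumCurve, renorm: bool = True) -> ZoneLabels:
    """Segment a velum curve into nasal and non-nasal zones.

    Pipeline: threshold at τ = x̄ + σ/2 → per run, pick the first / last
    local maximum for the rising / falling geometry → find the adjacent
    x = x̄ crossings → extend both boundaries outward via the mirrored-angle
    rule → merge overlapping extended runs → everything else is non-nasal.
    Zone boundaries are half-open on the curve clock; the square wave is 1
    exactly on nasal zones.
    """
    if renorm:
        v = renormalize(v)
    if v.degenerate:
        raise ValueError("no nasality detectable in a degenerate curve")
    mean, tau = compute_threshold(v)
    x, times = v.values, v.times
    span_end = v.duration
    above = x >= tau
    if not above.any():
        raise ValueError("no samples reach the nasal threshold")
    # candidate runs [i0, i1] inclusive
    d = np.diff(above.astype(np.int8))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0])
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(x.size - 1)

    # Group candidate runs by their enclosing x = x̄ excursion: noise can
    # split one nasal event into several τ-runs, but they share the same
    # adjacent mean crossings and must use common peak geometry.
    grouped = []
    for i0, i1 in zip(starts, ends):
        t_l = _crossing_time(x, times, mean, i0, "left")
        t_r = _crossing_time(x, times, mean, i1, "right")
        if grouped and t_l <= grouped[-1][3] + 1e-12:
            grouped[-1][1] = i1
            grouped[-1][3] = t_r
        else:
            grouped.append([i0, i1, t_l, t_r])

    proto = []  # (t_start, t_end, geometry pair)
    for i0, i1, t_c_left, t_c_right in grouped:
        run = x[i0 : i1 + 1]
        maxima = _local_maxima(run, prominence=v.sd / 2.0) + i0
        if maxima.size == 0:
            maxima = np.asarray([i0 + int(np.argmax(run))])
        p_first, p_last = maxima[0], maxima[-1]
        geo_l = geo_r = None
        peak_l = (times[p_first], x[p_first])
        peak_r = (times[p_last], x[p_last])
        if mean > 0 and x[p_first] > mean:
            t_start = extend_boundary(peak_l, (t_c_left, mean), "rising")
            geo_l = _boundary_geometry(peak_l, (t_c_left, mean), "rising", t_start)
        else:
            t_start = t_c_left
        if mean > 0 and x[p_last] > mean:
            t_end = extend_boundary(peak_r, (t_c_right, mean), "falling")
            geo_r = _boundary_geometry(peak_r, (t_c_right, mean), "falling", t_end)
        else:
            t_end = t_c_right
        t_start = max(0.0, min(t_start, times[i0]))
        t_end = min(span_end, max(t_end, times[i1]))
        proto.append([t_start, t_end, (geo_l, geo_r)])

    # merge overlapping extended runs
    merged = [proto[0]]
    for t0, t1, geo in proto[1:]:
        if t0 <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], t1)
            merged[-1][2] = (merged[-1][2][0], geo[1])
        else:
            merged.append([t0, t1, geo])

    zones = []
    cursor = 0.0
    for t0, t1, geo in merged:
        if t0 > cursor:
            zones.append(Zone(start=cursor, end=t0, label="non-nasal"))
        zones.append(Zone(start=t0, end=t1, label="nasal", geometry=geo))
        cursor = t1
    if cursor < span_end:
        zones.append(Zone(start=cursor, end=span_end, label="non-nasal"))

    square = np.zeros(x.size, dtype=np.int8)
    for z in zones:
        if z.label == "nasal":
            square[(times >= z.start) & (times < z.end)] = 1
    return ZoneLabels(zones=zones, square_wave=square, rate=v.rate, span=(0.0, span_end))


def label_frames(z: ZoneLabels, frame_times) -> list:
    """Label each (start, end) frame by the class of the zone containing
    its temporal midpoint."""
    labels = []
    for start, end in frame_times:
        labels.append(z.label_at((start + end) / 2.0))
    return labels
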