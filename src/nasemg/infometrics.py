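"""Dependence measures between the velum curve and the EMG signal.

Plug-in mutual information over an equal-width joint histogram,

    I(X;Y) = Σ_y Σ_x p(x,y) · log₂( p(x,y) / (p(x)·p(y)) )   [bits],

with empty cells contributing zero, plus a normalized variant
I/√(H(X)·H(Y)) and Pearson's r — overall and within nasal / non-nasal
zones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import VelumCurve, ZoneLabels

__all__ = ["MIEstimate", "mutual_information", "zone_dependence"]


@dataclass
class MIEstimate:
    I: float  # bits
    normalized: float  # in [0, 1]
    h_x: float
    h_y: float
    bins: int
    n: int
    zone_class: str = "all"
    degenerate: bool = False


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mutual_information(
    x, y, bins: int = 16, normalization: str = "sqrt", zone_class: str = "all"
) -> MIEstimate:
    """Histogram plug-in MI estimate in bits.

    ``normalization``: 'sqrt' → I/√(HxHy) (default), 'min' → I/min(Hx,Hy),
    'mean' → 2I/(Hx+Hy).  A constant input has zero entropy; normalized MI
    is then defined as 0 and the estimate is flagged degenerate.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if bins < 2:
        raise ValueError("need at least 2 bins")
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    p_xy = joint / joint.sum()
    p_x = p_xy.sum(axis=1)
    p_y = p_xy.sum(axis=0)
    nz = p_xy > 0
    outer = np.outer(p_x, p_y)
    I = float((p_xy[nz] * np.log2(p_xy[nz] / outer[nz])).sum())
    I = max(I, 0.0)
    h_x, h_y = _entropy_bits(p_x), _entropy_bits(p_y)
    degenerate = h_x == 0.0 or h_y == 0.0
    if degenerate:
        norm = 0.0
    elif normalization == "sqrt":
        norm = I / np.sqrt(h_x * h_y)
    elif normalization == "min":
        norm = I / min(h_x, h_y)
    elif normalization == "mean":
        norm = 2.0 * I / (h_x + h_y)
    else:
        raise ValueError("normalization must be 'sqrt', 'min' or 'mean'")
    return MIEstimate(
        I=I,
        normalized=float(min(norm, 1.0)),
        h_x=h_x,
        h_y=h_y,
        bins=bins,
        n=x.size,
        zone_class=zone_class,
        degenerate=degenerate,
    )


def zone_dependence(
    velum: VelumCurve,
    emg_channel,
    zones: ZoneLabels,
    bins: int = 16,
    normalization: str = "sqrt",
) -> dict:
    """MI, normalized MI and Pearson r between the velum curve and one EMG
    channel, per zone class and overall.

    Both signals must share the clock (the warped curve lives on the EMG
    sample clock).  Samples are concatenated by the class of the zone they
    fall in; empty classes are skipped with a warning.
    """
    emg = np.asarray(emg_channel, dtype=np.float64)
    n = min(velum.values.size, emg.size, zones.square_wave.size)
    v, e, sw = velum.values[:n], emg[:n], zones.square_wave[:n]
    out = {}
    for cls, mask in (
        ("all", np.ones(n, dtype=bool)),
        ("nasal", sw == 1),
        ("non-nasal", sw == 0),
    ):
        if not mask.any():
            warnings.warn(f"no samples in class '{cls}'; skipped", stacklevel=2)
            continue
        mi = mutual_information(
            v[mask], e[mask], bins=bins, normalization=normalization, zone_class=cls
        )
        if np.std(v[mask]) == 0 or np.std(e[mask]) == 0:
            r = 0.0
        else:
            r = float(stats.pearsonr(v[mask], e[mask]).statistic)
        out[cls] = {"mi": mi, "pearson_r": r}
    return out
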