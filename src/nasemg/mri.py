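"""Velum-movement extraction from RT-MRI image sequences.

Sagittal sequences: the airway between the lowered velum and the
pharyngeal wall appears hypo-intense (dark).  A region-growing pass seeded
at one dark pixel inside a fixed ROI, with a neighborhood that includes
the time axis, yields a per-frame airway area: area minima correspond to a
closed velopharyngeal port (oral sound), maxima to an open port (nasal).

Coronal-oblique sequences: the nasal-cavity compartment is segmented from
a few seeds; its per-frame area is zero when the port is closed.

Region growing over a thresholded intensity mask restricted to the ROI is
exactly the seed's connected component under the chosen connectivity, so
it is implemented with ``scipy.ndimage.label``.
"""

from __future__ import annotations

import numpy as np
import scipy.ndimage

from .datatypes import AreaCurve, ImageSequence, VelumCurve

__all__ = [
    "segment_sagittal",
    "segment_coronal",
    "area_to_velum_curve",
]

# face-adjacent in (t, y, x): 6-connectivity
_STRUCTURE_6 = scipy.ndimage.generate_binary_structure(3, 1)


def _grow(mask: np.ndarray, seeds) -> np.ndarray:
    """Union of the 6-connected components of ``mask`` containing the seeds."""
    labels, _ = scipy.ndimage.label(mask, structure=_STRUCTURE_6)
    wanted = {labels[s] for s in seeds}
    wanted.discard(0)
    if not wanted:
        return np.zeros_like(mask)
    return np.isin(labels, sorted(wanted))


def _per_frame_counts(region: np.ndarray) -> np.ndarray:
    return region.reshape(region.shape[0], -1).sum(axis=1).astype(np.int64)


def segment_sagittal(
    seq: ImageSequence,
    roi: np.ndarray,
    seed_pixel: tuple,
    intensity_threshold: float = 0.5,
) -> AreaCurve:
    """Grow a connected hypo-intense region from one seed, restricted to
    the ROI, with a (t, y, x) 6-connected neighborhood; return per-frame
    pixel counts.

    Thanks to the temporal connectivity a single seed propagates across
    all frames in which the airway region persists.

    Parameters
    ----------
    roi : (H, W) boolean mask limiting the growth (not the region itself).
    seed_pixel : (frame, row, col), 0-based.
    intensity_threshold : pixels with intensity strictly below this count
        as hypo-intense.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != seq.frames.shape[1:]:
        raise ValueError("ROI shape must match the image frames")
    if not roi.any():
        raise ValueError("ROI is empty")
    t, r, c = seed_pixel
    if not (0 <= t < seq.n_frames) or not roi[r, c]:
        raise ValueError("seed pixel must lie inside the ROI and the stack")
    if seq.frames[t, r, c] >= intensity_threshold:
        raise ValueError(
            f"seed pixel intensity {seq.frames[t, r, c]:.3f} is not hypo-intense "
            f"(threshold {intensity_threshold})"
        )
    mask = (seq.frames < intensity_threshold) & roi[None, :, :]
    region = _grow(mask, [(t, r, c)])
    return AreaCurve(areas=_per_frame_counts(region), fps=seq.fps)


def segment_coronal(
    seq: ImageSequence,
    seeds,
    intensity_threshold: float = 0.5,
    polarity: str = "dark",
) -> AreaCurve:
    """Segment the seeded cavity compartment and return its per-frame area.

    ``polarity`` selects the intensity criterion: ``"dark"`` grows over
    pixels below the threshold (airway in the toy images), ``"bright"``
    over pixels at or above it (cavities rendered bright, as in the
    figures of coronal acquisitions).  Seeding is idempotent: extra seeds
    inside an already-captured compartment change nothing.
    """
    if not seeds:
        raise ValueError("need at least one seed")
    if polarity not in ("dark", "bright"):
        raise ValueError("polarity must be 'dark' or 'bright'")
    if polarity == "dark":
        mask = seq.frames < intensity_threshold
    else:
        mask = seq.frames >= intensity_threshold
    valid = []
    for t, r, c in seeds:
        if not (0 <= t < seq.n_frames):
            raise ValueError("seed frame index out of range")
        if mask[t, r, c]:
            valid.append((t, r, c))
    if not valid:
        raise ValueError("no seed matches the requested intensity polarity")
    region = _grow(mask, valid)
    return AreaCurve(areas=_per_frame_counts(region), fps=seq.fps)


def area_to_velum_curve(areas: AreaCurve) -> VelumCurve:
    """Min–max normalize an area curve to [0, 1] and attach its mean and
    population SD (the statistics the nasal threshold is built from).

    A constant input carries no movement information; it maps to an
    all-zero curve flagged ``degenerate``.
    """
    a = areas.areas.astype(np.float64)
    lo, hi = a.min(), a.max()
    if hi == lo:
        return VelumCurve(
            values=np.zeros_like(a), rate=areas.fps, mean=0.0, sd=0.0, degenerate=True
        )
    return VelumCurve(values=(a - lo) / (hi - lo), rate=areas.fps)
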