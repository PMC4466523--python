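"""First-order temporal features per EMG frame.

The 9-component vector per frame (in this fixed order): mean, absolute
mean, standard deviation, maximum, minimum, kurtosis, energy,
zero-crossing rate, mean absolute slope.  Conventions chosen for
determinism: population SD; excess (Fisher) kurtosis with the population
estimator, 0 for constant frames; energy as the mean of squares
(length-invariant); ZCR counts sign changes between consecutive samples
with zeros inheriting the previous sign, divided by L−1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import EMGRecording, FrameIndex

__all__ = ["FEATURE_NAMES", "extract_features", "feature_table"]

FEATURE_NAMES = (
    "mean",
    "abs_mean",
    "std",
    "max",
    "min",
    "kurtosis",
    "energy",
    "zcr",
    "mean_abs_slope",
)


def _signs_inherit(x: np.ndarray) -> np.ndarray:
    """Sign of each sample with zeros inheriting the previous sign
    (leading zeros count as positive)."""
    s = np.sign(x)
    prev = 1.0
    out = np.empty_like(s)
    for i, v in enumerate(s):
        if v == 0:
            out[i] = prev
        else:
            out[i] = v
            prev = v
    return out


def extract_features(frame: np.ndarray) -> np.ndarray:
    """9-feature vector for one frame of samples (length >= 2)."""
    x = np.asarray(frame, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("frame must be 1-D with at least 2 samples")
    L = x.size
    mean = x.mean()
    abs_mean = np.abs(x).mean()
    std = x.std()  # population
    if std == 0.0:
        kurt = 0.0
    else:
        kurt = np.mean((x - mean) ** 4) / std**4 - 3.0
    energy = np.mean(x**2)
    signs = _signs_inherit(x)
    zcr = np.count_nonzero(signs[1:] != signs[:-1]) / (L - 1)
    mas = np.abs(np.diff(x)).mean()
    return np.array([mean, abs_mean, std, x.max(), x.min(), kurt, energy, zcr, mas])


def feature_table(
    rec: EMGRecording,
    index: FrameIndex,
    labels=None,
    channels=None,
) -> pd.DataFrame:
    """Per-frame feature table over the requested channels.

    Columns: ``channel``, ``frame_start_s``, the 9 feature names, and
    ``label`` ('nasal' / 'non-nasal' / 'unlabeled').
    """
    if channels is None:
        channels = list(range(rec.n_channels))
    if labels is None:
        labels = ["unlabeled"] * index.n_frames
    if len(labels) != index.n_frames:
        raise ValueError("labels length must match frame count")
    rows = []
    for c in channels:
        sig = rec.channels[c]
        for k, (i0, i1) in enumerate(index.frames):
            vec = extract_features(sig[i0:i1])
            rows.append(
                (rec.channel_meta[c]["id"], i0 / rec.rate, *vec, labels[k])
            )
    return pd.DataFrame(
        rows, columns=["channel", "frame_start_s", *FEATURE_NAMES, "label"]
    )
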