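"""Frame-level nasality classification and zone-majority voting.

Frames are classified nasal / non-nasal with an RBF-kernel SVM under
stratified 10-fold cross-validation (features standardized on each
training fold).  Reported per fold: error rate, sensitivity and
specificity (nasal = positive class), with Student-t 95% confidence
intervals over folds.  Zone-level classification takes the majority of
predicted frame classes inside each zone (ties go to nasal), optionally
restricted to a [a%, b%] part of the zone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .datatypes import ZoneLabels
from .features import FEATURE_NAMES

__all__ = [
    "CVResult",
    "crossvalidate",
    "combine_channels",
    "zone_majority",
    "class_distribution",
    "percent",
    "metric_summary",
]

POSITIVE = "nasal"
NEGATIVE = "non-nasal"


def percent(count: float, total: float) -> float:
    """Percentage to one decimal, half-up rounding; 0.0 for empty totals."""
    if total == 0:
        warnings.warn("empty group; reporting 0.0%", stacklevel=2)
        return 0.0
    return float(
        Decimal(100.0 * count / total).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


@dataclass
class CVResult:
    """Cross-validation outcome for one grouping key."""

    fold_error: np.ndarray  # %
    fold_sensitivity: np.ndarray  # %
    fold_specificity: np.ndarray  # %
    confusion: dict  # TP, FP, TN, FN totals over held-out folds
    predictions: np.ndarray  # out-of-fold predicted labels, frame order
    group: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.fold_error.size

    def _ci(self, values: np.ndarray) -> float:
        if self.k < 2:
            return 0.0
        t = stats.t.ppf(0.975, self.k - 1)
        return float(t * values.std(ddof=1) / np.sqrt(self.k))

    @property
    def mean_error(self) -> float:
        return float(self.fold_error.mean())

    @property
    def mean_sensitivity(self) -> float:
        return float(self.fold_sensitivity.mean())

    @property
    def mean_specificity(self) -> float:
        return float(self.fold_specificity.mean())

    @property
    def error_ci(self) -> float:
        return self._ci(self.fold_error)

    @property
    def sensitivity_ci(self) -> float:
        return self._ci(self.fold_sensitivity)

    @property
    def specificity_ci(self) -> float:
        return self._ci(self.fold_specificity)


def _fold_metrics(y_true, y_pred):
    tp = np.sum((y_true == POSITIVE) & (y_pred == POSITIVE))
    tn = np.sum((y_true == NEGATIVE) & (y_pred == NEGATIVE))
    fp = np.sum((y_true == NEGATIVE) & (y_pred == POSITIVE))
    fn = np.sum((y_true == POSITIVE) & (y_pred == NEGATIVE))
    err = 100.0 * (fp + fn) / max(1, tp + tn + fp + fn)
    sens = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    spec = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    return err, sens, spec, dict(TP=int(tp), FP=int(fp), TN=int(tn), FN=int(fn))


def crossvalidate(
    X,
    y,
    k: int = 10,
    seed: int = 0,
    C: float = 1.0,
    gamma="scale",
    group: dict | None = None,
) -> CVResult:
    """Stratified k-fold CV of an RBF-SVM over frame features.

    Features are standardized on each training fold; gamma='scale' is
    1/(d·var).  Both classes must be present and n >= k.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=object)
    classes = set(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if not classes <= {POSITIVE, NEGATIVE}:
        raise ValueError(f"labels must be '{POSITIVE}' / '{NEGATIVE}'")
    if k > len(y):
        raise ValueError("more folds than frames")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    errs, sens, specs = [], [], []
    totals = dict(TP=0, FP=0, TN=0, FN=0)
    preds = np.empty(len(y), dtype=object)
    for train, test in skf.split(X, y):
        clf = make_pipeline(StandardScaler(), SVC(C=C, gamma=gamma, kernel="rbf"))
        clf.fit(X[train], y[train])
        p = clf.predict(X[test])
        preds[test] = p
        e, s, sp, conf = _fold_metrics(y[test], p)
        errs.append(e)
        sens.append(s)
        specs.append(sp)
        for key in totals:
            totals[key] += conf[key]
    return CVResult(
        fold_error=np.asarray(errs),
        fold_sensitivity=np.asarray(sens),
        fold_specificity=np.asarray(specs),
        confusion=totals,
        predictions=preds,
        group=group or {},
    )


def combine_channels(tables: list) -> pd.DataFrame:
    """Concatenate per-channel feature tables over a common frame grid.

    Output columns: ``frame_start_s``, then for each channel in ascending
    id order its 9 features suffixed ``_c<id>``, then ``label``.
    """
    if not tables:
        raise ValueError("need at least one channel table")
    tables = sorted(tables, key=lambda t: int(t["channel"].iloc[0]))
    base = tables[0]
    out = pd.DataFrame({"frame_start_s": base["frame_start_s"].to_numpy()})
    for t in tables:
        if len(t) != len(base):
            raise ValueError("mismatched frame counts across channels")
        if not np.allclose(t["frame_start_s"].to_numpy(), out["frame_start_s"].to_numpy()):
            raise ValueError("channel tables must share the frame grid")
        cid = int(t["channel"].iloc[0])
        for f in FEATURE_NAMES:
            out[f"{f}_c{cid}"] = t[f].to_numpy()
    out["label"] = base["label"].to_numpy()
    return out


def zone_majority(
    frame_predictions,
    frame_midpoints,
    zones: ZoneLabels,
    part=(0.0, 100.0),
):
    """Majority-vote zone classification.

    Each zone is restricted to its [a%, b%] sub-interval by time; the
    predicted classes of the frames whose midpoints fall inside are
    collected and the zone is predicted nasal iff nasal frames are at
    least as numerous as non-nasal frames.  Zones left without any frame
    midpoint are skipped with a warning.

    Returns (per-zone records, error percentage over scored zones).
    """
    a, b = part
    if not (0.0 <= a < b <= 100.0):
        raise ValueError("part must satisfy 0 <= a < b <= 100")
    preds = np.asarray(frame_predictions, dtype=object)
    mids = np.asarray(frame_midpoints, dtype=np.float64)
    records = []
    wrong = scored = 0
    for z in zones.zones:
        lo = z.start + (a / 100.0) * z.duration
        hi = z.start + (b / 100.0) * z.duration
        inside = (mids >= lo) & (mids < hi)
        if not inside.any():
            warnings.warn(
                f"zone [{z.start:.3f}, {z.end:.3f}) has no frames in part "
                f"[{a}%, {b}%]; skipped",
                stacklevel=2,
            )
            continue
        n_nasal = int(np.sum(preds[inside] == POSITIVE))
        n_non = int(np.sum(preds[inside] == NEGATIVE))
        pred = POSITIVE if n_nasal >= n_non else NEGATIVE
        records.append(
            dict(start=z.start, end=z.end, truth=z.label, predicted=pred,
                 n_nasal=n_nasal, n_non_nasal=n_non)
        )
        scored += 1
        if pred != z.label:
            wrong += 1
    error = 100.0 * wrong / scored if scored else 0.0
    return records, error


def class_distribution(groups: dict) -> pd.DataFrame:
    """Class-distribution table from nasal / non-nasal counts per group.

    ``groups`` maps a group name to (nasal_count, non_nasal_count); the
    table reports totals, the share of each group in the grand total, and
    the within-group class percentages (one decimal, half-up), in the
    style used for corpus summaries.
    """
    rows = []
    grand = sum(n + m for n, m in groups.values())
    for name, (n_nasal, n_non) in groups.items():
        total = n_nasal + n_non
        rows.append(
            dict(
                group=name,
                total=total,
                total_pct=percent(total, grand),
                nasal=n_nasal,
                nasal_pct=percent(n_nasal, total),
                non_nasal=n_non,
                non_nasal_pct=percent(n_non, total),
            )
        )
    return pd.DataFrame(rows)


def metric_summary(results: list) -> pd.DataFrame:
    """Tabulate CVResults (one row per grouping key) with means, 95% CI
    half-widths, and the difference of each row's mean error from the
    cross-row mean error."""
    rows = []
    for r in results:
        rows.append(
            {
                **r.group,
                "mean_error": r.mean_error,
                "error_ci": r.error_ci,
                "mean_sensitivity": r.mean_sensitivity,
                "sensitivity_ci": r.sensitivity_ci,
                "mean_specificity": r.mean_specificity,
                "specificity_ci": r.specificity_ci,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["error_vs_mean"] = df["mean_error"] - df["mean_error"].mean()
    return df
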