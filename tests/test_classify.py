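"""SVM cross-validation, channel combination, zone-majority voting and
report arithmetic."""

import numpy as np
import pytest

from nasemg.classify import (
    class_distribution,
    combine_channels,
    crossvalidate,
    percent,
    zone_majority,
)
from nasemg.datatypes import VelumCurve
from nasemg.features import FEATURE_NAMES, feature_table
from nasemg.synthetic import Event, make_velum_curve
from nasemg.zoning import detect_zones


def _blobs(n=500, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 9))
    y = np.array(["nasal"] * (n // 2) + ["non-nasal"] * (n - n // 2))
    X[: n // 2, 0] += sep
    return X, y


class TestCrossvalidate:
    def test_separable_blobs_near_zero_error(self):
        X, y = _blobs()
        res = crossvalidate(X, y, k=10, seed=0)
        assert res.mean_error <= 2.0

    def test_permuted_labels_at_chance(self):
        """Random labels on balanced classes give ~50% error."""
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((1000, 9))
            y = np.array(["nasal", "non-nasal"] * 500)
            rng.shuffle(y)
            errs.append(crossvalidate(X, y, k=10, seed=seed).mean_error)
        assert abs(np.mean(errs) - 50.0) <= 5.0

    def test_single_class_rejected(self):
        X = np.zeros((20, 9))
        with pytest.raises(ValueError):
            crossvalidate(X, np.array(["nasal"] * 20), k=5)

    def test_more_folds_than_frames_rejected(self):
        X, y = _blobs(n=8)
        with pytest.raises(ValueError):
            crossvalidate(X, y, k=10)

    def test_fold_partition_stratified(self):
        from sklearn.model_selection import StratifiedKFold

        X, y = _blobs(n=203)
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=3)
        seen = np.zeros(203, dtype=int)
        sizes = []
        for _, test in skf.split(X, y):
            seen[test] += 1
            sizes.append(len(test))
            frac = np.mean(y[test] == "nasal")
            # within one frame of the stratified ideal
            assert abs(frac * len(test) - np.mean(y == "nasal") * len(test)) <= 1.0
        assert np.all(seen == 1)
        assert max(sizes) - min(sizes) <= 1

    def test_metrics_consistent_with_confusion(self):
        X, y = _blobs(n=300, sep=1.0, seed=2)
        res = crossvalidate(X, y, k=10, seed=2)
        c = res.confusion
        total = sum(c.values())
        err = 100.0 * (c["FP"] + c["FN"]) / total
        # fold means weight folds equally; totals agree to within a frame's worth
        assert err == pytest.approx(res.mean_error, abs=1.0)
        assert 0 <= res.mean_sensitivity <= 100
        assert 0 <= res.mean_specificity <= 100


class TestCombineChannels:
    def _tables(self, channel_ids, n=20, seed=0):
        from nasemg.datatypes import EMGRecording
        from nasemg.emg import frame_signal

        rng = np.random.default_rng(seed)
        rec = EMGRecording(
            channels=rng.standard_normal((len(channel_ids), 600)),
            channel_meta=[{"id": c, "configuration": "bipolar"} for c in channel_ids],
        )
        idx = frame_signal(600, 600.0)
        return [
            feature_table(rec, idx, channels=[k]) for k in range(len(channel_ids))
        ]

    def test_singleton_identity(self):
        t3 = self._tables([3])
        out = combine_channels(t3)
        np.testing.assert_allclose(
            out[[f"{f}_c3" for f in FEATURE_NAMES]].to_numpy(),
            t3[0][list(FEATURE_NAMES)].to_numpy(),
        )

    def test_pair_concatenation_shape(self):
        tabs = self._tables([3, 4])
        out = combine_channels(tabs)
        feat_cols = [c for c in out.columns if c not in ("frame_start_s", "label")]
        assert len(feat_cols) == 18
        assert len(out) == len(tabs[0])

    def test_column_order_ascending_channel_then_feature(self):
        tabs = self._tables([4, 3])  # deliberately unsorted
        out = combine_channels(tabs)
        feat_cols = [c for c in out.columns if c not in ("frame_start_s", "label")]
        expect = [f"{f}_c{c}" for c in (3, 4) for f in FEATURE_NAMES]
        assert feat_cols == expect

    def test_mismatched_counts_rejected(self):
        t3 = self._tables([3])[0]
        t4 = self._tables([4])[0].iloc[:-1]
        with pytest.raises(ValueError):
            combine_channels([t3, t4])


class TestZoneMajority:
    def _zones(self):
        v = make_velum_curve([Event(1.0, "nasal", 0.8)], 100.0, 3.0)
        return detect_zones(v, renorm=False)

    def test_tie_goes_to_nasal(self):
        zones = self._zones()
        nz = zones.nasal_zones()[0]
        mids = np.linspace(nz.start + 0.01, nz.end - 0.01, 6)
        preds = ["nasal"] * 3 + ["non-nasal"] * 3
        records, err = zone_majority(preds, mids, zones)
        rec = [r for r in records if r["truth"] == "nasal"][0]
        assert rec["predicted"] == "nasal"

    def test_all_non_nasal_prediction(self):
        zones = self._zones()
        nz = zones.nasal_zones()[0]
        mids = np.linspace(nz.start + 0.01, nz.end - 0.01, 5)
        records, err = zone_majority(["non-nasal"] * 5, mids, zones)
        rec = [r for r in records if r["truth"] == "nasal"][0]
        assert rec["predicted"] == "non-nasal"

    def test_part_restriction_membership(self):
        """[50%, 100%]: exactly the frames with midpoints in the second
        half are counted, verified by enumeration."""
        zones = self._zones()
        nz = zones.nasal_zones()[0]
        mids = np.linspace(nz.start + 0.005, nz.end - 0.005, 10)
        preds = ["nasal"] * 10
        records, _ = zone_majority(preds, mids, zones, part=(50.0, 100.0))
        rec = [r for r in records if r["truth"] == "nasal"][0]
        half = nz.start + 0.5 * nz.duration
        expect = int(np.sum((mids >= half) & (mids < nz.end)))
        assert rec["n_nasal"] == expect

    def test_perfect_predictions_zero_error(self):
        zones = self._zones()
        mids = np.arange(0.05, 3.0, 0.02)
        truth = [zones.label_at(t) for t in mids]
        for part in ((0.0, 100.0), (0.0, 50.0), (25.0, 75.0), (50.0, 100.0)):
            _, err = zone_majority(truth, mids, zones, part=part)
            assert err == 0.0

    def test_invalid_part_rejected(self):
        zones = self._zones()
        with pytest.raises(ValueError):
            zone_majority([], [], zones, part=(60.0, 40.0))

    def test_empty_zone_skipped_with_warning(self):
        zones = self._zones()
        with pytest.warns(UserWarning, match="skipped"):
            records, _ = zone_majority(["nasal"], [zones.zones[0].start + 0.01],
                                       zones, part=(0.0, 100.0))
        assert len(records) == 1


class TestReport:
    def test_speaker_percentages(self):
        assert percent(357, 357 + 479) == 42.7
        assert percent(479, 357 + 479) == 57.3

    def test_pooled_percentages(self):
        assert percent(801, 801 + 771) == 51.0
        assert percent(771, 801 + 771) == 49.0

    def test_distribution_table(self):
        df = class_distribution(
            {
                "speaker1": (357, 479),
                "speaker2": (195, 88),
                "speaker3": (249, 204),
            }
        )
        assert df.loc[df.group == "speaker1", "total_pct"].item() == 53.2
        assert df.loc[df.group == "speaker2", "nasal_pct"].item() == 68.9
        assert df.loc[df.group == "speaker3", "non_nasal_pct"].item() == 45.0

    def test_empty_group_warns_zero(self):
        with pytest.warns(UserWarning):
            assert percent(0, 0) == 0.0
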