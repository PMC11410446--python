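"""Classification rules and the as-printed evaluation formulas."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from ecgkit.classification import (ConfusionCounts, FuzzyRhythmClassifier,
                                   NearestCentroidRhythmClassifier,
                                   QRSIntervalClassifier, RecordFeatures,
                                   classify_qrs_interval, confusion_counts,
                                   features_matrix, metrics)


def _features(qrs=0.099, hr=72.0, sdnn=30.0, rmssd=25.0, beats=100):
    return RecordFeatures(qrs, hr, sdnn, rmssd, beats)


def _training_set(rng, n_per_class=20):
    """Synthetic feature vectors with separated class distributions."""
    reg = np.column_stack([
        rng.normal(0.099, 0.005, n_per_class),
        rng.normal(72, 4, n_per_class),
        rng.normal(25, 5, n_per_class),
        rng.normal(20, 5, n_per_class),
        rng.integers(90, 110, n_per_class),
    ])
    irr = np.column_stack([
        rng.normal(0.150, 0.02, n_per_class),
        rng.normal(85, 10, n_per_class),
        rng.normal(110, 20, n_per_class),
        rng.normal(130, 25, n_per_class),
        rng.integers(70, 130, n_per_class),
    ])
    X = np.vstack([reg, irr])
    y = np.array(["regular"] * n_per_class + ["irregular"] * n_per_class,
                 dtype=object)
    return X, y


class TestQrsIntervalRule:
    def test_standard_width_is_regular(self):
        assert classify_qrs_interval(_features(qrs=0.099)) == "regular"

    def test_wide_qrs_is_irregular(self):
        assert classify_qrs_interval(_features(qrs=0.150), tolerance=0.02) == \
            "irregular"

    def test_boundary_is_regular(self):
        # closed interval: exactly standard + tolerance still counts regular
        assert classify_qrs_interval(_features(qrs=0.119), tolerance=0.02) == \
            "regular"
        assert classify_qrs_interval(_features(qrs=0.1191), tolerance=0.02) == \
            "irregular"

    def test_non_finite_feature_rejected(self):
        with pytest.raises(ValueError):
            _features(qrs=float("nan"))

    def test_sklearn_protocol(self):
        clf = QRSIntervalClassifier(tolerance=0.03)
        assert clone(clf).get_params()["tolerance"] == 0.03
        X = features_matrix([_features(), _features(qrs=0.2)])
        preds = clf.fit(X).predict(X)
        assert list(preds) == ["regular", "irregular"]


class TestNearestCentroidRule:
    def test_training_centroid_classified_to_own_class(self):
        rng = np.random.default_rng(0)
        X, y = _training_set(rng)
        clf = NearestCentroidRhythmClassifier().fit(X, y)
        centroid_reg = X[y == "regular"].mean(axis=0)[None, :]
        assert clf.predict(centroid_reg)[0] == "regular"

    def test_equidistant_tie_goes_regular(self):
        rng = np.random.default_rng(1)
        X, y = _training_set(rng)
        clf = NearestCentroidRhythmClassifier().fit(X, y)
        # midpoint of the standardized centroids is exactly equidistant
        mid_z = (clf.centroid_regular_ + clf.centroid_irregular_) / 2
        mid = mid_z * clf.scale_ + clf.mean_
        X_mid = np.concatenate([mid, [100.0]])[None, :]
        assert clf.predict(X_mid)[0] == "regular"

    def test_agrees_with_brute_force_loop(self):
        rng = np.random.default_rng(2)
        X, y = _training_set(rng)
        clf = NearestCentroidRhythmClassifier().fit(X, y)
        probe = np.column_stack([
            rng.uniform(0.08, 0.2, 200), rng.uniform(50, 120, 200),
            rng.uniform(5, 150, 200), rng.uniform(5, 180, 200),
            rng.integers(50, 150, 200),
        ])
        preds = clf.predict(probe)
        Z = (probe[:, :4] - clf.mean_) / clf.scale_
        for i in range(200):
            d_reg = np.sqrt(np.sum((Z[i] - clf.centroid_regular_) ** 2))
            d_irr = np.sqrt(np.sum((Z[i] - clf.centroid_irregular_) ** 2))
            expected = "irregular" if d_irr < d_reg else "regular"
            assert preds[i] == expected

    def test_single_class_training_rejected(self):
        X = np.tile(_features().to_array(), (5, 1))
        with pytest.raises(ValueError, match="both classes"):
            NearestCentroidRhythmClassifier().fit(X, ["regular"] * 5)


class TestFuzzyRule:
    @pytest.fixture()
    def fitted(self):
        rng = np.random.default_rng(3)
        X, y = _training_set(rng)
        return FuzzyRhythmClassifier().fit(X, y), X, y

    def test_regular_prototype_has_full_membership(self, fitted):
        clf, X, y = fitted
        median_beats = float(np.median(X[:, 4]))
        # zero QRS deviation; pick HRV features on the regular centroid so
        # the margin is firmly negative (closer to regular)
        reg_mean = X[y == "regular"].mean(axis=0)
        proto = np.array([[0.099, reg_mean[1], reg_mean[2], reg_mean[3],
                           median_beats]])
        m = clf.predict_memberships(proto)
        assert m[0, 0] == pytest.approx(1.0)
        assert clf.predict(proto)[0] == "regular"

    @settings(deadline=None, max_examples=30)
    @given(st.floats(0.05, 0.3), st.floats(30, 150), st.floats(0, 200),
           st.floats(0, 200), st.integers(10, 300))
    def test_memberships_bounded(self, qrs, hr, sdnn, rmssd_v, beats):
        rng = np.random.default_rng(4)
        X, y = _training_set(rng)
        clf = FuzzyRhythmClassifier().fit(X, y)
        m = clf.predict_memberships(
            np.array([[qrs, hr, sdnn, rmssd_v, float(beats)]]))
        assert np.all(m >= 0) and np.all(m <= 1)

    def test_grid_decisions_match_rule_table_oracle(self, fitted):
        """Independent scalar evaluation of the rule base over a 50x50 grid
        of (QRS deviation, margin) must reproduce the classifier."""
        clf, X, y = fitted
        median_beats = float(np.median(X[:, 4]))

        def tri(x, a, b, c, d):
            if b <= x <= c:
                return 1.0
            if x < b:
                if not np.isfinite(b):
                    return 0.0
                if not np.isfinite(a):
                    return 1.0
                return max((x - a) / (b - a), 0.0)
            if not np.isfinite(c):
                return 0.0
            if not np.isfinite(d):
                return 1.0
            return max((d - x) / (d - c), 0.0)

        def oracle(qrs_dev, margin, beats):
            mu = {
                0: {t: tri(qrs_dev, *getattr(clf.qrs_var_, t))
                    for t in ("low", "medium", "high")},
                1: {t: tri(margin, *getattr(clf.margin_var_, t))
                    for t in ("low", "medium", "high")},
                2: {t: tri(beats, *getattr(clf.beats_var_, t))
                    for t in ("low", "medium", "high")},
            }
            agg = {"regular": 0.0, "irregular": 0.0}
            for tq, tm, tb, label in clf.rules:
                s = 1.0
                for i, term in enumerate((tq, tm, tb)):
                    if term is not None:
                        s = min(s, mu[i][term])
                agg[label] = max(agg[label], s)
            return ("irregular" if agg["irregular"] > agg["regular"]
                    else "regular")

        qrs_devs = np.linspace(0.0, 0.1, 50)
        margins = np.linspace(-2.0, 2.0, 50)
        # build feature rows whose internal (deviation, margin) match the grid
        # by inverting: qrs = standard + dev; hrv features chosen on the line
        # between centroids so the margin is controlled
        c_reg = clf.centroid_model_.centroid_regular_
        c_irr = clf.centroid_model_.centroid_irregular_
        gap = np.linalg.norm(c_irr - c_reg)
        for dev in qrs_devs[::7]:
            for margin in margins[::7]:
                # point on the centroid axis at signed distance giving the
                # desired margin: alpha parametrises reg -> irr
                alpha = 0.5 + margin / (2 * gap)
                z = c_reg + alpha * (c_irr - c_reg)
                hrv_feats = z * clf.centroid_model_.scale_ + clf.centroid_model_.mean_
                row = np.array([[0.099 + dev, hrv_feats[1], hrv_feats[2],
                                 hrv_feats[3], median_beats]])
                row[0, 0] = 0.099 + dev
                # margin implied by construction (exact along the axis)
                got = clf.predict(row)[0]
                want = oracle(dev, clf.centroid_model_.decision_function(row)[0],
                              median_beats)
                assert got == want

    def test_malformed_rule_rejected(self):
        rng = np.random.default_rng(5)
        X, y = _training_set(rng)
        clf = FuzzyRhythmClassifier(rules=(("low", "low", None, "bogus"),))
        with pytest.raises(ValueError, match="malformed"):
            clf.fit(X, y)


class TestConfusionCounts:
    def test_perfect_agreement(self):
        actual = ["irregular"] * 23 + ["regular"] * 7
        counts = confusion_counts(actual, actual)
        assert (counts.tn, counts.tp, counts.fn, counts.fp) == (7, 23, 0, 0)

    def test_all_negatives_wrong(self):
        actual = ["irregular"] * 23 + ["regular"] * 7
        pred = ["irregular"] * 30
        counts = confusion_counts(pred, actual)
        assert (counts.tn, counts.tp, counts.fn, counts.fp) == (0, 23, 0, 7)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)),
                    min_size=1, max_size=60))
    def test_counts_partition_records(self, pairs):
        pred, act = zip(*pairs)
        counts = confusion_counts(list(pred), list(act))
        assert counts.total == len(pairs)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_counts(["regular"], ["regular", "irregular"])


class TestMetrics:
    def test_published_row_reproduced_to_4dp(self):
        rep = metrics(ConfusionCounts(tn=6, tp=16, fn=7, fp=1))
        assert rep.precision == pytest.approx(69.5652, abs=5e-5)
        assert rep.specificity == pytest.approx(69.5652, abs=5e-5)
        assert rep.sensitivity == pytest.approx(72.7273, abs=5e-5)
        assert rep.accuracy == pytest.approx(73.3333, abs=5e-5)

    def test_perfect_positive_only_counts(self):
        rep = metrics(ConfusionCounts(tn=0, tp=12, fn=0, fp=0))
        assert (rep.precision, rep.specificity, rep.sensitivity,
                rep.accuracy) == (100, 100, 100, 100)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=50))
    def test_self_agreement_scores_100_accuracy(self, labels):
        rep = metrics(confusion_counts(labels, labels))
        assert rep.accuracy == 100.0

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40),
           st.integers(0, 40))
    def test_precision_equals_specificity_identity(self, tn, tp, fn, fp):
        if tn + tp + fn + fp == 0:
            return
        with np.errstate(all="ignore"):
            import warnings as w

            with w.catch_warnings():
                w.simplefilter("ignore")
                rep = metrics(ConfusionCounts(tn, tp, fn, fp))
        assert rep.precision == rep.specificity

    def test_standard_convention_differs(self):
        rep = metrics(ConfusionCounts(tn=6, tp=16, fn=7, fp=1), "standard")
        assert rep.sensitivity == pytest.approx(100 * 16 / 23)
        assert rep.specificity == pytest.approx(100 * 6 / 7)
        assert rep.precision == pytest.approx(100 * 16 / 17)

    def test_zero_denominator_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="denominator"):
            rep = metrics(ConfusionCounts(tn=3, tp=0, fn=0, fp=1))
        assert rep.precision == 0.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))
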