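"""Regular/irregular rhythm classification rules and their evaluation.

Three record-level rules operate on a five-column feature matrix
(``FEATURE_NAMES``): mean QRS interval (s), mean heart rate (bpm), SDNN
(ms), RMSSD (ms) and beat count.

1. :class:`QRSIntervalClassifier` — regular iff the mean QRS interval lies
   within a tolerance of the standard width 0.099 s (closed interval: a
   record exactly on the boundary counts as regular).
2. :class:`NearestCentroidRhythmClassifier` — per-class centroids of the
   z-scaled (QRS, HR, SDNN, RMSSD) vector, Euclidean nearest-centroid
   assignment, with a conservative margin rule: when the two distances are
   within ``margin_threshold`` of each other the record is called regular.
3. :class:`FuzzyRhythmClassifier` — a Mamdani-style rule base over three
   inputs (QRS-interval deviation from standard, the centroid-distance
   margin toward irregular, and beat count), triangular/trapezoidal
   memberships, min-conjunction firing, max aggregation per output label,
   arg-max defuzzification with ties resolved to regular.

The estimators follow scikit-learn conventions (``fit``/``predict``,
``get_params``, trailing-underscore fitted attributes) and compose with
sklearn pipelines and model selection.

Evaluation uses a specific, nonstandard set of confusion formulas that
this package reproduces verbatim as its default scoring convention (the
positive class is "irregular"):

    sensitivity = Tp / (Tp + Tn) * 100
    specificity = Tp / (Tp + Fn) * 100
    precision   = Tp / (Tp + Fn) * 100      (identical to specificity)
    accuracy    = (Tp + Tn) / (Tp + Tn + Fn + Fp) * 100

Textbook definitions are available via ``convention="standard"``; every
report names the convention it used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "FEATURE_NAMES",
    "RecordFeatures",
    "ConfusionCounts",
    "MetricsReport",
    "QRSIntervalClassifier",
    "NearestCentroidRhythmClassifier",
    "FuzzyRhythmClassifier",
    "classify_qrs_interval",
    "confusion_counts",
    "metrics",
    "STANDARD_QRS_INTERVAL",
]

FEATURE_NAMES = ("mean_qrs_s", "mean_hr_bpm", "sdnn_ms", "rmssd_ms", "beat_count")
STANDARD_QRS_INTERVAL = 0.099  # seconds
REGULAR, IRREGULAR = "regular", "irregular"
_HRV_COLS = slice(0, 4)  # columns entering the centroid distance


@dataclass(frozen=True)
class RecordFeatures:
    """Per-record feature vector consumed by the classification rules."""

    mean_qrs: float
    mean_heart_rate: float
    sdnn: float
    rmssd: float
    beat_count: int

    def __post_init__(self) -> None:
        vals = (self.mean_qrs, self.mean_heart_rate, self.sdnn, self.rmssd)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("features must be finite")
        if self.beat_count < 2:
            raise ValueError("need at least 2 beats")

    def to_array(self) -> np.ndarray:
        return np.array([self.mean_qrs, self.mean_heart_rate, self.sdnn,
                         self.rmssd, float(self.beat_count)])


def features_matrix(features: list[RecordFeatures]) -> np.ndarray:
    return np.vstack([f.to_array() for f in features])


# ---------------------------------------------------------------------------
# Rule 1: QRS-interval threshold


class QRSIntervalClassifier(ClassifierMixin, BaseEstimator):
    """Regular iff |mean QRS - standard| <= tolerance (closed interval)."""

    def __init__(self, standard_qrs: float = STANDARD_QRS_INTERVAL,
                 tolerance: float = 0.02):
        self.standard_qrs = standard_qrs
        self.tolerance = tolerance

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([IRREGULAR, REGULAR])
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(X)
        dev = np.abs(X[:, 0] - self.standard_qrs)
        return np.where(dev <= self.tolerance, REGULAR, IRREGULAR)


def classify_qrs_interval(
    features: RecordFeatures,
    standard_qrs: float = STANDARD_QRS_INTERVAL,
    tolerance: float = 0.02,
) -> str:
    """Functional form of the QRS-interval rule for a single record."""
    clf = QRSIntervalClassifier(standard_qrs, tolerance)
    X = features.to_array()[None, :]
    return str(clf.fit(X).predict(X)[0])


# ---------------------------------------------------------------------------
# Rule 2: nearest centroid on standardized QRS + HRV features


class NearestCentroidRhythmClassifier(ClassifierMixin, BaseEstimator):
    """Nearest-centroid rule on z-scaled (QRS, HR, SDNN, RMSSD) features.

    ``decision_function`` returns the margin d_regular - d_irregular in
    standardized units: positive values mean the record sits closer to the
    irregular centroid. Records whose absolute margin falls below
    ``margin_threshold`` are conservatively labelled regular, as are exact
    ties.
    """

    def __init__(self, margin_threshold: float = 0.0):
        self.margin_threshold = margin_threshold

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        y = np.asarray(y, dtype=object)
        self.classes_ = np.unique(y)
        missing = {REGULAR, IRREGULAR} - set(map(str, self.classes_))
        if missing:
            raise ValueError(f"training labels must include both classes; "
                             f"missing {sorted(missing)}")
        self.n_features_in_ = X.shape[1]
        Z = X[:, _HRV_COLS]
        self.scale_ = np.std(Z, axis=0)
        self.scale_[self.scale_ == 0] = 1.0
        self.mean_ = np.mean(Z, axis=0)
        Zs = (Z - self.mean_) / self.scale_
        self.centroid_regular_ = Zs[y == REGULAR].mean(axis=0)
        self.centroid_irregular_ = Zs[y == IRREGULAR].mean(axis=0)
        if np.allclose(self.centroid_regular_, self.centroid_irregular_):
            warnings.warn("degenerate (equal) class centroids; every record "
                          "will be labelled regular")
        return self

    def decision_function(self, X):
        check_is_fitted(self)
        X = check_array(X)
        Zs = (X[:, _HRV_COLS] - self.mean_) / self.scale_
        d_reg = np.linalg.norm(Zs - self.centroid_regular_, axis=1)
        d_irr = np.linalg.norm(Zs - self.centroid_irregular_, axis=1)
        return d_reg - d_irr

    def predict(self, X):
        margin = self.decision_function(X)
        irregular = margin > 0
        irregular &= np.abs(margin) >= self.margin_threshold
        return np.where(irregular, IRREGULAR, REGULAR)


# ---------------------------------------------------------------------------
# Rule 3: fuzzy QRS + HRV + beat count


def _trapezoid(x: np.ndarray, a: float, b: float, c: float, d: float) -> np.ndarray:
    """Trapezoidal membership: 0 below a, ramps to 1 on [a,b], flat on
    [b,c], ramps down on [c,d]. Degenerate b == c gives a triangle;
    infinite a/d give shoulders."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    rising = (x > a) & (x < b)
    if np.isfinite(a):
        out[rising] = (x[rising] - a) / (b - a)
    else:
        out[x < b] = 1.0
    out[(x >= b) & (x <= c)] = 1.0
    falling = (x > c) & (x < d)
    if np.isfinite(d):
        out[falling] = (d - x[falling]) / (d - c)
    else:
        out[x > c] = 1.0
    return out


@dataclass(frozen=True)
class FuzzyVariable:
    """Low/medium/high membership functions for one scalar input."""

    low: tuple[float, float, float, float]
    medium: tuple[float, float, float, float]
    high: tuple[float, float, float, float]

    def memberships(self, x) -> dict[str, np.ndarray]:
        return {term: _trapezoid(x, *getattr(self, term))
                for term in ("low", "medium", "high")}


# default rule table: (qrs_dev term, margin term, beats term) -> label,
# None is a wildcard matching any term with membership 1
DEFAULT_RULES: tuple[tuple[str | None, str | None, str | None, str], ...] = (
    ("low", "low", None, REGULAR),
    ("low", "medium", "medium", REGULAR),
    ("medium", "low", "medium", REGULAR),
    ("high", None, None, IRREGULAR),
    (None, "high", None, IRREGULAR),
    ("medium", "medium", None, IRREGULAR),
    ("low", "low", "low", IRREGULAR),
    ("low", "low", "high", IRREGULAR),
)


class FuzzyRhythmClassifier(ClassifierMixin, BaseEstimator):
    """Fuzzy rule-based rhythm classifier.

    Inputs per record: the absolute deviation of the mean QRS interval
    from the standard width (s), the nearest-centroid margin toward the
    irregular class (standardized units, from an internal
    :class:`NearestCentroidRhythmClassifier` fitted on the training data),
    and the beat count (whose terms are centered on the training-cohort
    median). Rules fire with min-conjunction; per-label activations
    aggregate by max; the label with the larger aggregate wins, ties going
    to regular.
    """

    def __init__(
        self,
        standard_qrs: float = STANDARD_QRS_INTERVAL,
        qrs_knees: tuple[float, float] = (0.02, 0.05),
        margin_knees: tuple[float, float] = (0.0, 1.0),
        beat_count_spread: float = 0.25,
        rules: tuple = DEFAULT_RULES,
    ):
        self.standard_qrs = standard_qrs
        self.qrs_knees = qrs_knees
        self.margin_knees = margin_knees
        self.beat_count_spread = beat_count_spread
        self.rules = rules

    def _check_rules(self) -> None:
        for rule in self.rules:
            if len(rule) != 4 or rule[3] not in (REGULAR, IRREGULAR):
                raise ValueError(f"malformed fuzzy rule {rule!r}")
            for term in rule[:3]:
                if term not in (None, "low", "medium", "high"):
                    raise ValueError(f"unknown fuzzy term {term!r} in {rule!r}")

    def fit(self, X, y):
        self._check_rules()
        lo, hi = self.qrs_knees
        if not 0 <= lo < hi:
            raise ValueError("qrs_knees must satisfy 0 <= low < high")
        mlo, mhi = self.margin_knees
        if not mlo < mhi:
            raise ValueError("margin_knees must be increasing")
        X, y = check_X_y(X, y, dtype=float)
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.unique(np.asarray(y, dtype=object))
        self.centroid_model_ = NearestCentroidRhythmClassifier().fit(X, y)
        median = float(np.median(X[:, 4]))
        spread = max(self.beat_count_spread * median, 1.0)
        self.qrs_var_ = FuzzyVariable(
            low=(-np.inf, -np.inf, lo, hi),
            medium=(lo, (lo + hi) / 2, (lo + hi) / 2, hi),
            high=(lo, hi, np.inf, np.inf),
        )
        self.margin_var_ = FuzzyVariable(
            low=(-np.inf, -np.inf, mlo, mhi),
            medium=(mlo, (mlo + mhi) / 2, (mlo + mhi) / 2, mhi),
            high=(mlo, mhi, np.inf, np.inf),
        )
        self.beats_var_ = FuzzyVariable(
            low=(-np.inf, -np.inf, median - 2 * spread, median - spread),
            medium=(median - 2 * spread, median - spread,
                    median + spread, median + 2 * spread),
            high=(median + spread, median + 2 * spread, np.inf, np.inf),
        )
        return self

    def _inputs(self, X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        qrs_dev = np.abs(X[:, 0] - self.standard_qrs)
        # d_regular - d_irregular: positive means closer to the irregular centroid
        margin = self.centroid_model_.decision_function(X)
        return qrs_dev, margin, X[:, 4]

    def predict_memberships(self, X) -> np.ndarray:
        """Aggregate memberships, columns (regular, irregular), each in [0, 1]."""
        check_is_fitted(self)
        X = check_array(X)
        qrs_dev, margin, beats = self._inputs(X)
        mu = {
            0: self.qrs_var_.memberships(qrs_dev),
            1: self.margin_var_.memberships(margin),
            2: self.beats_var_.memberships(beats),
        }
        agg = {REGULAR: np.zeros(X.shape[0]), IRREGULAR: np.zeros(X.shape[0])}
        ones = np.ones(X.shape[0])
        for t_qrs, t_margin, t_beats, label in self.rules:
            strength = ones
            for i, term in enumerate((t_qrs, t_margin, t_beats)):
                if term is not None:
                    strength = np.minimum(strength, mu[i][term])
            agg[label] = np.maximum(agg[label], strength)
        return np.column_stack([agg[REGULAR], agg[IRREGULAR]])

    def predict(self, X):
        m = self.predict_memberships(X)
        return np.where(m[:, 1] > m[:, 0], IRREGULAR, REGULAR)


# ---------------------------------------------------------------------------
# Evaluation


@dataclass(frozen=True)
class ConfusionCounts:
    """Agreement/disagreement counts with irregular as the positive class."""

    tn: int
    tp: int
    fn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tn, self.tp, self.fn, self.fp) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tn + self.tp + self.fn + self.fp


@dataclass(frozen=True)
class MetricsReport:
    """Percentage metrics plus the convention that produced them."""

    precision: float
    specificity: float
    sensitivity: float
    accuracy: float
    convention: str = "legacy"


def confusion_counts(predicted, actual) -> ConfusionCounts:
    """Count agreements/disagreements split by the actual class.

    ``Diff`` is the disagreement indicator; with irregular encoded as 1:
    Tp = agree & actual irregular, Tn = agree & actual regular,
    Fn = disagree & actual irregular, Fp = disagree & actual regular.
    The four counts partition the record set.
    """
    pred = np.asarray([_as01(v) for v in predicted])
    act = np.asarray([_as01(v) for v in actual])
    if pred.size != act.size:
        raise ValueError(f"length mismatch: {pred.size} vs {act.size}")
    if pred.size == 0:
        raise ValueError("need at least one record")
    diff = pred != act
    return ConfusionCounts(
        tn=int(np.sum(~diff & (act == 0))),
        tp=int(np.sum(~diff & (act == 1))),
        fn=int(np.sum(diff & (act == 1))),
        fp=int(np.sum(diff & (act == 0))),
    )


def _as01(value) -> int:
    if isinstance(value, str):
        if value not in (REGULAR, IRREGULAR):
            raise ValueError(f"unknown label {value!r}")
        return 1 if value == IRREGULAR else 0
    iv = int(value)
    if iv not in (0, 1):
        raise ValueError(f"labels must be 0/1 or regular/irregular, got {value!r}")
    return iv


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, reporting 0")
        return 0.0
    return 100.0 * num / den


def metrics(counts: ConfusionCounts, convention: str = "legacy") -> MetricsReport:
    """Percentage metrics from confusion counts.

    The default convention applies the nonstandard formulas documented in
    the module docstring (under which precision and specificity are the
    same expression and always agree); ``convention="standard"`` computes
    the textbook definitions instead.
    """
    if counts.total == 0:
        raise ValueError("all counts are zero")
    tn, tp, fn, fp = counts.tn, counts.tp, counts.fn, counts.fp
    accuracy = _ratio(tp + tn, counts.total, "accuracy")
    if convention == "legacy":
        return MetricsReport(
            precision=_ratio(tp, tp + fn, "precision"),
            specificity=_ratio(tp, tp + fn, "specificity"),
            sensitivity=_ratio(tp, tp + tn, "sensitivity"),
            accuracy=accuracy,
            convention="legacy",
        )
    if convention == "standard":
        return MetricsReport(
            precision=_ratio(tp, tp + fp, "precision"),
            specificity=_ratio(tn, tn + fp, "specificity"),
            sensitivity=_ratio(tp, tp + fn, "sensitivity"),
            accuracy=accuracy,
            convention="standard",
        )
    raise ValueError(f"unknown metrics convention {convention!r}")
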