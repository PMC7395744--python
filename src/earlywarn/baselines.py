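"""Comparison models: MEWS-as-predictor, SOFA-as-predictor, and GB-Vital.

MEWS and SOFA interpret the raw ward scores at prediction time as ranking
scores, recomputed whenever a component is updated, with carry-forward
imputation of missing components.  GB-Vital is a gradient-boosted tree
classifier over 30 features derived from the six vital signs: for each vital,
the hourly mean of the current hour, the prior hour and the hour before that,
plus the two trends between succeeding hourly means (current minus prior).

The published Danish ward-score variant's banding tables are not public, so
the standard MEWS bands are used, extended with a pulse-oximetry band;
the tables can be overridden per call.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier

from .ehr import HOUR, AdmissionTimeline
from .gold_standards import SOFA_PARAMETERS, _carry_forward_at, sofa_score
from .parameters import load_parameter_table, vital_names

#: (upper-exclusive band edges, band scores); the value falls in band i when
#: value < edges[i]; the final score applies at or above the last edge.
MEWS_BANDS: dict[str, tuple[tuple[float, ...], tuple[int, ...]]] = {
    "Respiration frequency": ((9, 15, 21, 30), (2, 0, 1, 2, 3)),
    "Pulse rate": ((40, 51, 101, 111, 130), (2, 1, 0, 1, 2, 3)),
    "Systolic blood pressure": ((71, 81, 101, 200), (3, 2, 1, 0, 2)),
    "Temperature": ((35.0, 38.5), (2, 0, 2)),
    "SpO2": ((92, 94, 96), (3, 2, 1, 0)),
}

MEWS_PARAMETERS = tuple(MEWS_BANDS)


def _band_score(value: float, edges, scores) -> int:
    if np.isnan(value):
        return 0
    for edge, score in zip(edges, scores):
        if value < edge:
            return int(score)
    return int(scores[-1])


def mews_score(snapshot, bands: dict | None = None) -> int:
    """Sum of MEWS component scores for one vitals snapshot.

    Missing components (absent or NaN) contribute 0; the consciousness
    component is omitted (not recorded in the parameter set).
    """
    bands = MEWS_BANDS if bands is None else bands
    total = 0
    for name, (edges, scores) in bands.items():
        try:
            value = float(snapshot[name])
        except (KeyError, IndexError, TypeError):
            value = np.nan
        total += _band_score(value, edges, scores)
    return total


def _snapshot_at(timeline: AdmissionTimeline, parameters, when: pd.Timestamp) -> dict:
    """Carry-forward values of the given parameters at one time point."""
    grid = np.array([np.datetime64(pd.Timestamp(when), "ns")])
    snap = {}
    for name in parameters:
        times, values = timeline.parameter_events(name)
        snap[name] = float(_carry_forward_at(times.astype("datetime64[ns]"), values, grid)[0])
    return snap


def mews_predictor(
    timeline: AdmissionTimeline, prediction_time: pd.Timestamp, bands: dict | None = None
) -> float:
    """Latest MEWS at prediction time, used directly as the risk-ranking score."""
    return float(mews_score(_snapshot_at(timeline, MEWS_PARAMETERS, prediction_time), bands))


def sofa_predictor(timeline: AdmissionTimeline, prediction_time: pd.Timestamp) -> float:
    """Latest SOFA at prediction time, used directly as the risk-ranking score."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sofa_score(_snapshot_at(timeline, SOFA_PARAMETERS, prediction_time)))


# ---------------------------------------------------------------------------
# GB-Vital
# ---------------------------------------------------------------------------

def gb_vital_features(
    timeline: AdmissionTimeline, prediction_time: pd.Timestamp, vitals=None
) -> np.ndarray:
    """The 30 GB-Vital features at prediction time (5 per vital sign).

    Per vital: mean of the current hour ``(t-1h, t]``, of the prior hour and of
    the hour before that, plus the two trends between succeeding hourly means
    (sign convention: later mean minus earlier mean).  A missing hourly mean is
    carried forward from the older hour; fully unobserved vitals stay NaN and
    are median-filled by the fitted classifier.
    """
    vitals = vital_names() if vitals is None else list(vitals)
    prediction_time = pd.Timestamp(prediction_time)
    features = []
    for name in vitals:
        times, values = timeline.parameter_events(name)
        times = times.astype("datetime64[ns]")
        means = []
        for back in (2, 1, 0):  # oldest -> current
            hi = np.datetime64(prediction_time - back * HOUR)
            lo = np.datetime64(prediction_time - (back + 1) * HOUR)
            in_hour = (times > lo) & (times <= hi)
            means.append(values[in_hour].mean() if in_hour.any() else np.nan)
        # carry forward across the three hourly means (oldest first)
        for i in (1, 2):
            if np.isnan(means[i]):
                means[i] = means[i - 1]
        h2, h1, h0 = means[0], means[1], means[2]
        features.extend([h0, h1, h2, h0 - h1, h1 - h2])
    return np.array(features, dtype=float)


class GBVital:
    """Gradient-boosted decision-tree classifier over the 30 vital features."""

    def __init__(self, n_estimators: int = 300, max_depth: int = 3, learning_rate: float = 0.1,
                 seed: int = 0):
        self._clf = GradientBoostingClassifier(
            n_estimators=n_estimators,
            max_depth=max_depth,
            learning_rate=learning_rate,
            random_state=seed,
        )
        self.medians_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GBVital":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training set contains a single class")
        med = np.nanmedian(X, axis=0)
        self.medians_ = np.where(np.isnan(med), 0.0, med)
        self._clf.fit(self._fill(X), y)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.medians_ is None:
            raise ValueError("classifier is not fitted")
        return self._clf.predict_proba(self._fill(np.asarray(X, dtype=float)))[:, 1]

    def _fill(self, X: np.ndarray) -> np.ndarray:
        return np.where(np.isnan(X), self.medians_[None, :], X)
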