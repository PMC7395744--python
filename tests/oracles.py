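"""Independent brute-force oracles used to cross-check the package.

Each oracle re-derives its result by exhaustive scanning with its own control
flow and banding code, deliberately avoiding the package's implementations.
"""
from __future__ import annotations

import numpy as np
import pandas as pd


def oracle_auroc(scores, labels) -> float:
    """Pair-counting AUROC: wins + half-ties over all positive/negative pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# labeler oracles
# ---------------------------------------------------------------------------

def _events(timeline, name):
    sel = timeline.events[timeline.events["parameter"] == name]
    return list(sel["timestamp"]), list(sel["value"])


def _last_before(times, values, when):
    best = None
    for t, v in zip(times, values):
        if t <= when:
            best = v
    return np.nan if best is None else best


def _sofa_at(timeline, when):
    """Independent SOFA banding via explicit if-chains."""
    score = 0
    plate = _last_before(*_events(timeline, "B-Platelets"), when)
    if not np.isnan(plate):
        if plate < 20:
            score += 4
        elif plate < 50:
            score += 3
        elif plate < 100:
            score += 2
        elif plate < 150:
            score += 1
    bili = _last_before(*_events(timeline, "P-Bilirubin"), when)
    if not np.isnan(bili):
        if bili > 204:
            score += 4
        elif bili > 101:
            score += 3
        elif bili > 32:
            score += 2
        elif bili > 19:
            score += 1
    sbp = _last_before(*_events(timeline, "Systolic blood pressure"), when)
    dbp = _last_before(*_events(timeline, "Diastolic blood pressure"), when)
    if not (np.isnan(sbp) or np.isnan(dbp)):
        if (sbp + 2 * dbp) / 3 < 70:
            score += 1
    crea = _last_before(*_events(timeline, "P-Creatinine"), when)
    if not np.isnan(crea):
        if crea > 440:
            score += 4
        elif crea > 299:
            score += 3
        elif crea > 170:
            score += 2
        elif crea > 109:
            score += 1
    spo2 = _last_before(*_events(timeline, "SpO2"), when)
    if not np.isnan(spo2):
        if spo2 < 90:
            score += 2
        elif spo2 < 94:
            score += 1
    return score


def oracle_sepsis(timeline):
    """(positive, onset) by exhaustive scan of all culture/antibiotic pairs and
    all ordered hourly snapshot pairs in the organ-dysfunction window."""
    cultures, _ = _events(timeline, "culture_sample")
    abx, _ = _events(timeline, "antibiotic_administration")
    si_candidates = []
    for c in cultures:
        for a in abx:
            if a >= c and (a - c) <= pd.Timedelta(hours=72):
                si_candidates.append(c)
            elif a < c and (c - a) <= pd.Timedelta(hours=24):
                si_candidates.append(a)
    if not si_candidates:
        return False, None
    si = min(si_candidates)
    start = max(timeline.admit_time, si - pd.Timedelta(hours=48))
    end = min(timeline.discharge_time, si + pd.Timedelta(hours=24))
    grid = list(pd.date_range(start, end, freq="1h"))
    scores = [_sofa_at(timeline, t) for t in grid]
    for i in range(len(scores)):
        for j in range(i, len(scores)):
            if scores[j] - scores[i] >= 2:
                return True, si
    return False, None


def oracle_aki(timeline):
    """(positive, onset) by double loop over all creatinine measurement pairs."""
    times, values = _events(timeline, "P-Creatinine")
    for i, (t, v) in enumerate(zip(times, values)):
        fired = False
        prior48 = [
            values[j]
            for j in range(i)
            if times[j] < t and times[j] >= t - pd.Timedelta(hours=48)
        ]
        if prior48 and v >= min(prior48) + 26.5:
            fired = True
        prior365 = [
            values[j]
            for j in range(i)
            if times[j] < t and times[j] >= t - pd.Timedelta(days=365)
        ]
        if not fired and prior365:
            habitual = sum(prior365) / len(prior365)
            if habitual > 0 and v >= 1.5 * habitual:
                fired = True
        if fired:
            return True, t
    return False, None


def oracle_ali(timeline):
    tt = []
    for name in ("niv", "cpap"):
        times, _ = _events(timeline, name)
        tt.extend(times)
    if not tt:
        return False, None
    return True, min(tt)
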