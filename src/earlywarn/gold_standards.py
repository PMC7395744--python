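"""Algorithmic outcome labeling: Sepsis-3, KDIGO acute kidney injury, and
CPAP/NIV-defined acute lung injury.

Sepsis follows the Sepsis-3 consensus: a suspected infection (qualifying
culture/antibiotic co-occurrence) together with an acute SOFA increase of at
least two points inside a 72-hour window running from 48 h before to 24 h
after the suspected-infection time.  AKI follows the two creatinine-based
KDIGO definitions (the urine-output criterion needs data that is not in the
33-parameter set); all KDIGO stages collapse to a binary positive.  ALI is
operationalized as the first use of CPAP or noninvasive ventilation.

All threshold comparisons are inclusive (>=), uniformly.
"""
from __future__ import annotations

import dataclasses
import enum
import warnings

import numpy as np
import pandas as pd

from .ehr import HOUR, AdmissionTimeline

ABX_AFTER_CULTURE_HOURS = 72.0
CULTURE_AFTER_ABX_HOURS = 24.0
SOFA_DELTA = 2
AKI_ABS_INCREASE = 26.5  # umol/l within 48 h (0.3 mg/dl)
AKI_REL_INCREASE = 1.5  # times the habitual (365-day mean) creatinine
AKI_ABS_WINDOW = pd.Timedelta(hours=48)
AKI_HABITUAL_WINDOW = pd.Timedelta(days=365)

CREATININE = "P-Creatinine"

#: Parameters consumed by the SOFA score (available subsystems only).
SOFA_PARAMETERS = (
    "B-Platelets",
    "P-Bilirubin",
    "Systolic blood pressure",
    "Diastolic blood pressure",
    "P-Creatinine",
    "SpO2",
)


class Illness(str, enum.Enum):
    SEPSIS = "sepsis"
    AKI = "aki"
    ALI = "ali"


@dataclasses.dataclass(frozen=True)
class OutcomeLabel:
    illness: str
    positive: bool
    onset_time: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        if self.positive != (self.onset_time is not None):
            raise ValueError("onset_time must be present exactly when positive")


@dataclasses.dataclass(frozen=True)
class SuspectedInfection:
    si_time: pd.Timestamp
    culture_time: pd.Timestamp
    antibiotic_time: pd.Timestamp


def detect_suspected_infection(timeline: AdmissionTimeline) -> SuspectedInfection | None:
    """Find the earliest qualifying culture/antibiotic pair.

    A culture followed by an antibiotic qualifies when the antibiotic comes
    within 72 h; an antibiotic followed by a culture qualifies when the culture
    comes within 24 h.  The suspected-infection time is the earlier event of
    the pair; among qualifying pairs the earliest suspected-infection time wins.
    """
    cultures, _ = timeline.parameter_events("culture_sample")
    abx, _ = timeline.parameter_events("antibiotic_administration")
    if len(cultures) == 0 or len(abx) == 0:
        return None
    best: SuspectedInfection | None = None
    for c in cultures:
        for a in abx:
            c_ts, a_ts = pd.Timestamp(c), pd.Timestamp(a)
            if a_ts >= c_ts:
                ok = (a_ts - c_ts) <= ABX_AFTER_CULTURE_HOURS * HOUR
                si = c_ts
            else:
                ok = (c_ts - a_ts) <= CULTURE_AFTER_ABX_HOURS * HOUR
                si = a_ts
            if ok and (best is None or si < best.si_time):
                best = SuspectedInfection(si_time=si, culture_time=c_ts, antibiotic_time=a_ts)
    return best


# ---------------------------------------------------------------------------
# SOFA score (available subsystems; CNS, urine output and vasopressor data are
# not in the 33-parameter set and contribute 0)
# ---------------------------------------------------------------------------

def _coagulation(platelets: float) -> int:
    if np.isnan(platelets):
        return 0
    for threshold, score in ((20, 4), (50, 3), (100, 2), (150, 1)):
        if platelets < threshold:
            return score
    return 0


def _liver(bilirubin: float) -> int:
    if np.isnan(bilirubin):
        return 0
    for threshold, score in ((204, 4), (101, 3), (32, 2), (19, 1)):
        if bilirubin > threshold:
            return score
    return 0


def _cardiovascular(map_mmhg: float) -> int:
    if np.isnan(map_mmhg):
        return 0
    return 1 if map_mmhg < 70 else 0


def _renal(creatinine: float) -> int:
    if np.isnan(creatinine):
        return 0
    for threshold, score in ((440, 4), (299, 3), (170, 2), (109, 1)):
        if creatinine > threshold:
            return score
    return 0


def _respiration(spo2: float) -> int:
    # SpO2 proxy banding (no FiO2 available); capped at 2.
    if np.isnan(spo2):
        return 0
    if spo2 < 90:
        return 2
    if spo2 < 94:
        return 1
    return 0


def sofa_score(snapshot) -> int:
    """Sum of available SOFA subsystem scores (each 0-4) for one snapshot.

    ``snapshot`` maps parameter names (see :data:`SOFA_PARAMETERS`) to values;
    missing parameters may be absent or NaN and contribute 0.  An all-missing
    snapshot scores 0 with a warning.
    """
    def get(key: str) -> float:
        try:
            return float(snapshot[key])
        except (KeyError, IndexError, TypeError):
            return np.nan

    plate, bili = get("B-Platelets"), get("P-Bilirubin")
    sbp, dbp = get("Systolic blood pressure"), get("Diastolic blood pressure")
    crea, spo2 = get("P-Creatinine"), get("SpO2")
    if all(np.isnan(v) for v in (plate, bili, sbp, dbp, crea, spo2)):
        warnings.warn("SOFA snapshot has no available parameters; scoring 0")
    mean_ap = (sbp + 2.0 * dbp) / 3.0 if not (np.isnan(sbp) or np.isnan(dbp)) else np.nan
    return (
        _coagulation(plate)
        + _liver(bili)
        + _cardiovascular(mean_ap)
        + _renal(crea)
        + _respiration(spo2)
    )


def _carry_forward_at(times: np.ndarray, values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Last observation at or before each grid time (NaN before the first)."""
    out = np.full(len(grid), np.nan)
    if len(times):
        idx = np.searchsorted(times, grid, side="right") - 1
        ok = idx >= 0
        out[ok] = values[idx[ok]]
    return out


def sofa_series(
    timeline: AdmissionTimeline, start: pd.Timestamp, end: pd.Timestamp
) -> tuple[pd.DatetimeIndex, np.ndarray]:
    """Hourly SOFA scores on carry-forward-imputed snapshots in [start, end]."""
    grid = pd.date_range(start, end, freq="1h")
    series = {}
    for name in SOFA_PARAMETERS:
        times, values = timeline.parameter_events(name)
        series[name] = _carry_forward_at(times.astype("datetime64[ns]"), values, grid.to_numpy())
    scores = np.empty(len(grid), dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-missing leading snapshots are expected
        for i in range(len(grid)):
            scores[i] = sofa_score({k: v[i] for k, v in series.items()})
    return grid, scores


def label_sepsis(timeline: AdmissionTimeline) -> OutcomeLabel:
    """Sepsis-3: suspected infection + SOFA increase >= 2 in the 72-h window.

    The increase is measured as the maximum over the window of the score minus
    the running minimum up to that point (a deterioration of at least two
    points occurring after its baseline), on hourly carry-forward snapshots.
    Onset is anchored at the suspected-infection time.
    """
    si = detect_suspected_infection(timeline)
    if si is None:
        return OutcomeLabel(Illness.SEPSIS.value, False)
    start = max(timeline.admit_time, si.si_time - 48 * HOUR)
    end = min(timeline.discharge_time, si.si_time + 24 * HOUR)
    if start > end:
        return OutcomeLabel(Illness.SEPSIS.value, False)
    _, scores = sofa_series(timeline, start, end)
    running_min = np.minimum.accumulate(scores)
    if len(scores) and int(np.max(scores - running_min)) >= SOFA_DELTA:
        return OutcomeLabel(Illness.SEPSIS.value, True, si.si_time)
    return OutcomeLabel(Illness.SEPSIS.value, False)


def label_aki(timeline: AdmissionTimeline) -> OutcomeLabel:
    """KDIGO AKI (binary): creatinine rise of >= 26.5 umol/l within 48 h, or a
    value >= 1.5x the habitual level (mean over the prior 365 days).

    Both definitions compare each measurement against strictly earlier
    measurements (pre-admission history counts).  Onset is the earliest
    measurement at which either definition fires.  With no prior history a
    definition cannot fire (no habitual level is fabricated).
    """
    times, values = timeline.parameter_events(CREATININE)
    if len(times) == 0:
        return OutcomeLabel(Illness.AKI.value, False)
    times = pd.DatetimeIndex(times)
    for i in range(len(times)):
        t, v = times[i], values[i]
        prior = times[:i]
        if len(prior):
            in48 = (prior >= t - AKI_ABS_WINDOW) & (prior < t)
            if in48.any() and v >= values[:i][in48].min() + AKI_ABS_INCREASE:
                return OutcomeLabel(Illness.AKI.value, True, t)
            in365 = (prior >= t - AKI_HABITUAL_WINDOW) & (prior < t)
            if in365.any():
                habitual = values[:i][in365].mean()
                if habitual > 0 and v >= AKI_REL_INCREASE * habitual:
                    return OutcomeLabel(Illness.AKI.value, True, t)
    return OutcomeLabel(Illness.AKI.value, False)


def label_ali(timeline: AdmissionTimeline) -> OutcomeLabel:
    """ALI: positive iff any NIV or CPAP event exists; onset is the first one."""
    niv, _ = timeline.parameter_events("niv")
    cpap, _ = timeline.parameter_events("cpap")
    candidates = [pd.Timestamp(t) for t in list(niv) + list(cpap)]
    if not candidates:
        return OutcomeLabel(Illness.ALI.value, False)
    return OutcomeLabel(Illness.ALI.value, True, min(candidates))


_LABELERS = {
    Illness.SEPSIS.value: label_sepsis,
    Illness.AKI.value: label_aki,
    Illness.ALI.value: label_ali,
}


def label_admission(timeline: AdmissionTimeline) -> dict[str, OutcomeLabel]:
    """All three outcome labels for one admission."""
    return {name: fn(timeline) for name, fn in _LABELERS.items()}


def label_cohort(timelines) -> pd.DataFrame:
    """Label every admission; returns a long frame
    (admission_id, illness, positive, onset_time)."""
    rows = []
    for tl in timelines:
        for name, label in label_admission(tl).items():
            rows.append(
                {
                    "admission_id": tl.admission_id,
                    "illness": name,
                    "positive": label.positive,
                    "onset_time": label.onset_time,
                }
            )
    return pd.DataFrame(rows, columns=["admission_id", "illness", "positive", "onset_time"])
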