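"""Synthetic admission generator with the statistical structure of the study
cohort: per-parameter 5/50/95 percentile profiles stratified by outcome, an
average of ~39 laboratory measurements per admission, a median length of stay
of 153.6 h, and outcome prevalences of 2.44% (sepsis), 0.75% (AKI) and 1.68%
(ALI).

Values are drawn from two-piece split-normal distributions matched exactly to
the three profile percentiles (on a log scale for skewed positive analytes).
Positive admissions sample from the outcome-negative profile far from onset
and drift linearly, in quantile-parameter space, toward the outcome-positive
profile over the 24 hours before the planted onset.  Each positive admission
additionally emits the events its gold-standard labeler requires, with
trajectories controlled so the labeler recovers the planted onset exactly:

* sepsis - a culture/antibiotic pair at onset plus a platelet drop that raises
  the SOFA coagulation subscore by exactly two points across the onset;
* AKI - a creatinine ramp whose first crossing of the +26.5 umol/l KDIGO
  threshold is the onset measurement (with optional pre-admission history for
  the habitual-creatinine baseline);
* ALI - a CPAP event at onset.

All randomness derives from one master seed through per-admission seed
sequences, so cohorts are reproducible byte for byte.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .ehr import AdmissionTimeline
from .parameters import ILLNESSES, ParameterSpec, load_parameter_table

Z95 = float(ndtri(0.95))  # 1.6448536...

REFERENCE_LOS_HOURS = 153.6
_EPOCH = pd.Timestamp("2016-01-01 00:00")


# ---------------------------------------------------------------------------
# quantile-matched split-normal sampler
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SplitNormal:
    """Two-piece normal parameterized by median and one-sided spreads.

    The quantile function splices two half-normals at the median:
    ``Q(u) = m + s_lo * z(u)`` for ``u <= 0.5`` and ``m + s_hi * z(u)`` above,
    so the 5th/50th/95th percentiles match the fitted triple exactly.  For
    log-scale parameters the transform applies on the log scale.
    """

    loc: float
    s_lo: float
    s_hi: float
    log: bool = False
    clip_min: float | None = None

    def ppf(self, u: np.ndarray) -> np.ndarray:
        u = np.clip(np.asarray(u, dtype=float), 1e-9, 1 - 1e-9)
        z = ndtri(u)
        x = self.loc + np.where(u <= 0.5, self.s_lo, self.s_hi) * z
        if self.log:
            x = np.exp(x)
        if self.clip_min is not None:
            x = np.maximum(x, self.clip_min)
        return x

    def rvs(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return self.ppf(rng.uniform(size=size))


def fit_quantile_distribution(
    p5: float,
    p50: float,
    p95: float,
    scale: str = "linear",
    clip_min: float | None = None,
) -> SplitNormal:
    """Fit a split-normal whose 5th/50th/95th quantiles equal the inputs.

    Degenerate triples (``p5 == p95``) yield a point mass with a warning.
    """
    if not p5 <= p50 <= p95:
        raise ValueError("quantile triple must satisfy p5 <= p50 <= p95")
    log = scale == "log"
    if log and p5 <= 0:
        raise ValueError("log-scale fitting requires strictly positive quantiles")
    if p5 == p95:
        warnings.warn(f"degenerate quantile triple ({p5}); using a point mass")
        loc = np.log(p50) if log else p50
        return SplitNormal(loc, 0.0, 0.0, log=log, clip_min=clip_min)
    a5, a50, a95 = (np.log(v) for v in (p5, p50, p95)) if log else (p5, p50, p95)
    return SplitNormal(
        loc=float(a50),
        s_lo=float((a50 - a5) / Z95),
        s_hi=float((a95 - a50) / Z95),
        log=log,
        clip_min=clip_min,
    )


def _fit_params(spec: ParameterSpec, illness: str, cls: str) -> tuple[float, float, float]:
    """(loc, s_lo, s_hi) on the fitting scale for one profile column."""
    sn = fit_quantile_distribution(*spec.triple(illness, cls), scale=spec.scale)
    return sn.loc, sn.s_lo, sn.s_hi


# ---------------------------------------------------------------------------
# cohort specification
# ---------------------------------------------------------------------------

def default_prevalences() -> dict[str, float]:
    return {"sepsis": 0.0244, "aki": 0.0075, "ali": 0.0168}


@dataclasses.dataclass
class CohortSpec:
    """Study conditions of the generated cohort."""

    n_admissions: int
    prevalences: dict[str, float] = dataclasses.field(default_factory=default_prevalences)
    median_los_hours: float = REFERENCE_LOS_HOURS
    lab_events_per_admission: float = 39.0
    seed: int = 0
    #: restrict the pre-onset deterioration drift to these parameters
    #: (None = every parameter drifts per its outcome profile)
    drift_parameters: Sequence[str] | None = None
    #: multiplier on the negative->positive drift in quantile-parameter space
    drift_scale: float = 1.0
    #: emit pre-admission creatinine history for AKI-positive admissions
    aki_history: bool = True

    def __post_init__(self) -> None:
        if self.n_admissions < 1:
            raise ValueError("n_admissions must be >= 1")
        for illness, p in self.prevalences.items():
            if illness not in ILLNESSES:
                raise ValueError(f"unknown illness {illness!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError("prevalences must lie in [0, 1]")
        if sum(self.prevalences.values()) > 1.0:
            raise ValueError("prevalences must sum to at most 1")


# ---------------------------------------------------------------------------
# single-admission generation
# ---------------------------------------------------------------------------

#: channels whose trajectory is fully controlled to guarantee the labeler fires
_CONTROLLED = {"sepsis": {"B-Platelets"}, "aki": {"P-Creatinine"}, "ali": set()}

_DRIFT_HOURS = 24.0  # deterioration ramp length before onset
_U_JITTER = 0.08  # within-admission percentile jitter (standard deviations)


def _los_hours(rng: np.random.Generator, spec: CohortSpec, positive: bool) -> float:
    los = float(np.exp(rng.normal(np.log(spec.median_los_hours), 0.6)))
    los = float(np.clip(los, 48.0, 720.0))
    if positive:
        los = max(los, 96.0)
    return los


def _vital_times(rng: np.random.Generator, los: float) -> np.ndarray:
    """Vital-sign sampling times: admission start, then every 2-8 h, plus one
    observation shortly before discharge (anchors the admission span)."""
    times = [0.0]
    t = 0.0
    while t < los - 1.5:
        t += float(rng.uniform(2.0, 8.0))
        times.append(min(t, los - 0.5))
    if times[-1] < los - 0.5:
        times.append(los - 0.5)
    return np.array(times)


def generate_admission(
    spec: CohortSpec,
    illness: str,
    seed,
    admission_id: str = "adm-00000",
    patient_id: str = "pat-00000",
    admit_time: pd.Timestamp = _EPOCH,
    table: Sequence[ParameterSpec] | None = None,
) -> tuple[AdmissionTimeline, pd.Timestamp | None]:
    """Generate one admission timeline and its planted onset (None if negative).

    ``illness`` is one of ``sepsis``, ``aki``, ``ali`` or ``negative``.
    ``seed`` may be an integer or a :class:`numpy.random.SeedSequence`.
    """
    if illness not in (*ILLNESSES, "negative"):
        raise ValueError(f"illness must be one of {ILLNESSES} or 'negative'")
    table = load_parameter_table() if table is None else list(table)
    rng = np.random.default_rng(seed)
    positive = illness != "negative"
    los = _los_hours(rng, spec, positive)
    if positive and los < 56.0:
        raise ValueError("admission too short to place an onset 48 h after admission")
    onset_h = float(rng.uniform(48.0, los - 8.0)) if positive else None

    # profile column used away from onset; positives drift toward their own
    # positive column, negatives stay on the sepsis-negative column
    base_illness = illness if positive else "sepsis"
    drift_set = (
        set(spec.drift_parameters) if spec.drift_parameters is not None else {p.name for p in table}
    )
    controlled = _CONTROLLED.get(illness, set())

    total_weight = sum(p.sampling_weight for p in table if p.kind == "lab")
    hours: list[np.ndarray] = []
    names: list[list[str]] = []
    values: list[np.ndarray] = []

    for p in table:
        if p.name in controlled:
            continue
        if p.kind == "vital":
            t = _vital_times(rng, los)
        else:
            lam = (
                p.sampling_weight
                / total_weight
                * spec.lab_events_per_admission
                * (los / REFERENCE_LOS_HOURS)
            )
            n = int(rng.poisson(lam))
            if n == 0:
                continue
            t = np.sort(rng.uniform(0.0, los, n))
        loc_n, slo_n, shi_n = _fit_params(p, base_illness, "negative")
        u0 = float(rng.uniform(0.02, 0.98))
        if p.name == "P-Creatinine" and illness != "aki":
            # The AKI gold standard keys on absolute 48-h creatinine
            # excursions, so within-patient variation must stay physiological
            # (a few percent around a patient baseline) rather than
            # percentile-resampled; otherwise sampling noise alone would
            # plant kidney injuries in non-AKI admissions.
            z0 = float(ndtri(u0))
            b = loc_n + (slo_n if u0 <= 0.5 else shi_n) * z0
            if p.scale == "log":
                b = float(np.exp(b))
            x = b * (1.0 + 0.02 * np.clip(rng.standard_normal(len(t)), -2.0, 2.0))
            if p.clip_min is not None:
                x = np.maximum(x, p.clip_min)
            hours.append(t)
            names.append([p.name] * len(t))
            values.append(x)
            continue
        u = np.clip(u0 + _U_JITTER * rng.standard_normal(len(t)), 0.01, 0.99)
        if positive and p.name in drift_set:
            loc_p, slo_p, shi_p = _fit_params(p, illness, "positive")
            alpha = np.clip(1.0 - (onset_h - t) / _DRIFT_HOURS, 0.0, 1.0) * spec.drift_scale
        else:
            loc_p, slo_p, shi_p = loc_n, slo_n, shi_n
            alpha = np.zeros(len(t))
        loc = loc_n + alpha * (loc_p - loc_n)
        s_lo = np.maximum(slo_n + alpha * (slo_p - slo_n), 0.0)
        s_hi = np.maximum(shi_n + alpha * (shi_p - shi_n), 0.0)
        z = ndtri(u)
        x = loc + np.where(u <= 0.5, s_lo, s_hi) * z
        if p.scale == "log":
            x = np.exp(x)
        if p.clip_min is not None:
            x = np.maximum(x, p.clip_min)
        hours.append(t)
        names.append([p.name] * len(t))
        values.append(x)

    def emit(t, name, value) -> None:
        hours.append(np.atleast_1d(np.asarray(t, dtype=float)))
        vals = np.atleast_1d(np.asarray(value, dtype=float))
        names.append([name] * len(vals))
        values.append(vals)

    if illness == "sepsis":
        # SOFA coagulation 0 -> 2 across onset; culture+antibiotic at onset
        high = float(rng.uniform(180.0, 280.0))
        t_high = np.arange(0.0, max(onset_h - 2.0, 1.0), 6.0)
        emit(t_high, "B-Platelets", high + rng.uniform(-10, 10, len(t_high)))
        low = rng.uniform(60.0, 90.0)
        t_low = np.concatenate([[onset_h - 1.0, onset_h + 2.0], np.arange(onset_h + 8.0, los, 6.0)])
        emit(t_low, "B-Platelets", low + rng.uniform(-5, 5, len(t_low)))
        emit([onset_h], "culture_sample", [1.0])
        abx_delay = float(rng.uniform(1.0, min(24.0, los - onset_h - 0.5)))
        emit([onset_h + abx_delay], "antibiotic_administration", [1.0])
    elif illness == "aki":
        # creatinine ramp first crossing +26.5 umol/l at the onset measurement
        b = float(rng.uniform(50.0, 110.0))
        t_base = np.arange(0.0, max(onset_h - 10.0, 1.0), 6.0)
        emit(t_base, "P-Creatinine", b + rng.uniform(-2, 2, len(t_base)))
        emit([onset_h - 8.0, onset_h - 4.0], "P-Creatinine", [b + 10.0, b + 18.0])
        emit([onset_h], "P-Creatinine", [b + 30.0])
        t_post = np.arange(onset_h + 6.0, los, 6.0)
        emit(t_post, "P-Creatinine", b + 30.0 + rng.uniform(-3, 3, len(t_post)))
        if spec.aki_history:
            emit([-7200.0, -4800.0, -2400.0], "P-Creatinine", b + rng.uniform(-2, 2, 3))
    elif illness == "ali":
        emit([onset_h], "cpap", [1.0])
        if onset_h + 12.0 < los:
            emit([onset_h + 12.0], "niv", [1.0])

    all_hours = np.concatenate(hours)
    all_names = [n for sub in names for n in sub]
    all_values = np.concatenate(values)
    # minute resolution, as recorded in the source systems
    stamps = admit_time + pd.to_timedelta(np.round(all_hours * 60.0), unit="m")
    events = (
        pd.DataFrame({"timestamp": stamps, "parameter": all_names, "value": all_values})
        .sort_values(["timestamp", "parameter"], kind="stable")
        .reset_index(drop=True)
    )
    timeline = AdmissionTimeline(
        admission_id=admission_id,
        patient_id=patient_id,
        admit_time=admit_time,
        discharge_time=admit_time + pd.to_timedelta(round(los * 60.0), unit="m"),
        events=events,
    )
    onset = None if onset_h is None else admit_time + pd.to_timedelta(round(onset_h * 60.0), unit="m")
    return timeline, onset


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(
    spec: CohortSpec, table: Sequence[ParameterSpec] | None = None
) -> list[tuple[AdmissionTimeline, str, pd.Timestamp | None]]:
    """Generate a full cohort: list of (timeline, planted illness, onset).

    Class counts are the deterministic rounded targets ``round(n * prevalence)``;
    per-admission seeds derive from the master seed via seed sequences.  Each
    synthetic patient has exactly one admission.
    """
    table = load_parameter_table() if table is None else list(table)
    n = spec.n_admissions
    assignment = ["negative"] * n
    cursor = 0
    for illness in ILLNESSES:
        count = int(round(n * spec.prevalences.get(illness, 0.0)))
        for _ in range(count):
            if cursor >= n:
                raise ValueError("prevalences exceed cohort size")
            assignment[cursor] = illness
            cursor += 1
    order = np.random.default_rng(spec.seed).permutation(n)
    assignment = [assignment[i] for i in order]

    children = np.random.SeedSequence(spec.seed).spawn(n)
    cohort = []
    for i, (illness, child) in enumerate(zip(assignment, children)):
        timeline, onset = generate_admission(
            spec,
            illness,
            child,
            admission_id=f"adm-{i:05d}",
            patient_id=f"pat-{i:05d}",
            admit_time=_EPOCH + pd.Timedelta(hours=3 * i),
            table=table,
        )
        cohort.append((timeline, illness, onset))
    return cohort


def planted_labels(cohort) -> pd.DataFrame:
    """Long label frame (admission_id, illness, positive, onset_time) from the
    planted ground truth."""
    rows = []
    for timeline, illness, onset in cohort:
        for name in ILLNESSES:
            rows.append(
                {
                    "admission_id": timeline.admission_id,
                    "illness": name,
                    "positive": illness == name,
                    "onset_time": onset if illness == name else None,
                }
            )
    return pd.DataFrame(rows, columns=["admission_id", "illness", "positive", "onset_time"])


def write_cohort(cohort, events_path, labels_path) -> None:
    """Write events and planted labels as deterministic CSV files."""
    frames = []
    for timeline, _, _ in cohort:
        ev = timeline.events.copy()
        ev.insert(0, "admission_id", timeline.admission_id)
        ev.insert(0, "patient_id", timeline.patient_id)
        frames.append(ev)
    events = pd.concat(frames, ignore_index=True)
    events["timestamp"] = events["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    events.to_csv(events_path, index=False, float_format="%.6g")

    labels = planted_labels(cohort).copy()
    labels["onset_time"] = labels["onset_time"].map(
        lambda t: "" if t is None or pd.isna(t) else pd.Timestamp(t).strftime("%Y-%m-%dT%H:%M:%S")
    )
    labels.to_csv(labels_path, index=False)


def read_labels(path) -> pd.DataFrame:
    """Read a label CSV written by :func:`write_cohort` or the labeling CLI."""
    df = pd.read_csv(path, dtype={"admission_id": str, "illness": str})
    df["positive"] = df["positive"].astype(bool)
    df["onset_time"] = pd.to_datetime(df["onset_time"], errors="coerce", format="ISO8601")
    return df
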