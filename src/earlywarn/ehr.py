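"""Event-stream data model, hourly binning, and imputation.

An admission is a time-ordered sequence of (timestamp, parameter, value)
events.  Before prediction, the 24-hour observation window ending at the
prediction time is partitioned into one-hour bins; all observations of a
parameter falling in the same bin are averaged.  Bins are half-open intervals
``(start, end]`` with the last bin ending exactly at the prediction time, so
no future information can leak across the boundary.

Missing cells are filled by carry-forward within the window and, before the
first observation, by the per-parameter training-population median recorded
in a fitted :class:`Preprocessor`.
"""
from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .parameters import MARKER_EVENTS, load_parameter_table, parameter_names, vital_names

HOUR = pd.Timedelta(hours=1)

EVENT_COLUMNS = ["patient_id", "admission_id", "timestamp", "parameter", "value"]


@dataclasses.dataclass(frozen=True)
class EventRecord:
    """A single time-stamped clinical observation or marker event."""

    patient_id: str
    admission_id: str
    timestamp: pd.Timestamp
    parameter: str
    value: float


@dataclasses.dataclass
class AdmissionTimeline:
    """All events of one admission, ordered by time.

    ``events`` is a DataFrame with columns ``timestamp, parameter, value``.
    Events may precede ``admit_time`` (pre-admission laboratory history used
    by the habitual-creatinine baseline); no event may follow discharge.
    """

    admission_id: str
    patient_id: str
    admit_time: pd.Timestamp
    discharge_time: pd.Timestamp
    events: pd.DataFrame

    def __post_init__(self) -> None:
        if self.admit_time >= self.discharge_time:
            raise ValueError(
                f"admission {self.admission_id}: admit_time must precede discharge_time"
            )
        ev = self.events
        missing = {"timestamp", "parameter", "value"} - set(ev.columns)
        if missing:
            raise ValueError(f"events frame lacks columns: {sorted(missing)}")
        if not ev["timestamp"].is_monotonic_increasing:
            ev = ev.sort_values("timestamp", kind="stable").reset_index(drop=True)
        self.events = ev.reset_index(drop=True)

    def validate(self) -> None:
        """Strict invariant check: finite values, events not after discharge."""
        if not np.isfinite(self.events["value"].to_numpy(dtype=float)).all():
            raise ValueError(f"admission {self.admission_id}: non-finite event value")
        if len(self.events) and self.events["timestamp"].iloc[-1] > self.discharge_time:
            raise ValueError(f"admission {self.admission_id}: event after discharge")

    def records(self) -> Iterator[EventRecord]:
        for row in self.events.itertuples(index=False):
            yield EventRecord(
                self.patient_id, self.admission_id, row.timestamp, row.parameter, row.value
            )

    def parameter_events(self, parameter: str) -> tuple[np.ndarray, np.ndarray]:
        """(times, values) of one parameter, time-sorted; times as datetime64[ns]."""
        sel = self.events[self.events["parameter"] == parameter]
        return sel["timestamp"].to_numpy(), sel["value"].to_numpy(dtype=float)


@dataclasses.dataclass
class HourlyMatrix:
    """The binned observation window: T x F grid with an observation mask.

    ``values[t, f]`` is the mean of all observations of parameter ``f`` in
    hour bin ``t`` (NaN if none before imputation); ``mask[t, f]`` is True
    iff at least one observation fell in the bin.
    """

    values: np.ndarray
    mask: np.ndarray
    bin_end_times: pd.DatetimeIndex
    parameter_names: list[str]

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def prediction_time(self) -> pd.Timestamp:
        return self.bin_end_times[-1]


def read_events(
    path,
    table=None,
    strict: bool = False,
) -> list[AdmissionTimeline]:
    """Read a long-format events CSV and group it into admission timelines.

    The file must have a header ``patient_id,admission_id,timestamp,parameter,
    value`` with ISO-8601 timestamps.  Unknown parameter names are dropped with
    a warning (``strict=True`` raises).  Admission bounds are inferred from the
    event span: admit time is the first vital-sign event when vitals exist
    (pre-admission laboratory history may precede it), discharge is the last
    event.
    """
    table = load_parameter_table() if table is None else table
    known = set(parameter_names(table)) | set(MARKER_EVENTS)
    vitals = set(vital_names(table))

    df = pd.read_csv(path, dtype={"patient_id": str, "admission_id": str, "parameter": str})
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"events file lacks columns: {sorted(missing)}")

    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.isna() & df["value"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"non-numeric value {df['value'].iloc[row]!r} in row {row + 2} of {path}"
        )
    df["value"] = values
    times = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    if times.isna().any():
        row = int(np.flatnonzero(times.isna().to_numpy())[0])
        raise ValueError(
            f"unparseable timestamp {df['timestamp'].iloc[row]!r} in row {row + 2} of {path}"
        )
    df["timestamp"] = times

    unknown = ~df["parameter"].isin(known)
    if unknown.any():
        names = sorted(df.loc[unknown, "parameter"].unique())
        if strict:
            raise ValueError(f"unknown parameter names: {names}")
        warnings.warn(f"dropping events with unknown parameter names: {names}")
        df = df[~unknown]

    timelines = []
    for admission_id, group in df.groupby("admission_id", sort=True):
        group = group.sort_values("timestamp", kind="stable")
        patients = group["patient_id"].unique()
        if len(patients) != 1:
            raise ValueError(f"admission {admission_id} maps to multiple patients")
        vital_times = group.loc[group["parameter"].isin(vitals), "timestamp"]
        admit = vital_times.iloc[0] if len(vital_times) else group["timestamp"].iloc[0]
        discharge = group["timestamp"].iloc[-1]
        if admit >= discharge:
            discharge = admit + pd.Timedelta(minutes=1)
        timelines.append(
            AdmissionTimeline(
                admission_id=str(admission_id),
                patient_id=str(patients[0]),
                admit_time=admit,
                discharge_time=discharge,
                events=group[["timestamp", "parameter", "value"]].reset_index(drop=True),
            )
        )
    return timelines


def bin_hourly(
    timeline: AdmissionTimeline,
    prediction_time: pd.Timestamp,
    window_hours: int = 24,
    parameters: Sequence[str] | None = None,
) -> HourlyMatrix:
    """Aggregate the observation window ending at ``prediction_time`` into hourly bins.

    Bin ``t`` covers the half-open interval ``(end - (T-t) h, end - (T-t-1) h]``;
    each cell is the arithmetic mean of the parameter's observations in that
    hour.  Events outside the window (including anything after the prediction
    time) are ignored.
    """
    if parameters is None:
        parameters = parameter_names()
    parameters = list(parameters)
    if not parameters:
        raise ValueError("parameter list must not be empty")
    if window_hours < 1:
        raise ValueError("window_hours must be >= 1")
    T, F = int(window_hours), len(parameters)
    prediction_time = pd.Timestamp(prediction_time)
    window_start = prediction_time - T * HOUR

    ev = timeline.events
    ts = ev["timestamp"].to_numpy()
    in_window = (ts > np.datetime64(window_start)) & (ts <= np.datetime64(prediction_time))
    param_idx = pd.Index(parameters)
    codes = param_idx.get_indexer(ev["parameter"].to_numpy())
    keep = in_window & (codes >= 0)

    sums = np.zeros((T, F))
    counts = np.zeros((T, F))
    if keep.any():
        t_ns = ts[keep].astype("datetime64[ns]").astype(np.int64)
        start_ns = np.datetime64(window_start, "ns").astype(np.int64)
        offsets = t_ns - start_ns
        ns_per_hour = 3_600_000_000_000
        bins = (offsets + ns_per_hour - 1) // ns_per_hour - 1  # ceil(offset/h) - 1
        bins = np.clip(bins, 0, T - 1).astype(int)
        np.add.at(sums, (bins, codes[keep]), ev["value"].to_numpy(dtype=float)[keep])
        np.add.at(counts, (bins, codes[keep]), 1.0)

    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1.0), np.nan)
    bin_ends = pd.DatetimeIndex([window_start + (t + 1) * HOUR for t in range(T)])
    return HourlyMatrix(
        values=values,
        mask=counts > 0,
        bin_end_times=bin_ends,
        parameter_names=parameters,
    )


def impute(matrix: HourlyMatrix, medians: Mapping[str, float] | np.ndarray) -> HourlyMatrix:
    """Fill missing cells: carry-forward within the window, then population medians.

    ``medians`` maps parameter name to the training-population median (or is an
    array aligned with ``matrix.parameter_names``).  The observation mask is
    preserved unchanged so downstream consumers can distinguish observed from
    filled cells.
    """
    if isinstance(medians, np.ndarray):
        med = np.asarray(medians, dtype=float)
        if med.shape != (len(matrix.parameter_names),):
            raise ValueError("median array does not align with parameter_names")
    else:
        try:
            med = np.array([float(medians[p]) for p in matrix.parameter_names])
        except KeyError as exc:
            raise ValueError(
                f"no population median for parameter {exc.args[0]!r}; "
                "fit the preprocessing state on training data first"
            ) from None
    values = matrix.values.copy()
    for t in range(1, values.shape[0]):
        row = values[t]
        values[t] = np.where(np.isnan(row), values[t - 1], row)
    values = np.where(np.isnan(values), med[None, :], values)
    return HourlyMatrix(
        values=values,
        mask=matrix.mask.copy(),
        bin_end_times=matrix.bin_end_times,
        parameter_names=list(matrix.parameter_names),
    )


class Preprocessor:
    """Fitted imputation + per-parameter standardization state.

    Medians are computed from observed cells of the training windows;
    mean/standard deviation are computed from the imputed training windows and
    applied as a z-score after imputation.  Standardized values are winsorized
    at ``clip_sigma`` standard deviations: several laboratory analytes are
    heavily right-skewed, and a single extreme draw would otherwise dominate a
    whole carried-forward window.  The state is serialized alongside trained
    models so test-fold statistics never leak into preprocessing.
    """

    def __init__(self, parameters: Sequence[str], clip_sigma: float = 5.0):
        self.parameters = list(parameters)
        self.clip_sigma = float(clip_sigma)
        self.medians_: np.ndarray | None = None
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None

    @property
    def is_fitted(self) -> bool:
        return self.medians_ is not None

    def fit(self, windows: Iterable[HourlyMatrix]) -> "Preprocessor":
        windows = list(windows)
        if not windows:
            raise ValueError("cannot fit preprocessing state on zero windows")
        stacked = np.stack([w.values for w in windows])  # (N, T, F)
        flat = stacked.reshape(-1, stacked.shape[-1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(flat, axis=0)
        never_observed = np.isnan(med)
        if never_observed.any():
            warnings.warn(
                "parameters never observed in training windows get median 0: "
                f"{[self.parameters[i] for i in np.flatnonzero(never_observed)]}"
            )
            med = np.where(never_observed, 0.0, med)
        self.medians_ = med
        imputed = np.stack([impute(w, med).values for w in windows]).reshape(-1, len(med))
        self.mean_ = imputed.mean(axis=0)
        self.std_ = np.maximum(imputed.std(axis=0), 1e-6)
        return self

    def transform(self, matrix: HourlyMatrix) -> np.ndarray:
        """Impute and z-score one window; returns a dense (T, F) float array."""
        if not self.is_fitted:
            raise ValueError("preprocessing state not fitted; call fit() first")
        if list(matrix.parameter_names) != self.parameters:
            raise ValueError("window parameters do not match fitted preprocessing state")
        dense = impute(matrix, self.medians_).values
        z = (dense - self.mean_) / self.std_
        return np.clip(z, -self.clip_sigma, self.clip_sigma)

    def to_json(self) -> str:
        if not self.is_fitted:
            raise ValueError("preprocessing state not fitted")
        return json.dumps(
            {
                "parameters": self.parameters,
                "clip_sigma": self.clip_sigma,
                "medians": self.medians_.tolist(),
                "mean": self.mean_.tolist(),
                "std": self.std_.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Preprocessor":
        data = json.loads(text)
        obj = cls(data["parameters"], clip_sigma=data.get("clip_sigma", 5.0))
        obj.medians_ = np.array(data["medians"], dtype=float)
        obj.mean_ = np.array(data["mean"], dtype=float)
        obj.std_ = np.array(data["std"], dtype=float)
        return obj
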