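"""Clinical parameter vocabulary and per-outcome percentile profiles.

The default vocabulary comprises 27 laboratory parameters and 6 vital signs
(33 model input channels), plus four marker event types used only by the
outcome labelers (antibiotic administration, culture sampling, NIV, CPAP).
Each parameter carries per-outcome 5th/50th/95th percentile triples for the
outcome-positive and outcome-negative admission populations, which drive the
synthetic cohort generator.
"""
from __future__ import annotations

import dataclasses
from importlib import resources
from typing import Mapping, Sequence

import yaml

ILLNESSES = ("sepsis", "aki", "ali")

#: Marker event names (labeler inputs, not model channels).
MARKER_EVENTS = ("antibiotic_administration", "culture_sample", "niv", "cpap")


@dataclasses.dataclass(frozen=True)
class ParameterSpec:
    """One clinical parameter: identity, units, and sampling metadata."""

    name: str
    unit: str
    kind: str  # "lab" or "vital"
    scale: str  # "linear" or "log" (split-normal fitting scale)
    clip_min: float | None
    sampling_weight: float
    #: (illness, "positive"/"negative") -> (p5, p50, p95)
    quantiles: Mapping[tuple[str, str], tuple[float, float, float]]

    def triple(self, illness: str, cls: str) -> tuple[float, float, float]:
        return self.quantiles[(illness, cls)]


def load_parameter_table(path: str | None = None) -> list[ParameterSpec]:
    """Load the parameter vocabulary, by default from the packaged profiles file."""
    if path is None:
        text = (resources.files("earlywarn") / "data" / "profiles.yaml").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    table: list[ParameterSpec] = []
    for entry in raw["parameters"]:
        quantiles: dict[tuple[str, str], tuple[float, float, float]] = {}
        for illness in ILLNESSES:
            prof = entry["profiles"][illness]
            for cls in ("positive", "negative"):
                p5, p50, p95 = (float(v) for v in prof[cls])
                if not p5 <= p50 <= p95:
                    raise ValueError(
                        f"profile for {entry['name']} ({illness}/{cls}) is not ordered"
                    )
                quantiles[(illness, cls)] = (p5, p50, p95)
        table.append(
            ParameterSpec(
                name=str(entry["name"]),
                unit=str(entry["unit"]),
                kind=str(entry["kind"]),
                scale=str(entry.get("scale", "linear")),
                clip_min=(None if entry.get("min") is None else float(entry["min"])),
                sampling_weight=float(entry.get("weight", 0.0)),
                quantiles=quantiles,
            )
        )
    return table


def parameter_names(table: Sequence[ParameterSpec] | None = None) -> list[str]:
    """The 33 model input channel names, in canonical (file) order."""
    table = load_parameter_table() if table is None else list(table)
    return [p.name for p in table]


def vital_names(table: Sequence[ParameterSpec] | None = None) -> list[str]:
    table = load_parameter_table() if table is None else list(table)
    return [p.name for p in table if p.kind == "vital"]


def lab_names(table: Sequence[ParameterSpec] | None = None) -> list[str]:
    table = load_parameter_table() if table is None else list(table)
    return [p.name for p in table if p.kind == "lab"]
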