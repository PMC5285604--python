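"""Feature schema for the ICU cohort.

The predictor set mirrors a widely used first-24-hour ICU summary: demographics,
administrative admission descriptors, windowed vital-sign extrema, first-day lab
extrema, two intervention flags, worst Glasgow Coma Scale and per-window urinary
output — 75 predictors in total, plus a binary 30-day mortality outcome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "FeatureEntry",
    "FeatureSchema",
    "make_table1_schema",
    "OUTCOME_COLUMN",
    "VITAL_SIGNALS",
    "LAB_SIGNALS",
    "N_WINDOWS",
]

OUTCOME_COLUMN = "death_30d"

KINDS = ("numeric", "binary", "categorical")
GROUPS = ("demographics", "administrative", "vitals", "labs", "intervention", "other")

#: vital signs summarized as min/max in each 6-hour window of the first 24 h
VITAL_SIGNALS = ("heart_rate", "mean_bp", "systolic_bp", "spo2", "resp_rate", "temperature")
#: labs summarized as min/max over the first 24 h
LAB_SIGNALS = ("hematocrit", "wbc", "glucose", "hco3", "potassium", "sodium", "bun", "creatinine")
N_WINDOWS = 4


@dataclass(frozen=True)
class FeatureEntry:
    name: str
    kind: str  # numeric | binary | categorical
    levels: tuple[str, ...] = ()
    unit: str = ""
    group: str = "other"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown feature group {self.group!r} for {self.name!r}")
        if self.kind == "categorical" and len(self.levels) < 2:
            raise ValueError(f"categorical feature {self.name!r} needs >=2 levels")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered predictor entries; the outcome column is fixed (`death_30d`)."""

    entries: tuple[FeatureEntry, ...]
    outcome: str = OUTCOME_COLUMN

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        if self.outcome in names:
            raise ValueError("outcome column collides with a predictor name")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def n_predictors(self) -> int:
        return len(self.entries)

    def __getitem__(self, name: str) -> FeatureEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def group_names(self, group: str) -> list[str]:
        return [e.name for e in self.entries if e.group == group]

    def subset(self, names: Iterable[str]) -> "FeatureSchema":
        keep = set(names)
        return FeatureSchema(tuple(e for e in self.entries if e.name in keep), self.outcome)

    # -- encoded (model-facing) column layout ---------------------------------
    def encoded_columns(self, drop_first: bool = True) -> list[str]:
        """Column names after one-hot encoding (reference level = first declared)."""
        cols: list[str] = []
        for e in self.entries:
            if e.kind == "categorical":
                levels = e.levels[1:] if drop_first else e.levels
                cols.extend(f"{e.name}={lv}" for lv in levels)
            else:
                cols.append(e.name)
        return cols

    # -- JSON round-trip ------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "outcome": self.outcome,
            "entries": [
                {
                    "name": e.name,
                    "kind": e.kind,
                    "levels": list(e.levels),
                    "unit": e.unit,
                    "group": e.group,
                }
                for e in self.entries
            ],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FeatureSchema":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        entries = tuple(
            FeatureEntry(
                name=d["name"],
                kind=d["kind"],
                levels=tuple(d.get("levels", ())),
                unit=d.get("unit", ""),
                group=d.get("group", "other"),
            )
            for d in doc["entries"]
        )
        return cls(entries, doc.get("outcome", OUTCOME_COLUMN))


def _windowed(signal: str, stat: str, window: int) -> str:
    return f"{signal}_{stat}_w{window}"


def make_table1_schema() -> FeatureSchema:
    """Build the 75-predictor first-24-hour ICU schema.

    Counts per group: demographics 2, administrative 2 (categoricals),
    vitals 48 (6 signals x min/max x 4 windows), labs 16 (8 x min/max),
    intervention 2, worst GCS 1, urinary output 4.
    """
    entries: list[FeatureEntry] = [
        FeatureEntry("age", "numeric", unit="years", group="demographics"),
        FeatureEntry("gender_male", "binary", group="demographics"),
        FeatureEntry(
            "admission_type",
            "categorical",
            levels=("elective", "urgent", "emergency"),
            group="administrative",
        ),
        FeatureEntry(
            "icu_service_type",
            "categorical",
            levels=("MICU", "SICU", "CCU", "CSRU"),
            group="administrative",
        ),
    ]
    units = {
        "heart_rate": "bpm",
        "mean_bp": "mmHg",
        "systolic_bp": "mmHg",
        "spo2": "%",
        "resp_rate": "breaths/min",
        "temperature": "degC",
    }
    for signal in VITAL_SIGNALS:
        for window in range(1, N_WINDOWS + 1):
            for stat in ("min", "max"):
                entries.append(
                    FeatureEntry(_windowed(signal, stat, window), "numeric",
                                 unit=units[signal], group="vitals")
                )
    lab_units = {
        "hematocrit": "%", "wbc": "K/uL", "glucose": "mg/dL", "hco3": "mEq/L",
        "potassium": "mEq/L", "sodium": "mEq/L", "bun": "mg/dL", "creatinine": "mg/dL",
    }
    for signal in LAB_SIGNALS:
        for stat in ("min", "max"):
            entries.append(
                FeatureEntry(f"{signal}_{stat}", "numeric", unit=lab_units[signal], group="labs")
            )
    entries.append(FeatureEntry("vasopressor", "binary", group="intervention"))
    entries.append(FeatureEntry("mech_vent_or_cpap", "binary", group="intervention"))
    entries.append(FeatureEntry("gcs_worst", "numeric", unit="points", group="other"))
    for window in range(1, N_WINDOWS + 1):
        entries.append(
            FeatureEntry(f"urine_output_w{window}", "numeric", unit="mL", group="other")
        )
    schema = FeatureSchema(tuple(entries))
    assert schema.n_predictors == 75
    return schema
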