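"""Cohort data model, CSV readers/writers and model-facing feature encoding.

A cohort is one row per ICU admission (treated as an independent "patient"),
the schema's predictor columns in order, and a 0/1 30-day-mortality outcome.
Rows with any missing value are excluded at read time (complete-case rule);
the exclusion count is kept on the table and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import FeatureSchema, OUTCOME_COLUMN

__all__ = ["CohortTable", "CohortValidationError", "read_cohort", "write_cohort", "FeatureEncoder"]

log = logging.getLogger(__name__)


class CohortValidationError(ValueError):
    pass


@dataclass
class CohortTable:
    """Validated feature table plus binary outcome.

    ``df`` holds the predictor columns in schema order followed by the outcome
    column; categorical features are stored as level strings. ``patient_index``
    is the stable 0..n-1 identifier used by similarity ranking.
    """

    schema: FeatureSchema
    df: pd.DataFrame
    n_excluded: int = 0

    def __post_init__(self) -> None:
        expected = self.schema.names + [self.schema.outcome]
        if list(self.df.columns) != expected:
            self.df = self.df.reindex(columns=expected)
        self.df = self.df.reset_index(drop=True)
        _validate(self.df, self.schema)

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def patient_index(self) -> np.ndarray:
        return np.arange(self.n)

    @property
    def features(self) -> pd.DataFrame:
        return self.df[self.schema.names]

    @property
    def outcome(self) -> np.ndarray:
        return self.df[self.schema.outcome].to_numpy(dtype=int)

    def take(self, indices) -> "CohortTable":
        return CohortTable(self.schema, self.df.iloc[np.asarray(indices)].reset_index(drop=True))

    def equals(self, other: "CohortTable") -> bool:
        if self.schema.names != other.schema.names or self.n != other.n:
            return False
        for e in self.schema.entries:
            a, b = self.df[e.name], other.df[e.name]
            if e.kind == "numeric":
                if not np.allclose(a.to_numpy(float), b.to_numpy(float), rtol=0, atol=1e-9):
                    return False
            elif not (a.astype(str).to_numpy() == b.astype(str).to_numpy()).all():
                return False
        return bool((self.outcome == other.outcome).all())


def _validate(df: pd.DataFrame, schema: FeatureSchema) -> None:
    if df.isna().any().any():
        raise CohortValidationError("cohort contains missing values after filtering")
    for e in schema.entries:
        col = df[e.name]
        if e.kind == "numeric":
            vals = col.to_numpy(dtype=float)
            if not np.isfinite(vals).all():
                raise CohortValidationError(f"non-finite values in numeric feature {e.name!r}")
        elif e.kind == "binary":
            vals = col.to_numpy()
            if not np.isin(vals, [0, 1]).all():
                raise CohortValidationError(f"binary feature {e.name!r} has values outside {{0,1}}")
        else:
            bad = set(col.astype(str)) - set(e.levels)
            if bad:
                raise CohortValidationError(
                    f"unknown level(s) {sorted(bad)} in categorical feature {e.name!r}"
                )
    out = df[schema.outcome].to_numpy()
    if not np.isin(out, [0, 1]).all():
        raise CohortValidationError(f"outcome {schema.outcome!r} must be 0/1")


def read_cohort(path: str | Path, schema: FeatureSchema) -> CohortTable:
    """Read and validate a cohort CSV; complete cases only.

    Rows with any missing cell are dropped (their count is logged and stored
    as ``n_excluded``). Unknown or absent columns, non-coercible values,
    unknown categorical levels and non-binary outcomes raise
    :class:`CohortValidationError`.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=True)
    expected = schema.names + [schema.outcome]
    unknown = set(raw.columns) - set(expected)
    if unknown:
        raise CohortValidationError(f"unknown column(s): {sorted(unknown)}")
    missing_cols = set(expected) - set(raw.columns)
    if missing_cols:
        raise CohortValidationError(f"missing column(s): {sorted(missing_cols)}")
    raw = raw[expected]
    n_before = len(raw)
    raw = raw.replace("", np.nan).dropna(axis=0, how="any")
    n_excluded = n_before - len(raw)
    if n_excluded:
        log.info("excluded %d row(s) with missing data", n_excluded)

    df = pd.DataFrame(index=raw.index)
    for e in schema.entries:
        col = raw[e.name]
        if e.kind in ("numeric", "binary"):
            try:
                vals = pd.to_numeric(col)
            except (ValueError, TypeError) as exc:
                raise CohortValidationError(f"non-numeric value in {e.name!r}: {exc}") from exc
            df[e.name] = vals.astype(float if e.kind == "numeric" else int)
        else:
            df[e.name] = col.astype(str)
    try:
        df[schema.outcome] = pd.to_numeric(raw[schema.outcome]).astype(int)
    except (ValueError, TypeError) as exc:
        raise CohortValidationError(f"non-numeric outcome value: {exc}") from exc
    return CohortTable(schema, df.reset_index(drop=True), n_excluded=n_excluded)


def write_cohort(cohort: CohortTable, path: str | Path) -> Path:
    """Write the cohort as CSV with columns in schema order (round-trip safe)."""
    path = Path(path)
    cohort.df.to_csv(path, index=False)
    return path


class FeatureEncoder:
    """Schema-driven numeric encoding of predictor rows.

    Numeric and binary features pass through as floats; categorical features
    become 0/1 dummies for every level after the first declared (reference)
    level. The column layout depends only on the schema, never on which levels
    happen to occur in a given subset, so a model fitted on a small
    neighborhood can score any schema-conforming row.
    """

    def __init__(self, schema: FeatureSchema, predictors: list[str] | None = None,
                 drop_first: bool = True):
        self.schema = schema if predictors is None else schema.subset(predictors)
        self.drop_first = drop_first
        self.columns = self.schema.encoded_columns(drop_first=drop_first)

    @property
    def n_features(self) -> int:
        return len(self.columns)

    def transform(self, features: pd.DataFrame) -> np.ndarray:
        n = len(features)
        X = np.empty((n, self.n_features), dtype=float)
        j = 0
        for e in self.schema.entries:
            col = features[e.name]
            if e.kind == "categorical":
                vals = col.astype(str).to_numpy()
                levels = e.levels[1:] if self.drop_first else e.levels
                for lv in levels:
                    X[:, j] = (vals == lv).astype(float)
                    j += 1
            else:
                X[:, j] = col.to_numpy(dtype=float)
                j += 1
        return X


@dataclass
class Standardizer:
    """Column-wise z-scaling with train-set statistics (zero-sd columns pass through)."""

    mean: np.ndarray = field(default_factory=lambda: np.array([]))
    scale: np.ndarray = field(default_factory=lambda: np.array([]))

    def fit(self, X: np.ndarray) -> "Standardizer":
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale
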