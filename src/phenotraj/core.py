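"""Domain types, CSV I/O, feature normalization and sequence utilities.

The central container is :class:`ObservationTable`: one row per clinical
encounter, carrying the subject identifier, time since the subject's first
visit (days), a binary disease-stage label (1 = complication present) and a
fixed-order vector of clinical features.  Row indices are 0-based and stable
after the initial (subject, time) sort; every downstream stage (Mapper node
membership, pseudo-time-series paths) refers to rows by these indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("phenotraj")


class SchemaError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


@dataclass
class ObservationTable:
    """Encounter-level observations for a cohort.

    Attributes
    ----------
    subject_ids : array of str, one per encounter row.
    time_days : float array, days since the subject's first visit (>= 0).
    labels : int array in {0, 1}, the disease-stage marker.
    features : 2-D float array, one fixed-order feature vector per row.
    feature_names : ordered feature names matching ``features`` columns.
    """

    subject_ids: np.ndarray
    time_days: np.ndarray
    labels: np.ndarray
    features: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.time_days = np.asarray(self.time_days, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        n = len(self.subject_ids)
        if not (len(self.time_days) == len(self.labels) == self.features.shape[0] == n):
            raise ValueError("field lengths disagree")
        if self.features.shape[1] != len(self.feature_names):
            raise ValueError("feature matrix width does not match feature_names")
        if n and (not np.all(np.isfinite(self.time_days)) or np.any(self.time_days < 0)):
            raise ValueError("time_days must be finite and non-negative")
        if n and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    @property
    def n_rows(self) -> int:
        return len(self.subject_ids)

    def subjects(self) -> list[str]:
        """Unique subject ids in first-appearance (sorted) order."""
        seen: dict[str, None] = {}
        for s in self.subject_ids:
            seen.setdefault(s, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"subject": self.subject_ids, "time_days": self.time_days, "label": self.labels}
        )
        for j, name in enumerate(self.feature_names):
            df[name] = self.features[:, j]
        return df


@dataclass
class NormalizationSpec:
    """Per-feature min/max recorded on a training table (minmax-symmetric).

    ``transform`` maps a feature linearly so that min -> -1 and max -> +1;
    ``inverse`` undoes it.  Constant features are passed through at 0.
    """

    feature_names: list[str]
    mins: np.ndarray
    maxs: np.ndarray
    method: str = "minmax-symmetric"

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if np.any(self.maxs < self.mins):
            raise ValueError("max < min in normalization spec")

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        span = self.maxs - self.mins
        out = np.zeros_like(X)
        ok = span > 0
        out[:, ok] = 2.0 * (X[:, ok] - self.mins[ok]) / span[ok] - 1.0
        return out

    def inverse(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        span = self.maxs - self.mins
        out = np.tile(self.mins, (X.shape[0], 1))
        ok = span > 0
        out[:, ok] = (X[:, ok] + 1.0) / 2.0 * span[ok] + self.mins[ok]
        return out


@dataclass
class Schema:
    """Column-name mapping for reading an observation CSV."""

    subject_col: str = "subject"
    time_col: str = "time"
    label_col: str = "label"
    feature_cols: Sequence[str] = field(default_factory=list)

    @classmethod
    def from_mapping(cls, m: Mapping[str, object]) -> "Schema":
        feats = m.get("feature_cols", [])
        if isinstance(feats, str):
            feats = [c.strip() for c in feats.split(",") if c.strip()]
        return cls(
            subject_col=str(m.get("subject_col", "subject")),
            time_col=str(m.get("time_col", "time")),
            label_col=str(m.get("label_col", "label")),
            feature_cols=list(feats),
        )


def load_observations(path, schema: Schema | Mapping[str, object] | None = None) -> ObservationTable:
    """Read an encounter CSV and return a sorted :class:`ObservationTable`.

    Rows are sorted by (subject, time); the resulting 0-based row index is
    the stable coordinate used by all later stages.  Rows with any missing
    feature are dropped (and counted in the log); duplicate (subject, time)
    pairs are retained.

    Raises
    ------
    SchemaError
        If a required column is absent, or a feature cell is non-numeric.
    """
    if schema is None:
        schema = Schema()
    elif not isinstance(schema, Schema):
        schema = Schema.from_mapping(schema)

    df = pd.read_csv(path)
    feature_cols = list(schema.feature_cols)
    if not feature_cols:
        reserved = {schema.subject_col, schema.time_col, schema.label_col}
        feature_cols = [c for c in df.columns if c not in reserved]
    required = [schema.subject_col, schema.time_col, schema.label_col, *feature_cols]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} not found in {path}")
    for col in [schema.time_col, schema.label_col, *feature_cols]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(f"non-numeric value in column {col!r} at data row {row}")
        df[col] = coerced

    n_before = len(df)
    df = df.dropna(subset=[schema.time_col, schema.label_col, *feature_cols])
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.warning("load_observations: dropped %d rows with missing values", n_dropped)

    df = df.sort_values([schema.subject_col, schema.time_col], kind="mergesort").reset_index(drop=True)
    dup = df.duplicated([schema.subject_col, schema.time_col]).sum()
    if dup:
        logger.info("load_observations: %d duplicate (subject, time) rows retained", dup)

    table = ObservationTable(
        subject_ids=df[schema.subject_col].astype(str).to_numpy(dtype=object),
        time_days=df[schema.time_col].to_numpy(dtype=float),
        labels=df[schema.label_col].to_numpy(dtype=int),
        features=df[feature_cols].to_numpy(dtype=float),
        feature_names=feature_cols,
    )
    logger.info("load_observations: %d rows, %d features from %s", table.n_rows, len(feature_cols), path)
    return table


def write_observations(table: ObservationTable, path) -> None:
    """Write a table to CSV so that ``load_observations`` round-trips it."""
    table.to_frame().rename(columns={"time_days": "time", "subject": "subject", "label": "label"}).to_csv(
        path, index=False
    )


def normalize_features(
    table: ObservationTable, spec: NormalizationSpec | None = None
) -> tuple[ObservationTable, NormalizationSpec]:
    """Scale every feature to [-1, +1] by symmetric min-max.

    x' = 2 (x - min) / (max - min) - 1, with min/max taken from ``spec``
    when supplied (out-of-range inputs then map outside [-1, 1]) or from
    the table itself.  Binary features come out as exactly {-1, +1};
    constant features pass through at 0 with a logged warning.
    """
    if spec is None:
        mins = table.features.min(axis=0) if table.n_rows else np.zeros(len(table.feature_names))
        maxs = table.features.max(axis=0) if table.n_rows else np.zeros(len(table.feature_names))
        spec = NormalizationSpec(list(table.feature_names), mins, maxs)
        const = np.flatnonzero(spec.maxs == spec.mins)
        for j in const:
            logger.warning("normalize_features: feature %r is constant; passed through at 0",
                           table.feature_names[j])
    out = ObservationTable(
        subject_ids=table.subject_ids.copy(),
        time_days=table.time_days.copy(),
        labels=table.labels.copy(),
        features=spec.transform(table.features),
        feature_names=list(table.feature_names),
    )
    return out, spec


def compress_sequence(seq: Sequence) -> list:
    """Collapse consecutive duplicates, preserving order.

    Non-consecutive repeats are kept: a subject that leaves a node and
    later returns contributes the node twice to its trajectory.
    """
    out: list = []
    for item in seq:
        if not out or out[-1] != item:
            out.append(item)
    return out
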