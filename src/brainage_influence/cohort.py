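"""Subject-level cohort tables: ages, clinical labels and named numeric features.

A :class:`CohortTable` is the common currency of the package: every downstream
stage (mutual-information ranking, brain-age model fitting, delta-based
classification) consumes one.  Validation is strict — missing feature values
are rejected rather than imputed, ages must be positive and finite, and
subject identifiers must be unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortTable",
    "GroupPair",
    "CohortSchema",
    "SchemaError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "subset_by_labels",
]


class SchemaError(ValueError):
    """A declared column is missing from the input file."""


class CohortValidationError(ValueError):
    """A cohort invariant is violated (bad cell, duplicate id, bad age...)."""


def _coerce_numeric(series: pd.Series) -> pd.Series:
    """Parse a column to float64; unparseable cells become NaN.

    String cells go through Python ``float()`` (correctly-rounded), so CSV
    round-trips are exact to the last ulp.
    """
    if series.dtype.kind in "fiu":
        return series.astype(float)
    out = np.empty(len(series), dtype=float)
    for i, v in enumerate(series):
        try:
            out[i] = float(v)
        except (TypeError, ValueError):
            out[i] = np.nan
    return pd.Series(out, index=series.index)


@dataclass(frozen=True)
class CohortSchema:
    """Column-name mapping for reading subject-level CSV files.

    Defaults follow common tabular exports: ``subject_id``, ``age``,
    ``diagnosis``.  If ``feature_columns`` is None, every column other than
    the id/age/label columns is treated as a feature, in file order.
    """

    id_column: str = "subject_id"
    age_column: str = "age"
    label_column: str = "diagnosis"
    feature_columns: Sequence[str] | None = None


@dataclass(frozen=True)
class GroupPair:
    """A two-group clinical comparison, e.g. CN vs AD or sMCI vs pMCI.

    ``control_label`` names the group used to train the brain-age model
    (cognitively normal by default); it need not be one of the two compared
    groups.
    """

    group_a: str
    group_b: str
    control_label: str = "CN"

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError(f"group_a and group_b must differ (both {self.group_a!r})")

    @property
    def labels(self) -> tuple[str, str]:
        return (self.group_a, self.group_b)

    def __str__(self) -> str:  # used in output file names / curve labels
        return f"{self.group_a}_vs_{self.group_b}"


class CohortTable:
    """Validated table of subjects with age, clinical label and features.

    Parameters
    ----------
    data
        DataFrame with one row per subject, containing an ``age`` column,
        a ``label`` column and one column per feature.  The index holds the
        subject identifiers.
    feature_names
        Ordered feature column names.  Order is preserved end-to-end so that
        rankings and reports are stable with respect to the input file.
    """

    def __init__(self, data: pd.DataFrame, feature_names: Sequence[str]):
        feature_names = list(feature_names)
        if not feature_names:
            raise CohortValidationError("a cohort must declare at least one feature")
        missing = [c for c in ["age", "label", *feature_names] if c not in data.columns]
        if missing:
            raise CohortValidationError(f"cohort frame lacks columns: {missing}")
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise CohortValidationError(f"duplicate subject_id values: {dupes}")
        if len(data) == 0:
            raise CohortValidationError("cohort has no subjects")

        ages = _coerce_numeric(data["age"])
        bad_age = data.index[~(np.isfinite(ages) & (ages > 0))].tolist()
        if bad_age:
            raise CohortValidationError(
                f"ages must be positive and finite; offending subjects: {bad_age}"
            )
        parsed_features = {}
        for name in feature_names:
            col = _coerce_numeric(data[name])
            bad = data.index[~np.isfinite(col)].tolist()
            if bad:
                raise CohortValidationError(
                    f"feature {name!r} has missing or non-numeric values for "
                    f"subjects: {bad}"
                )
            parsed_features[name] = col

        frame = data[["age", "label", *feature_names]].copy()
        frame["age"] = ages.astype(float)
        frame["label"] = frame["label"].astype(str)
        for name, col in parsed_features.items():
            frame[name] = col
        frame.index = frame.index.astype(str)
        frame.index.name = "subject_id"
        self._frame = frame
        self._feature_names = feature_names

    # -- accessors ---------------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying (age, label, features) DataFrame, indexed by subject."""
        return self._frame

    @property
    def feature_names(self) -> list[str]:
        return list(self._feature_names)

    @property
    def subject_ids(self) -> list[str]:
        return self._frame.index.tolist()

    @property
    def ages(self) -> pd.Series:
        return self._frame["age"]

    @property
    def labels(self) -> pd.Series:
        return self._frame["label"]

    @property
    def label_set(self) -> set[str]:
        return set(self._frame["label"].unique())

    @property
    def n_subjects(self) -> int:
        return len(self._frame)

    def features(self, names: Sequence[str] | None = None) -> pd.DataFrame:
        """Feature matrix; ``names`` selects a subset in *cohort* column order.

        Selecting in cohort order (rather than the order of ``names``) makes
        model fits independent of how a feature subset was assembled, so two
        rankings that end up with the same set of features produce identical
        design matrices.
        """
        if names is None:
            return self._frame[self._feature_names]
        names = set(names)
        unknown = names - set(self._feature_names)
        if unknown:
            raise KeyError(f"unknown features: {sorted(unknown)}")
        ordered = [f for f in self._feature_names if f in names]
        return self._frame[ordered]

    def equals(self, other: "CohortTable") -> bool:
        return (
            self._feature_names == other._feature_names
            and self._frame.equals(other._frame)
        )

    def __repr__(self) -> str:
        counts = self._frame["label"].value_counts().to_dict()
        return (
            f"CohortTable(n={self.n_subjects}, features={len(self._feature_names)}, "
            f"groups={counts})"
        )


def read_cohort(path: str | Path, schema: CohortSchema | Mapping | None = None) -> CohortTable:
    """Read a subject-level CSV into a validated :class:`CohortTable`.

    Raises :class:`SchemaError` if a declared column is absent and
    :class:`CohortValidationError` (naming the subject) for bad cells.
    """
    if schema is None:
        schema = CohortSchema()
    elif isinstance(schema, Mapping):
        schema = CohortSchema(**dict(schema))

    raw = pd.read_csv(path, dtype=str, encoding="utf-8")
    for col in (schema.id_column, schema.age_column, schema.label_column):
        if col not in raw.columns:
            raise SchemaError(f"required column {col!r} not found in {path}")

    if schema.feature_columns is None:
        reserved = {schema.id_column, schema.age_column, schema.label_column}
        feature_cols = [c for c in raw.columns if c not in reserved]
    else:
        feature_cols = list(schema.feature_columns)
        absent = [c for c in feature_cols if c not in raw.columns]
        if absent:
            raise SchemaError(f"declared feature columns not found: {absent}")
    if not feature_cols:
        raise SchemaError(f"no feature columns found in {path}")

    ids = raw[schema.id_column]
    if ids.isna().any():
        raise CohortValidationError("empty subject identifier encountered")
    if ids.duplicated().any():
        raise CohortValidationError(
            f"duplicate subject_id values: {ids[ids.duplicated()].unique().tolist()}"
        )

    frame = raw.set_index(schema.id_column)
    frame = frame.rename(
        columns={schema.age_column: "age", schema.label_column: "label"}
    )
    return CohortTable(frame, feature_cols)


def write_cohort(
    cohort: CohortTable,
    path: str | Path,
    schema: CohortSchema | None = None,
) -> Path:
    """Write a cohort as CSV; round-trips losslessly through :func:`read_cohort`."""
    if schema is None:
        schema = CohortSchema()
    path = Path(path)
    out = cohort.frame.reset_index()
    out = out.rename(
        columns={
            "subject_id": schema.id_column,
            "age": schema.age_column,
            "label": schema.label_column,
        }
    )
    # repr-based float formatting: read(write(c)) == c exactly
    out.to_csv(path, index=False, encoding="utf-8")
    return path


def subset_by_labels(cohort: CohortTable, labels: Iterable[str]) -> CohortTable:
    """Rows whose clinical label is in ``labels``; feature set unchanged."""
    labels = set(labels)
    unknown = labels - cohort.label_set
    if unknown:
        raise KeyError(
            f"labels {sorted(unknown)} not present in cohort (has {sorted(cohort.label_set)})"
        )
    mask = cohort.labels.isin(labels)
    return CohortTable(cohort.frame.loc[mask], cohort.feature_names)
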