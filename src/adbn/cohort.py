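"""Subject-visit cohort tables: I/O, validation, complete-case filtering and
assembly of the longitudinal analysis groups.

A cohort table holds one row per subject-visit. Mandatory columns are
``subject_id``, ``visit`` (BL/M18/M36/M54), ``cdr`` and ``diagnosis``;
the remaining columns are typed by a data dictionary
(:mod:`adbn.dictionary`). Missing values are a single sentinel (NaN / NA)
distinct from every category label; the pipeline is complete-case and never
imputes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dictionary import (
    CDR_SCORES,
    DIAGNOSES,
    VISITS,
    FeatureSpec,
    feature_map,
    lookup,
    validate_dictionary,
)
from .errors import IntegrityError, SchemaError

MANDATORY_COLUMNS = ("subject_id", "visit", "cdr", "diagnosis")

LATER_VISITS = ("M18", "M36", "M54")


@dataclass
class CohortTable:
    """A validated subject-visit table plus its data dictionary."""

    df: pd.DataFrame
    dictionary: list[FeatureSpec]

    def __post_init__(self):
        validate_dictionary(self.dictionary)
        validate_cohort(self.df, self.dictionary)

    @property
    def feature_names(self) -> list[str]:
        return [s.name for s in self.dictionary]

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "CohortTable":
        return CohortTable(self.df.copy(), list(self.dictionary))


@dataclass
class GroupAssignment:
    """Row indices (labels of ``df.index``) of one analysis group.

    Group 1: all subjects complete at baseline plus all subjects complete at
    at least one later visit (sets of subjects need not overlap).
    Group 2: subjects complete at baseline AND at >=1 later visit; one
    baseline row and the earliest complete later row per subject.
    Group 3: subjects complete at all four visits.
    """

    group_id: int
    baseline_rows: list = field(default_factory=list)
    later_rows: list = field(default_factory=list)


def validate_cohort(df: pd.DataFrame, dictionary: list[FeatureSpec]) -> None:
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    dupes = df.duplicated(subset=["subject_id", "visit"])
    if dupes.any():
        pairs = df.loc[dupes, ["subject_id", "visit"]].values.tolist()
        raise IntegrityError(f"duplicate (subject_id, visit) pairs: {pairs}")
    bad_visit = ~df["visit"].isin(VISITS)
    if bad_visit.any():
        raise IntegrityError(
            f"unknown visit labels: {sorted(df.loc[bad_visit, 'visit'].unique())}"
        )
    cdr = pd.to_numeric(df["cdr"], errors="coerce")
    present = cdr.notna()
    bad_cdr = present & ~cdr.isin(CDR_SCORES)
    if bad_cdr.any():
        raise IntegrityError(
            f"CDR values outside {CDR_SCORES}: "
            f"{sorted(cdr[bad_cdr].unique())}"
        )
    diag = df["diagnosis"]
    bad_diag = diag.notna() & ~diag.isin(DIAGNOSES)
    if bad_diag.any():
        raise IntegrityError(
            f"unknown diagnosis labels: {sorted(diag[bad_diag].unique())}"
        )
    fmap = feature_map(dictionary)
    for name, spec in fmap.items():
        if name == "cdr" or name not in df.columns:
            continue
        if spec.kind in ("categorical", "ordinal"):
            col = df[name]
            bad = col.notna() & ~col.isin(spec.categories)
            if bad.any():
                raise IntegrityError(
                    f"{name}: values outside declared categories: "
                    f"{sorted(map(str, col[bad].unique()))}"
                )


def read_cohort(path, dictionary: list[FeatureSpec]) -> tuple[CohortTable, int]:
    """Read a cohort CSV and validate it against ``dictionary``.

    Returns ``(table, n_warnings)`` where ``n_warnings`` counts cells in
    continuous columns that could not be parsed as numbers and were turned
    into missing values.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    warnings = 0
    df["cdr"] = pd.to_numeric(df["cdr"], errors="coerce")
    for spec in dictionary:
        if spec.name == "cdr" or spec.name not in df.columns:
            continue
        if spec.kind == "continuous":
            raw = df[spec.name]
            parsed = pd.to_numeric(raw, errors="coerce")
            warnings += int((raw.notna() & parsed.isna()).sum())
            df[spec.name] = parsed
    return CohortTable(df, list(dictionary)), warnings


def write_cohort(table: CohortTable, path) -> None:
    table.df.to_csv(path, index=False)


def _is_complete(df: pd.DataFrame, features: list[str]) -> pd.Series:
    if not features:
        return pd.Series(True, index=df.index)
    return df[features].notna().all(axis=1)


def complete_case_filter(table: CohortTable,
                         features: list[str]) -> CohortTable:
    """Keep only rows with no missing value among ``features``; order kept."""
    for f in features:
        lookup(table.dictionary, f)  # raises FeatureLookupError
    keep = _is_complete(table.df, list(features))
    return CohortTable(table.df.loc[keep].copy(), list(table.dictionary))


def assemble_groups(table: CohortTable,
                    features: list[str]) -> list[GroupAssignment]:
    """Build the three longitudinal analysis groups.

    Completeness is judged on ``features`` only. Deterministic: row order of
    the input decides tie-breaks, the earliest complete later visit (M18
    before M36 before M54) represents a subject's "later time".
    """
    for f in features:
        lookup(table.dictionary, f)
    df = table.df
    complete = _is_complete(df, list(features))
    visit_rank = {v: i for i, v in enumerate(VISITS)}

    bl_rows = df.index[complete & (df["visit"] == "BL")].tolist()
    later = df.loc[complete & df["visit"].isin(LATER_VISITS)]
    # earliest complete later visit per subject
    order = later["visit"].map(visit_rank).sort_values(kind="stable")
    earliest_later: dict = {}
    for idx in order.index:
        subj = later.at[idx, "subject_id"]
        earliest_later.setdefault(subj, idx)

    g1 = GroupAssignment(1, baseline_rows=bl_rows,
                         later_rows=list(earliest_later.values()))

    bl_subjects = {df.at[i, "subject_id"]: i for i in bl_rows}
    g2_subjects = [s for s in bl_subjects if s in earliest_later]
    g2 = GroupAssignment(
        2,
        baseline_rows=[bl_subjects[s] for s in g2_subjects],
        later_rows=[earliest_later[s] for s in g2_subjects],
    )

    complete_visits = (
        df.loc[complete]
        .groupby("subject_id")["visit"]
        .apply(lambda v: set(v) == set(VISITS))
    )
    g3_subjects = set(complete_visits.index[complete_visits])
    g3_mask = complete & df["subject_id"].isin(g3_subjects)
    g3 = GroupAssignment(
        3,
        baseline_rows=df.index[g3_mask & (df["visit"] == "BL")].tolist(),
        later_rows=df.index[g3_mask & df["visit"].isin(LATER_VISITS)].tolist(),
    )
    return [g1, g2, g3]
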