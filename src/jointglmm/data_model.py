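"""Cohort I/O, validation, and the two-rows-per-visit stacking.

The joint model treats the bivariate outcome (CD4 count, TB screen) as a
single mixed-family response vector: every complete patient-visit expands to
two stacked rows, one per outcome channel, with a ``channel`` indicator
saying which conditional family (Poisson-count vs Bernoulli-binary) that row
belongs to.  Covariates are duplicated verbatim across the pair.

The in-memory containers are plain :class:`pandas.DataFrame` objects:

* a **cohort frame** has one row per patient-visit with the canonical
  columns of :mod:`jointglmm.schema`;
* a **stacked frame** has columns ``patient_id, visit, channel, response``
  followed by the shared covariates, with ``channel`` in {"count","binary"}.

Visits with exactly one observed outcome contribute only their observed
channel to the stack (the mixed-model likelihood factorises over observed
rows given the random effect); covariate missingness is the imputation
module's job.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .schema import (
    CANONICAL_COLUMNS,
    CATEGORICAL_LEVELS,
    COVARIATE_COLUMNS,
    default_schema,
)

CHANNEL_COUNT = "count"
CHANNEL_BINARY = "binary"

STACKED_ID_COLUMNS = ["patient_id", "visit", "channel", "response"]


class CohortValidationError(ValueError):
    """Raised when cohort rows violate schema invariants.

    ``problems`` is a list of human-readable strings, each naming the
    offending row number (0-based data row) and column.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        preview = "; ".join(self.problems[:10])
        more = "" if len(self.problems) <= 10 else f" (+{len(self.problems) - 10} more)"
        super().__init__(f"{len(self.problems)} invalid cohort row(s): {preview}{more}")


def _recode_on_read(df: pd.DataFrame, schema: dict, problems: list) -> pd.DataFrame:
    tb_coding = schema.get("tb_coding", "12")
    oi_coding = schema.get("oi_coding", "01")
    if tb_coding == "12":
        bad = df["tb_status"].dropna().loc[lambda s: ~s.isin([1, 2])]
        for i in bad.index:
            problems.append(f"row {i}: tb_status={df.loc[i, 'tb_status']} not in {{1,2}}")
        df["tb_status"] = df["tb_status"].map({1.0: 0.0, 2.0: 1.0})
    elif tb_coding != "01":
        raise ValueError(f"unknown tb_coding {tb_coding!r}")
    if oi_coding == "12":
        bad = df["oi_status"].dropna().loc[lambda s: ~s.isin([1, 2])]
        for i in bad.index:
            problems.append(f"row {i}: oi_status={df.loc[i, 'oi_status']} not in {{1,2}}")
        df["oi_status"] = df["oi_status"].map({1.0: 1.0, 2.0: 0.0})
    elif oi_coding != "01":
        raise ValueError(f"unknown oi_coding {oi_coding!r}")
    return df


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort frame against the schema invariants.

    Checks categorical code sets, positivity constraints, and uniqueness of
    (patient_id, visit).  Missing cells are allowed everywhere except the
    identifiers.  Raises :class:`CohortValidationError` listing every
    offending row; returns the frame sorted by (patient_id, visit) otherwise.
    """
    problems: list[str] = []
    for col in ("patient_id", "visit"):
        if df[col].isna().any():
            for i in df.index[df[col].isna()]:
                problems.append(f"row {i}: missing {col}")
    dup = df.duplicated(subset=["patient_id", "visit"], keep=False)
    if dup.any():
        for i in df.index[dup]:
            problems.append(
                f"row {i}: duplicate (patient_id={df.loc[i, 'patient_id']}, "
                f"visit={df.loc[i, 'visit']})"
            )
    visits = pd.to_numeric(df["visit"], errors="coerce")
    bad_visit = visits.notna() & ((visits < 1) | (visits != visits.round()))
    for i in df.index[bad_visit]:
        problems.append(f"row {i}: visit={df.loc[i, 'visit']} not a positive integer")

    for col, levels in CATEGORICAL_LEVELS.items():
        if col not in df.columns:
            continue
        vals = df[col].dropna()
        bad = vals.loc[~vals.isin(levels)]
        for i in bad.index:
            problems.append(f"row {i}: {col}={df.loc[i, col]} not in {sorted(levels)}")

    for col, cond, desc in [
        ("cd4_count", lambda s: s < 0, ">= 0"),
        ("weight", lambda s: s <= 0, "> 0"),
        ("hemoglobin", lambda s: s <= 0, "> 0"),
        ("baseline_cd4", lambda s: s < 0, ">= 0"),
    ]:
        if col not in df.columns:
            continue
        vals = df[col].dropna()
        bad = vals.loc[cond(vals)]
        for i in bad.index:
            problems.append(f"row {i}: {col}={df.loc[i, col]} must be {desc}")

    if problems:
        raise CohortValidationError(problems)
    return df.sort_values(["patient_id", "visit"], kind="stable").reset_index(drop=True)


def read_cohort(path, schema: dict | None = None) -> pd.DataFrame:
    """Read and validate a long-format cohort CSV.

    Parameters
    ----------
    path : str or file-like
        Comma-separated UTF-8 file, '.' decimal, empty cell = missing.
    schema : dict, optional
        Schema map (see :func:`jointglmm.schema.default_schema`): column-name
        mapping plus the tb/oi codings of the source file.
    """
    schema = {**default_schema(), **(schema or {})}
    raw = pd.read_csv(path, dtype={schema["columns"]["patient_id"]: str})
    rename = {v: k for k, v in schema["columns"].items() if v in raw.columns}
    missing_cols = [v for k, v in schema["columns"].items() if v not in raw.columns]
    if missing_cols:
        raise CohortValidationError(
            [f"column {c!r} absent from {getattr(path, 'name', path)}" for c in missing_cols]
        )
    df = raw.rename(columns=rename)[CANONICAL_COLUMNS].copy()
    for col in CANONICAL_COLUMNS:
        if col != "patient_id":
            df[col] = pd.to_numeric(df[col], errors="coerce")
    problems: list[str] = []
    df = _recode_on_read(df, schema, problems)
    if problems:
        raise CohortValidationError(problems)
    return validate_cohort(df)


def write_cohort(df: pd.DataFrame, path, schema: dict | None = None) -> None:
    """Write a cohort frame to CSV, applying the schema map's codings."""
    schema = {**default_schema(), **(schema or {})}
    out = df[CANONICAL_COLUMNS].copy()
    if schema.get("tb_coding", "12") == "12":
        out["tb_status"] = out["tb_status"].map({0.0: 1, 1.0: 2})
    if schema.get("oi_coding", "01") == "12":
        out["oi_status"] = out["oi_status"].map({1.0: 1, 0.0: 2})
    out = out.rename(columns=schema["columns"])
    out.to_csv(path, index=False)


def stack_bivariate(records: pd.DataFrame) -> pd.DataFrame:
    """Expand each patient-visit into up to two channel-specific rows.

    A visit with both outcomes observed yields one ``count`` row (response =
    cd4_count) and one ``binary`` row (response = tb_status); a visit with
    exactly one outcome yields only the observed channel's row.  Covariates
    are carried unchanged onto both rows of a pair.
    """
    cols = ["patient_id", "visit"] + COVARIATE_COLUMNS
    pieces = []
    for channel, outcome in ((CHANNEL_COUNT, "cd4_count"), (CHANNEL_BINARY, "tb_status")):
        sub = records.loc[records[outcome].notna(), cols + [outcome]].copy()
        sub.insert(2, "channel", channel)
        sub.insert(3, "response", sub.pop(outcome).astype(float))
        pieces.append(sub)
    if not pieces or all(len(p) == 0 for p in pieces):
        return pd.DataFrame(columns=STACKED_ID_COLUMNS + COVARIATE_COLUMNS)
    stacked = pd.concat(pieces, ignore_index=True)
    order = pd.Categorical(stacked["channel"], categories=[CHANNEL_COUNT, CHANNEL_BINARY])
    stacked = (
        stacked.assign(_ord=order.codes)
        .sort_values(["patient_id", "visit", "_ord"], kind="stable")
        .drop(columns="_ord")
        .reset_index(drop=True)
    )
    return stacked


def unstack(stacked: pd.DataFrame) -> pd.DataFrame:
    """Invert :func:`stack_bivariate`.

    Raises ``ValueError`` if the two rows of a (patient_id, visit) pair
    disagree on any shared covariate.
    """
    if len(stacked) == 0:
        return pd.DataFrame(columns=CANONICAL_COLUMNS)
    cov = stacked[["patient_id", "visit"] + COVARIATE_COLUMNS]
    grouped = cov.groupby(["patient_id", "visit"], sort=True)
    n_unique = grouped.nunique(dropna=False)
    bad = n_unique.gt(1).any(axis=1)
    if bad.any():
        pid, visit = n_unique.index[bad.argmax()]
        cols = list(n_unique.columns[n_unique.loc[(pid, visit)].gt(1)])
        raise ValueError(
            f"covariate mismatch within stacked pair (patient_id={pid}, "
            f"visit={visit}): {cols}"
        )
    base = grouped.first().reset_index()
    wide = stacked.pivot_table(
        index=["patient_id", "visit"], columns="channel", values="response",
        aggfunc="first",
    ).reindex(pd.MultiIndex.from_frame(base[["patient_id", "visit"]]))
    for channel, outcome in ((CHANNEL_COUNT, "cd4_count"), (CHANNEL_BINARY, "tb_status")):
        base[outcome] = (
            wide[channel].to_numpy() if channel in wide.columns else np.nan
        )
    return base[CANONICAL_COLUMNS].reset_index(drop=True)
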