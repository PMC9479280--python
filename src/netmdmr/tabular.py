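"""Reading and validating the two tabular inputs.

The pipeline consumes a participant (cohort) table and an ROI-volume
matrix, both delimited text with a header row.  Validation is strict:
rows with missing required fields or missing ROI volumes are rejected
with an explicit report, never silently dropped or imputed.

Canonical cohort fields: ``participant_id``, ``group`` (P-high / P-low /
changers), ``sex`` (male / female), ``age_years``, ``tbv_cm3``, and the
optional ordinal covariates ``income_bracket`` and ``parental_education``.
ROI volumes are in mm^3; total brain volume (TBV) is in cm^3 — the unit
reconciliation happens exactly once, in :mod:`netmdmr.normalize`.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import pandas as pd

from .networks import NetworkSpec

log = logging.getLogger(__name__)

__all__ = [
    "GROUPS",
    "SEXES",
    "COHORT_REQUIRED",
    "read_cohort",
    "read_volumes",
    "validate_cohort",
    "validate_volumes",
]

GROUPS: tuple[str, ...] = ("P-high", "P-low", "changers")
SEXES: tuple[str, str] = ("male", "female")

COHORT_REQUIRED = ("participant_id", "group", "sex", "age_years", "tbv_cm3")
COHORT_OPTIONAL = ("income_bracket", "parental_education")

# accepted spellings for categorical levels, after lowercasing and
# stripping non-alphanumerics
_GROUP_ALIASES = {
    "phigh": "P-high", "persistenthigh": "P-high", "persistentlyhigh": "P-high",
    "high": "P-high",
    "plow": "P-low", "persistentlow": "P-low", "persistentlylow": "P-low",
    "low": "P-low",
    "changers": "changers", "changer": "changers",
}
_SEX_ALIASES = {"m": "male", "male": "male", "f": "female", "female": "female"}


def _canon_token(value: object) -> str:
    return re.sub(r"[^a-z0-9]", "", str(value).lower())


def _normalize_level(value: object, aliases: dict[str, str], what: str) -> str:
    token = _canon_token(value)
    if token not in aliases:
        raise ValueError(f"unknown {what} level {value!r}")
    return aliases[token]


def _read_delimited(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    if delimiter is None:  # sniff comma vs tab from the header line
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
        delimiter = "\t" if first.count("\t") > first.count(",") else ","
    # round_trip parsing so write->read is bit-exact on float values
    return pd.read_csv(path, sep=delimiter, float_precision="round_trip")


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a cohort table already in canonical columns."""
    missing = [c for c in COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing required column(s): {missing}")
    out = df.copy()
    for col in ("participant_id", "group", "sex", "age_years", "tbv_cm3"):
        if out[col].isna().any():
            bad = out.loc[out[col].isna(), "participant_id"].tolist()
            raise ValueError(f"missing {col} for rows {bad[:5]}")
    out["participant_id"] = out["participant_id"].astype(str)
    if out["participant_id"].duplicated().any():
        dups = out.loc[out["participant_id"].duplicated(), "participant_id"].tolist()
        raise ValueError(f"duplicate participant_id(s): {dups[:5]}")
    out["group"] = [_normalize_level(v, _GROUP_ALIASES, "group") for v in out["group"]]
    out["sex"] = [_normalize_level(v, _SEX_ALIASES, "sex") for v in out["sex"]]
    for col in ("age_years", "tbv_cm3"):
        out[col] = pd.to_numeric(out[col])
        if (out[col] <= 0).any():
            raise ValueError(f"non-positive values in {col}")
    out["group"] = pd.Categorical(out["group"], categories=GROUPS)
    out["sex"] = pd.Categorical(out["sex"], categories=SEXES)
    counts = out.groupby(["group", "sex"], observed=False).size()
    log.info("cohort validated: n=%d\n%s", len(out), counts.to_string())
    return out.reset_index(drop=True)


def read_cohort(
    path: str | Path,
    schema: dict[str, str] | None = None,
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read and validate a participant table.

    Parameters
    ----------
    schema
        Optional mapping from file column names to canonical field names,
        e.g. ``{"subj": "participant_id"}``.  Canonical names present in
        the file need no entry.
    """
    df = _read_delimited(path, delimiter)
    if schema:
        df = df.rename(columns=schema)
    keep = [c for c in (*COHORT_REQUIRED, *COHORT_OPTIONAL) if c in df.columns]
    return validate_cohort(df[keep])


def _resolve_columns(file_cols: list[str], wanted: tuple[str, ...]) -> dict[str, str]:
    """Case- and separator-insensitive match of file columns to spec columns."""
    canon = {_canon_token(c): c for c in file_cols}
    mapping: dict[str, str] = {}
    unresolved: list[str] = []
    for col in wanted:
        hit = canon.get(_canon_token(col))
        if hit is None:
            unresolved.append(col)
        else:
            mapping[hit] = col
    if unresolved:
        raise ValueError(f"volume table is missing network column(s): {unresolved}")
    return mapping


def validate_volumes(df: pd.DataFrame, spec: NetworkSpec) -> pd.DataFrame:
    """Restrict a volume table to ``spec`` columns, in spec order."""
    if df.index.duplicated().any():
        raise ValueError("duplicate participant rows in volume table")
    mapping = _resolve_columns(list(df.columns), spec.columns)
    out = df.rename(columns=mapping)[list(spec.columns)].astype(float)
    if out.isna().any().any():
        bad = out.index[out.isna().any(axis=1)].tolist()
        raise ValueError(f"missing ROI volumes for participants {bad[:5]}; rows rejected")
    if (out.to_numpy() < 0).any():
        raise ValueError("negative ROI volume encountered")
    return out


def read_volumes(
    path: str | Path,
    spec: NetworkSpec,
    id_column: str = "participant_id",
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read an ROI-volume matrix (mm^3), indexed by participant id.

    Extra non-network columns are dropped; a missing network column is an
    error that names the column.
    """
    df = _read_delimited(path, delimiter)
    if id_column not in df.columns:
        raise ValueError(f"volume table missing id column {id_column!r}")
    df = df.set_index(df[id_column].astype(str)).drop(columns=[id_column])
    df.index.name = "participant_id"
    return validate_volumes(df, spec)


def align(cohort: pd.DataFrame, volumes: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inner-join cohort and volumes on participant id, cohort order.

    Volume rows must be a subset of cohort ids; cohort rows without a
    volume row are dropped (they have no scan) and reported.
    """
    vol_ids = set(volumes.index)
    unknown = vol_ids - set(cohort["participant_id"])
    if unknown:
        raise ValueError(f"volume rows with no cohort entry: {sorted(unknown)[:5]}")
    keep = cohort["participant_id"].isin(vol_ids)
    if (~keep).any():
        log.info("dropping %d cohort rows without volumes", int((~keep).sum()))
    coh = cohort.loc[keep].reset_index(drop=True)
    vols = volumes.loc[coh["participant_id"]]
    return coh, vols
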