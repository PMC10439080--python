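"""Delimited-table input/output with schema validation.

Canonical dialect: tab-delimited UTF-8 with a header row and empty
fields for missing values (Polish names need UTF-8 throughout).
Comma-delimited files are accepted on read.  Each table schema declares
required columns with semantic types and optional bounds plus a key; the
reader reports bound violations and duplicate keys with row numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class Column:
    name: str
    dtype: str  # "str" | "float" | "int" | "bool"
    required: bool = True
    bounds: tuple[float, float] | None = None
    allowed: tuple[str, ...] | None = None
    nullable: bool = True


@dataclass
class Schema:
    name: str
    columns: list[Column]
    key: tuple[str, ...] = ()

    def column(self, name: str) -> Column:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)


TRIALS_SCHEMA = Schema(
    "trials",
    [
        Column("participant", "str", nullable=False),
        Column("picture", "str", nullable=False),
        Column("word_class", "str", allowed=("object", "action"), nullable=False),
        Column("raw_name", "str"),
        Column("latency_ms", "float", bounds=(0.0, np.inf)),
        Column("validity", "str", required=False,
               allowed=("valid", "invalid", "no_response")),
        Column("lexical_code", "int", required=False, bounds=(1, 4)),
    ],
    key=("participant", "picture"),
)

RATINGS_SCHEMA = Schema(
    "ratings",
    [
        Column("rater_id", "str", nullable=False),
        Column("item_id", "str", nullable=False),
        Column("study", "str", nullable=False),
        Column("value", "float", nullable=False),
    ],
    key=("rater_id", "item_id", "study"),
)

WORD_FEATURES_SCHEMA = Schema(
    "word_features",
    [
        Column("word", "str", nullable=False),
        Column("word_class", "str", allowed=("noun", "verb"), nullable=False),
        Column("phoneme_count", "int", bounds=(1, np.inf), nullable=False),
        Column("initial_fricative_affricate", "bool"),
        Column("initial_cluster", "bool"),
        Column("medial_cluster", "bool"),
        Column("n_stems", "int", bounds=(1, np.inf)),
        Column("is_derivation", "bool"),
        Column("has_prefix", "bool"),
        Column("has_suffix", "bool"),
        Column("available_in_country", "bool"),
        Column("preschool_access", "str",
               allowed=("not_or_rarely", "quite_often", "very_often")),
        Column("is_loanword", "bool"),
    ],
    key=("word",),
)

WORD_ESTIMATES_SCHEMA = Schema(
    "word_estimates",
    [
        Column("name", "str", nullable=False),
        Column("word_class", "str", allowed=("object", "action")),
        Column("age_of_acquisition", "float", bounds=(1, 18)),
        Column("imageability", "float", bounds=(1, 7)),
        Column("frequency", "float", bounds=(0, np.inf)),
    ],
    key=("name",),
)

RATING_STUDY_BOUNDS = {
    "goodness_of_depiction": (0, 3),
    "image_agreement": (1, 7),
    "concept_familiarity": (1, 7),
    "imageability": (1, 7),
    "age_of_acquisition": (1, 18),
}

SCHEMAS = {
    s.name: s
    for s in (TRIALS_SCHEMA, RATINGS_SCHEMA, WORD_FEATURES_SCHEMA, WORD_ESTIMATES_SCHEMA)
}

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False, "": pd.NA}


def _coerce(series: pd.Series, col: Column, table: str) -> pd.Series:
    if col.dtype == "str":
        out = series.astype("string")
        out = out.replace("", pd.NA)
        return out
    if col.dtype == "bool":
        out = series.astype("string").str.strip().str.lower().map(_BOOL_MAP)
        bad = series.notna() & out.isna() & (series.astype(str).str.strip() != "")
        if bad.any():
            raise ValueError(
                f"{table}: column {col.name!r} has non-boolean values at rows "
                f"{series.index[bad].tolist()[:10]}"
            )
        return out.astype("boolean")
    numeric = pd.to_numeric(series, errors="coerce")
    bad = series.notna() & numeric.isna() & (series.astype(str).str.strip() != "")
    if bad.any():
        raise ValueError(
            f"{table}: column {col.name!r} has malformed numbers at rows "
            f"{series.index[bad].tolist()[:10]}"
        )
    if col.dtype == "int":
        return numeric.astype("Int64")
    return numeric.astype(float)


def read_table(path: str | Path, schema: Schema) -> pd.DataFrame:
    """Read and validate a delimited table against a schema.

    Raises on missing required columns, malformed numerics, bound or
    category violations, and duplicate keys — always naming the rows.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")
    df = df.replace("", pd.NA)
    missing = [c.name for c in schema.columns if c.required and c.name not in df.columns]
    if missing:
        raise ValueError(f"{schema.name}: missing required columns {missing}")
    for col in schema.columns:
        if col.name not in df.columns:
            continue
        df[col.name] = _coerce(df[col.name], col, schema.name)
        s = df[col.name]
        if not col.nullable and s.isna().any():
            rows = s.index[s.isna()].tolist()[:10]
            raise ValueError(f"{schema.name}: column {col.name!r} missing at rows {rows}")
        if col.bounds is not None:
            lo, hi = col.bounds
            viol = s.notna() & ((s < lo) | (s > hi))
            if viol.any():
                rows = s.index[viol].tolist()[:10]
                raise ValueError(
                    f"{schema.name}: column {col.name!r} outside [{lo}, {hi}] "
                    f"at rows {rows}"
                )
        if col.allowed is not None:
            viol = s.notna() & ~s.isin(col.allowed)
            if viol.any():
                rows = s.index[viol].tolist()[:10]
                raise ValueError(
                    f"{schema.name}: column {col.name!r} outside {col.allowed} "
                    f"at rows {rows}"
                )
    if schema.key:
        keys = [k for k in schema.key if k in df.columns]
        dup = df.duplicated(subset=keys, keep=False)
        if dup.any():
            rows = df.index[dup].tolist()[:10]
            raise ValueError(f"{schema.name}: duplicate keys {keys} at rows {rows}")
    if schema.name == "ratings":
        for study, sub in df.groupby("study"):
            if study not in RATING_STUDY_BOUNDS:
                raise ValueError(f"ratings: unknown study {study!r}")
            lo, hi = RATING_STUDY_BOUNDS[study]
            viol = (sub["value"] < lo) | (sub["value"] > hi)
            if viol.any():
                rows = sub.index[viol].tolist()[:10]
                raise ValueError(
                    f"ratings: study {study!r} value outside [{lo}, {hi}] at rows {rows}"
                )
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a table in the canonical dialect (TSV, UTF-8, empty=missing)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for c in out.columns:
        if pd.api.types.is_bool_dtype(out[c]):
            out[c] = out[c].map({True: "true", False: "false"})
        elif pd.api.types.is_float_dtype(out[c]):
            out[c] = out[c].map(lambda v: "" if pd.isna(v) else format(v, ".10g"))
    out.to_csv(path, sep="\t", index=False, na_rep="", encoding="utf-8")
    return path
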