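"""Norm-table aggregation.

Combines coded trials, name-agreement statistics, rating aggregates,
and word-level estimates into the two published summary shapes:

* a **dominant-only** table with one row per picture (agreement indices,
  lexical-code shares, latency statistics, picture-rating means, and the
  word estimates of the dominant name), and
* an **extended** table with one row per picture x retained name, where
  a name is retained if it is the dominant name or was produced by at
  least 5 participants (nouns) / 8 participants (verbs).

Missing word estimates (e.g. corpus frequencies unavailable for
multiword names) are carried through as missing values, never imputed;
descriptive summaries are complete-case per variable.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from . import agreement as ag
from .coding import INVALID, NO_RESPONSE, VALID, UnificationMaps, assign_lexical_codes

logger = logging.getLogger(__name__)

RATING_BOUNDS = {
    "goodness_of_depiction": (0, 3),
    "image_agreement": (1, 7),
    "concept_familiarity": (1, 7),
    "imageability": (1, 7),
    "age_of_acquisition": (1, 18),
}

NOUN_RETENTION_THRESHOLD = 5
VERB_RETENTION_THRESHOLD = 8


def aggregate_ratings(
    records: pd.DataFrame,
    study: str | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per-item mean/SD/n of a rating study.

    ``records`` needs columns rater_id, item_id, value and either a
    ``study`` column or an explicit ``study`` argument.  Out-of-bounds
    values are rejected with their row index named.
    """
    bounds = dict(bounds or RATING_BOUNDS)
    df = records.copy()
    if study is not None:
        df["study"] = study
    if "study" not in df.columns:
        raise ValueError("rating records need a study column or argument")
    for st, sub in df.groupby("study"):
        if st not in bounds:
            raise ValueError(f"unknown rating study {st!r}")
        lo, hi = bounds[st]
        bad = sub[(sub["value"] < lo) | (sub["value"] > hi)]
        if not bad.empty:
            raise ValueError(
                f"study {st!r}: value outside [{lo}, {hi}] at rows "
                f"{bad.index.tolist()[:10]}"
            )
    out = (
        df.groupby(["study", "item_id"])["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    return out


def filter_alternative_names(
    name_counts: Mapping[str, int],
    word_class: str,
    dominant: str | None = None,
    noun_threshold: int = NOUN_RETENTION_THRESHOLD,
    verb_threshold: int = VERB_RETENTION_THRESHOLD,
) -> list[str]:
    """Names retained for word-estimate collection.

    Nouns (object names) are kept from 5 users upward, verbs (action
    names) from 8; the dominant name is always retained.
    """
    threshold = noun_threshold if word_class == "object" else verb_threshold
    kept = [n for n, c in name_counts.items() if c >= threshold]
    if dominant is not None and dominant not in kept:
        kept.append(dominant)
    return sorted(kept)


def _latency_stats(lat: pd.Series) -> dict[str, float]:
    lat = lat.dropna()
    if lat.empty:
        return {"latency_mean": np.nan, "latency_sd": np.nan, "latency_median": np.nan}
    return {
        "latency_mean": float(lat.mean()),
        "latency_sd": float(lat.std(ddof=1)) if len(lat) > 1 else 0.0,
        "latency_median": float(lat.median()),
    }


def build_norm_table(
    trials: pd.DataFrame,
    maps: UnificationMaps | None = None,
    rating_aggregates: pd.DataFrame | None = None,
    word_estimates: pd.DataFrame | None = None,
    ci_table: pd.DataFrame | None = None,
    strategy_by_class: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate everything into (dominant-only, extended) norm tables.

    ``trials`` must carry validity labels.  ``rating_aggregates`` is the
    output of :func:`aggregate_ratings` (picture studies keyed by picture
    id, word studies by name).  ``word_estimates`` has one row per name
    with age_of_acquisition / imageability / frequency; ``ci_table`` has
    word + ci columns.  Pictures with zero valid trials appear as flagged
    rows with missing norms.
    """
    maps = maps or UnificationMaps()
    strategy_by_class = dict(strategy_by_class or {"object": 1, "action": 3})

    estimates = None
    if word_estimates is not None:
        estimates = word_estimates.set_index("name")
    ci = None
    if ci_table is not None:
        ci = ci_table.set_index("word")

    picture_ratings: dict[str, pd.DataFrame] = {}
    word_ratings: dict[str, pd.DataFrame] = {}
    if rating_aggregates is not None:
        for st, sub in rating_aggregates.groupby("study"):
            target = (
                word_ratings
                if st in ("imageability", "age_of_acquisition")
                else picture_ratings
            )
            target[st] = sub.set_index("item_id")

    dominants: dict[str, str] = {}
    dominant_rows = []
    extended_rows = []
    for pic, sub in trials.groupby("picture", sort=True):
        wc = sub["word_class"].iloc[0]
        strategy = strategy_by_class.get(wc, 1)
        counts = sub["validity"].value_counts()
        row: dict[str, object] = {
            "picture": pic,
            "word_class": wc,
            "n_valid": int(counts.get(VALID, 0)),
            "n_invalid": int(counts.get(INVALID, 0)),
            "n_no_response": int(counts.get(NO_RESPONSE, 0)),
        }
        if row["n_valid"] == 0:
            logger.warning("picture %r has no valid trials; norms flagged missing", pic)
            row.update({"flagged_no_valid": True})
            dominant_rows.append(row)
            continue
        row["flagged_no_valid"] = False

        strategies = (1, 2, 3) if wc == "action" else (1,)
        for s in strategies:
            dist_s = ag.tally_names(trials, pic, strategy=s, maps=maps)
            row[f"H_s{s}"] = ag.entropy_h(dist_s)
            row[f"na_pct_s{s}"] = ag.percent_na(dist_s)
        dist = ag.tally_names(trials, pic, strategy=strategy, maps=maps)
        dom, tie = ag.dominant_name(dist)
        dominants[pic] = dom
        row.update(
            {
                "dominant_name": dom,
                "tie_flag": tie,
                "k": dist.k,
                "H": ag.entropy_h(dist),
                "na_pct": ag.percent_na(dist),
            }
        )
        row.update(_latency_stats(sub.loc[sub["validity"] == VALID, "latency_ms"]))
        for st, table in picture_ratings.items():
            row[f"{st}_mean"] = (
                float(table.loc[pic, "mean"]) if pic in table.index else np.nan
            )

        def _word_row(name: str, count: int) -> dict[str, object]:
            wrow: dict[str, object] = {"name": name, "n_users": count}
            for st, table in word_ratings.items():
                wrow[st] = float(table.loc[name, "mean"]) if name in table.index else np.nan
            if estimates is not None and name in estimates.index:
                for col in ("age_of_acquisition", "imageability", "frequency"):
                    if col in estimates.columns:
                        wrow[col] = estimates.loc[name, col]
            else:
                for col in ("age_of_acquisition", "imageability", "frequency"):
                    wrow.setdefault(col, np.nan)
            wrow["ci"] = (
                float(ci.loc[name, "ci"]) if ci is not None and name in ci.index else np.nan
            )
            return wrow

        dom_count = int(dict(zip(dist.names, dist.counts))[dom])
        for key, val in _word_row(dom, dom_count).items():
            if key != "name":
                row[f"dominant_{key}" if key == "n_users" else key] = val
        dominant_rows.append(row)

        name_counts = {n: int(c) for n, c in zip(dist.names, dist.counts)}
        for name in filter_alternative_names(name_counts, wc, dominant=dom):
            wrow = _word_row(name, name_counts[name])
            wrow.update(
                {
                    "picture": pic,
                    "word_class": wc,
                    "is_dominant": name == dom,
                    "share_pct": 100.0 * name_counts[name] / dist.n_valid,
                }
            )
            extended_rows.append(wrow)

    dominant_df = pd.DataFrame(dominant_rows)

    # lexical-code percentages against the per-picture dominants
    coded = assign_lexical_codes(
        trials[trials["picture"].isin(dominants)], dominants, maps, strategy_by_class
    )
    valid = coded[coded["validity"] == VALID]
    code_pct = (
        valid.groupby("picture")["lexical_code"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .mul(100.0)
    )
    for code in (1, 2, 3, 4):
        series = (
            code_pct[code]
            if code in code_pct.columns
            else pd.Series(0.0, index=code_pct.index)
        )
        dominant_df[f"code{code}_pct"] = dominant_df["picture"].map(series)
    extended_df = pd.DataFrame(extended_rows)
    if not extended_df.empty:
        lead = ["picture", "word_class", "name", "is_dominant", "n_users", "share_pct"]
        extended_df = extended_df[lead + [c for c in extended_df.columns if c not in lead]]
    return dominant_df, extended_df


def descriptive_summary(
    norm_table: pd.DataFrame,
    variables: list[str],
    by: str = "word_class",
) -> pd.DataFrame:
    """Mean/SD/median/range per variable per word class (complete-case)."""
    rows = []
    for group, sub in norm_table.groupby(by, sort=True):
        for v in variables:
            if v not in sub.columns:
                raise ValueError(f"variable {v!r} not in table")
            vals = pd.to_numeric(sub[v], errors="coerce").dropna()
            if vals.empty:
                raise ValueError(f"variable {v!r} has no non-missing values in {group!r}")
            rows.append(
                {
                    by: group,
                    "variable": v,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    "median": float(vals.median()),
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                    "n": int(len(vals)),
                }
            )
    return pd.DataFrame(rows)
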