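"""Name-agreement statistics for picture-naming norms.

For each picture the valid responses (optionally unified across verb
variants) define a categorical name distribution with ``k`` distinct
names used in proportions ``p_i``.  Two agreement indices are computed:

* Name agreement percentage, ``NA% = 100 * max_i p_i`` — the share of
  responses matching the dominant (modal) name;
* the H statistic, the Shannon entropy of the name distribution in bits,

  .. math:: H = \\sum_{i=1}^{k} p_i \\log_2 (1 / p_i)

  which is 0 when naming is unanimous and ``log2(k)`` when all ``k``
  names are equally popular.  H is sensitive to the number and spread of
  alternative names where NA% is not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coding import STRATEGIES, VALID, UnificationMaps, unify_response

logger = logging.getLogger(__name__)


@dataclass
class NameDistribution:
    """Tally of valid (unified) names for one picture under one strategy."""

    picture_id: str
    strategy: int
    names: list[str]
    counts: np.ndarray
    n_valid: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.names) != len(self.counts):
            raise ValueError("names and counts differ in length")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.n_valid <= 0:
            raise ValueError(
                f"picture {self.picture_id!r}: distribution needs at least "
                "one valid trial"
            )
        if not np.isclose(self.counts.sum(), self.n_valid):
            raise ValueError("counts do not sum to n_valid")

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.n_valid

    @property
    def k(self) -> int:
        """Number of distinct names actually used."""
        return int((self.counts > 0).sum())

    @classmethod
    def from_counts(
        cls, counts: dict[str, int], picture_id: str = "", strategy: int = 1
    ) -> "NameDistribution":
        names = list(counts)
        c = np.array([counts[n] for n in names], dtype=float)
        return cls(picture_id, strategy, names, c, int(c.sum()))


def tally_names(
    trials: pd.DataFrame,
    picture_id: str,
    strategy: int = 1,
    maps: UnificationMaps | None = None,
) -> NameDistribution:
    """Tally unified names over the valid trials of one picture.

    Invalid and no-response trials are excluded before counting.  A
    picture with zero valid trials raises (the norms layer flags such
    pictures explicitly rather than emitting a silent zero row).
    """
    maps = maps or UnificationMaps()
    rows = trials[(trials["picture"] == picture_id) & (trials["validity"] == VALID)]
    if rows.empty:
        raise ValueError(f"picture {picture_id!r} has no valid trials")
    unified = [
        unify_response(
            raw,
            strategy if wc == "action" else 1,
            maps,
            word_class=wc,
        )
        for raw, wc in zip(rows["raw_name"], rows["word_class"])
    ]
    counts = pd.Series(unified).value_counts().to_dict()
    return NameDistribution.from_counts(counts, picture_id, strategy)


def entropy_h(dist: NameDistribution) -> float:
    """H statistic (bits) of a name distribution; 0 for unanimous naming."""
    p = dist.proportions
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def percent_na(dist: NameDistribution) -> float:
    """Name agreement as a percentage: 100 x the dominant name's share."""
    return float(100.0 * dist.proportions.max())


def dominant_name(dist: NameDistribution) -> tuple[str, bool]:
    """Modal name and a tie flag.

    Ties on the maximal count are broken lexicographically (smallest name
    wins) and flagged, since downstream lexical coding needs a unique
    dominant response.
    """
    top = dist.counts.max()
    winners = sorted(n for n, c in zip(dist.names, dist.counts) if c == top)
    tie = len(winners) > 1
    if tie:
        logger.warning(
            "picture %r: dominant-name tie between %s; picked %r",
            dist.picture_id,
            winners,
            winners[0],
        )
    return winners[0], tie


def agreement_table(
    trials: pd.DataFrame,
    maps: UnificationMaps | None = None,
    strategies: tuple[int, ...] = STRATEGIES,
) -> pd.DataFrame:
    """Per-picture agreement statistics, one row per picture x strategy.

    Object pictures are tallied under strategy 1 only (verb unification
    does not apply); action pictures under every requested strategy.
    """
    maps = maps or UnificationMaps()
    records = []
    for pic, sub in trials.groupby("picture", sort=True):
        word_class = sub["word_class"].iloc[0]
        pic_strategies = strategies if word_class == "action" else (1,)
        for s in pic_strategies:
            try:
                dist = tally_names(trials, pic, strategy=s, maps=maps)
            except ValueError:
                records.append(
                    {
                        "picture": pic,
                        "word_class": word_class,
                        "strategy": s,
                        "n_valid": 0,
                        "k": pd.NA,
                        "H": np.nan,
                        "na_pct": np.nan,
                        "dominant_name": pd.NA,
                        "tie_flag": pd.NA,
                    }
                )
                continue
            dom, tie = dominant_name(dist)
            records.append(
                {
                    "picture": pic,
                    "word_class": word_class,
                    "strategy": s,
                    "n_valid": dist.n_valid,
                    "k": dist.k,
                    "H": entropy_h(dist),
                    "na_pct": percent_na(dist),
                    "dominant_name": dom,
                    "tie_flag": tie,
                }
            )
    return pd.DataFrame.from_records(records)
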