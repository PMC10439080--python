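"""Response coding for picture-naming trials.

A naming response is first sorted into one of three validity classes
(valid / invalid / no_response), then — for valid trials — unified across
morphological variants (three strategies of increasing aggressiveness for
verbs) and assigned a lexical code describing its relation to the picture's
dominant name:

1. the dominant name itself,
2. a morphological variation sharing the dominant name's root,
3. a synonym of the dominant name,
4. any other response.

Human transcription judgements are replaced by explicit lookup tables
(:class:`UnificationMaps`) so the whole coding step is deterministic and
auditable.  Unmapped cases fall through conservatively (identity
unification, code 4) with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID = "valid"
INVALID = "invalid"
NO_RESPONSE = "no_response"
VALIDITY_CLASSES = (VALID, INVALID, NO_RESPONSE)

#: Unification strategies for verb responses.
#: 1 — raw responses, every surface variant is a separate name.
#: 2 — responses recoded to the infinitive (removes tense/number variation).
#: 3 — unified infinitives: aspect pairs and reflexive/non-reflexive forms
#:     merged into a single target form.
STRATEGIES = (1, 2, 3)


def _normalize(name: str | None) -> str:
    """Lowercase and trim a raw transcription; missing becomes empty."""
    if name is None or (isinstance(name, float) and np.isnan(name)):
        return ""
    return str(name).strip().lower()


@dataclass
class UnificationMaps:
    """Lookup tables standing in for manual morphological coding.

    All maps are keyed and valued by normalized (lowercased, trimmed)
    names.  ``merge_map`` values must be fixed points of ``merge_map``:
    the target form of an aspect/reflexivity pair maps to itself.
    """

    infinitive_map: dict[str, str] = field(default_factory=dict)
    merge_map: dict[str, str] = field(default_factory=dict)
    root_map: dict[str, str] = field(default_factory=dict)
    synonym_map: dict[str, str] = field(default_factory=dict)
    lexicon: set[str] | None = None

    def __post_init__(self) -> None:
        for target in self.merge_map.values():
            resolved = self.merge_map.get(target, target)
            if resolved != target:
                raise ValueError(
                    f"merge_map target {target!r} is not a fixed point "
                    f"(maps on to {resolved!r})"
                )

    def in_lexicon(self, name: str) -> bool:
        """True if the name is attested or shares a root with one.

        With no lexicon supplied every non-empty name is accepted.
        """
        if self.lexicon is None:
            return True
        return name in self.lexicon or name in self.root_map


def code_validity(
    raw_name: str | None,
    latency_ms: float | None,
    maps: UnificationMaps | None = None,
) -> str:
    """Classify one trial as valid, invalid, or no_response.

    An empty or unrecognizable transcription is a non-response; a named
    trial with a missing latency, or a rootless neologism (a name absent
    from the lexicon with no root mapping), is invalid; everything else
    is valid.
    """
    maps = maps or UnificationMaps()
    name = _normalize(raw_name)
    if name == "":
        return NO_RESPONSE
    latency_missing = latency_ms is None or (
        isinstance(latency_ms, float) and np.isnan(latency_ms)
    )
    if latency_missing or latency_ms <= 0:
        return INVALID
    if not maps.in_lexicon(name):
        return INVALID
    return VALID


def unify_response(
    raw_name: str,
    strategy: int,
    maps: UnificationMaps,
    word_class: str = "action",
) -> str:
    """Map a raw response to its canonical name under a strategy.

    Strategy 1 is the identity; strategy 2 recodes to the infinitive;
    strategy 3 additionally merges aspect pairs and reflexive variants.
    Strategies 2 and 3 are defined for action (verb) responses only.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown unification strategy {strategy!r}")
    name = _normalize(raw_name)
    if strategy == 1:
        return name
    if word_class != "action":
        raise ValueError(
            f"strategy {strategy} applies to action responses only, "
            f"got word_class={word_class!r}"
        )
    infinitive = maps.infinitive_map.get(name)
    if infinitive is None:
        logger.warning("no infinitive mapping for %r; kept as is", name)
        infinitive = name
    if strategy == 2:
        return infinitive
    return maps.merge_map.get(infinitive, infinitive)


def assign_lexical_code(
    name: str,
    dominant: str,
    maps: UnificationMaps,
) -> int:
    """Assign Lexical Code 1-4 to a valid response.

    Exact match with the dominant name gives 1; a shared root class gives
    2; a synonym mapping on to the dominant gives 3; anything else 4.
    """
    if dominant is None or _normalize(dominant) == "":
        raise ValueError("dominant name is required for lexical coding")
    name = _normalize(name)
    dominant = _normalize(dominant)
    if name == dominant:
        return 1
    root = maps.root_map.get(name)
    if root is not None and root == maps.root_map.get(dominant):
        return 2
    if maps.synonym_map.get(name) == dominant:
        return 3
    return 4


def code_trials(
    trials: pd.DataFrame,
    maps: UnificationMaps | None = None,
) -> pd.DataFrame:
    """Add (or recompute) the validity column of a trial table.

    Expects columns participant, picture, word_class, raw_name,
    latency_ms.  Rows already carrying a validity label are left alone
    so that simulator-assigned ground-truth outcomes survive re-coding.
    """
    maps = maps or UnificationMaps()
    out = trials.copy()
    if "validity" not in out.columns:
        out["validity"] = pd.NA
    needs = out["validity"].isna()
    out.loc[needs, "validity"] = [
        code_validity(n, l, maps)
        for n, l in zip(out.loc[needs, "raw_name"], out.loc[needs, "latency_ms"])
    ]
    bad = ~out["validity"].isin(VALIDITY_CLASSES)
    if bad.any():
        raise ValueError(
            f"unknown validity labels: {sorted(out.loc[bad, 'validity'].unique())}"
        )
    return out


def unify_trials(
    trials: pd.DataFrame,
    strategy: int,
    maps: UnificationMaps,
) -> pd.Series:
    """Unified name per trial; objects always use strategy 1."""
    names = []
    for raw, wc in zip(trials["raw_name"], trials["word_class"]):
        s = strategy if wc == "action" else 1
        names.append(unify_response(raw, s, maps, word_class=wc))
    return pd.Series(names, index=trials.index, name="unified_name")


def assign_lexical_codes(
    trials: pd.DataFrame,
    dominants: Mapping[str, str],
    maps: UnificationMaps,
    strategy_by_class: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Assign Lexical Codes 1-4 to all valid trials against per-picture dominants.

    ``dominants`` maps picture id to its dominant (already unified) name.
    Codes are set only on valid trials; others keep a missing code.
    """
    strategy_by_class = dict(strategy_by_class or {"object": 1, "action": 3})
    out = trials.copy()
    out["lexical_code"] = pd.array([pd.NA] * len(out), dtype="Int64")
    valid = out["validity"] == VALID
    codes = []
    for _, row in out.loc[valid].iterrows():
        pic = row["picture"]
        if pic not in dominants:
            raise ValueError(f"no dominant name known for picture {pic!r}")
        strategy = strategy_by_class.get(row["word_class"], 1)
        unified = unify_response(
            row["raw_name"], strategy, maps, word_class=row["word_class"]
        )
        codes.append(assign_lexical_code(unified, dominants[pic], maps))
    out.loc[valid, "lexical_code"] = codes
    return out
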