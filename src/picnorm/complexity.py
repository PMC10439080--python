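"""Complexity Index: a composite word-difficulty score.

The index sums three groups of contributions:

* **phonology** — a doubled, class-standardized phoneme-length term
  ``2 * (length - mean_class) / sd_class`` plus one point each for a
  word-initial fricative/affricate, a word-initial consonant cluster,
  and the presence of word-medial consonant clusters;
* **morphology** — one point per stem, one if the word is a derivation,
  and one per affix (prefix and/or suffix, up to two);
* **exposure** — one point if the referent is not available to direct
  experience in the country, graded access points for preschool children
  (not at all / rarely: 1, quite often: 0.5, very often: 0), and one
  point if the word is a loanword.

Phonological and morphological feature values are inputs (no automatic
phoneme counting or morphological analysis); the module only scores them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ACCESS_POINTS = {"not_or_rarely": 1.0, "quite_often": 0.5, "very_often": 0.0}


@dataclass
class ClassLengthStats:
    """Phoneme-length mean and SD of a word class, for standardization."""

    word_class: str
    mean_length: float
    sd_length: float

    def __post_init__(self) -> None:
        if self.sd_length <= 0:
            raise ValueError("sd_length must be positive")

    @classmethod
    def from_lengths(cls, word_class: str, lengths: Sequence[float]) -> "ClassLengthStats":
        arr = np.asarray(lengths, dtype=float)
        if len(arr) < 2:
            raise ValueError("need at least two lengths to estimate an SD")
        return cls(word_class, float(arr.mean()), float(arr.std(ddof=1)))


@dataclass
class WordFeatureRecord:
    """The feature bundle of one word entering the Complexity Index."""

    word: str
    word_class: str  # noun | verb
    phoneme_count: int
    initial_fricative_affricate: bool = False
    initial_cluster: bool = False
    medial_cluster: bool = False
    n_stems: int = 1
    is_derivation: bool = False
    has_prefix: bool = False
    has_suffix: bool = False
    available_in_country: bool = True
    preschool_access: str = "very_often"
    is_loanword: bool = False

    def __post_init__(self) -> None:
        if self.phoneme_count < 1:
            raise ValueError("phoneme_count must be >= 1")
        if self.n_stems < 1:
            raise ValueError("n_stems must be >= 1")
        if self.preschool_access not in ACCESS_POINTS:
            raise ValueError(
                f"preschool_access must be one of {sorted(ACCESS_POINTS)}, "
                f"got {self.preschool_access!r}"
            )


@dataclass
class ComplexityScore:
    """A scored word: total CI plus audit subscores.

    ``normed_length + phonology + morphology + exposure == ci`` exactly;
    the stem point is counted under morphology.
    """

    word: str
    ci: float
    normed_length: float
    phonology: float
    morphology: float
    exposure: float


def normed_length(phoneme_count: float, stats: ClassLengthStats) -> float:
    """Doubled standardized word length: 2 * (length - mean) / SD."""
    return 2.0 * (phoneme_count - stats.mean_length) / stats.sd_length


def complexity_index(
    rec: WordFeatureRecord,
    stats: ClassLengthStats | None = None,
    length_term: float | None = None,
) -> ComplexityScore:
    """Score one word.

    The length contribution is either computed from ``stats`` or derived
    from ``length_term``, the *standardized* (not yet doubled) length
    ``(phoneme_count - mean)/SD`` — the "normed length" a word list
    usually reports; the index doubles it.  Exactly one of the two must
    be given.
    """
    if (stats is None) == (length_term is None):
        raise ValueError("supply exactly one of stats or length_term")
    nl = 2.0 * length_term if length_term is not None else normed_length(rec.phoneme_count, stats)
    phonology = (
        float(rec.initial_fricative_affricate)
        + float(rec.initial_cluster)
        + float(rec.medial_cluster)
    )
    morphology = (
        float(rec.n_stems)
        + float(rec.is_derivation)
        + float(rec.has_prefix)
        + float(rec.has_suffix)
    )
    exposure = (
        float(not rec.available_in_country)
        + ACCESS_POINTS[rec.preschool_access]
        + float(rec.is_loanword)
    )
    ci = nl + phonology + morphology + exposure
    return ComplexityScore(rec.word, ci, nl, phonology, morphology, exposure)


def standardize_ci(ci_values: Sequence[float]) -> np.ndarray:
    """Z-score CI values over the pooled set (sample SD, ddof=1).

    Used to place noun and verb CI scales on a common footing before
    cross-class comparisons.
    """
    arr = np.asarray(ci_values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values to standardize")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("constant input cannot be standardized")
    return (arr - arr.mean()) / sd


def _record_from_row(row: pd.Series) -> WordFeatureRecord:
    fields = [
        "word",
        "word_class",
        "phoneme_count",
        "initial_fricative_affricate",
        "initial_cluster",
        "medial_cluster",
        "n_stems",
        "is_derivation",
        "has_prefix",
        "has_suffix",
        "available_in_country",
        "preschool_access",
        "is_loanword",
    ]
    kwargs = {f: row[f] for f in fields if f in row.index}
    for key, val in list(kwargs.items()):
        if key in ("word", "word_class", "preschool_access"):
            continue
        if key == "phoneme_count" or key == "n_stems":
            kwargs[key] = int(val)
        elif key != "word":
            kwargs[key] = bool(val)
    return WordFeatureRecord(**kwargs)


def complexity_table(
    features: pd.DataFrame,
    length_stats: dict[str, ClassLengthStats] | None = None,
    standardize: bool = True,
) -> pd.DataFrame:
    """Score a word-feature table; one output row per word.

    Class length statistics default to the mean/SD of ``phoneme_count``
    within each word class of the supplied table; pass ``length_stats``
    to pin them to externally known constants.  The ``ci_z`` column
    standardizes CI within word class (each class is normed over its own
    word set).
    """
    if length_stats is None:
        length_stats = {
            wc: ClassLengthStats.from_lengths(wc, sub["phoneme_count"].to_numpy())
            for wc, sub in features.groupby("word_class")
        }
    rows = []
    for _, row in features.iterrows():
        rec = _record_from_row(row)
        score = complexity_index(rec, stats=length_stats[rec.word_class])
        rows.append(
            {
                "word": rec.word,
                "word_class": rec.word_class,
                "normed_length": score.normed_length,
                "phonology": score.phonology,
                "morphology": score.morphology,
                "exposure": score.exposure,
                "ci": score.ci,
            }
        )
    out = pd.DataFrame(rows)
    if standardize:
        out["ci_z"] = np.nan
        for wc, sub in out.groupby("word_class"):
            if len(sub) >= 2 and sub["ci"].std(ddof=1) > 0:
                out.loc[sub.index, "ci_z"] = standardize_ci(sub["ci"].to_numpy())
    return out
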