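"""Synthetic picture-naming experiments with known ground truth.

The generator emulates the structure of a two-part norming study
(objects named first, then actions) so that every downstream stage —
coding, agreement, complexity scoring, norm aggregation, and the latency
model — can be exercised and validated against known parameters:

* per-picture name distributions are a single Dirichlet draw over a
  fixed name pool, so name-agreement entropy is controlled by the
  concentration vector;
* trial outcomes (valid / invalid / no response) are i.i.d. with
  class-specific rates defaulting to the rates observed in a large
  laboratory norming study of Polish object and action pictures;
* naming latencies are generated by inverting the analysis model: a
  Gaussian linear model on the -1000/RT scale with fixed effects and
  random intercepts for participants, pictures, and names within
  pictures — so the mixed-model analysis is exactly well-specified and
  parameter recovery is a clean oracle;
* ratings are round-then-clip discretized Gaussians on bounded integer
  scales.

Name tokens are synthetic ("name_<picture>_<j>"); no Polish morphology
is simulated.  Instead, explicit unification maps (surface form ->
infinitive, aspect/reflexive merges, roots, synonyms) are generated
alongside the data so the coding module has realistic work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coding import INVALID, NO_RESPONSE, VALID, UnificationMaps

WORD_CLASSES = ("object", "action")

#: Observed outcome rates (valid, invalid, no_response).  The printed
#: object rates sum to 0.9989; both vectors are renormalized onto the
#: simplex at config construction.
RAW_OUTCOME_RATES = {
    "object": (0.9836, 0.0032, 0.0121),
    "action": (0.9561, 0.0087, 0.0351),
}

DEFAULT_RATING_SCALES = {
    "goodness_of_depiction": (0, 3),
    "image_agreement": (1, 7),
    "concept_familiarity": (1, 7),
    "imageability": (1, 7),
    "age_of_acquisition": (1, 18),
}

DEFAULT_N_RATERS = {
    "goodness_of_depiction": 36,
    "image_agreement": 46,
    "concept_familiarity": 37,
    "imageability": 54,
    "age_of_acquisition": 58,
}

#: Default fixed effects on the -1000/RT scale, named after the eight
#: study predictors (values of the magnitude seen in object-naming fits).
DEFAULT_BETAS = {
    "H": -0.31,
    "goodness_of_depiction": 0.01,
    "image_agreement": -0.06,
    "concept_familiarity": -0.01,
    "age_of_acquisition": -0.52,
    "imageability": -0.22,
    "frequency": -0.01,
    "complexity_index": -0.03,
}


def _normalize_rates(rates: Sequence[float]) -> tuple[float, float, float]:
    arr = np.asarray(rates, dtype=float)
    if arr.shape != (3,):
        raise ValueError("outcome rates must be (valid, invalid, no_response)")
    if (arr < 0).any():
        raise ValueError("outcome rates must be non-negative")
    total = arr.sum()
    if total <= 0:
        raise ValueError("outcome rates must have positive mass")
    return tuple(arr / total)


def default_concentration(pool: int, dominant_mass: float) -> np.ndarray:
    """Concentration vector with one heavy (dominant) component."""
    if pool < 1:
        raise ValueError("name pool must have at least one name")
    c = np.ones(pool)
    c[0] = dominant_mass
    return c


@dataclass
class SimulationConfig:
    """Everything needed to generate one synthetic norming experiment.

    Defaults reproduce the study conditions of the reference norming
    experiment: 98 participants, 168 object and 146 action pictures,
    the observed valid/invalid/no-response rates per class, latency
    locations of 897.33 ms (objects) and 1157.70 ms (actions), and the
    published rating scales and rater counts.
    """

    n_participants: int = 98
    n_pictures_objects: int = 168
    n_pictures_actions: int = 146
    name_pool_size: int = 5
    #: per-class Dirichlet concentration; scalar mass on the dominant name
    dominant_concentration: Mapping[str, float] = field(
        default_factory=lambda: {"object": 24.0, "action": 10.0}
    )
    true_betas: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BETAS))
    predictor_sd: float = 0.5
    sd_participant: float = 0.12
    sd_picture: float = 0.08
    sd_name: float = 0.05
    sd_residual: float = 0.15
    latency_location_ms: Mapping[str, float] = field(
        default_factory=lambda: {"object": 897.33, "action": 1157.70}
    )
    outcome_rates: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {k: _normalize_rates(v) for k, v in RAW_OUTCOME_RATES.items()}
    )
    rating_scales: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RATING_SCALES)
    )
    n_raters: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_N_RATERS))
    rating_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_participants", "n_pictures_objects", "n_pictures_actions",
                     "name_pool_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("sd_participant", "sd_picture", "sd_name", "sd_residual",
                     "rating_sd", "predictor_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for wc, mass in self.dominant_concentration.items():
            if mass <= 0:
                raise ValueError(f"dominant_concentration[{wc!r}] must be > 0")
        for wc, loc in self.latency_location_ms.items():
            if loc <= 0:
                raise ValueError(f"latency_location_ms[{wc!r}] must be > 0")
        self.outcome_rates = {
            wc: _normalize_rates(r) for wc, r in self.outcome_rates.items()
        }
        for wc, r in self.outcome_rates.items():
            if abs(sum(r) - 1.0) > 1e-9:
                raise ValueError(f"outcome_rates[{wc!r}] do not sum to 1")

    def pictures(self, word_class: str) -> list[str]:
        n = self.n_pictures_objects if word_class == "object" else self.n_pictures_actions
        prefix = "obj" if word_class == "object" else "act"
        return [f"{prefix}{i:04d}" for i in range(n)]

    def concentration(self, word_class: str) -> np.ndarray:
        return default_concentration(
            self.name_pool_size, self.dominant_concentration[word_class]
        )


@dataclass
class GroundTruth:
    """The latent quantities behind one simulated dataset."""

    name_probs: dict[str, np.ndarray]
    betas: dict[str, float]
    participant_intercepts: dict[str, float] = field(default_factory=dict)
    picture_intercepts: dict[str, float] = field(default_factory=dict)
    name_intercepts: dict[str, float] = field(default_factory=dict)
    n_resampled: int = 0


def _subrng(seed: int, stage: int) -> np.random.Generator:
    """Deterministic per-stage stream derived from one dataset seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


def canonical_names(config: SimulationConfig, picture: str) -> list[str]:
    return [f"name_{picture}_{j}" for j in range(config.name_pool_size)]


def make_unification_maps(config: SimulationConfig) -> UnificationMaps:
    """Token-merge tables mirroring verb morphology, generated explicitly.

    Each action name has two surface forms ("<name>~s0", "<name>~s1")
    that the infinitive map collapses; the last two names of each action
    pool form an aspect pair merged by strategy 3.  For objects, the last
    pool name is registered as a synonym of the dominant-pool name, and
    merged pairs share a root class (driving Lexical Code 2).
    """
    infinitive_map: dict[str, str] = {}
    merge_map: dict[str, str] = {}
    root_map: dict[str, str] = {}
    synonym_map: dict[str, str] = {}
    lexicon: set[str] = set()
    pool = config.name_pool_size
    for wc in WORD_CLASSES:
        for pic in config.pictures(wc):
            names = canonical_names(config, pic)
            lexicon.update(names)
            for name in names:
                root_map[name] = name
            if wc == "action":
                for name in names:
                    for s in range(2):
                        surface = f"{name}~s{s}"
                        infinitive_map[surface] = name
                        lexicon.add(surface)
                        root_map[surface] = name
                if pool >= 2:
                    merge_map[names[-1]] = names[-2]
                    merge_map[names[-2]] = names[-2]
                    root_map[names[-1]] = names[-2]
            elif pool >= 2:
                synonym_map[names[-1]] = names[0]
    return UnificationMaps(
        infinitive_map=infinitive_map,
        merge_map=merge_map,
        root_map=root_map,
        synonym_map=synonym_map,
        lexicon=lexicon,
    )


def generate_name_responses(
    config: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """One naming response per participant x picture.

    Per-picture name probabilities are a single Dirichlet draw with the
    configured concentration; the drawn canonical name is rendered as a
    surface form ("<name>~s<j>") for actions so the unification maps
    have work to do.
    """
    rng = _subrng(config.seed if seed is None else seed, 0)
    participants = [f"p{i:03d}" for i in range(config.n_participants)]
    name_probs: dict[str, np.ndarray] = {}
    rows = []
    for wc in WORD_CLASSES:
        conc = config.concentration(wc)
        for pic in config.pictures(wc):
            names = canonical_names(config, pic)
            probs = rng.dirichlet(conc)
            name_probs[pic] = probs
            draws = rng.choice(len(names), size=len(participants), p=probs)
            for part, j in zip(participants, draws):
                canonical = names[j]
                raw = f"{canonical}~s{rng.integers(2)}" if wc == "action" else canonical
                rows.append((part, pic, wc, raw, canonical))
    trials = pd.DataFrame(
        rows, columns=["participant", "picture", "word_class", "raw_name", "canonical_name"]
    )
    return trials, GroundTruth(name_probs=name_probs, betas=dict(config.true_betas))


def generate_trial_outcomes(
    trials: pd.DataFrame,
    rates: Mapping[str, Sequence[float]] | Sequence[float],
    seed: int = 0,
) -> pd.DataFrame:
    """Label each trial valid / invalid / no_response independently.

    No-response trials lose their transcription; invalid trials keep the
    name but will never receive a latency.
    """
    rng = _subrng(seed, 1)
    out = trials.copy()
    labels = np.empty(len(out), dtype=object)
    classes = np.array([VALID, INVALID, NO_RESPONSE], dtype=object)
    if isinstance(rates, Mapping):
        per_class = {wc: _normalize_rates(r) for wc, r in rates.items()}
        for wc, sub in out.groupby("word_class"):
            p = per_class[wc]
            labels[out.index.get_indexer(sub.index)] = rng.choice(
                classes, size=len(sub), p=p
            )
    else:
        p = _normalize_rates(rates)
        labels[:] = rng.choice(classes, size=len(out), p=p)
    out["validity"] = labels
    out.loc[out["validity"] == NO_RESPONSE, "raw_name"] = ""
    out.loc[out["validity"] == NO_RESPONSE, "canonical_name"] = ""
    return out


def generate_predictors(
    config: SimulationConfig, seed: int = 0
) -> pd.DataFrame:
    """Predictor values per (picture, canonical name), on the analysis scale.

    Columns are named after the fixed effects in ``config.true_betas``
    and are drawn i.i.d. Gaussian with SD ``predictor_sd`` — i.e. they
    represent already-transformed, demeaned predictors.
    """
    rng = _subrng(seed, 2)
    rows = []
    for wc in WORD_CLASSES:
        for pic in config.pictures(wc):
            for name in canonical_names(config, pic):
                rows.append((pic, name, wc))
    pred = pd.DataFrame(rows, columns=["picture", "name", "word_class"])
    for key in config.true_betas:
        pred[key] = rng.normal(0.0, config.predictor_sd, size=len(pred))
    return pred


def generate_latencies(
    trials: pd.DataFrame,
    predictors: pd.DataFrame,
    config: SimulationConfig,
    seed: int = 0,
    ground_truth: GroundTruth | None = None,
    max_violation_frac: float = 0.01,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Latency per valid trial by inverting the -1000/RT analysis model.

    y = intercept(class) + x'beta + u_participant + v_picture + w_name + eps,
    latency = -1000/y.  The class intercept is -1000/location so that
    with all effects at zero the latency equals the configured location.
    Rows where y >= 0 (which would invert to a non-positive latency) are
    resampled on their residual and counted; if more than
    ``max_violation_frac`` of trials violate on the first pass the
    configuration is rejected with advice to adjust the intercept.
    """
    gt = ground_truth or GroundTruth(name_probs={}, betas=dict(config.true_betas))
    rng = _subrng(seed, 3)
    out = trials.copy()
    beta_names = list(config.true_betas)
    pred = predictors.set_index(["picture", "name"])

    participants = sorted(out["participant"].unique())
    pictures = sorted(out["picture"].unique())
    u = dict(zip(participants, rng.normal(0, config.sd_participant, len(participants))))
    v = dict(zip(pictures, rng.normal(0, config.sd_picture, len(pictures))))
    name_keys = sorted(set(zip(pred.index.get_level_values(0), pred.index.get_level_values(1))))
    w = dict(zip(name_keys, rng.normal(0, config.sd_name, len(name_keys))))
    gt.participant_intercepts = {k: float(x) for k, x in u.items()}
    gt.picture_intercepts = {k: float(x) for k, x in v.items()}
    gt.name_intercepts = {f"{p}:{n}": float(x) for (p, n), x in w.items()}

    valid = out["validity"] == VALID if "validity" in out.columns else pd.Series(True, index=out.index)
    out["latency_ms"] = np.nan
    vrows = out.loc[valid]
    if vrows.empty:
        return out, gt
    missing = [
        (p, n)
        for p, n in zip(vrows["picture"], vrows["canonical_name"])
        if (p, n) not in pred.index
    ]
    if missing:
        raise ValueError(f"no predictor row for (picture, name) pairs: {missing[:5]}")
    X = pred.loc[list(zip(vrows["picture"], vrows["canonical_name"])), beta_names].to_numpy()
    beta = np.array([config.true_betas[b] for b in beta_names])
    intercepts = np.array(
        [-1000.0 / config.latency_location_ms[wc] for wc in vrows["word_class"]]
    )
    mean = (
        intercepts
        + X @ beta
        + np.array([u[p] for p in vrows["participant"]])
        + np.array([v[p] for p in vrows["picture"]])
        + np.array([w[(p, n)] for p, n in zip(vrows["picture"], vrows["canonical_name"])])
    )
    y = mean + rng.normal(0, config.sd_residual, len(mean))
    bad = y >= 0
    frac = bad.mean()
    if frac > max_violation_frac:
        raise ValueError(
            f"{frac:.1%} of trials produced non-negative transformed latency; "
            "lower the betas/SDs or move the intercept (latency_location_ms) down"
        )
    n_resampled = int(bad.sum())
    tries = 0
    while bad.any():
        y[bad] = mean[bad] + rng.normal(0, config.sd_residual, bad.sum())
        bad = y >= 0
        tries += 1
        if tries > 1000:
            raise ValueError("could not keep transformed latency negative")
    gt.n_resampled = n_resampled
    out.loc[valid, "latency_ms"] = -1000.0 / y
    return out, gt


def generate_ratings(
    item_means: Mapping[str, float],
    scale_bounds: tuple[float, float],
    n_raters: int,
    seed: int = 0,
    rating_sd: float = 1.0,
) -> pd.DataFrame:
    """Integer ratings from a round-then-clip discretized Gaussian.

    Each rater's rating of an item is a Gaussian draw around the item
    mean, rounded to the nearest integer and clipped to the scale.
    """
    lo, hi = scale_bounds
    for item, m in item_means.items():
        if not (lo <= m <= hi):
            raise ValueError(f"item {item!r}: mean {m} outside bounds [{lo}, {hi}]")
    rng = _subrng(seed, 4)
    items = list(item_means)
    rows = []
    for r in range(n_raters):
        draws = rng.normal([item_means[i] for i in items], rating_sd)
        vals = np.clip(np.rint(draws), lo, hi).astype(int)
        rows.extend((f"r{r:03d}", item, int(v)) for item, v in zip(items, vals))
    return pd.DataFrame(rows, columns=["rater_id", "item_id", "value"])


def generate_word_features(
    config: SimulationConfig, seed: int = 0
) -> pd.DataFrame:
    """Random but plausible word-feature rows for every canonical name."""
    rng = _subrng(seed, 5)
    rows = []
    for wc in WORD_CLASSES:
        word_class = "noun" if wc == "object" else "verb"
        for pic in config.pictures(wc):
            for name in canonical_names(config, pic):
                rows.append(
                    {
                        "word": name,
                        "word_class": word_class,
                        "phoneme_count": int(rng.integers(3, 11)),
                        "initial_fricative_affricate": bool(rng.random() < 0.3),
                        "initial_cluster": bool(rng.random() < 0.25),
                        "medial_cluster": bool(rng.random() < 0.4),
                        "n_stems": int(1 + (rng.random() < 0.08)),
                        "is_derivation": bool(rng.random() < 0.3),
                        "has_prefix": bool(rng.random() < 0.15),
                        "has_suffix": bool(rng.random() < 0.35),
                        "available_in_country": bool(rng.random() < 0.97),
                        "preschool_access": rng.choice(
                            ["not_or_rarely", "quite_often", "very_often"],
                            p=[0.2, 0.3, 0.5],
                        ),
                        "is_loanword": bool(rng.random() < 0.15),
                    }
                )
    return pd.DataFrame(rows)


def generate_word_estimates(
    config: SimulationConfig, seed: int = 0,
    missing_frequency_rates: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Raw word estimates (AoA, imageability, log frequency) per name.

    A class-specific share of names gets a missing frequency, mirroring
    multiword names and reflexive verbs for which corpus lemma
    frequencies cannot be looked up.
    """
    rng = _subrng(seed, 6)
    miss = dict(missing_frequency_rates or {"object": 0.081, "action": 0.1745})
    rows = []
    for wc in WORD_CLASSES:
        for pic in config.pictures(wc):
            for name in canonical_names(config, pic):
                freq = float(np.clip(rng.normal(7.6, 1.5), 0.5, None))
                if rng.random() < miss[wc]:
                    freq = np.nan
                rows.append(
                    {
                        "name": name,
                        "word_class": wc,
                        "age_of_acquisition": float(np.clip(rng.normal(4.0, 1.2), 1, 18)),
                        "imageability": float(np.clip(rng.normal(6.0, 0.6), 1, 7)),
                        "frequency": freq,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class SimulatedExperiment:
    """A complete synthetic norming experiment plus its ground truth."""

    config: SimulationConfig
    trials: pd.DataFrame
    maps: UnificationMaps
    predictors: pd.DataFrame
    ratings: dict[str, pd.DataFrame]
    word_features: pd.DataFrame
    word_estimates: pd.DataFrame
    ground_truth: GroundTruth


def simulate_experiment(config: SimulationConfig, seed: int | None = None) -> SimulatedExperiment:
    """Run every generation stage with deterministic per-stage sub-seeds."""
    seed = config.seed if seed is None else seed
    maps = make_unification_maps(config)
    trials, gt = generate_name_responses(config, seed)
    trials = generate_trial_outcomes(trials, config.outcome_rates, seed)
    predictors = generate_predictors(config, seed)
    trials, gt = generate_latencies(trials, predictors, config, seed, ground_truth=gt)
    rng = _subrng(seed, 7)
    ratings = {}
    picture_items = [p for wc in WORD_CLASSES for p in config.pictures(wc)]
    word_items = [
        n for wc in WORD_CLASSES for pic in config.pictures(wc)
        for n in canonical_names(config, pic)
    ]
    for idx, (study, bounds) in enumerate(sorted(config.rating_scales.items())):
        items = word_items if study in ("imageability", "age_of_acquisition") else picture_items
        lo, hi = bounds
        span = hi - lo
        means = {
            item: float(lo + span * np.clip(rng.beta(2.5, 2.5), 0.02, 0.98))
            for item in items
        }
        ratings[study] = generate_ratings(
            means, bounds, config.n_raters[study],
            seed=(seed + idx + 1) % 2**31, rating_sd=config.rating_sd,
        )
    return SimulatedExperiment(
        config=config,
        trials=trials,
        maps=maps,
        predictors=predictors,
        ratings=ratings,
        word_features=generate_word_features(config, seed),
        word_estimates=generate_word_estimates(config, seed),
        ground_truth=gt,
    )
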