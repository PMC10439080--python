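"""End-to-end pipeline driver.

Executes simulate -> code -> agreement -> complexity -> norms -> analyze
and writes every artifact plus a manifest (package version, seed, config,
SHA-256 of each output) so a run is reproducible from config + seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import agreement, complexity, inference, norms, simulate, tableio
from .coding import VALID, code_trials

logger = logging.getLogger(__name__)


def load_config(path: str | Path) -> dict:
    """Read a pipeline configuration from a plain-text YAML key-value file."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: dict | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
) -> dict:
    """Run the full pipeline; returns the manifest dictionary.

    The config either requests a simulation (key ``simulation`` with
    :class:`~picnorm.simulate.SimulationConfig` field overrides) or names
    input tables (keys ``trials``, ``ratings``, ``word_features``,
    ``word_estimates``).  Any stage failure propagates with the stage
    named.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        written[name] = tableio.write_table(df, out / f"{name}.tsv")

    stage = "simulate/load"
    try:
        if "simulation" in config or "trials" not in config:
            sim_kwargs = dict(config.get("simulation") or {})
            if seed is not None:
                sim_kwargs["seed"] = int(seed)
            sim_config = simulate.SimulationConfig(**sim_kwargs)
            exp = simulate.simulate_experiment(sim_config)
            trials = exp.trials
            maps = exp.maps
            word_features = exp.word_features
            word_estimates = exp.word_estimates
            predictors = exp.predictors
            rating_frames = []
            for study, table in exp.ratings.items():
                t = table.copy()
                t["study"] = study
                rating_frames.append(t)
            ratings = pd.concat(rating_frames, ignore_index=True)
            emit("trials", trials.drop(columns=["canonical_name"]))
            emit("ratings", ratings)
            emit("word_features", word_features)
            emit("word_estimates", word_estimates)
            emit("predictors", predictors)
            emit(
                "ground_truth_betas",
                pd.DataFrame(
                    {"term": list(exp.ground_truth.betas),
                     "beta": list(exp.ground_truth.betas.values())}
                ),
            )
        else:
            trials = tableio.read_table(config["trials"], tableio.TRIALS_SCHEMA)
            ratings = tableio.read_table(config["ratings"], tableio.RATINGS_SCHEMA)
            word_features = tableio.read_table(
                config["word_features"], tableio.WORD_FEATURES_SCHEMA
            )
            word_estimates = tableio.read_table(
                config["word_estimates"], tableio.WORD_ESTIMATES_SCHEMA
            )
            maps = None
            predictors = None
            exp = None

        stage = "code"
        trials = code_trials(trials, maps)

        stage = "agreement"
        agreement_df = agreement.agreement_table(trials, maps)
        emit("agreement", agreement_df)

        stage = "complexity"
        ci_df = complexity.complexity_table(word_features)
        emit("complexity", ci_df)

        stage = "norms"
        rating_agg = norms.aggregate_ratings(ratings)
        dominant_df, extended_df = norms.build_norm_table(
            trials,
            maps=maps,
            rating_aggregates=rating_agg,
            word_estimates=word_estimates,
            ci_table=ci_df,
        )
        emit("norms_dominant", dominant_df)
        emit("norms_extended", extended_df)
        summary_vars = [
            v for v in ("H", "na_pct", "latency_mean") if v in dominant_df.columns
        ]
        emit("descriptives", norms.descriptive_summary(dominant_df, summary_vars))

        stage = "analyze"
        analyze_outputs = _analyze(trials, dominant_df, predictors, emit)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {
        "package": "picnorm",
        "version": __version__,
        "seed": seed if seed is not None else config.get("simulation", {}).get("seed"),
        "config": {k: v for k, v in config.items()},
        "outputs": {name: _sha256(path) for name, path in sorted(written.items())},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str), encoding="utf-8"
    )
    return manifest


def _analyze(trials, dominant_df, predictors, emit) -> None:
    """Correlations, class comparisons, VIF, and the latency model."""
    numeric_vars = [
        v
        for v in (
            "H",
            "na_pct",
            "latency_mean",
            "goodness_of_depiction_mean",
            "image_agreement_mean",
            "concept_familiarity_mean",
            "age_of_acquisition",
            "imageability",
            "frequency",
            "ci",
        )
        if v in dominant_df.columns
    ]
    ok_rows = dominant_df[~dominant_df["flagged_no_valid"].astype(bool)]
    if len(ok_rows) >= 5 and len(numeric_vars) >= 2:
        mats = inference.spearman_matrix(ok_rows, numeric_vars)
        emit("spearman_rho", mats["rho"].reset_index(names="variable"))
        emit("spearman_significant", mats["significant"].reset_index(names="variable"))
        obj = ok_rows[ok_rows["word_class"] == "object"]
        act = ok_rows[ok_rows["word_class"] == "action"]
        if len(obj) >= 2 and len(act) >= 2:
            emit(
                "class_comparisons",
                inference.compare_class_table(obj, act, numeric_vars),
            )

    if predictors is None:
        return
    beta_terms = [c for c in predictors.columns if c not in ("picture", "name", "word_class")]
    valid = trials[trials["validity"] == VALID].copy()
    valid["neg_inv_rt"] = -1000.0 / valid["latency_ms"]
    merged = valid.merge(
        predictors,
        left_on=["picture", "canonical_name"] if "canonical_name" in valid.columns else ["picture", "raw_name"],
        right_on=["picture", "name"],
        how="inner",
        suffixes=("", "_pred"),
    )
    if merged.empty:
        logger.warning("no trials matched predictor rows; skipping latency model")
        return
    emit("vif", inference.compute_vif(merged[beta_terms]).rename_axis("term").reset_index())
    for wc, sub in merged.groupby("word_class"):
        result = inference.fit_latency_model(sub, beta_terms, name_col="name")
        emit(f"latency_model_{wc}", result.fixed_effects)
        emit(
            f"latency_model_{wc}_random",
            pd.DataFrame(
                {
                    "component": list(result.random_components),
                    "variance": list(result.random_components.values()),
                }
            ),
        )
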