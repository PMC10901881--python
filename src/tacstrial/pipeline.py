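"""End-to-end pipeline wiring and trial-table file I/O.

``run_pipeline`` executes simulate -> preprocess -> fit/select ->
learning indices -> trial statistics on a ``StudyConfig`` and writes a
versioned report bundle (CSV tables, JSON reports, the config itself and
its hash) under the config's output directory.  Runs are bit-reproducible
given the config's seeds.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort, lmm, outcomes, preprocess, trialstats
from .config import StudyConfig
from .sequence import TRIAL_COLUMNS

log = logging.getLogger("tacstrial")

SCHEMA_VERSION = "tacstrial-trials-v1"


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def dump_json(data: dict, path: Path) -> None:
    path.write_text(json.dumps(data, indent=2, default=_jsonify))


_DTYPES = {
    "participant_id": str,
    "session": np.int64,
    "block": np.int64,
    "trial_index_in_block": np.int64,
    "stimulus_position": np.int64,
    "trial_type": str,
    "is_practice": bool,
    "triplet_class": str,
    "is_trill": bool,
    "is_repetition": bool,
    "rt_ms": float,
}


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Lossless RFC-4180 CSV round-trip with a versioned header comment."""
    path = Path(path)
    cols = [c for c in TRIAL_COLUMNS if c in trials.columns] + [
        c for c in trials.columns if c not in TRIAL_COLUMNS
    ]
    with open(path, "w", newline="") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION}\n")
        trials[cols].to_csv(fh, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial CSV written by :func:`write_trials`, validating schema."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial file {path} is missing columns: {missing}")
    for col, dtype in _DTYPES.items():
        df[col] = df[col].astype(dtype)
    df["correct"] = df["correct"].astype("boolean")
    return df


def run_pipeline(config: StudyConfig, *, make_figures: bool = True) -> dict:
    """Run every stage; return the report bundle (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    seeds = {
        "cohort": config.seed_cohort,
        "responses": config.seed_responses,
        "meta": config.seed_meta,
    }
    provenance = {"config_hash": config.digest(), "seeds": seeds}
    model = config.generative_model

    log.info("simulating cohort (%d active / %d sham)", config.n_active, config.n_sham)
    profiles = cohort.sample_cohort(
        config.n_active, config.n_sham, model=model, rng_seed=config.seed_cohort
    )
    prof_df = cohort.profiles_frame(profiles)
    prof_df.to_csv(out / "participants.csv", index=False)

    trials = cohort.simulate_responses(
        profiles,
        model,
        sessions=config.sessions,
        n_blocks=config.n_blocks,
        trials_per_block=config.trials_per_block,
        practice_blocks=config.practice_blocks,
        same_pattern_across_sessions=config.same_pattern_across_sessions,
        rng_seed=config.seed_responses,
    )
    write_trials(trials, out / "trials.csv")

    log.info("filtering %d trials", len(trials))
    filtered, report = preprocess.filter_trials(trials)
    log.info(
        "excluded %.1f%% (practice %d, first-two %d, trill %d, repetition %d)",
        100 * report.excluded_fraction,
        report.removed_practice,
        report.removed_first_two,
        report.removed_trill,
        report.removed_repetition,
    )
    aggregates = preprocess.aggregate_epochs(
        filtered, practice_blocks=config.practice_blocks
    )
    aggregates.to_csv(out / "epoch_aggregates.csv", index=False)
    dump_json({**report.to_dict(), **provenance}, out / "exclusion_report.json")

    log.info("fitting candidate models")
    comparison = lmm.compare_models(aggregates, lmm.default_model_family())
    selected = lmm.fit_model(aggregates, comparison.selected.spec)
    for f in comparison.fits:
        log.info("AIC %.1f  converged=%s  %s", f.aic, f.converged, f.spec.name)
    comparison.aic_table().to_csv(out / "model_comparison.csv", index=False)
    dump_json({**selected.to_dict(), **provenance}, out / "selected_model.json")
    (out / "selected_model.txt").write_text(selected.to_table() + "\n")

    indices = outcomes.extract_indices(selected)
    scores = outcomes.descriptive_scores(aggregates)
    dump_json({**indices.to_dict(), **provenance}, out / "learning_indices.json")
    scores.per_participant.to_csv(out / "learning_scores.csv", index=False)

    guesses, ae_counts = cohort.simulate_trial_meta(
        profiles,
        guess_probs=config.guess_probs,
        n_stim_sessions=config.n_stim_sessions,
        rng_seed=config.seed_meta,
    )
    blinding = trialstats.blinding_assessment(trialstats.blinding_table(guesses))
    baseline = trialstats.baseline_comparisons(prof_df)
    ae_tests = trialstats.adverse_event_comparison(ae_counts)
    trial_report = {
        "blinding": blinding.to_dict(),
        "baseline": [t.__dict__ for t in baseline],
        "adverse_events": [t.__dict__ for t in ae_tests],
        **provenance,
    }
    dump_json(trial_report, out / "trial_statistics.json")
    (out / "baseline_table.txt").write_text(
        trialstats.baseline_table(prof_df) + "\n"
    )

    if make_figures:
        outcomes.plot_learning(scores, aggregates, str(out / "learning.png"))

    return {
        "provenance": provenance,
        "exclusion": report.to_dict(),
        "aic_table": comparison.aic_table().to_dict("records"),
        "selected_model": selected.to_dict(),
        "learning_indices": indices.to_dict(),
        "trial_statistics": trial_report,
    }
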