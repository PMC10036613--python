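"""End-to-end experiment: generate games, simulate gaze, render, train, and
evaluate on the full test set plus eight partial-scanpath test sets.

The protocol mirrors the early-prediction design: a single model is
trained once, on full scanpaths from training participants only, and that
same fitted artifact is then evaluated on the held-out participants' full
scanpaths and on partial scanpaths cut at 15/30/50/80% of trial duration
and at 2/5/10/15 s.  Accuracy as a function of the cut quantifies how
early the strategy is detectable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import BASELINE_COLUMNS, features_frame
from .games import Game, StrategyLabel, generate_battery, read_games
from .models import (
    CT1,
    CT2,
    Metrics,
    SplitAssignment,
    balance_binary,
    evaluate,
    split_participants,
    train_logit,
    train_svm_image,
)
from .render import AOILayout, RenderSpec, build_layout, render_to_array
from .synth import GeneratorConfig, ScanpathRecord, read_events, simulate_dataset
from .truncate import TruncationSpec, build_truncation_sets, default_specs

log = logging.getLogger("gazestrat")

FULL_SET = "full"


@dataclass
class ExperimentConfig:
    n_participants: int = 150
    n_do: int = 5
    n_ue: int = 5
    task: str = CT1
    model: str = "svm"  # "svm" | "logit" | "cnn"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    render_spec: RenderSpec = field(default_factory=RenderSpec)
    truncation_grid: list[TruncationSpec] = field(default_factory=default_specs)
    split_fractions: tuple[float, float, float] = (0.7, 0.2, 0.1)
    seed: int = 0
    svm_cv_config: dict | None = None

    def __post_init__(self) -> None:
        if self.task not in (CT1, CT2):
            raise ValueError(f"task must be CT1 or CT2, got {self.task!r}")
        if self.model not in ("svm", "logit", "cnn"):
            raise ValueError(f"unknown model {self.model!r}")


@dataclass
class ExperimentResult:
    per_set: dict[str, Metrics]
    manifest: dict

    def metrics_frame(self) -> pd.DataFrame:
        rows = [
            {"set": name, "accuracy": m.accuracy, "auc": m.auc, "f1": m.f1, "n": m.n}
            for name, m in self.per_set.items()
        ]
        return pd.DataFrame(rows)


def _targets(records: list[ScanpathRecord], task: str) -> np.ndarray:
    labels = [r.label for r in records]
    if any(l is None for l in labels):
        raise ValueError("records must carry strategy labels")
    if task == CT1:
        return np.array([int(l is StrategyLabel.EQUILIBRIUM) for l in labels])
    return np.array([l.value for l in labels])


def _render_all(records, layout, spec) -> np.ndarray:
    return np.stack([render_to_array(r, layout, spec) for r in records])


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Execute every stage and return per-set metrics plus a manifest."""
    rng = np.random.default_rng(config.seed)
    layout = build_layout()
    manifest: dict = {
        "seed": config.seed,
        "task": config.task,
        "model": config.model,
        "versions": _versions(),
        "stages": {},
    }

    battery = generate_battery(rng, n_do=config.n_do, n_ue=config.n_ue)
    log.info("generated battery: %d games", len(battery))
    records = simulate_dataset(config.n_participants, battery, config.generator, rng, layout)
    manifest["stages"]["simulate"] = {"records": len(records), "games": len(battery)}
    log.info("simulated %d records from %d participants", len(records), config.n_participants)

    if config.task == CT1:
        n_before = len(records)
        records = balance_binary(
            records, key=lambda r: r.label is StrategyLabel.EQUILIBRIUM,
            seed=int(rng.integers(2**31)),
        )
        manifest["stages"]["balance"] = {"in": n_before, "out": len(records),
                                         "removed": n_before - len(records)}
        log.info("balanced CT1 dataset: removed %d records", n_before - len(records))

    split = split_participants(
        [r.participant_id for r in records],
        fractions=config.split_fractions,
        seed=int(rng.integers(2**31)),
    )
    train_recs = split.subset_of(records, "train")
    test_recs = split.subset_of(records, "test")
    manifest["stages"]["split"] = {
        s: len(split.ids(s)) for s in ("train", "val", "test")
    }
    log.info("split: %s", manifest["stages"]["split"])

    y_train = _targets(train_recs, config.task)
    model_seed = int(rng.integers(2**31))
    if config.model == "logit":
        df = features_frame(train_recs, layout)
        model = train_logit(df[list(BASELINE_COLUMNS)].to_numpy(), y_train, task=config.task)
    elif config.model == "svm":
        imgs = _render_all(train_recs, layout, config.render_spec)
        model = train_svm_image(imgs, y_train, task=config.task,
                                cv_config=config.svm_cv_config, seed=model_seed)
    else:
        from .cnn import train_cnn

        imgs = _render_all(train_recs, layout, config.render_spec)
        model = train_cnn(imgs, y_train, task=config.task, allow_fallback=True,
                          seed=model_seed)
    manifest["stages"]["train"] = {"records": len(train_recs), "model_seed": model_seed}
    log.info("trained %s on %d full scanpaths", config.model, len(train_recs))

    # the single trained model evaluates the full and every truncated test set
    eval_sets: dict[str, list[ScanpathRecord]] = {FULL_SET: test_recs}
    for spec, recs in build_truncation_sets(test_recs, config.truncation_grid).items():
        eval_sets[spec.name] = recs

    per_set: dict[str, Metrics] = {}
    for name, recs in eval_sets.items():
        y = _targets(recs, config.task)
        if config.model == "logit":
            df = features_frame(recs, layout)
            per_set[name] = evaluate(model, df[list(BASELINE_COLUMNS)].to_numpy(), y,
                                     task=config.task)
        else:
            imgs = _render_all(recs, layout, config.render_spec)
            if config.model == "cnn":
                from .models import compute_metrics

                per_set[name] = compute_metrics(
                    y, model.predict(imgs), scores=model.predict_proba(imgs),
                    task=config.task, classes=model.classes_)
            else:
                per_set[name] = evaluate(model, imgs, y, task=config.task,
                                         vectorize_images=True)
        log.info("evaluated set %-5s n=%d accuracy=%.3f", name, per_set[name].n,
                 per_set[name].accuracy)
    manifest["stages"]["evaluate"] = {"sets": list(per_set)}
    return ExperimentResult(per_set=per_set, manifest=manifest)


def accuracy_curve(result: ExperimentResult) -> pd.DataFrame:
    """Ordered (set, accuracy, auc) series: percent grid then time grid.

    The full set is appended to the percent series (as the 100% point).
    Raises if a configured set is missing from the result.
    """
    rows = []
    percent = sorted(
        (n for n in result.per_set if n.startswith("p")),
        key=lambda n: int(n[1:]),
    )
    times = sorted(
        (n for n in result.per_set if n.startswith("t")),
        key=lambda n: float(n[1:].rstrip("sm")),
    )
    if FULL_SET not in result.per_set:
        raise KeyError("result is missing the full-set entry")
    for series, names in (("percent", percent + [FULL_SET]), ("time", times)):
        for name in names:
            m = result.per_set[name]
            rows.append({"series": series, "set": name, "accuracy": m.accuracy,
                         "auc": m.auc})
    return pd.DataFrame(rows)


def ingest_osf_dataset(path: str | Path, games_path: str | Path | None = None) -> list[ScanpathRecord]:
    """Adapt a locally downloaded deposit into ScanpathRecords.

    Expects the event/metadata CSV dialect written by
    :func:`gazestrat.synth.write_events` (``events.csv`` + ``trials.csv``
    in one directory).  If ``games_path`` points to a games JSON file,
    choices are re-labelled against those games.  No network access is
    performed.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"dataset directory not found: {path}")
    records = read_events(path)
    if games_path is not None:
        from .games import label_choice

        games = {g.game_id: g for g in read_games(games_path)}
        relabelled = []
        for r in records:
            if r.game_id not in games:
                raise ValueError(f"trial references unknown game {r.game_id!r}")
            from dataclasses import replace

            relabelled.append(replace(r, label=label_choice(games[r.game_id], r.chosen)))
        records = relabelled
    return records


def _versions() -> dict:
    import PIL
    import sklearn

    return {
        "gazestrat": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "pillow": PIL.__version__,
    }
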