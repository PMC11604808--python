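"""End-to-end orchestration: simulate -> store -> preprocess -> datasets ->
LSTM -> fusion classifier -> evaluation, with every stochastic stage seeded
from one run seed.

A run directory receives the record store, the seizure catalog, the
normalization checkpoint, the trained models, the cached per-minute LSTM
feature table, and a JSON evaluation report, so every artifact can be
regenerated from config + seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dataset as ds
from . import evaluate as ev
from . import time_fusion as tf
from .lstm_core import (
    LstmConfig,
    StackedLstmClassifier,
    segments_to_arrays,
    train_with_restarts,
)
from .preprocess import load_normalized, preprocess_scan
from .record_store import RecordStore, SeizureCatalog
from .synthetic_eeg import SimConfig, generate_seizure_times, simulate_recording
from .time_fusion import ClassifierConfig

__all__ = ["RunConfig", "desk_config", "run_pipeline", "retarget_run"]


@dataclass
class RunConfig:
    """Everything needed to reproduce one end-to-end run."""

    sim: SimConfig
    lstm: LstmConfig
    classifier: ClassifierConfig
    paradigm: str = "paradigm1"
    segment_duration: float = 10.0
    train_fraction: float = 0.8
    exclusion_days: int = 0
    target_per_label: int | None = None
    tail_policy: str = "exclude"
    lstm_restarts: int = 5
    out_dir: str = "run"
    seed: int = 0

    def __post_init__(self) -> None:
        # one run seed fans out to every stochastic component
        base = int(self.seed) % (2**31 - 1)
        self.sim = dataclasses.replace(self.sim, seed=base)
        n_labels = ds.PARADIGMS[self.paradigm].n_labels
        self.lstm = dataclasses.replace(self.lstm, seed=base + 1, n_labels=n_labels)
        self.classifier = dataclasses.replace(
            self.classifier, seed=base + 2, n_labels=n_labels
        )


def desk_config(
    paradigm: str = "paradigm1",
    duration_days: int = 6,
    seizure_rate: float = 4.0,
    preictal_horizon: float = 16.0,
    preictal_near: float = 0.0,
    seed: int = 0,
    out_dir: str = "run",
    epochs: int = 30,
    learning_rate: float = 3e-3,
    patience: int | None = None,
    target_per_label: int = 250,
) -> RunConfig:
    """Single-CPU preset: 4 channels at 100 Hz, 2-s segments, tiny LSTM.

    The desk scale keeps every structural element of the full-scale model
    (four LSTM layers, three pools, the 5-window minute convention) while
    shrinking channels, rate, segment length and unit counts so a full run
    fits in minutes.  The learning rate is raised accordingly: the tiny
    model on hundreds of segments needs it to converge within the epoch
    budget.
    """
    sim = SimConfig(
        n_channels=4,
        sample_rate=100.0,
        duration_days=duration_days,
        seizure_rate=seizure_rate,
        preictal_mode="marker",
        preictal_horizon=preictal_horizon,
        preictal_near=preictal_near,
        dropout_rate=2.0,
        seed=seed,
    )
    lstm = LstmConfig(
        layer_units=(16, 8, 8, 4),
        pool_size=4,
        recurrent_dropout=0.25,
        learning_rate=learning_rate,
        epochs=epochs,
        batch_size=32,
        patience=patience if patience is not None else max(6, epochs // 3),
        seed=seed,
    )
    clf = ClassifierConfig(learning_rate=3e-3, epochs=150, patience=15, seed=seed)
    return RunConfig(
        sim=sim,
        lstm=lstm,
        classifier=clf,
        paradigm=paradigm,
        segment_duration=2.0,
        exclusion_days=0,
        target_per_label=target_per_label,
        out_dir=out_dir,
        seed=seed,
    )


@dataclass
class RunResult:
    config: RunConfig
    catalog: SeizureCatalog
    split: ds.SplitSpec
    lstm_model: StackedLstmClassifier
    classifier: tf.DenseFusionClassifier
    features: pd.DataFrame          # cached per-minute LSTM + time features
    minute_labels: pd.Series        # labels for every eligible labeled minute
    report: dict = field(default_factory=dict)


def _evaluate_two_label(scores, pos_indicator):
    roc = ev.roc_auc(scores, pos_indicator)
    ci = ev.hanley_mcneil_ci(roc.auc, roc.n_pos, roc.n_neg)
    # the natural operating point: pre-ictal score above inter-ictal (thr 0)
    natural = min(
        ev.operating_points(scores, pos_indicator),
        key=lambda p: abs(p.threshold) if np.isfinite(p.threshold) else np.inf,
    )
    return roc, ci, natural


def _minute_scores(classifier, features, minutes):
    X = features.loc[minutes].to_numpy()
    return classifier.predict(X)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full desk-scale study; see module docstring for stages."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paradigm = ds.PARADIGMS[config.paradigm]

    # 1. simulate and persist
    schedule = generate_seizure_times(config.sim)
    store = RecordStore(out / "store")
    manifest = store.write_recording(
        patient_id="synthetic",
        channels=config.sim.n_channels,
        sample_rate=config.sim.sample_rate,
        records=simulate_recording(config.sim, schedule),
    )
    catalog = ds.find_lead_seizures(schedule.to_catalog())
    catalog.to_csv(store.catalog_path)

    # 2. preprocessing pass: daily divisors + screening
    index = preprocess_scan(store, manifest)

    # 3. eligibility, split, labels
    eligible = ds.apply_exclusions(
        index.kept_minutes,
        catalog,
        recording_start=manifest.start_times[0],
        exclusion_days=config.exclusion_days,
    )
    split = ds.split_by_seizures(
        catalog,
        recording_start=manifest.start_times[0],
        recording_end=manifest.start_times[-1] + pd.Timedelta(minutes=1),
        train_fraction=config.train_fraction,
    )
    labels = {}
    for ts in eligible:
        lab = ds.label_minute(ts, catalog, paradigm, config.tail_policy)
        if lab is not None:
            labels[ts] = lab
    minute_labels = pd.Series(labels).sort_index()
    train_minutes = minute_labels.index[minute_labels.index < split.boundary]
    test_minutes = minute_labels.index[minute_labels.index >= split.boundary]

    loader = lambda ts: load_normalized(store, ts, index)

    # 4. balanced segment set and LSTM training
    train_segments = ds.build_lstm_train_set(
        train_minutes,
        catalog,
        paradigm,
        loader,
        duration=config.segment_duration,
        target_per_label=config.target_per_label,
        seed=config.seed + 101,
        tail_policy=config.tail_policy,
    )
    time_steps = round(config.segment_duration * config.sim.sample_rate)
    X, y = segments_to_arrays(train_segments)
    lstm_model = train_with_restarts(
        config.lstm,
        (time_steps, config.sim.n_channels),
        X,
        y,
        max_restarts=config.lstm_restarts,
    )
    lstm_model.save(out / "lstm_model.npz")

    # 5. frozen-LSTM per-minute feature cache (train + test)
    features = tf.cache_minute_features(
        lstm_model, minute_labels.index, loader, catalog,
        duration=config.segment_duration,
    )
    features.to_csv(out / "minute_features.csv")

    # 6. fusion classifier on balanced minute-level items
    Xc, yc = ds.build_classifier_train_set(
        features.loc[train_minutes].to_numpy(),
        minute_labels.loc[train_minutes].to_numpy(),
        seed=config.seed + 102,
    )
    classifier = tf.DenseFusionClassifier(
        config.classifier, input_width=features.shape[1]
    )
    classifier.fit(Xc, yc)

    # 7. evaluation on the untouched, unbalanced test minutes
    report: dict = {
        "paradigm": config.paradigm,
        "n_labels": paradigm.n_labels,
        "n_train_minutes": int(len(train_minutes)),
        "n_test_minutes": int(len(test_minutes)),
        "n_lead_seizures": int(catalog.lead_flags.sum()),
        "split_boundary": str(split.boundary),
        "lstm_structure": lstm_model.structure_report(),
        "classifier_structure": classifier.structure_report(),
    }
    y_test = minute_labels.loc[test_minutes].to_numpy()
    if len(test_minutes) and paradigm.n_labels == 2:
        scores = ev.combine_scores(_minute_scores(classifier, features, test_minutes))
        pos = (y_test == 0).astype(int)
        if pos.sum() and (1 - pos).sum():
            roc, ci, natural = _evaluate_two_label(scores, pos)
            report["classifier_auc"] = ci.auc
            report["classifier_ci_half_width"] = ci.half_width
            report["classifier_ci_lower"] = ci.lower
            report["significant_vs_random"] = bool(ev.vs_random(ci))
            report["natural_operating_point"] = dataclasses.asdict(natural)
        # segment-level LSTM AUC from the cached 5 outputs per minute
        seg_scores, seg_pos = [], []
        n_out = paradigm.n_labels
        lstm_block = features.loc[test_minutes].to_numpy()[:, : 5 * n_out]
        for k in range(5):
            seg_scores.append(
                lstm_block[:, k * n_out + 0] - lstm_block[:, k * n_out + 1]
            )
            seg_pos.append(pos)
        seg_scores = np.concatenate(seg_scores)
        seg_pos = np.concatenate(seg_pos)
        if seg_pos.sum() and (1 - seg_pos).sum():
            roc_l = ev.roc_auc(seg_scores, seg_pos)
            ci_l = ev.hanley_mcneil_ci(roc_l.auc, roc_l.n_pos, roc_l.n_neg)
            report["lstm_segment_auc"] = ci_l.auc
            report["lstm_segment_ci_lower"] = ci_l.lower
            report["lstm_segment_significant"] = bool(ev.vs_random(ci_l))
    elif len(test_minutes):
        preds = np.argmax(_minute_scores(classifier, features, test_minutes), axis=1)
        cm = ev.confusion_and_baseline(y_test, preds, paradigm.n_labels)
        report["confusion_counts"] = cm.counts.tolist()
        report["total_accuracy"] = cm.total_accuracy
        report["selection_proportions"] = cm.selection_proportions.tolist()
        report["baseline_sensitivity"] = cm.baseline_sensitivity.tolist()
        report["model_sensitivity"] = cm.model_sensitivity.tolist()
        report["better_than_baseline"] = cm.better.tolist()

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    minute_labels.to_frame("label").to_csv(out / "minute_labels.csv")
    with open(out / "split.json", "w") as fh:
        json.dump(
            {
                "boundary": str(split.boundary),
                "train_start": str(split.train_start),
                "test_end": str(split.test_end),
            },
            fh,
        )
    return RunResult(
        config=config,
        catalog=catalog,
        split=split,
        lstm_model=lstm_model,
        classifier=classifier,
        features=features,
        minute_labels=minute_labels,
        report=report,
    )


def retarget_run(
    result: RunResult,
    new_paradigm: str,
    classifier_config: ClassifierConfig | None = None,
    tail_policy: str = "exclude",
) -> dict:
    """Retrain only the fusion classifier under new labels (frozen LSTM).

    Uses the cached feature table from the original run; returns an
    evaluation report for the new labeling on the test range, including a
    checksum proof that the LSTM weights were untouched.
    """
    paradigm = ds.PARADIGMS[new_paradigm]
    cfg = classifier_config or dataclasses.replace(
        result.config.classifier, n_labels=paradigm.n_labels
    )
    if cfg.n_labels != paradigm.n_labels:
        cfg = dataclasses.replace(cfg, n_labels=paradigm.n_labels)
    checksum_before = result.lstm_model.checksum()

    labels = {}
    for ts in result.features.index:
        lab = ds.label_minute(ts, result.catalog, paradigm, tail_policy)
        if lab is not None:
            labels[ts] = lab
    relabeled = pd.Series(labels).sort_index()
    train_idx = relabeled.index[relabeled.index < result.split.boundary]
    test_idx = relabeled.index[relabeled.index >= result.split.boundary]
    if not len(train_idx) or not len(test_idx):
        raise ValueError(f"paradigm {new_paradigm} leaves an empty split range")
    for lab in range(paradigm.n_labels):
        if not (relabeled.loc[train_idx] == lab).any():
            raise ValueError(f"label {lab} absent from retarget training range")

    clf = tf.retarget_classifier(
        result.features.loc[train_idx].to_numpy(),
        relabeled.loc[train_idx].to_numpy(),
        cfg,
        balance_seed=result.config.seed + 103,
    )
    report: dict = {
        "paradigm": new_paradigm,
        "n_labels": paradigm.n_labels,
        "lstm_checksum_unchanged": result.lstm_model.checksum() == checksum_before,
        "n_train_minutes": int(len(train_idx)),
        "n_test_minutes": int(len(test_idx)),
    }
    y_test = relabeled.loc[test_idx].to_numpy()
    scores_mat = clf.predict(result.features.loc[test_idx].to_numpy())
    if paradigm.n_labels == 2:
        pos = (y_test == 0).astype(int)
        if pos.sum() and (1 - pos).sum():
            scores = ev.combine_scores(scores_mat)
            roc = ev.roc_auc(scores, pos)
            ci = ev.hanley_mcneil_ci(roc.auc, roc.n_pos, roc.n_neg)
            report["auc"] = ci.auc
            report["ci_half_width"] = ci.half_width
            report["ci_lower"] = ci.lower
            report["significant_vs_random"] = bool(ev.vs_random(ci))
            report["n_pos"] = roc.n_pos
            report["n_neg"] = roc.n_neg
    else:
        preds = np.argmax(scores_mat, axis=1)
        cm = ev.confusion_and_baseline(y_test, preds, paradigm.n_labels)
        report["total_accuracy"] = cm.total_accuracy
        report["confusion_counts"] = cm.counts.tolist()
    return report
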