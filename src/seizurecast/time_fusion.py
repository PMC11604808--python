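"""Seizure-cycle time features and the dense fusion classifier.

Seizures cluster on circadian, weekly and multidien cycles, so the final
prediction combines the five per-minute LSTM output vectors with nine
time-information values:

* two values per cycle for hour-of-day (24 h), day-of-month (fixed 31 d),
  month-of-year (12 mo) and day-of-week (7 d): the calendar value and the
  time elapsed since the cycle start, both scaled to [0, 5] at 1-min
  resolution;
* the natural log of (1 + minutes since the last seizure of any kind),
  capped so the feature stays bounded when no prior seizure exists — a
  handle for cycles that fit none of the four calendar periods.

The fusion classifier is two dense sigmoid layers separated by dropout
(0.25); the hidden layer has 10x the label count, the loss is MSE on
one-hot targets and the optimizer is Adam.  Retargeting trains a fresh
classifier on cached LSTM outputs under new labels while the LSTM weights
stay frozen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import dataset as _dataset
from .lstm_core import StackedLstmClassifier, one_hot
from .preprocess import extract_segments, five_segment_starts
from .record_store import MinuteRecord, SeizureCatalog

__all__ = [
    "N_TIME_FEATURES",
    "LOG_MINUTES_CAP",
    "ClassifierConfig",
    "encode_time_features",
    "DenseFusionClassifier",
    "build_classifier",
    "cache_minute_features",
    "predict_minute",
    "retarget_classifier",
]

N_TIME_FEATURES = 9
# cap at 60 days expressed in minutes: ln(1 + 60 * 24 * 60)
LOG_MINUTES_CAP = float(np.log(1.0 + 60 * 24 * 60))
_SCALE = 5.0


def encode_time_features(
    minute_start: pd.Timestamp,
    catalog: SeizureCatalog | None,
    log_cap: float = LOG_MINUTES_CAP,
) -> np.ndarray:
    """Nine time-information values for one minute.

    Cyclic pairs are (calendar value, minutes since cycle start), each
    scaled to [0, 5].  The ninth value is ln(1 + minutes since the last
    seizure of any kind), capped; the cap is also the fallback when no
    seizure precedes the minute.
    """
    ts = pd.Timestamp(minute_start)
    minute_of_day = ts.hour * 60 + ts.minute
    frac_day = minute_of_day / 1440.0

    hour_v1 = (ts.hour + ts.minute / 60.0) / 24.0 * _SCALE
    hour_v2 = minute_of_day / 1440.0 * _SCALE

    dom = ts.day - 1 + frac_day
    dom_v1 = dom / 31.0 * _SCALE
    dom_v2 = dom * 1440.0 / (31.0 * 1440.0) * _SCALE

    month_start = ts.normalize().replace(day=1)
    frac_month = dom / ts.days_in_month
    moy_v1 = (ts.month - 1 + frac_month) / 12.0 * _SCALE
    year_start = ts.normalize().replace(month=1, day=1)
    year_minutes = (366.0 if ts.is_leap_year else 365.0) * 1440.0
    moy_v2 = ((ts - year_start) / pd.Timedelta(minutes=1)) / year_minutes * _SCALE

    dow = ts.weekday() + frac_day
    dow_v1 = dow / 7.0 * _SCALE
    dow_v2 = dow * 1440.0 / (7.0 * 1440.0) * _SCALE

    log_term = log_cap
    if catalog is not None and len(catalog) > 0:
        pos = catalog.onsets.searchsorted(ts, side="left")
        if pos > 0:
            minutes_since = (ts - catalog.onsets[pos - 1]) / pd.Timedelta(minutes=1)
            log_term = min(float(np.log1p(minutes_since)), log_cap)
    _ = month_start  # calendar anchor retained for clarity
    return np.array(
        [hour_v1, hour_v2, dom_v1, dom_v2, moy_v1, moy_v2, dow_v1, dow_v2, log_term]
    )


@dataclass
class ClassifierConfig:
    """Fusion-classifier hyperparameters; hidden width is 10x the label count."""

    n_labels: int = 2
    dropout: float = 0.25
    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 32
    validation_fraction: float = 0.15
    patience: int = 10
    seed: int = 0

    @property
    def hidden_units(self) -> int:
        return 10 * self.n_labels


class DenseFusionClassifier:
    """dense(10 * n_labels, sigmoid) -> dropout(0.25) -> dense(n_labels, sigmoid)."""

    def __init__(self, config: ClassifierConfig, input_width: int):
        self.config = config
        self.input_width = input_width
        rng = np.random.default_rng(config.seed)
        h = config.hidden_units
        lim1 = np.sqrt(6.0 / (input_width + h))
        lim2 = np.sqrt(6.0 / (h + config.n_labels))
        self.W1 = rng.uniform(-lim1, lim1, (input_width, h))
        self.b1 = np.zeros(h)
        self.W2 = rng.uniform(-lim2, lim2, (h, config.n_labels))
        self.b2 = np.zeros(config.n_labels)
        self._train_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
        self.history: dict[str, list[float]] = {"loss": [], "val_loss": []}

    def _params(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def _forward(self, X, training=False):
        h = expit(X @ self.W1 + self.b1)
        mask = None
        p = self.config.dropout
        if training and p > 0:
            mask = (self._train_rng.random(h.shape) >= p) / (1.0 - p)
            h_used = h * mask
        else:
            h_used = h
        y = expit(h_used @ self.W2 + self.b2)
        return y, h, h_used, mask

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Per-label scores in [0, 1]; deterministic (dropout disabled)."""
        return self._forward(np.atleast_2d(X))[0]

    def fit(self, X: np.ndarray, labels: np.ndarray) -> dict:
        cfg = self.config
        if len(X) == 0:
            raise ValueError("empty classifier training set")
        if X.shape[1] != self.input_width:
            raise ValueError(
                f"input width {X.shape[1]} != expected {self.input_width}"
            )
        T = one_hot(labels, cfg.n_labels)
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 17]))
        from .lstm_core import _Adam  # shared optimizer

        order = rng.permutation(len(X))
        X, T = X[order], T[order]
        n_val = min(max(int(round(cfg.validation_fraction * len(X))), 0), len(X) - 1)
        X_val, T_val = X[len(X) - n_val :], T[len(X) - n_val :]
        X_tr, T_tr = X[: len(X) - n_val], T[: len(X) - n_val]
        opt = _Adam(self._params(), cfg.learning_rate)
        best = np.inf
        best_state = [p.copy() for p in self._params()]
        stall = 0
        for _epoch in range(cfg.epochs):
            perm = rng.permutation(len(X_tr))
            losses = []
            for i in range(0, len(X_tr), cfg.batch_size):
                idx = perm[i : i + cfg.batch_size]
                xb, tb = X_tr[idx], T_tr[idx]
                y, h, h_used, mask = self._forward(xb, training=True)
                B, L = y.shape
                loss = float(np.mean((y - tb) ** 2))
                losses.append(loss)
                dy = 2.0 * (y - tb) / (B * L)
                dz2 = dy * y * (1.0 - y)
                gW2 = h_used.T @ dz2
                gb2 = dz2.sum(axis=0)
                dh = dz2 @ self.W2.T
                if mask is not None:
                    dh = dh * mask
                dz1 = dh * h * (1.0 - h)
                gW1 = xb.T @ dz1
                gb1 = dz1.sum(axis=0)
                opt.step(self._params(), [gW1, gb1, gW2, gb2])
            train_loss = float(np.mean(losses))
            if n_val:
                val_loss = float(np.mean((self.predict(X_val) - T_val) ** 2))
            else:
                val_loss = train_loss
            self.history["loss"].append(train_loss)
            self.history["val_loss"].append(val_loss)
            if val_loss < best - 1e-7:
                best, stall = val_loss, 0
                best_state = [p.copy() for p in self._params()]
            else:
                stall += 1
                if stall > cfg.patience:
                    break
        for p, b in zip(self._params(), best_state):
            p[...] = b
        return self.history

    def structure_report(self) -> dict:
        return {
            "layers": [
                {"kind": "dense", "units": self.config.hidden_units,
                 "activation": "sigmoid"},
                {"kind": "dropout", "rate": self.config.dropout},
                {"kind": "dense", "units": self.config.n_labels,
                 "activation": "sigmoid"},
            ],
            "n_dense_layers": 2,
            "n_dropout_layers": 1,
        }


def build_classifier(
    config: ClassifierConfig, n_lstm_outputs: int
) -> DenseFusionClassifier:
    """Fusion classifier over 5 LSTM output vectors plus the 9 time values."""
    width = 5 * n_lstm_outputs + N_TIME_FEATURES
    return DenseFusionClassifier(config, width)


def minute_feature_vector(
    lstm_model: StackedLstmClassifier,
    record: MinuteRecord,
    catalog: SeizureCatalog | None,
    duration: float = 10.0,
) -> np.ndarray:
    """Concatenated [5 x LSTM outputs, 9 time values] for one minute."""
    segs = extract_segments(record, five_segment_starts(), duration)
    X = np.stack([s.data.T for s in segs])
    outputs = lstm_model.predict(X).ravel()
    return np.concatenate([outputs, encode_time_features(record.start_time, catalog)])


def cache_minute_features(
    lstm_model: StackedLstmClassifier,
    minutes: Sequence[pd.Timestamp],
    load_minute: Callable[[pd.Timestamp], MinuteRecord],
    catalog: SeizureCatalog | None,
    duration: float = 10.0,
    batch_minutes: int = 128,
) -> pd.DataFrame:
    """Frozen-LSTM feature table keyed by minute (columns lstm*, time*).

    Caching makes classifier (re)training cheap: the expensive recurrent
    forward pass runs once per minute, after which any relabeling only
    touches the small dense classifier.
    """
    minutes = list(minutes)
    n_out = lstm_model.config.n_labels
    lstm_cols = [f"lstm{s}_{j}" for s in range(5) for j in range(n_out)]
    time_cols = [f"time{j}" for j in range(N_TIME_FEATURES)]
    rows = np.empty((len(minutes), 5 * n_out + N_TIME_FEATURES))
    for i0 in range(0, len(minutes), batch_minutes):
        chunk = minutes[i0 : i0 + batch_minutes]
        seg_data = []
        for ts in chunk:
            rec = load_minute(ts)
            segs = extract_segments(rec, five_segment_starts(), duration)
            seg_data.extend(s.data.T for s in segs)
        outputs = lstm_model.predict(np.stack(seg_data))
        outputs = outputs.reshape(len(chunk), 5 * n_out)
        for k, ts in enumerate(chunk):
            rows[i0 + k, : 5 * n_out] = outputs[k]
            rows[i0 + k, 5 * n_out :] = encode_time_features(ts, catalog)
    return pd.DataFrame(rows, index=pd.DatetimeIndex(minutes), columns=lstm_cols + time_cols)


def predict_minute(
    lstm_model: StackedLstmClassifier,
    classifier: DenseFusionClassifier,
    record: MinuteRecord,
    catalog: SeizureCatalog | None,
    duration: float = 10.0,
) -> tuple[np.ndarray, int]:
    """Per-label scores and the argmax label (lowest index wins ties)."""
    x = minute_feature_vector(lstm_model, record, catalog, duration)
    scores = classifier.predict(x)[0]
    return scores, int(np.argmax(scores))


def retarget_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    config: ClassifierConfig,
    balance_seed: int = 0,
) -> DenseFusionClassifier:
    """Train a fresh fusion classifier on cached LSTM features + new labels.

    The LSTM is not touched (its outputs are already frozen in ``features``);
    the training set is balanced by +/-5% multiplicative-noise up-sampling.
    """
    X, y = _dataset.build_classifier_train_set(features, labels, seed=balance_seed)
    clf = DenseFusionClassifier(config, input_width=features.shape[1])
    clf.fit(X, y)
    return clf
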