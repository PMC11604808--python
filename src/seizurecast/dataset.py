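"""Labeled train/test dataset construction.

Implements the bookkeeping that turns a continuous recording plus a seizure
catalog into balanced training sets and unbalanced test sets:

* lead-seizure identification (no seizure in the 4 h prior);
* exclusions: a configurable initial settling period, 4 h after every
  seizure (post-ictal), and the onset minute itself;
* chronological 80:20 split on lead seizures, with the boundary at the
  midpoint between the last training and first test lead seizure;
* paradigm labeling by time-before-next-lead-seizure with half-open
  [lower, upper) bins in minutes;
* tiered up-sampling of minority labels (even starts, half-offset,
  quarter-offset, then random starts on a 2.5 ms grid) to balance the
  segment-level training set, and multiplicative +/-5% noise up-sampling
  for the minute-level classifier training set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .preprocess import (
    Segment,
    extract_segments,
    five_segment_starts,
    train_tier_starts,
)
from .record_store import MinuteRecord, SeizureCatalog

__all__ = [
    "ParadigmSpec",
    "PARADIGMS",
    "LabeledSegment",
    "SplitSpec",
    "find_lead_seizures",
    "apply_exclusions",
    "label_minute",
    "split_by_seizures",
    "build_lstm_train_set",
    "build_test_set",
    "build_classifier_train_set",
]

RANDOM_START_GRID_S = 0.0025  # random-tier start resolution


@dataclass(frozen=True)
class ParadigmSpec:
    """Label bins measured as minutes before the next lead seizure.

    ``bins`` is an ordered list of (lower, upper, label) with half-open
    [lower, upper) intervals; label 0 is the bin closest to seizure
    (pre-ictal).  Minutes whose delta falls in no bin are excluded
    (e.g. the re-targeted 40-80 min paradigm excludes deltas below 40).
    """

    name: str
    bins: tuple = ()

    @property
    def n_labels(self) -> int:
        return len({b[2] for b in self.bins})

    def label_for_delta(self, delta_minutes: float) -> int | None:
        if not np.isfinite(delta_minutes):
            return None
        for lo, hi, label in self.bins:
            if lo <= delta_minutes < hi:
                return label
        return None


_INF = float("inf")

PARADIGMS: dict[str, ParadigmSpec] = {
    # pre-ictal 1-16 min vs inter-ictal >16 min
    "paradigm1": ParadigmSpec("paradigm1", ((1, 16, 0), (16, _INF, 1))),
    # pre-ictal 1-4 min vs inter-ictal >4 min
    "paradigm2": ParadigmSpec("paradigm2", ((1, 4, 0), (4, _INF, 1))),
    # four bins: 1-15 min, 15-75 min, 75 min-24 h, >24 h
    "paradigm3": ParadigmSpec(
        "paradigm3", ((1, 15, 0), (15, 75, 1), (75, 1440, 2), (1440, _INF, 3))
    ),
    # five bins: 1-5 min, 5-65 min, 65 min-8 h, 8-24 h, >24 h
    "paradigm4": ParadigmSpec(
        "paradigm4",
        ((1, 5, 0), (5, 65, 1), (65, 480, 2), (480, 1440, 3), (1440, _INF, 4)),
    ),
    # classifier re-targeting: pre-ictal 40-80 min, inter-ictal >80 min,
    # deltas below 40 min excluded
    "dlstm_40_80": ParadigmSpec("dlstm_40_80", ((40, 80, 0), (80, _INF, 1))),
}


@dataclass
class LabeledSegment:
    segment: Segment
    label: int
    paradigm: str
    tier: int  # 0 = canonical first window / test window


@dataclass
class SplitSpec:
    """Half-open train/test ranges meeting at the boundary minute."""

    boundary: pd.Timestamp
    train_start: pd.Timestamp
    test_end: pd.Timestamp

    def in_train(self, ts) -> bool:
        return self.train_start <= pd.Timestamp(ts) < self.boundary

    def in_test(self, ts) -> bool:
        return self.boundary <= pd.Timestamp(ts) < self.test_end


def find_lead_seizures(
    catalog: SeizureCatalog, gap: pd.Timedelta = pd.Timedelta(hours=4)
) -> SeizureCatalog:
    """Flag onsets with no seizure in the open interval (t - gap, t).

    An onset exactly ``gap`` before another still makes the later one a
    lead (open-interval convention).  The first seizure is always a lead.
    """
    onsets = catalog.onsets
    flags = np.ones(len(onsets), dtype=bool)
    for i in range(1, len(onsets)):
        flags[i] = onsets[i] - onsets[i - 1] >= gap
    return SeizureCatalog(onsets, flags)


def apply_exclusions(
    minutes: pd.DatetimeIndex,
    catalog: SeizureCatalog,
    recording_start: pd.Timestamp,
    exclusion_days: int = 100,
    post_ictal: pd.Timedelta = pd.Timedelta(hours=4),
) -> pd.DatetimeIndex:
    """Eligible minute starts after the standard exclusions.

    Removes: the first ``exclusion_days`` of the recording (settling
    period), minutes within ``post_ictal`` after ANY seizure onset
    (inclusive of the onset minute), and minutes starting less than 1 min
    before the next lead seizure (the implicit prediction horizon; the
    minute starting exactly 1 min before the onset is kept and labeled).
    Screening failures are expected to be filtered before this call.
    """
    minutes = pd.DatetimeIndex(minutes)
    keep = np.ones(len(minutes), dtype=bool)
    cutoff = pd.Timestamp(recording_start) + pd.Timedelta(days=exclusion_days)
    keep &= minutes >= cutoff
    for onset in catalog.onsets:
        keep &= ~((minutes >= onset) & (minutes < onset + post_ictal))
    lead = catalog.lead_onsets
    for onset in lead:
        keep &= ~((minutes > onset - pd.Timedelta(minutes=1)) & (minutes < onset))
    return minutes[keep]


def delta_to_next_lead(ts: pd.Timestamp, catalog: SeizureCatalog) -> float:
    """Minutes from ``ts`` to the next lead-seizure onset (inf if none)."""
    lead = catalog.lead_onsets
    pos = lead.searchsorted(pd.Timestamp(ts), side="left")
    if pos >= len(lead):
        return _INF
    return (lead[pos] - pd.Timestamp(ts)) / pd.Timedelta(minutes=1)


def label_minute(
    minute_start: pd.Timestamp,
    catalog: SeizureCatalog,
    paradigm: ParadigmSpec,
    tail_policy: str = "exclude",
) -> int | None:
    """Paradigm label for one eligible minute, or None if excluded.

    Delta is measured from the minute start to the next lead onset; minutes
    after the final catalog seizure have an unknowable delta and are
    excluded unless ``tail_policy='label'`` assigns them the open-ended bin.
    """
    delta = delta_to_next_lead(minute_start, catalog)
    if delta < 1.0:
        return None  # inside the 1-min prediction horizon
    if not np.isfinite(delta):
        if tail_policy == "label":
            lo, hi, label = paradigm.bins[-1]
            return label if not np.isfinite(hi) else None
        return None
    return paradigm.label_for_delta(delta)


def split_by_seizures(
    catalog: SeizureCatalog,
    recording_start: pd.Timestamp,
    recording_end: pd.Timestamp,
    train_fraction: float = 0.8,
) -> SplitSpec:
    """Chronological split allocating the first 80% of lead seizures to train.

    The boundary is the midpoint (rounded to the minute) between the last
    training lead onset and the first test lead onset, so no time-correlated
    minute can appear on both sides.
    """
    lead = catalog.lead_onsets
    n = len(lead)
    if n < 2:
        raise ValueError(f"need >= 2 lead seizures to split, have {n}")
    k = int(np.floor(train_fraction * n))
    k = min(max(k, 1), n - 1)
    boundary = (lead[k - 1] + (lead[k] - lead[k - 1]) / 2).floor("min")
    return SplitSpec(
        boundary=boundary,
        train_start=pd.Timestamp(recording_start),
        test_end=pd.Timestamp(recording_end),
    )


def _group_minutes_by_label(
    minutes: Sequence[pd.Timestamp],
    catalog: SeizureCatalog,
    paradigm: ParadigmSpec,
    tail_policy: str = "exclude",
) -> dict[int, list[pd.Timestamp]]:
    by_label: dict[int, list[pd.Timestamp]] = {}
    for ts in minutes:
        label = label_minute(ts, catalog, paradigm, tail_policy)
        if label is not None:
            by_label.setdefault(label, []).append(ts)
    return by_label


def build_lstm_train_set(
    minutes: Sequence[pd.Timestamp],
    catalog: SeizureCatalog,
    paradigm: ParadigmSpec,
    load_minute: Callable[[pd.Timestamp], MinuteRecord],
    duration: float = 10.0,
    target_per_label: int | None = None,
    seed: int = 0,
    tail_policy: str = "exclude",
) -> list[LabeledSegment]:
    """Balanced segment-level training set via tiered up-sampling.

    The majority label contributes the first ``duration`` seconds of each
    of its minutes.  Minority labels are up-sampled per minute through the
    tiers -- even starts, half-offset, quarter-offset, then random starts
    on a 2.5 ms grid -- drawing round-robin across that label's minutes so
    no single minute dominates, until every label matches the target count
    (default: the majority label's minute count).
    """
    rng = np.random.default_rng(seed)
    by_label = _group_minutes_by_label(minutes, catalog, paradigm, tail_policy)
    for label in range(paradigm.n_labels):
        if label not in by_label or not by_label[label]:
            raise ValueError(f"label {label} has zero eligible minutes")
    majority = max(by_label.values(), key=len)
    target = target_per_label if target_per_label is not None else len(majority)

    out: list[LabeledSegment] = []
    for label, ts_list in sorted(by_label.items()):
        ts_list = list(ts_list)
        if len(ts_list) > target:
            idx = rng.choice(len(ts_list), size=target, replace=False)
            ts_list = [ts_list[i] for i in sorted(idx)]
        records = {ts: load_minute(ts) for ts in ts_list}
        produced = 0
        # deterministic tiers, round-robin: slot index varies slowest
        for tier in (1, 2, 3):
            starts = train_tier_starts(tier, duration)
            for slot in range(len(starts)):
                for ts in ts_list:
                    if produced >= target:
                        break
                    seg = extract_segments(records[ts], [starts[slot]], duration)[0]
                    out.append(LabeledSegment(seg, label, paradigm.name, tier))
                    produced += 1
                if produced >= target:
                    break
            if produced >= target:
                break
        # random top-up on the 2.5 ms grid
        max_start = 60.0 - duration
        n_grid = int(round(max_start / RANDOM_START_GRID_S)) + 1
        while produced < target:
            for ts in ts_list:
                if produced >= target:
                    break
                start = float(rng.integers(0, n_grid)) * RANDOM_START_GRID_S
                seg = extract_segments(records[ts], [start], duration)[0]
                out.append(LabeledSegment(seg, label, paradigm.name, 4))
                produced += 1
    return out


def build_test_set(
    minutes: Sequence[pd.Timestamp],
    catalog: SeizureCatalog,
    paradigm: ParadigmSpec,
    load_minute: Callable[[pd.Timestamp], MinuteRecord],
    duration: float = 10.0,
    tail_policy: str = "exclude",
) -> list[LabeledSegment]:
    """Unbalanced test set: the five non-overlapping windows per minute."""
    out: list[LabeledSegment] = []
    for ts in minutes:
        label = label_minute(ts, catalog, paradigm, tail_policy)
        if label is None:
            continue
        record = load_minute(ts)
        for seg in extract_segments(record, five_segment_starts(), duration):
            out.append(LabeledSegment(seg, label, paradigm.name, 0))
    return out


def build_classifier_train_set(
    features: np.ndarray,
    labels: np.ndarray,
    target_per_label: int | None = None,
    noise: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Balance minute-level classifier inputs by +/-5% multiplicative noise.

    Minority-label rows are duplicated with every value multiplied by an
    independent uniform factor in [1 - noise, 1 + noise] until each label
    reaches the target count (default: the majority count).
    """
    rng = np.random.default_rng(seed)
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    counts = pd.Series(labels).value_counts()
    target = int(target_per_label if target_per_label is not None else counts.max())
    out_x = [features]
    out_y = [labels]
    for label, count in counts.items():
        short = target - int(count)
        if short <= 0:
            continue
        pool = features[labels == label]
        idx = rng.integers(0, len(pool), size=short)
        factors = rng.uniform(1.0 - noise, 1.0 + noise, size=(short, features.shape[1]))
        out_x.append(pool[idx] * factors)
        out_y.append(np.full(short, label, dtype=labels.dtype))
    x = np.concatenate(out_x)
    y = np.concatenate(out_y)
    order = rng.permutation(len(y))
    return x[order], y[order]
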