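"""Amplitude normalization, missing-data policy, and segmentation.

The only preprocessing applied to the raw EEG, mirroring a chronic-recording
pipeline: per electrode, each 1-min recording is centred on its own mean and
divided by the average of the daily signal standard deviations over the
previous 30 days (updated once per day).  Missing samples are replaced by
the per-electrode minute mean (so they become exactly 0 after centring), and
a minute is dropped when any electrode is missing more than one second of
data.  No filtering, artifact rejection or resampling of any kind.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .record_store import MinuteRecord, RecordStore, RecordingManifest

__all__ = [
    "NormalizationState",
    "Segment",
    "update_normalization",
    "normalize_minute",
    "normalize_with_divisor",
    "screen_minute",
    "extract_segments",
    "five_segment_starts",
    "train_tier_starts",
    "PreprocessIndex",
    "preprocess_scan",
]

WINDOW_DAYS = 30
_EPS = 1e-12


@dataclass
class NormalizationState:
    """Trailing per-electrode store of daily signal SDs (<= 30 entries)."""

    n_channels: int
    window_days: int = WINDOW_DAYS
    days: list = field(default_factory=list)        # day labels (dates)
    daily_sds: list = field(default_factory=list)   # per-day (n_channels,) arrays

    def append_day(self, day, sds: np.ndarray) -> None:
        self.days.append(day)
        self.daily_sds.append(np.asarray(sds, dtype=float))
        while len(self.days) > self.window_days:
            self.days.pop(0)
            self.daily_sds.pop(0)

    @property
    def n_days(self) -> int:
        return len(self.days)

    def divisor(self) -> np.ndarray | None:
        """Mean of the stored daily SDs per electrode; None with no history."""
        if not self.daily_sds:
            return None
        return np.mean(self.daily_sds, axis=0)

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for day, sds in zip(self.days, self.daily_sds):
            rows.append({"day": day, **{f"ch{i}": s for i, s in enumerate(sds)}})
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, window_days: int = WINDOW_DAYS):
        df = pd.read_csv(path)
        ch_cols = [c for c in df.columns if c.startswith("ch")]
        state = cls(n_channels=len(ch_cols), window_days=window_days)
        for _, row in df.iterrows():
            state.append_day(row["day"], row[ch_cols].to_numpy(dtype=float))
        return state


def update_normalization(
    state: NormalizationState, day_of_records: list[MinuteRecord]
) -> NormalizationState:
    """Append one day's per-electrode SD and evict entries older than 30 days.

    The daily SD is computed over the concatenated non-missing samples of
    the whole day per electrode.  A day with zero usable samples on every
    electrode appends nothing (with a warning).
    """
    if not day_of_records:
        warnings.warn("empty day: no normalization entry appended", stacklevel=2)
        return state
    days = {r.start_time.normalize() for r in day_of_records}
    if len(days) != 1:
        raise ValueError("update_normalization expects records from one day")
    n_ch = day_of_records[0].n_channels
    s = np.zeros(n_ch)
    ss = np.zeros(n_ch)
    n = np.zeros(n_ch)
    for rec in day_of_records:
        valid = ~rec.missing_mask
        d = np.where(valid, rec.data, 0.0)
        s += d.sum(axis=1)
        ss += (d * d).sum(axis=1)
        n += valid.sum(axis=1)
    if (n == 0).all():
        warnings.warn(
            f"day {days.pop().date()} has no usable samples; skipped", stacklevel=2
        )
        return state
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s / n
        var = ss / n - mean**2
    sds = np.sqrt(np.clip(var, 0.0, None))
    sds[n == 0] = 0.0
    state.append_day(day_of_records[0].start_time.normalize().date(), sds)
    return state


def normalize_with_divisor(record: MinuteRecord, divisor: np.ndarray) -> MinuteRecord:
    """Centre each electrode on its minute mean and divide by ``divisor``.

    Missing samples are first replaced by the per-electrode mean of the
    non-missing samples, so they are exactly zero afterwards.  The mask is
    preserved.  Raises on a degenerate (zero) divisor: the minute is unusable.
    """
    if record.normalized:
        raise ValueError(f"minute {record.start_time} already normalized")
    divisor = np.asarray(divisor, dtype=float)
    if (divisor <= _EPS).any():
        bad = np.flatnonzero(divisor <= _EPS).tolist()
        raise ValueError(
            f"degenerate normalization divisor on electrode(s) {bad}; "
            f"minute {record.start_time} unusable"
        )
    valid = ~record.missing_mask
    counts = valid.sum(axis=1)
    sums = np.where(valid, record.data, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    filled = np.where(valid, record.data, means[:, None])
    out_data = (filled - means[:, None]) / divisor[:, None]
    out = record.copy()
    out.data = out_data
    out.normalized = True
    return out


def normalize_minute(record: MinuteRecord, state: NormalizationState) -> MinuteRecord:
    """Normalize one minute with the state's 30-day average SD.

    Cold start: with no daily history yet, the minute's own per-electrode SD
    is used (the long-recording regime this emulates discards its early data,
    a desk-scale run cannot).
    """
    divisor = state.divisor()
    if divisor is None:
        valid = ~record.missing_mask
        d = np.where(valid, record.data, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            divisor = np.nanstd(d, axis=1)
        divisor = np.nan_to_num(divisor, nan=0.0)
    return normalize_with_divisor(record, divisor)


def screen_minute(record: MinuteRecord, sample_rate: float | None = None):
    """Keep/drop decision from the missing mask alone.

    Drop iff any electrode is missing strictly more than 1 s of samples
    (more than 400 at 400 Hz).  Returns (keep, reason).
    """
    rate = sample_rate if sample_rate is not None else record.sample_rate
    threshold = round(rate)  # samples in 1 s
    worst = int(record.missing_mask.sum(axis=1).max()) if record.n_channels else 0
    if worst > threshold:
        return False, f"{worst} missing samples on an electrode (> {threshold})"
    return True, None


@dataclass
class Segment:
    """A fixed-duration window of normalized EEG within one minute."""

    minute_start: pd.Timestamp
    start_offset: float          # seconds within the minute
    duration: float              # seconds
    data: np.ndarray             # (channels, duration * sample_rate)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def five_segment_starts() -> tuple[float, ...]:
    """The non-overlapping test-set convention: five windows per minute.

    (A sixth window would need overlap because the emulated device rate is
    marginally below nominal; the five-window convention is kept by fiat.)
    """
    return (0.0, 10.0, 20.0, 30.0, 40.0)


def train_tier_starts(tier: int, duration: float = 10.0) -> np.ndarray:
    """Up-sampling start offsets for tiers 1-3 (tier 4 is random-start).

    Tier 1: even spacing (0, d, 2d, ...); tier 2: offset by d/2;
    tier 3: offset by d/4.  Only starts with start + duration <= 60 s.
    """
    if tier == 1:
        offset = 0.0
    elif tier == 2:
        offset = duration / 2.0
    elif tier == 3:
        offset = duration / 4.0
    else:
        raise ValueError("deterministic tiers are 1, 2, 3")
    starts = offset + duration * np.arange(int(np.ceil(60.0 / duration)))
    return starts[starts + duration <= 60.0 + 1e-9]


def extract_segments(
    record: MinuteRecord, starts, duration: float = 10.0
) -> list[Segment]:
    """Cut windows out of a normalized minute; sample values are untouched."""
    rate = record.sample_rate
    n = round(duration * rate)
    out = []
    for start in starts:
        if start + duration > 60.0 + 1e-9:
            raise ValueError(f"segment [{start}, {start + duration}) exceeds the minute")
        i0 = round(start * rate)
        out.append(
            Segment(
                minute_start=record.start_time,
                start_offset=float(start),
                duration=float(duration),
                data=record.data[:, i0 : i0 + n],
            )
        )
    return out


# -- single-pass preprocessing index -------------------------------------


@dataclass
class PreprocessIndex:
    """Per-day divisors and the screened minute set for a whole store.

    ``divisors[date]`` is the average-SD divisor in force on that date
    (built from the trailing window of *previous* days; first day falls
    back to per-minute SDs, signalled by None).
    """

    divisors: dict
    kept_minutes: pd.DatetimeIndex
    dropped: dict

    def divisor_for(self, ts: pd.Timestamp) -> np.ndarray | None:
        return self.divisors[pd.Timestamp(ts).normalize().date()]


def preprocess_scan(
    store: RecordStore,
    manifest: RecordingManifest,
    window_days: int = WINDOW_DAYS,
) -> PreprocessIndex:
    """One chronological pass: daily-SD updates plus minute screening.

    The divisor recorded for day D is the trailing average over days < D
    (expanding window before 30 days of history exist), so normalization of
    any minute never uses same-day or future data.
    """
    state = NormalizationState(n_channels=manifest.channels, window_days=window_days)
    divisors: dict = {}
    kept: list[pd.Timestamp] = []
    dropped: dict = {}
    frame = pd.DataFrame({"ts": manifest.start_times})
    frame["day"] = frame["ts"].dt.normalize()
    for day, group in frame.groupby("day", sort=True):
        divisors[day.date()] = state.divisor()
        day_records = []
        for ts in group["ts"]:
            rec = store.read_minute(ts)
            day_records.append(rec)
            keep, reason = screen_minute(rec)
            if keep:
                kept.append(ts)
            else:
                dropped[ts] = reason
        update_normalization(state, day_records)
    return PreprocessIndex(
        divisors=divisors, kept_minutes=pd.DatetimeIndex(kept), dropped=dropped
    )


def load_normalized(
    store: RecordStore, ts: pd.Timestamp, index: PreprocessIndex
) -> MinuteRecord:
    """Read one minute and normalize it with its day's frozen divisor."""
    rec = store.read_minute(ts)
    divisor = index.divisor_for(ts)
    if divisor is None:
        state = NormalizationState(n_channels=rec.n_channels)
        return normalize_minute(rec, state)
    return normalize_with_divisor(rec, divisor)
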