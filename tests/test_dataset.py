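"""Lead seizures, exclusions, splits, paradigm labeling and up-sampling."""

import numpy as np
import pandas as pd
import pytest
from conftest import make_minute

from seizurecast.dataset import (
    PARADIGMS,
    RANDOM_START_GRID_S,
    apply_exclusions,
    build_classifier_train_set,
    build_lstm_train_set,
    build_test_set,
    find_lead_seizures,
    label_minute,
    split_by_seizures,
)
from seizurecast.record_store import SeizureCatalog

BASE = pd.Timestamp("2024-01-01")


def _catalog(hours):
    return SeizureCatalog(pd.DatetimeIndex([BASE + pd.Timedelta(hours=h) for h in hours]))


class TestLeadSeizures:
    def test_single_seizure_is_lead(self):
        cat = find_lead_seizures(_catalog([5]))
        assert cat.lead_flags.tolist() == [True]

    def test_definition_on_three_seizures(self):
        # 0 h, 3 h, 10 h: the 3 h seizure has one 3 h earlier -> not lead
        cat = find_lead_seizures(_catalog([0, 3, 10]))
        assert cat.lead_flags.tolist() == [True, False, True]

    def test_exact_four_hour_spacing_all_lead(self):
        """'In the 4 h prior' read as open interval: 4 h gaps still lead."""
        cat = find_lead_seizures(_catalog([0, 4, 8, 12]))
        assert cat.lead_flags.all()


class TestExclusions:
    def test_post_ictal_window(self):
        cat = find_lead_seizures(_catalog([101 * 24]))  # onset day 101 00:00
        minutes = pd.date_range(
            BASE + pd.Timedelta(days=101), periods=300, freq="1min"
        )
        eligible = apply_exclusions(minutes, cat, BASE, exclusion_days=100)
        onset = BASE + pd.Timedelta(days=101)
        assert (eligible >= onset + pd.Timedelta(hours=4)).all()

    def test_no_seizures_everything_eligible_at_desk_scale(self):
        cat = find_lead_seizures(SeizureCatalog(pd.DatetimeIndex([])))
        minutes = pd.date_range(BASE, periods=100, freq="1min")
        eligible = apply_exclusions(minutes, cat, BASE, exclusion_days=0)
        assert len(eligible) == 100

    def test_toy_catalog_matches_brute_force_enumeration(self):
        """10 h recording, seizures at 5 h and 5.5 h (second non-lead)."""
        cat = find_lead_seizures(_catalog([5, 5.5]))
        minutes = pd.date_range(BASE, periods=600, freq="1min")
        eligible = apply_exclusions(minutes, cat, BASE, exclusion_days=0)

        expected = []
        onsets_min = [300, 330]
        leads_min = [300]
        for m in range(600):
            if any(o <= m < o + 240 for o in onsets_min):
                continue  # post-ictal
            if any(o - 1 < m < o for o in leads_min):
                continue  # sub-horizon gap (empty at integer resolution)
            expected.append(m)
        got = [(t - BASE) // pd.Timedelta(minutes=1) for t in eligible]
        assert got == expected


class TestLabeling:
    @pytest.mark.parametrize(
        "paradigm,delta,expect",
        [
            ("paradigm1", 10, 0),     # 1-16 min: pre-ictal
            ("paradigm1", 16, 1),
            ("paradigm2", 3, 0),      # 1-4 min
            ("paradigm3", 30, 1),     # 15-75 min bin
            ("paradigm3", 1, 0),
            ("paradigm4", 25 * 60, 4),  # >24 h bin
            ("dlstm_40_80", 50, 0),
            ("dlstm_40_80", 120, 1),
            ("dlstm_40_80", 20, None),  # below 40 min: excluded
        ],
    )
    def test_bin_assignment(self, paradigm, delta, expect):
        cat = find_lead_seizures(_catalog([48]))
        minute = BASE + pd.Timedelta(hours=48) - pd.Timedelta(minutes=delta)
        assert label_minute(minute, cat, PARADIGMS[paradigm]) == expect

    def test_onset_minute_excluded(self):
        cat = find_lead_seizures(_catalog([48]))
        assert label_minute(BASE + pd.Timedelta(hours=48), cat,
                            PARADIGMS["paradigm1"]) is None

    def test_tail_minutes_after_last_seizure(self):
        cat = find_lead_seizures(_catalog([1]))
        late = BASE + pd.Timedelta(hours=30)
        assert label_minute(late, cat, PARADIGMS["paradigm4"]) is None
        assert label_minute(
            late, cat, PARADIGMS["paradigm4"], tail_policy="label"
        ) == 4

    @pytest.mark.parametrize("name", sorted(PARADIGMS))
    def test_exhaustive_delta_sweep_covers_all_labels_contiguously(self, name):
        """Sweeping delta on a 1-min grid to 48 h hits every label in one run."""
        paradigm = PARADIGMS[name]
        cat = find_lead_seizures(_catalog([72]))
        onset = BASE + pd.Timedelta(hours=72)
        labels = [
            label_minute(onset - pd.Timedelta(minutes=d), cat, paradigm)
            for d in range(1, 48 * 60 + 1)
        ]
        seen = [l for l in labels if l is not None]
        assert set(seen) == set(range(paradigm.n_labels))
        # contiguous runs: the label sequence never revisits a finished bin
        changes = sum(
            1 for a, b in zip(seen, seen[1:]) if a != b
        )
        assert changes == paradigm.n_labels - 1


class TestSplit:
    def test_80_20_allocation(self):
        cat = find_lead_seizures(_catalog(list(range(0, 10 * 12, 12))))
        assert cat.lead_flags.sum() == 10
        split = split_by_seizures(cat, BASE, BASE + pd.Timedelta(days=10))
        # k = 8: boundary halfway between 8th and 9th lead onset
        expect = BASE + pd.Timedelta(hours=(84 + 96) / 2)
        assert split.boundary == expect

    def test_midpoint_between_day_100_and_110(self):
        # 5 leads, k = 4: last train onset day 100, first test onset day 110
        cat = find_lead_seizures(
            _catalog([70 * 24, 80 * 24, 90 * 24, 100 * 24, 110 * 24])
        )
        split = split_by_seizures(cat, BASE, BASE + pd.Timedelta(days=120),
                                  train_fraction=0.8)
        assert split.boundary == BASE + pd.Timedelta(days=105)

    def test_five_leads_floor(self):
        cat = find_lead_seizures(_catalog([0, 12, 24, 36, 48]))
        split = split_by_seizures(cat, BASE, BASE + pd.Timedelta(days=4))
        assert split.boundary == BASE + pd.Timedelta(hours=(36 + 48) / 2)

    def test_fewer_than_two_leads_is_an_error(self):
        cat = find_lead_seizures(_catalog([5]))
        with pytest.raises(ValueError, match="lead"):
            split_by_seizures(cat, BASE, BASE + pd.Timedelta(days=1))


def _minute_loader(rate=50.0, n_channels=2):
    cache = {}

    def load(ts):
        if ts not in cache:
            rec = make_minute(
                start=ts, n_channels=n_channels, sample_rate=rate,
                seed=int(ts.value % 100000),
            )
            rec.normalized = True
            cache[ts] = rec
        return cache[ts]

    return load


class TestLstmTrainSet:
    def _minutes(self, cat, paradigm, pre, inter):
        onset = cat.lead_onsets[0]
        pre_min = [onset - pd.Timedelta(minutes=2 + i) for i in range(pre)]
        inter_min = [onset - pd.Timedelta(minutes=30 + i) for i in range(inter)]
        return pre_min + inter_min

    def test_tier_arithmetic_one_pre_vs_six_inter(self):
        """1 pre-ictal vs 6 inter-ictal minutes: the pre minute yields 6
        even-start segments (tier 1 exhausted exactly)."""
        cat = find_lead_seizures(_catalog([10]))
        minutes = self._minutes(cat, "paradigm1", pre=1, inter=6)
        segs = build_lstm_train_set(
            minutes, cat, PARADIGMS["paradigm1"], _minute_loader(),
            duration=10.0, seed=0,
        )
        pre = [s for s in segs if s.label == 0]
        inter = [s for s in segs if s.label == 1]
        assert len(pre) == len(inter) == 6
        assert sorted(s.segment.start_offset for s in pre) == [0, 10, 20, 30, 40, 50]
        assert all(s.tier == 1 for s in pre)
        assert all(s.segment.start_offset == 0.0 for s in inter)

    def test_balanced_with_no_upsampling_needed(self):
        cat = find_lead_seizures(_catalog([10]))
        minutes = self._minutes(cat, "paradigm1", pre=4, inter=4)
        segs = build_lstm_train_set(
            minutes, cat, PARADIGMS["paradigm1"], _minute_loader(),
            duration=10.0, seed=0,
        )
        assert len(segs) == 8
        assert all(s.segment.start_offset == 0.0 and s.tier == 1 for s in segs)

    def test_random_tier_starts_on_2p5_ms_grid(self):
        cat = find_lead_seizures(_catalog([10]))
        minutes = self._minutes(cat, "paradigm1", pre=1, inter=30)
        segs = build_lstm_train_set(
            minutes, cat, PARADIGMS["paradigm1"], _minute_loader(),
            duration=10.0, seed=3,
        )
        random_tier = [s for s in segs if s.label == 0 and s.tier == 4]
        assert random_tier  # tiers 1-3 supply only 16 of 30 needed
        for s in random_tier:
            steps = s.segment.start_offset / RANDOM_START_GRID_S
            assert abs(steps - round(steps)) < 1e-6

    def test_missing_label_raises_naming_it(self):
        cat = find_lead_seizures(_catalog([10]))
        minutes = self._minutes(cat, "paradigm1", pre=0, inter=5)
        with pytest.raises(ValueError, match="label 0"):
            build_lstm_train_set(
                minutes, cat, PARADIGMS["paradigm1"], _minute_loader(),
                duration=10.0,
            )


class TestTestSet:
    def test_five_segments_per_minute_unbalanced(self):
        cat = find_lead_seizures(_catalog([10]))
        onset = cat.lead_onsets[0]
        minutes = [onset - pd.Timedelta(minutes=k) for k in range(2, 22)]
        segs = build_test_set(
            minutes, cat, PARADIGMS["paradigm1"], _minute_loader(), duration=10.0
        )
        assert len(segs) == 100
        # label proportions equal minute-level proportions (14 pre, 6 inter)
        assert sum(s.label == 0 for s in segs) == 5 * 14
        assert all(
            s.segment.start_offset + s.segment.duration <= 60.0 for s in segs
        )


class TestClassifierTrainSet:
    def test_balancing_and_noise_bounds(self):
        rng = np.random.default_rng(0)
        X = np.abs(rng.normal(size=(30, 4))) + 1.0
        y = np.array([0] * 24 + [1] * 6)
        Xb, yb = build_classifier_train_set(X, y, seed=1)
        assert (np.bincount(yb) == [24, 24]).all()
        # each augmented row is an original row times factors in [0.95, 1.05]
        originals = X[y == 1]
        for row in Xb[yb == 1]:
            ratios = row[None, :] / originals
            ok = np.any(
                np.all((ratios >= 0.95 - 1e-12) & (ratios <= 1.05 + 1e-12), axis=1)
            )
            assert ok

    def test_zero_input_stays_zero(self):
        X = np.zeros((10, 3))
        y = np.array([0] * 8 + [1] * 2)
        Xb, yb = build_classifier_train_set(X, y, seed=0)
        np.testing.assert_array_equal(Xb, 0.0)
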