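# seizurecast

Seizure forecasting from **raw** intracranial EEG — no feature
engineering. One-minute EEG records are cut into five 10-s windows, each
window is classified by a stacked LSTM (four recurrent layers interleaved
with three temporal max-pools), and the five outputs are fused with nine
seizure-cycle time features (hour-of-day, day-of-month, month-of-year,
day-of-week pairs, plus log-minutes-since-last-seizure) by a small dense
classifier that scores each minute per label. Because the expensive LSTM
outputs are cached per minute, the classifier can be *retargeted* to a new
labeling (say, pre-ictal redefined as 40–80 min before onset) in seconds
with the LSTM frozen.

The package is aimed at researchers studying seizure-prediction pipelines
and their evaluation. Clinical long-term recordings are not
redistributable, so the package ships a synthetic long-term iEEG generator
that emulates the chronic-recording regime — per-minute files, seizures on
circadian/weekly/multidien cycles, pre-ictal signatures (a 25 ms marker
pulse, a variance ramp, or critical-slowing autocorrelation), telemetry
dropouts, and slow gain drift — so the whole pipeline runs end to end on
one CPU.

The model per minute-window x_t follows the standard gate recurrence

    i_t = σ(x_t U_i + h_{t−1} W_i)      f_t = σ(x_t U_f + h_{t−1} W_f)
    o_t = σ(x_t U_o + h_{t−1} W_o)      c̃_t = tanh(x_t U_g + h_{t−1} W_g)
    C_t = f_t ∘ C_{t−1} + i_t ∘ c̃_t     h_t = tanh(C_t) ∘ o_t

trained with MSE on one-hot labels, Adam, and recurrent dropout 0.25.
Two-label runs are scored by the ROC of pre − inter with AUC confidence
intervals from the Hanley–McNeil closed form

    SE² = [A(1−A) + (n₊−1)(Q₁−A²) + (n₋−1)(Q₂−A²)] / (n₊ n₋),
    Q₁ = A/(2−A),  Q₂ = 2A²/(1+A)

(significant vs chance when A − 1.96·SE > 0.5). Multi-label runs produce
confusion matrices with a time-matched random baseline. The only
preprocessing is per-electrode normalization by the trailing 30-day
average of daily signal SDs, plus a missing-data policy (mean-fill; drop
a minute when any electrode misses more than 1 s).

## Worked example

A desk-scale end-to-end run — 4 channels at 100 Hz for 6 synthetic days,
~4 seizures/day with a 25 ms marker inserted 0–16 min before each onset,
1–16 min pre-ictal vs >16 min inter-ictal labels:

```bash
seizurecast run-all --paradigm paradigm1 --seed 1 --days 6 --rate 4 --out run1
```

which simulates, stores, normalizes, labels, balances, trains and
evaluates, and prints (abridged):

```json
{
  "paradigm": "paradigm1",
  "n_train_minutes": 2842,
  "n_test_minutes": 1982,
  "n_lead_seizures": 11,
  "classifier_auc": 1.0,
  "classifier_ci_lower": 1.0,
  "significant_vs_random": true,
  "natural_operating_point": {"sensitivity": 1.0, "time_in_high": 0.0227},
  "lstm_segment_auc": 1.0,
  "lstm_segment_ci_lower": 1.0
}
```

Reading this: the first 80% of lead seizures (and everything before the
halfway point to the next one) trained the models; on the untouched test
minutes the fused per-minute classifier separates pre-ictal from
inter-ictal perfectly (AUC 1.0, so the Hanley–McNeil lower bound 1.0 is
above 0.5 — significant by the no-overlap rule), and at the natural
threshold it flags every pre-ictal minute while spending 2.3% of all time
in warning. The segment-level LSTM alone is also perfect, as it should be
when the planted marker is fully detectable — the run validates the
machinery, not clinical difficulty.

Retargeting the classifier on the cached LSTM outputs, without touching
the LSTM:

```bash
seizurecast retarget --run-dir run1 --paradigm paradigm2
```

The library mirrors the CLI (`seizurecast.pipeline.run_pipeline`,
`retarget_run`) and exposes every stage separately: `synthetic_eeg`
(generator), `record_store` (minute records, manifests, EDF export),
`preprocess` (rolling normalization, screening, segmentation), `dataset`
(lead seizures, exclusions, 80:20 split, paradigm labeling, tiered
up-sampling), `lstm_core` (the recurrence, hand-written BPTT, Adam),
`time_fusion` (time features, dense fusion, retargeting) and `evaluate`
(ROC/AUC, Hanley–McNeil, operating points, confusion baselines).

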