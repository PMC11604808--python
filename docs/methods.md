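# Methods

This package implements a feature-engineering-free seizure-forecasting
framework for long-term intracranial EEG, together with the synthetic data
machinery needed to exercise it end to end without clinical recordings.

## The forecasting model

The unit of prediction is one minute of raw multi-channel EEG. Each minute
is cut into five non-overlapping 10-s windows (five, not six, because the
emulated recording device runs marginally below its nominal rate; the
convention is kept at every scale). Each window is classified by a stacked
LSTM; the five output vectors are then fused with nine time features by a
small dense classifier that emits one score per label.

**Stacked LSTM.** Four LSTM layers interleaved with three temporal
max-pooling layers (pool factor 4 by default, so 4,000 input steps shrink
to 62 at the last layer); the first three layers return full sequences,
the fourth only its final state, followed by a dense sigmoid layer with
one output per label. The gate recurrence is

    i_t = σ(x_t U_i + h_{t-1} W_i)        f_t = σ(x_t U_f + h_{t-1} W_f)
    o_t = σ(x_t U_o + h_{t-1} W_o)        c̃_t = act(x_t U_g + h_{t-1} W_g)
    C_t = f_t ∘ C_{t-1} + i_t ∘ c̃_t       h_t = act(C_t) ∘ o_t

with `act = tanh` by default. A sigmoid candidate/cell activation is
available as a config option but is not the default: combined with
bias-free gates its strictly positive candidate cannot train at all (the
loss never leaves the constant-predictor floor), while the tanh recurrence
learns the validation tasks to AUC ≈ 1. Trained models use additive gate
biases with the forget bias initialised to 1, the standard device for
letting a cell retain state from the first epoch; a bias-free cell is
available (`use_bias=False`) and is what the reference single-step
function `lstm_cell_step` implements by default. Targets are one-hot, the
loss is mean squared error, the optimizer is Adam, and recurrent dropout
(0.25) multiplies `h_{t-1}` in the recurrent term with one mask per
sequence. Backpropagation through time is hand-written in numpy and
verified against numerical directional derivatives (relative error below
1e-6) and against the naive per-step reference recurrence (1e-12).

**Plateau restarts.** On the sparse-signature tasks used for validation
the MSE sits exactly at the balanced one-hot floor ((1−1/L)/L for L
labels) for tens of epochs before the gradient finds the discriminative
feature, and whether it ever does within a fixed budget depends on the
initialisation. `train_with_restarts` therefore probes each
initialisation for a fixed number of epochs and restarts from a
deterministically derived seed unless the *validation* loss (an internal
slice of the training set — test data is never consulted) has dropped
below 97% of the floor; a fall in training loss alone can be memorisation
and does not count. The first escaped attempt trains to the full epoch
budget. Desk-scale presets use learning rates of 3e-3 to 2e-2; the
full-scale default stays at 1e-4.

**Time features.** Nine values per minute: for each of four cycles —
hour-of-day (24 h), day-of-month (fixed 31 d), month-of-year (12 mo),
day-of-week (7 d) — the calendar value and the minutes elapsed since the
cycle start, each scaled to [0, 5] at 1-min resolution; plus
ln(1 + minutes since the last seizure of any kind), capped at
ln(1 + 86,400) (60 days), which is also the fallback when no seizure
precedes the minute. The two members of each pair are nearly redundant by
construction; both are provided as specified. The 24 h and 7 d pairs are
exactly periodic; the day-of-month pair normalises the true calendar day
by a fixed 31-day cycle and is therefore only approximately periodic
across months of different lengths, as is month-of-year across leap
years.

**Fusion classifier.** dense(10 × n_labels, sigmoid) → dropout(0.25) →
dense(n_labels, sigmoid), MSE loss, Adam. Its input is the concatenation
of the five LSTM output vectors and the nine time features
(5 × n_labels + 9 wide). Because the LSTM outputs are cached per minute,
retraining the classifier under a new labeling ("retargeting", e.g.
pre-ictal redefined as 40–80 min before onset) takes seconds and provably
never touches the LSTM weights (a checksum is asserted).

## Data handling

**Storage.** EEG lives as one-minute records (channels × samples with a
boolean missing mask) in an HDF5 container plus a CSV manifest; seizure
onsets in a CSV catalog. Timestamps are calendar-aware because the time
features need hour/day/month semantics; intervals are half-open
throughout. A minimal EDF writer (1-s data records, 16-bit, missing
samples zeroed and flagged in an extra `MISSING` channel) provides
interoperability; round-trips are tested against an independent EDF
reader.

**Preprocessing.** The only signal processing is per-electrode
normalization: subtract the minute mean, divide by the average of the
daily signal SDs over the previous 30 days (updated once per day; the
daily SD pools all non-missing samples of the day, and the average is
taken over days). Missing samples are first replaced by the electrode's
minute mean, so they become exactly zero. Cold start — which a long
clinical recording avoids by discarding its first 100 days, but a
desk-scale run cannot — uses an expanding window of available daily SDs,
and the minute's own SD before any full day exists. A minute is dropped
when any single electrode is missing more than one second of samples
(strictly more than 400 at 400 Hz; the threshold is per electrode, reading
the two published clauses as synonyms). No filtering, artifact rejection
or resampling of any kind.

**Labeling and datasets.** A lead seizure has no other seizure in the
open interval 4 h before its onset. Exclusions: a configurable initial
settling period (100 days at full scale, 0 at desk scale), 4 h after
every seizure, and the onset minute itself. Labels are
time-before-next-lead-seizure bins, half-open [lower, upper) in minutes
with Δ = 1 labeled (the printed "1–16 min" convention; an exhaustive
1-min sweep produces every label exactly once). Minutes after the final
catalog seizure are excluded by default (their true Δ is unknowable).
The chronological split allocates the first 80% of lead seizures to
training, with the boundary at the midpoint between the last training and
first test lead onsets. Training sets are balanced: the majority label
contributes the first window of each of its minutes; minority labels are
up-sampled per minute through tiers (even starts, half-offset,
quarter-offset, then random starts on a 2.5 ms grid), drawn round-robin
across minutes so no single minute dominates. Test sets are always the
unbalanced five-windows-per-minute convention. Classifier training sets
are balanced by duplicating minority minutes with ±5% independent
multiplicative noise on every input.

## Evaluation

Two-label runs are scored by the ROC of the score
`pre_score − inter_score` (fixed weights; any monotone linear combination
gives the same ordering). AUC is trapezoidal over the threshold sweep and
equals the Mann–Whitney statistic with tie midpoints (asserted against
brute-force pair counting). Confidence intervals use the Hanley–McNeil
closed form with z = 1.96 at 95%; two AUCs differ significantly when
their intervals do not overlap, and an AUC beats chance when its lower
bound exceeds 0.5. Sensitivity is sample-level (every pre-ictal minute
must be flagged), time in high is the flagged fraction of all minutes,
and operating points can be matched to a target sensitivity or time in
high with ties resolved toward less time in warning. Multi-label runs
produce a confusion matrix (rows = actual), row-normalized sensitivities,
total accuracy, and a time-matched random baseline: for each label the
baseline sensitivity equals the model's own selection proportion for that
label, with flags for labels beaten at all and by more than 0.1.

## The synthetic recording generator

The generator emulates the regime of months-long implanted recordings at
a configurable scale: per-minute files, seizures clustered on cycles,
pre-ictal signal changes, telemetry dropouts, and slow gain drift.

* **Background**: per channel, AR(1) with pole 0.95 driven by unit
  innovations plus unit white noise (filter state carried across minute
  boundaries), giving a 1/f-like spectrum and genuine autocorrelation.
* **Seizure schedule**: inhomogeneous Poisson at minute resolution; the
  base rate (default 2/day at desk scale) is modulated multiplicatively
  by each configured cycle, `1 + a·cos(2πt/T)`, so each cycle peaks at
  its phase origin and the time-averaged rate is unchanged.
* **Pre-ictal signature**, active for minutes starting within
  [near, horizon) minutes of the next onset: `marker` superimposes a
  25 ms half-sine pulse of amplitude 5× the background SD on all channels
  at a per-second insertion probability (default 1.0); `variance_ramp`
  scales the amplitude linearly toward onset (default 2×, i.e. ~4×
  variance at onset); `autocorr_ramp` moves the AR pole linearly toward
  0.999 (critical slowing). Marker amplitude, insertion rate and exact
  placement are not published for the original detectability experiment;
  the defaults here are the package's own choices, set once to be
  detectable without saturating.
* **Dropouts**: Poisson blocks per day (default 2/day of 5 s), merged
  when overlapping, masked and NaN-ed.
* **Gain drift**: a per-day log-normal random walk with step
  0.1/√(timescale) and default timescale 30 days, applied to the complete
  signal — signature included, since a gain change at the electrode
  scales everything recorded. The drift is deliberately slow relative to
  the 30-day normalization window; drift faster than the window would
  make the published normalization scheme internally inconsistent and
  leaves per-day amplitude shortcuts that a classifier can exploit.

Everything derives from one integer seed (streams for schedule,
background, markers, dropouts and drift are split deterministically);
identical configs give bit-identical records.

**What the generator does not emulate**: biophysically realistic EEG
(spectra, spindles, epileptiform morphology), electrode montage geometry,
state-dependent amplitude changes, or any causal link between the
background process and seizure times. Passing the validation studies
therefore demonstrates that the pipeline machinery — normalization,
labeling, balancing, the recurrence, fusion, retargeting, and the
statistics — recovers a known planted signature under realistic data
plumbing; it says nothing about predictive power on clinical recordings.

## Validation studies (desk scale)

Both studies run on 4 channels at 100 Hz with 2-s segments, LSTM units
16/8/8/4, pool 4 — every structural element of the full-scale model at a
size that trains on one CPU in minutes. Problem sizes were chosen so each
study completes in a few minutes while keeping hundreds of pre-ictal test
minutes.

1. **Marker recovery** (6 days, 4 seizures/day, marker in the 1–16 min
   window, 1–16 min vs >16 min labels): the held-out segment-level LSTM
   AUC and the fused per-minute classifier AUC must have Hanley–McNeil
   lower bounds above 0.5; both reach ≈ 1.0.
2. **Signature placement** (18 days, 1 seizure/day, marker confined to
   40–80 min pre-onset, LSTM trained on the four-bin labeling with 400
   segments per label): retargeting the classifier to 40–80 min
   pre-ictal labels recovers the signature (lower CI bound > 0.5, in
   practice AUC ≈ 1.0), while retargeting to 1–4 min labels — a window
   containing no signature — stays at chance, demonstrating that the
   flexibility of the framework is carried by the frozen LSTM features
   plus cheap classifier retraining.

## Numerical choices and degenerate inputs

Max-pool windows floor the sequence length (4000 → 1000 → 250 → 62 at
pool 4); argmax ties take the first index, consistently in forward and
backward passes. A degenerate normalization divisor (constant signal for
30 days) marks the minute unusable rather than emitting infinities. An
empty label bin raises, naming the label. The Hanley–McNeil SE is clamped
at zero before the square root for AUC = 1. `predict` never applies
dropout. All stochastic components draw from `numpy` Generators seeded
from a single run seed (kept below 2³¹), so reruns are bit-identical on
the deterministic path.

## Known limitations

* The desk scale cannot reproduce clinical per-patient performance
  numbers; only structural and recovery properties are claimed.
* The log-seizure-time feature's cap and the marker experiment's
  amplitude/rate are package choices where the source material is silent.
* Sensitivity/time-in-high operating-point matching is implemented
  sample-level only; per-seizure event scoring used by some comparison
  methods is out of scope.
* The EDF writer covers the plain 16-bit variant with 1-s records and an
  auxiliary missing-data channel; it is not a general EDF+ implementation.
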