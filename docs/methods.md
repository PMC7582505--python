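# Methods

This package turns event-related EEG recorded around button-press responses
into upper-extremity Fugl–Meyer Assessment (FMA) scores (0–66 points) and
evaluates how well those EEG-derived scores track the clinical score over
repeated sessions. It also ships a synthetic EEG generator so the entire
pipeline is testable without access to clinical recordings.

## Signal model and preprocessing

Recordings are 32-channel EEG at 500 Hz with response events marked as
sample indices. Preprocessing applies, on the continuous signal and in this
order:

1. **Laterality normalisation.** Sessions recorded with left-hand responses
   have every homologous electrode pair (C3/C4, FC1/FC2, …) swapped so all
   sessions look like right-hand responses. The pair table lives in an
   editable YAML montage; the packaged default is a standard 32-channel
   10-20 layout (the vendor's exact sheet is not public, so this is a
   documented assumption). The unconditional channel permutation
   (`flip_channels`) is an involution; `flip_laterality` applies it only to
   left-hand sessions and relabels them, so it is idempotent rather than
   involutive.
2. **Band-pass 1–45 Hz.** Windowed-sinc (Hamming) FIR, applied
   forward–backward for zero phase, length preserving. The tap count is the
   smallest odd number whose single-pass response is ≥ 20 dB down at the
   0.1 Hz and 60 Hz probe frequencies (≈ 1 800 taps at 500 Hz — the 1 Hz
   low edge needs a narrow transition). Filtering uses FFT convolution with
   reflect padding; edge transients therefore stay within one filter length
   of the recording ends, and the generator places the first event 12 s in.
3. **Event screening.** Responses closer than 9 s to the previously *kept*
   response are dropped (greedy keep-first pass). The 9 s floor leaves room
   for the 8–10 s desynchronisation/synchronisation (ERD/ERS) cycle around
   a movement. Greedy keep-first is a deliberate resolution of an ambiguous
   rule ("events less than 9 s apart are discarded" could also drop both
   members of a close pair); it keeps the maximal prefix-consistent set and
   is deterministic.
4. **Sliding-window epochs.** Five 6 s windows per kept event, starting
   −4.0, −3.8, −3.6, −3.4, −3.2 s relative to the response. The offset grid
   is the half-open interval [−4 s, −3 s) at 0.2 s steps — the closed
   interval would give six windows, and five is the documented count.
   Events whose windows would cross the recording boundary are skipped (no
   zero padding, which would distort spectra).

## Feature tensors

Each 6 s, 500 Hz epoch (3 000 samples) is transformed channel-wise by an
FFT. Bins 1…270 (spacing 1/6 Hz, i.e. everything above DC up to and
including 45 Hz) are kept; plane 0 holds the power spectrum |X(f)|², plane 1
the principal-value phase. One trial is therefore a 270 × 32 × 2 tensor.
Retaining bins 1…270 rather than the 265 bins strictly inside (1 Hz, 45 Hz)
follows the documented bin count; the band-pass filter has already removed
the sub-1 Hz energy, so the difference is immaterial. Power is unnormalised
magnitude-squared — no log transform and no per-trial normalisation (an
optional per-trial standardisation flag exists for experimentation, default
off).

## Score regressors

Two architectures, both mapping one 270 × 32 × 2 tensor to one real score:

* **CNN** — conv(f₁, k₁) → maxpool 2×2 → conv(f₂, 2×2) → maxpool 2×2 →
  flatten → dense 100 → dropout → dense 25 → dense 10 → dense 5 → 1 output,
  ELU activations. Searchable: f₁, f₂ ∈ {25, 50, 100}; k₁ ∈ {2,4,6,8,10}²;
  dropout on a 0.05 grid; batch ∈ {64, 128}; iterations ∈ {100, 150, 200}.
  (In code the ELU is applied after each pooling stage; ELU is monotone, so
  the composite function is identical and the transcendental touches a
  quarter of the activations.)
* **ResNet** — 3×3 conv stem → three stages of post-activation residual
  blocks (conv 3×3 → BN → ELU → conv k₂ → BN, identity shortcut, ELU after
  the sum; 1×1 strided projection shortcut at stage transitions, where the
  channel count doubles and resolution halves) → global average pooling →
  dense 100 → dropout → dense 10 → 1 output. Searchable: blocks per stage
  ∈ {1, 2, 3}, first-stage filters ∈ {8, 16, 32}, second kernel ∈
  {2×2, 3×3, 5×5}, batch ∈ {16, 32, 64}, iterations ∈ {100, 150, 200}. The
  search bounds for depth/width are artifact choices (the original
  configuration figure does not print them); global average pooling before
  the dense head is the standard residual-network convention.

The layer engine is a small NumPy implementation (convolution via
im2col/BLAS, gradient-checked against finite differences in the test
suite); it exists because the package targets a plain scientific-Python
runtime. Everything is float32 and deterministic under a fixed seed.

### Training

Mean-squared-error regression with Adam at its conventional 10⁻³ step size;
"iterations" counts epochs over the training set. Numerical choices that
matter:

* **Input scaling.** Inputs are standardised with one scalar mean/std per
  plane (power, phase) computed on the training set. The power plane is
  naturally sparse — rhythm bins carry orders of magnitude more energy than
  background bins — and that concentration is what the convolutional front
  end keys on. Per-feature z-scoring was tried and rejected: it inflates
  ~17 000 background bins to unit variance and the score signal drowns
  (held-out error roughly doubles). Targets are z-scored; both transforms
  are stored on the model and inverted at prediction time.
* **Gradient clipping.** Global L2 norm clipped at 5. Spectral power is
  heavy-tailed, and an occasional extreme minibatch otherwise throws the
  ELU stack into its saturated constant-output regime.
* **Collapse restarts.** A minority of weight initialisations converge to
  the constant mean predictor (MSE → 1 on z-scored targets) and stay there.
  Training probes the loss after ~80 gradient steps; if it is still above
  0.5 the run restarts from a deterministically derived seed (at most 3
  restarts, all derived from the user seed, so the procedure remains
  reproducible).
* Predictions are unbounded reals by default; clipping to [0, 66] is an
  explicit flag.

## Hyperparameter search

Both search spaces are finite products of categorical sets, so the
Tree-structured Parzen Estimator reduces to per-dimension smoothed
categorical densities: after five random start-up trials the history is
split at the 25 % loss quantile, 24 candidates are drawn from the "good"
density and ranked by the log-likelihood ratio against the "bad" density.
A seeded random-search strategy is available as the pluggable alternative.
The tuning objective is validation MAE from a train-then-validate run on
disjoint trial sets. The desk-scale default budget is 10 evaluations;
cluster-scale budgets are configuration values.

## Session-level evaluation

Per-trial scores are averaged within each (participant, session) pair.
Against the clinical scores the package reports:

* **MAE** in FMA points over sessions;
* **Pearson r** between session means and clinical scores;
* **TOST equivalence**: a one-sample two one-sided t-test on the paired
  differences (predicted − true) against the asymmetric interval
  (−5, +6.6) points — the published FMA upper-extremity test-retest
  agreement band, applied asymmetrically as reported. Reported
  p = max of the two one-sided p-values; equivalence is declared at
  p < 0.05. With zero sample variance the limiting p is 0 if the mean lies
  strictly inside the interval, 1 otherwise.
* **t-tests**: two-sided paired, plus Welch's two-sample (the
  degrees-of-freedom convention is not standardised for this comparison;
  Welch is the safer default). Identical vectors make the paired test
  degenerate; it is reported as p = 1 with a flag.

TOST is computed on session means rather than pooled trials, matching the
"average all trials collected on the same day" convention.

Two protocols: **within-participant** (the training pool may contain the
participant's earlier data) and **cross-participant** (leave-one-subject-
out: every trial of the target participant is removed from the pool and the
removal is *verified* — participant ids and trial ids are intersected and
any overlap raises a hard `LeakageError` rather than a warning).

## Synthetic data generator

Each simulated session is 32-channel, 500 Hz EEG composed of per-channel
1/f background noise (RMS 10 µV), mu (10 Hz, 10 µV) and beta (20 Hz, 5 µV)
rhythms on three central channels per hemisphere with slow multiplicative
amplitude drift (sd 5 %, < 0.2 Hz), and event-locked desynchronisation:
around each response the rhythm amplitude over the hemisphere contralateral
to the response hand drops by `depth_max · score/66` (default depth_max
0.6) from 2.5 s before to 2.5 s after the event, with a 30 % ipsilateral
echo and a 10 % synchronisation rebound at +3…+5.5 s. Events are spaced
≥ 10 s, so the 9 s screening rule never fires on generated data, and the
first event sits 12 s in, clear of filter edge effects.

The score→ERD mapping is linear and positive (healthier → deeper ERD),
following the reported association between sensorimotor-rhythm
desynchronisation and motor function. The ERD window, depth and rhythm
amplitudes were sized from a noise budget so that single-trial band power
carries enough information to regress the score: with a 5 s ERD in a 6 s
analysis window the full score range spans roughly an 8 dB mu-power swing,
while the two noise terms — slow amplitude drift (~0.4 dB) and 1/f
background power leaking into the mu band (the dominant term, which is why
the rhythm amplitudes sit at 10/5 µV against a 10 µV-RMS background) —
together leave a session-level score uncertainty of about 2–3 points and a
trial-level one of 3–4 points, comfortably inside the 6.6-point smallest
real difference of the FMA that the end-to-end check uses.

What the generator deliberately does **not** model: per-participant
baseline rhythm amplitudes (all simulated heads share the same mu/beta
amplitude, which is what makes absolute band power transfer across
participants — real cross-participant transfer is harder), artifacts
(ocular, EMG, line noise), volume conduction and electrode covariance,
non-stationarity across sessions beyond the slow drift, and any real
relationship between clinical scores and EEG. Passing tests on synthetic
data therefore demonstrate that the pipeline is implemented correctly and
can extract a score that is monotonically encoded in ERD depth — not that
the method works on clinical EEG.

Stroke participants' scores are drawn from the three clusters 10–24, 36–41
and 45–51 points that the chronic-stroke pool naturally forms; healthy
participants sit at the ceiling score of 66. The pool defaults are 12
healthy + 14 stroke participants with 140 training and 30 held-out trials
each (3 640 training trials in total). The train/test split is by event:
the five sliding windows of one response overlap by > 90 %, so splitting by
trial would leak.

## Scaled-down validation experiment

Training the full pool configuration is cluster-scale work, so the packaged
validation study (`eegmotor.validation.synthetic_recovery_study`, also run
by `scripts/acceptance.py`) uses 8 participants (4 healthy, 4 stroke from
the three chronic-stroke clusters), 60 training + 15 held-out trials each, and the small
CNN configuration (25 conv-1 filters, 2×2 kernels, batch 64, 100
iterations). The problem sizes are the package's own desk-scale choice; all
counts scale back up through configuration. Success is held-out
single-trial MAE < 6.6 FMA points and Pearson r > 0.8 between session-mean
predictions and assigned scores, plus a six-session longitudinal
equivalence check (TOST) for one stroke participant from the 45–51 cluster.

## Known limitations

* The NumPy engine is CPU-bound and single-threaded; cluster-scale budgets
  (full 26-participant pools, large search budgets, the big CNN/ResNet
  grid points) are configuration values, not defaults.
* The EDF writer pads recordings to whole seconds (16-bit EDF quantisation
  applies); the `.npz` + CSV array container is lossless.
* TOST on n = 3 sessions has little power — expected behaviour, visible in
  the longitudinal statistics for short trajectories.
* The collapse-restart heuristic assumes a learnable signal; on pure-noise
  labels it will simply exhaust its restarts and return the mean predictor.
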