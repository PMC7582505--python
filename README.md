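# eegmotor

Scoring upper-extremity motor function from button-press EEG.

After a stroke, motor recovery is tracked with questionnaire-based clinical
scales — most commonly the upper-extremity section of the Fugl–Meyer
Assessment (FMA, 0–66 points) — which need a trained examiner and are not
fully objective. Sensorimotor rhythms offer a physiological alternative:
the mu (≈10 Hz) and beta (≈20 Hz) oscillations over central electrodes
desynchronise around a voluntary movement (ERD), and the depth of that
desynchronisation correlates with motor ability. `eegmotor` implements a
complete pipeline that learns this mapping: it converts 32-channel, 500 Hz
EEG recorded around button presses into per-trial spectral tensors, trains
convolutional or residual network regressors to emit an FMA-scale score per
trial, and evaluates session-averaged scores against the clinical scale
with equivalence statistics suitable for longitudinal monitoring.

The pipeline, in order:

1. **Laterality normalisation** — left-hand response sessions have every
   homologous electrode pair swapped so all data look right-handed
   (montage = editable YAML, standard 32-channel 10-20 default).
2. **1–45 Hz zero-phase FIR band-pass** on the continuous signal.
3. **Event screening** — responses < 9 s after the previous kept response
   are dropped (the ERD/ERS cycle spans ~8–10 s).
4. **Epoching** — five 6 s sliding windows per event, starting 4.0 … 3.2 s
   before the press in 0.2 s steps.
5. **Features** — channel-wise FFT; bins 1/6 … 45 Hz; power and phase
   planes stacked into a 270 × 32 × 2 tensor per trial.
6. **Regression** — CNN (two conv/pool stages, 100-25-10-5-1 dense head)
   or ResNet (three residual stages, global average pooling, three dense
   layers), mean-squared-error training, hyperparameters constrained to
   their fixed categorical grids with TPE (or random) search.
7. **Evaluation** — per-trial scores averaged per session; MAE, Pearson r,
   TOST equivalence on the asymmetric FMA test-retest band (−5, +6.6)
   points, paired/Welch t-tests; within-participant and verified
   leave-one-subject-out protocols.

A synthetic generator (`eegmotor.simulate`) produces 32-channel sessions
with 1/f background, central mu/beta rhythms, and event-locked
contralateral ERD whose depth is linear in an assigned FMA score, so every
stage — including end-to-end score recovery — is testable without clinical
data. See `docs/methods.md` for the model details and the generator's
limitations.

## Worked example

Generate a synthetic pool (4 healthy + 4 stroke participants, 60 training
and 15 held-out trials each), train the small CNN, and score the held-out
trials:

```python
import numpy as np
import eegmotor as em
from eegmotor.simulate import SimPoolSpec, simulate_pool

train, test = simulate_pool(
    SimPoolSpec(n_healthy=4, n_stroke=4, train_trials=60, test_trials=15),
    seed=11)
model = em.train_model(em.build_model(em.CnnConfig()), train, seed=5)
pred = model.predict(test.features)
print(f"held-out trial MAE: {np.mean(np.abs(pred - test.scores)):.2f}")

sessions = em.aggregate_sessions(pred, test.index_frame())
for s in sessions:
    print(f"{s.participant_id}: predicted {s.predicted:5.1f}  true {s.fma_true:4.0f}")
print(f"session r = {em.pearson([s.predicted for s in sessions],
                                [s.fma_true for s in sessions]):.3f}")
```

Output (about six minutes on one CPU core):

```
held-out trial MAE: 5.37
H01: predicted  61.2  true   66
H02: predicted  58.1  true   66
H03: predicted  58.8  true   66
H04: predicted  61.7  true   66
S01: predicted  37.7  true   38
S02: predicted  45.4  true   40
S03: predicted  42.6  true   40
S04: predicted  16.5  true   12
session r = 0.986
```

Each held-out trial is a single 6 s EEG window; its score is the network's
FMA estimate from that window alone. Averaging the 15 held-out trials per
participant gives the session scores above: healthy participants sit near
the 66-point ceiling, the three stroke clusters are recovered in order, and
the session means track the assigned scores (r ≈ 0.99) with errors well
inside the scale's ~6.6-point smallest real difference.

The same flow is available from the shell:

```sh
eegmotor simulate --score 45 --side left --n-events 40 --out sess.edf \
    --labels-out labels.csv
eegmotor featurize --recording sess.edf --labels labels.csv --out feat.h5
eegmotor train --features feat.h5 --arch cnn --out model
eegmotor evaluate --model model --features feat.h5
eegmotor run-all --seed 0 --out-dir run/     # whole pipeline, one manifest
```

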