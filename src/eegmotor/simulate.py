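"""Synthetic button-press EEG whose spectral structure encodes a motor score.

Each simulated session is 32-channel, 500 Hz EEG made of

* per-channel 1/f^beta background noise (beta = 1),
* mu (10 Hz) and beta (20 Hz) sensorimotor rhythms on a small group of
  central channels over each hemisphere, with slow random amplitude
  modulation,
* event-locked desynchronisation (ERD): around every button press the
  rhythm amplitude over the hemisphere *contralateral* to the response hand
  drops by a fraction linear in the assigned FMA score (depth 0 at score 0,
  0.5 at the ceiling score of 66), with a weaker ipsilateral drop and a
  small synchronisation rebound (ERS) afterwards,
* response events spaced at least 10 s apart, so the 9 s screening rule
  never removes a generated event.

Healthier participants therefore show deeper contralateral ERD — the
direction reported for sensorimotor rhythms — and a regressor can recover
the score from single-trial spectra.  Everything is deterministic per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import LabeledDataset, assemble_dataset, featurize_recording
from .io import Montage, Recording, SessionLabel, default_montage
from .preprocess import EpochSpec

FMA_MAX = 66

#: FMA ranges of the three clusters the chronic-stroke pool naturally forms.
STROKE_SCORE_CLUSTERS = ((10, 24), (36, 41), (45, 51))


@dataclass(frozen=True)
class SimSpec:
    """Generative settings for one session (defaults follow the target acquisition protocol)."""

    sampling_rate: float = 500.0
    n_events: int = 40                  # at least 40 responses per session
    min_event_gap_s: float = 10.0       # > the 9 s screening rule
    max_event_gap_s: float = 11.5
    first_event_s: float = 12.0
    tail_s: float = 8.0
    background_beta: float = 1.0        # 1/f exponent
    background_rms_uv: float = 10.0
    mu_freq_hz: float = 10.0
    beta_freq_hz: float = 20.0
    mu_amp_uv: float = 10.0
    beta_amp_uv: float = 5.0
    amp_mod_sd: float = 0.05            # slow multiplicative amplitude drift
    erd_depth_max: float = 0.6          # fractional amplitude drop at score 66
    ipsilateral_fraction: float = 0.3
    ers_amplitude: float = 0.1          # fractional rebound
    erd_start_s: float = -2.5           # readiness desynchronisation onset
    erd_end_s: float = 2.5
    ers_start_s: float = 3.0
    ers_end_s: float = 5.5
    ramp_s: float = 0.25
    left_motor_channels: tuple = ("C3", "FC1", "CP1")
    right_motor_channels: tuple = ("C4", "FC2", "CP2")

    def erd_depth(self, score: float) -> float:
        """Fractional contralateral amplitude suppression, linear in score."""
        if not 0 <= score <= FMA_MAX:
            raise ValueError("score must lie in [0, 66]")
        return self.erd_depth_max * score / FMA_MAX


@dataclass(frozen=True)
class SimPoolSpec:
    """Composition of the training pool (defaults mirror the reference pool)."""

    n_healthy: int = 12
    n_stroke: int = 14
    train_trials: int = 140
    test_trials: int = 30
    score_clusters: tuple = STROKE_SCORE_CLUSTERS
    sim: SimSpec = field(default_factory=SimSpec)

    def __post_init__(self):
        if self.train_trials % 5 or self.test_trials % 5:
            raise ValueError("trial counts must be multiples of the 5 "
                             "windows per event")


def _one_over_f_noise(rng, n, fs, beta, rms):
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1 / fs)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-beta / 2)
    x = np.fft.irfft(spec * shape, n=n)
    return x * (rms / max(x.std(), 1e-12))


def _slow_modulation(rng, n, fs, sd, cutoff_hz=0.2):
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1 / fs)
    spec[f > cutoff_hz] = 0.0
    x = np.fft.irfft(spec, n=n)
    return 1.0 + sd * x / max(x.std(), 1e-12)


def _event_gain(t, events_s, spec: SimSpec, depth: float) -> np.ndarray:
    """Multiplicative rhythm-amplitude envelope: ERD dip + ERS rebound."""
    gain = np.ones_like(t)
    for ev in events_s:
        gain -= depth * _trapezoid(t - ev, spec.erd_start_s, spec.erd_end_s,
                                   spec.ramp_s)
        gain += spec.ers_amplitude * _trapezoid(t - ev, spec.ers_start_s,
                                                spec.ers_end_s, spec.ramp_s)
    return np.clip(gain, 0.0, None)


def _trapezoid(x, start, end, ramp):
    up = np.clip((x - start) / ramp, 0.0, 1.0)
    down = np.clip((end - x) / ramp, 0.0, 1.0)
    return up * down


def simulate_session(score: float, side: str, spec: SimSpec = SimSpec(),
                     seed: int = 0, montage: Montage | None = None,
                     participant_id: str = "SIM", session_id: str = "s1"
                     ) -> Recording:
    """Generate one session Recording; deterministic per seed."""
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    montage = montage or default_montage()
    rng = np.random.default_rng(seed)
    fs = spec.sampling_rate

    gaps = rng.uniform(spec.min_event_gap_s, spec.max_event_gap_s,
                       size=spec.n_events)
    events_s = spec.first_event_s + np.concatenate(
        [[0.0], np.cumsum(gaps[:-1])])
    duration_s = math.ceil(events_s[-1] + spec.tail_s)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    events = np.rint(events_s * fs).astype(np.int64)

    labels = list(montage.labels)
    signals = np.empty((len(labels), n))
    for ch in range(len(labels)):
        signals[ch] = _one_over_f_noise(rng, n, fs, spec.background_beta,
                                        spec.background_rms_uv)

    depth_contra = spec.erd_depth(score)
    depth_ipsi = spec.ipsilateral_fraction * depth_contra
    # responses with the right hand desynchronise the left hemisphere
    contra_group, ipsi_group = (
        (spec.left_motor_channels, spec.right_motor_channels)
        if side == "right" else
        (spec.right_motor_channels, spec.left_motor_channels))

    for group, depth in ((contra_group, depth_contra),
                         (ipsi_group, depth_ipsi)):
        gain = _event_gain(t, events_s, spec, depth)
        for name in group:
            if name not in labels:
                raise ValueError(f"motor channel {name} not in montage")
        for name in group:
            ch = labels.index(name)
            for freq, amp in ((spec.mu_freq_hz, spec.mu_amp_uv),
                              (spec.beta_freq_hz, spec.beta_amp_uv)):
                phase = rng.uniform(0, 2 * np.pi)
                mod = _slow_modulation(rng, n, fs, spec.amp_mod_sd)
                signals[ch] += (amp * mod * gain
                                * np.sin(2 * np.pi * freq * t + phase))

    return Recording(signals=signals, sampling_rate=fs,
                     channel_labels=labels, events=events,
                     response_side=side, participant_id=participant_id,
                     session_id=session_id)


# ---------------------------------------------------------------------------
# pool and longitudinal generation
# ---------------------------------------------------------------------------

def _stage_seed(seed: int, *key) -> int:
    return int(np.random.SeedSequence([int(seed), *map(int, key)])
               .generate_state(1)[0] % 2 ** 31)


def sample_stroke_score(rng, clusters=STROKE_SCORE_CLUSTERS) -> int:
    lo, hi = clusters[rng.integers(len(clusters))]
    return int(rng.integers(lo, hi + 1))


def plan_pool(pool_spec: SimPoolSpec, seed: int = 0) -> pd.DataFrame:
    """The pool's participant/trial index, before any signal is generated."""
    rng = np.random.default_rng(_stage_seed(seed, 0))
    rows = []
    for i in range(pool_spec.n_healthy):
        rows.append({"participant_id": f"H{i + 1:02d}", "group": "healthy",
                     "fma_ue": FMA_MAX})
    for i in range(pool_spec.n_stroke):
        rows.append({"participant_id": f"S{i + 1:02d}", "group": "stroke",
                     "fma_ue": sample_stroke_score(rng,
                                                   pool_spec.score_clusters)})
    df = pd.DataFrame(rows)
    df["side"] = [("right", "left")[i % 2] for i in range(len(df))]
    df["n_train_trials"] = pool_spec.train_trials
    df["n_test_trials"] = pool_spec.test_trials
    return df


def simulate_pool(pool_spec: SimPoolSpec = SimPoolSpec(), seed: int = 0,
                  montage: Montage | None = None,
                  epoch_spec: EpochSpec = EpochSpec()
                  ) -> tuple[LabeledDataset, LabeledDataset]:
    """Generate and featurize the whole pool; returns (train, test).

    The per-participant split is by event (whole events with their five
    sliding windows go to one side) so the heavily overlapping windows of a
    single response never straddle the split; test events are spread evenly
    across the session so slow amplitude drift affects both sides alike.
    """
    montage = montage or default_montage()
    plan = plan_pool(pool_spec, seed)
    per = epoch_spec.epochs_per_event
    n_train_events = pool_spec.train_trials // per
    n_test_events = pool_spec.test_trials // per
    n_events = n_train_events + n_test_events

    test_events = np.unique(np.round(
        np.linspace(0, n_events - 1, n_test_events)).astype(int))
    if len(test_events) != n_test_events:
        raise ValueError("test trials cannot exceed total trials")
    train_parts, test_parts = [], []
    for i, row in enumerate(plan.itertuples()):
        sim = replace(pool_spec.sim, n_events=n_events)
        rec = simulate_session(row.fma_ue, row.side, sim,
                               seed=_stage_seed(seed, 1, i),
                               montage=montage,
                               participant_id=row.participant_id,
                               session_id="pool")
        values, prov = featurize_recording(rec, montage, epoch_spec)
        label = SessionLabel(row.participant_id, "pool", int(row.fma_ue),
                             row.group)
        ds = assemble_dataset(values, prov, [label])
        in_test = prov["event_index"].isin(test_events).to_numpy()
        train_parts.append(ds.subset(np.flatnonzero(~in_test)))
        test_parts.append(ds.subset(np.flatnonzero(in_test)))
    return (LabeledDataset.concatenate(train_parts),
            LabeledDataset.concatenate(test_parts))


def plan_longitudinal(trajectory) -> pd.DataFrame:
    """Trial index for a longitudinal series of (session_id, score) points."""
    rows = [{"session_id": str(sid), "fma_ue": int(score)}
            for sid, score in trajectory]
    return pd.DataFrame(rows)


def simulate_longitudinal(trajectory, spec: SimSpec = SimSpec(),
                          seed: int = 0, montage: Montage | None = None,
                          participant_id: str = "P1", side: str = "right"
                          ) -> list[Recording]:
    """One Recording per (session_id, score) trajectory point."""
    montage = montage or default_montage()
    recs = []
    for k, (session_id, score) in enumerate(trajectory):
        recs.append(simulate_session(score, side, spec,
                                     seed=_stage_seed(seed, 2, k),
                                     montage=montage,
                                     participant_id=participant_id,
                                     session_id=str(session_id)))
    return recs


# ---------------------------------------------------------------------------
# measurement oracle used by tests and docs
# ---------------------------------------------------------------------------

def measured_erd_depth(rec: Recording, spec: SimSpec = SimSpec(),
                       band=(8.0, 13.0)) -> float:
    """Empirical contralateral mu-band ERD depth of a recording.

    Compares band power in a post-event window [0, 1.4] s against an
    equal-length pre-event baseline [-4.2, -2.8] s (after the previous
    event's rebound, before this event's desynchronisation onset) over the
    central channels contralateral to the response side, averaged over
    events:  1 - sqrt(P_active / P_baseline).
    """
    fs = rec.sampling_rate
    group = (spec.left_motor_channels if rec.response_side == "right"
             else spec.right_motor_channels)
    idx = [rec.channel_labels.index(c) for c in group]

    def band_power(seg):
        spec_ = np.fft.rfft(seg, axis=-1)
        f = np.fft.rfftfreq(seg.shape[-1], 1 / fs)
        sel = (f >= band[0]) & (f <= band[1])
        return float(np.mean(np.abs(spec_[..., sel]) ** 2)
                     / seg.shape[-1] ** 2)

    ratios = []
    for ev in rec.events:
        b0, b1 = int(ev - 4.2 * fs), int(ev - 2.8 * fs)
        a0, a1 = int(ev), int(ev + 1.4 * fs)
        if b0 < 0 or a1 > rec.n_samples:
            continue
        p_base = band_power(rec.signals[idx, b0:b1])
        p_act = band_power(rec.signals[idx, a0:a1])
        ratios.append(p_act / p_base)
    if not ratios:
        raise ValueError("no events with enough surrounding signal")
    return float(1.0 - np.sqrt(np.mean(ratios)))
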