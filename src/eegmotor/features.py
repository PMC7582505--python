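"""Spectral feature tensors and labeled datasets.

Each 6 s, 500 Hz epoch becomes a 270 x 32 x 2 tensor: a channel-wise DFT
whose bins 1..270 (1/6 Hz spacing, i.e. everything above DC up to and
including 45 Hz) are kept; plane 0 is the power spectrum |X(f)|², plane 1
the principal-value phase arg X(f).

The canonical 270-row tensor fixes the retention convention (bins 1..270
inclusive rather than the 265 strictly inside 1-45 Hz), and the band-pass filter has already
removed the sub-1 Hz energy those low bins would otherwise carry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Montage, Recording, SessionLabel
from .preprocess import EpochSet, EpochSpec, bandpass, extract_epochs, \
    flip_laterality, screen_events

MAX_FREQ_HZ = 45.0


def n_retained_bins(window_length_s: float, max_freq_hz: float = MAX_FREQ_HZ
                    ) -> int:
    """Bins above DC up to ``max_freq_hz``: floor(f_max * T)."""
    return int(np.floor(max_freq_hz * window_length_s + 1e-9))


def bin_frequencies(window_length_s: float,
                    max_freq_hz: float = MAX_FREQ_HZ) -> np.ndarray:
    n = n_retained_bins(window_length_s, max_freq_hz)
    return np.arange(1, n + 1) / window_length_s


def spectral_features(epochs: EpochSet, max_freq_hz: float = MAX_FREQ_HZ,
                      standardize: bool = False) -> np.ndarray:
    """Per-trial power/phase tensors, shape (n_trials, bins, channels, 2).

    ``standardize`` optionally z-scores each trial's power plane in place
    (experimentation flag; off by default — the regressors see raw power).
    """
    data = np.asarray(epochs.data)
    if data.ndim != 3:
        raise ValueError("epochs.data must be trials x channels x samples")
    n_samples = data.shape[2]
    window_s = n_samples / epochs.sampling_rate
    n_bins = n_retained_bins(window_s, max_freq_hz)
    spec = np.fft.rfft(data, axis=2)
    if spec.shape[2] < n_bins + 1:
        raise ValueError("epoch too short for the requested frequency range")
    kept = spec[:, :, 1:n_bins + 1]
    power = np.abs(kept) ** 2
    phase = np.angle(kept)
    phase = np.where(phase <= -np.pi, np.pi, phase)   # principal value (-pi, pi]
    if standardize:
        mu = power.mean(axis=(1, 2), keepdims=True)
        sd = power.std(axis=(1, 2), keepdims=True)
        power = (power - mu) / np.maximum(sd, 1e-12)
    # (trials, channels, bins) -> (trials, bins, channels, planes)
    return np.stack([power, phase], axis=-1).transpose(0, 2, 1, 3)


@dataclass
class LabeledDataset:
    """Trial feature tensors paired with session-level FMA labels."""

    features: np.ndarray          # (n, bins, channels, 2)
    scores: np.ndarray            # (n,) FMA points
    participants: np.ndarray      # (n,) str
    sessions: np.ndarray          # (n,) str
    groups: np.ndarray            # (n,) str
    trial_ids: np.ndarray         # (n,) unique str

    def __post_init__(self):
        n = len(self.features)
        for name in ("scores", "participants", "sessions", "groups",
                     "trial_ids"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} trials")
            setattr(self, name, arr)
        if len(np.unique(self.trial_ids)) != n:
            raise ValueError("trial ids must be unique")

    def __len__(self):
        return len(self.features)

    def subset(self, idx) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(self.features[idx], self.scores[idx],
                              self.participants[idx], self.sessions[idx],
                              self.groups[idx], self.trial_ids[idx])

    def exclude_participant(self, participant_id: str) -> "LabeledDataset":
        return self.subset(np.flatnonzero(self.participants
                                          != participant_id))

    @staticmethod
    def concatenate(parts) -> "LabeledDataset":
        parts = list(parts)
        return LabeledDataset(
            np.concatenate([p.features for p in parts]),
            np.concatenate([p.scores for p in parts]),
            np.concatenate([p.participants for p in parts]),
            np.concatenate([p.sessions for p in parts]),
            np.concatenate([p.groups for p in parts]),
            np.concatenate([p.trial_ids for p in parts]))

    def index_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "participant_id": self.participants,
            "session_id": self.sessions,
            "group": self.groups,
            "fma_ue": self.scores,
            "trial_id": self.trial_ids,
        })


def assemble_dataset(features: np.ndarray, provenance: pd.DataFrame,
                     labels: list[SessionLabel]) -> LabeledDataset:
    """Pair trial tensors with their session's FMA score.

    ``provenance`` needs columns participant_id, session_id, event_index,
    offset_s.  Every (participant, session) must have a label row; healthy
    sessions carry the ceiling score of 66 in their label.
    """
    table = {(l.participant_id, l.session_id): l for l in labels}
    scores, groups, trial_ids = [], [], []
    for row in provenance.itertuples():
        key = (str(row.participant_id), str(row.session_id))
        if key not in table:
            raise KeyError(f"no session label for {key}")
        lab = table[key]
        scores.append(lab.fma_ue)
        groups.append(lab.group)
        trial_ids.append(f"{key[0]}/{key[1]}/e{row.event_index}/"
                         f"o{row.offset_s:+.1f}")
    return LabeledDataset(
        features=np.asarray(features),
        scores=np.asarray(scores, dtype=float),
        participants=provenance["participant_id"].to_numpy(dtype=str),
        sessions=provenance["session_id"].to_numpy(dtype=str),
        groups=np.asarray(groups),
        trial_ids=np.asarray(trial_ids))


def featurize_recording(rec: Recording, montage: Montage,
                        spec: EpochSpec = EpochSpec(),
                        low_hz: float = 1.0, high_hz: float = 45.0,
                        standardize: bool = False):
    """Full conditioning chain for one session.

    flip -> band-pass -> screen -> epoch -> spectral tensors; returns
    ``(values, provenance)`` where provenance carries participant/session
    columns ready for :func:`assemble_dataset`.
    """
    rec = flip_laterality(rec, montage)
    rec = bandpass(rec, low_hz, high_hz)
    kept = screen_events(rec.events, rec.sampling_rate, spec.min_event_gap_s)
    rec.events = kept
    epochs = extract_epochs(rec, spec)
    values = spectral_features(epochs, standardize=standardize)
    prov = epochs.provenance.copy()
    prov.insert(0, "participant_id", rec.participant_id)
    prov.insert(1, "session_id", rec.session_id)
    return values, prov
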