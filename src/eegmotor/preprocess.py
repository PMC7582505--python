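"""Signal conditioning for button-press EEG sessions.

Four steps, applied to the continuous recording in this order:

1. laterality normalisation — left-hand response sessions have every
   homologous electrode pair swapped so all data look like right-hand
   responses,
2. 1-45 Hz zero-phase FIR band-pass,
3. event screening — responses closer than 9 s to the previously kept
   response are discarded, leaving room for the 8-10 s ERD/ERS cycle,
4. sliding-window epoch extraction — five 6 s windows per kept event,
   starting 4.0, 3.8, 3.6, 3.4 and 3.2 s before the response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import Montage, Recording

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EpochSpec:
    """Sliding-window plan around each response event.

    The start-offset grid is the half-open interval
    ``[first_offset_s, first_offset_s + 1)`` at ``step_s`` spacing: with the
    defaults that is −4.0 … −3.2 s, i.e. exactly five windows per event.
    """

    window_length_s: float = 6.0
    first_offset_s: float = -4.0
    step_s: float = 0.2
    epochs_per_event: int = 5
    min_event_gap_s: float = 9.0

    def __post_init__(self):
        if self.window_length_s <= 0:
            raise ValueError("window_length_s must be positive")
        if self.step_s <= 0:
            raise ValueError("step_s must be positive")
        n_grid = int(np.floor((1.0 - 1e-9) / self.step_s)) + 1
        if self.epochs_per_event != n_grid:
            raise ValueError(
                f"epochs_per_event={self.epochs_per_event} inconsistent with "
                f"a [{self.first_offset_s}, {self.first_offset_s + 1}) grid "
                f"at {self.step_s} s spacing ({n_grid} offsets)")

    @property
    def offsets_s(self) -> np.ndarray:
        return self.first_offset_s + self.step_s * np.arange(
            self.epochs_per_event)


@dataclass
class EpochSet:
    """Extracted trials: ``data`` is trials x channels x samples (µV)."""

    data: np.ndarray
    provenance: pd.DataFrame    # columns: event_index, event_sample, offset_s
    sampling_rate: float
    channel_labels: list[str] = field(default_factory=list)

    def __len__(self):
        return len(self.data)


# ---------------------------------------------------------------------------
# laterality
# ---------------------------------------------------------------------------

def flip_channels(rec: Recording, montage: Montage) -> Recording:
    """Swap every homologous electrode pair (unconditional involution)."""
    fm = montage.flip_map()
    missing = set(rec.channel_labels) - set(fm)
    if missing:
        raise ValueError(f"channels absent from montage: {sorted(missing)}")
    pos = {c: i for i, c in enumerate(rec.channel_labels)}
    perm = np.arange(rec.n_channels)
    for i, c in enumerate(rec.channel_labels):
        partner = fm[c]
        if partner in pos:
            perm[i] = pos[partner]
        elif partner != c:
            raise ValueError(
                f"channel {c}: homologous partner {partner} not recorded")
    out = rec.copy()
    out.signals = rec.signals[perm]
    return out


def flip_laterality(rec: Recording, montage: Montage) -> Recording:
    """Normalise a session to right-hand-response channel layout.

    Left-hand sessions get their homologous pairs swapped and are relabelled
    as right-hand; right-hand sessions pass through unchanged.
    """
    if rec.response_side == "right":
        return rec.copy()
    out = flip_channels(rec, montage)
    out.response_side = "right"
    return out


# ---------------------------------------------------------------------------
# band-pass filter
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def design_bandpass(low_hz: float, high_hz: float, sampling_rate: float,
                    stop_atten_db: float = 20.0,
                    stop_low_hz: float = 0.1,
                    stop_high_hz: float = 60.0) -> np.ndarray:
    """Design a windowed-sinc (Hamming) band-pass FIR.

    The number of taps is the smallest odd count (even order) whose
    single-pass response is at least ``stop_atten_db`` down at the two probe
    stopband frequencies (0.1 and 60 Hz by default for 500 Hz input).
    """
    if not 0 < low_hz < high_hz < sampling_rate / 2:
        raise ValueError("band edges must satisfy 0 < low < high < fs/2")

    def attenuation_ok(taps: np.ndarray) -> bool:
        freqs = [f for f in (stop_low_hz, stop_high_hz)
                 if 0 < f < sampling_rate / 2]
        _, h = sps.freqz(taps, worN=freqs, fs=sampling_rate)
        return bool(np.all(20 * np.log10(np.abs(h) + 1e-300)
                           <= -stop_atten_db))

    # Hamming-window transition-width estimate, then grow / shrink to the
    # smallest odd tap count that meets the probe-frequency attenuation.
    trans = min(low_hz - stop_low_hz, stop_high_hz - high_hz)
    n = int(np.ceil(3.3 * sampling_rate / max(trans, 1e-6)))
    n += 1 - n % 2
    taps = sps.firwin(n, [low_hz, high_hz], pass_zero=False,
                      fs=sampling_rate, window="hamming")
    while not attenuation_ok(taps):
        n = n + 2 if n < 64 else int(n * 1.3) | 1
        taps = sps.firwin(n, [low_hz, high_hz], pass_zero=False,
                          fs=sampling_rate, window="hamming")
    while n > 3:
        n2 = max(3, int(n / 1.15)) | 1
        t2 = sps.firwin(n2, [low_hz, high_hz], pass_zero=False,
                        fs=sampling_rate, window="hamming")
        if attenuation_ok(t2):
            n, taps = n2, t2
        else:
            break
    return taps


def bandpass(rec: Recording, low_hz: float = 1.0, high_hz: float = 45.0
             ) -> Recording:
    """Zero-phase (forward-backward) FIR band-pass, length preserving.

    Signals are reflect-padded by the filter length at both ends before the
    two passes, so edge transients from the padding do not fold into the
    interior.
    """
    taps = design_bandpass(low_hz, high_hz, float(rec.sampling_rate))
    out = rec.copy()
    out.signals = filtfilt_fir(rec.signals, taps)
    return out


def filtfilt_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Forward-backward FIR filtering along the last axis (FFT-based)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    pad = min(len(taps), x.shape[-1] - 1)
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="reflect")
    fwd = sps.fftconvolve(xp, taps[None, :], mode="same", axes=-1)
    back = sps.fftconvolve(fwd[..., ::-1], taps[None, :], mode="same",
                           axes=-1)[..., ::-1]
    return back[..., pad:back.shape[-1] - pad]


# ---------------------------------------------------------------------------
# event screening
# ---------------------------------------------------------------------------

def screen_events(events, sampling_rate: float, min_gap_s: float = 9.0
                  ) -> np.ndarray:
    """Greedy keep-first screening of too-close response events.

    The first event is kept; afterwards an event is kept only if it falls at
    least ``min_gap_s`` after the most recently *kept* event.
    """
    events = np.asarray(events, dtype=np.int64)
    if events.size and np.any(np.diff(events) <= 0):
        raise ValueError("events must be strictly ascending")
    gap = min_gap_s * sampling_rate
    kept: list[int] = []
    for e in events:
        if not kept or e - kept[-1] >= gap:
            kept.append(int(e))
    return np.asarray(kept, dtype=np.int64)


# ---------------------------------------------------------------------------
# epoch extraction
# ---------------------------------------------------------------------------

def extract_epochs(rec: Recording, spec: EpochSpec = EpochSpec()) -> EpochSet:
    """Cut the sliding windows around each event.

    Events whose five windows would cross the recording boundaries are
    skipped entirely (no zero padding), with a logged warning.
    """
    fs = rec.sampling_rate
    n_win = spec.window_length_s * fs
    step = spec.step_s * fs
    first = spec.first_offset_s * fs
    for name, v in (("window", n_win), ("step", step), ("first offset", first)):
        if abs(v - round(v)) > 1e-6:
            raise ValueError(
                f"{name} of {v / fs} s is not a whole number of samples at "
                f"{fs} Hz")
    n_win, step, first = int(round(n_win)), int(round(step)), int(round(first))

    trials, rows = [], []
    for ev_idx, ev in enumerate(rec.events):
        starts = ev + first + step * np.arange(spec.epochs_per_event)
        if starts[0] < 0 or starts[-1] + n_win > rec.n_samples:
            logger.warning(
                "event %d at sample %d skipped: window exceeds recording "
                "bounds", ev_idx, ev)
            continue
        for k, s in enumerate(starts):
            trials.append(rec.signals[:, s:s + n_win])
            rows.append({"event_index": ev_idx, "event_sample": int(ev),
                         "offset_s": float(spec.offsets_s[k])})
    data = (np.stack(trials) if trials else
            np.empty((0, rec.n_channels, n_win)))
    return EpochSet(data=data, provenance=pd.DataFrame(
        rows, columns=["event_index", "event_sample", "offset_s"]),
        sampling_rate=fs, channel_labels=list(rec.channel_labels))
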