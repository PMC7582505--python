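"""Reading and writing recordings, events, labels, montages and feature stores.

On-disk formats:

* recordings — 16-bit EDF+ (events carried as annotations) written by a
  small built-in writer and read back through :mod:`mne`; alternatively a
  plain NumPy ``.npz`` container with a companion ``.events.csv``
  (column ``sample_index``) for synthetic data,
* session labels — CSV with columns
  ``participant_id,session_id,fma_ue,group``,
* feature tensors — HDF5 with per-trial provenance columns,
* montage — YAML (channel order, homologous left/right pairs, midline).

Events are stored as 0-based sample indices; conversion to seconds always
uses the recording's own sampling rate.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

FEATURE_SHAPE = (270, 32, 2)   # frequency bins x channels x (power, phase)

VALID_GROUPS = ("healthy", "stroke")
VALID_SIDES = ("left", "right")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Continuous multichannel EEG with response events.

    signals are channels x samples in microvolts; ``events`` are ascending
    0-based sample indices of button-press responses.
    """

    signals: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    events: np.ndarray
    response_side: str
    participant_id: str = "unknown"
    session_id: str = "unknown"

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        self.events = np.asarray(self.events, dtype=np.int64)
        self.channel_labels = [str(c) for c in self.channel_labels]
        self.validate()

    def validate(self):
        if self.signals.ndim != 2:
            raise ValueError("signals must be channels x samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channel_labels) != self.signals.shape[0]:
            raise ValueError("channel_labels length must match signal rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.response_side not in VALID_SIDES:
            raise ValueError(f"response_side must be one of {VALID_SIDES}")
        if self.events.size:
            if np.any(np.diff(self.events) <= 0):
                raise ValueError("events must be strictly ascending")
            if self.events[0] < 0 or self.events[-1] >= self.signals.shape[1]:
                raise ValueError("events must lie within the recording")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    def copy(self) -> "Recording":
        return replace(self, signals=self.signals.copy(),
                       events=self.events.copy(),
                       channel_labels=list(self.channel_labels))


@dataclass
class Montage:
    """Channel order plus the left/right homologous-pair table."""

    labels: list[str]
    homologous_pairs: list[tuple[str, str]]
    midline: list[str]

    def __post_init__(self):
        self.labels = [str(c) for c in self.labels]
        self.homologous_pairs = [(str(a), str(b))
                                 for a, b in self.homologous_pairs]
        self.midline = [str(c) for c in self.midline]
        self.validate()

    def validate(self):
        seen: dict[str, int] = {}
        for a, b in self.homologous_pairs:
            for c in (a, b):
                seen[c] = seen.get(c, 0) + 1
        for c in self.midline:
            seen[c] = seen.get(c, 0) + 1
        if set(seen) != set(self.labels) or any(v != 1 for v in seen.values()):
            raise ValueError("every montage label must appear in exactly one "
                             "homologous pair or in the midline")
        fm = self.flip_map()
        if any(fm[fm[c]] != c for c in self.labels):
            raise ValueError("flip map must be an involution")

    def flip_map(self) -> dict[str, str]:
        m = {c: c for c in self.midline}
        for a, b in self.homologous_pairs:
            m[a] = b
            m[b] = a
        return m


@dataclass(frozen=True)
class SessionLabel:
    """One session's clinical ground truth (upper-extremity FMA, 0-66)."""

    participant_id: str
    session_id: str
    fma_ue: int
    group: str

    def __post_init__(self):
        if not 0 <= int(self.fma_ue) <= 66:
            raise ValueError(f"fma_ue {self.fma_ue} outside [0, 66]")
        if self.group not in VALID_GROUPS:
            raise ValueError(f"group must be one of {VALID_GROUPS}")


# ---------------------------------------------------------------------------
# montage I/O
# ---------------------------------------------------------------------------

def load_montage(path) -> Montage:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return Montage(labels=raw["channels"],
                   homologous_pairs=[tuple(p) for p in raw["homologous_pairs"]],
                   midline=raw["midline"])


def default_montage() -> Montage:
    """The packaged 32-channel 10-20 layout."""
    ref = importlib.resources.files("eegmotor").joinpath(
        "data/montage_32.yaml")
    with importlib.resources.as_file(ref) as path:
        return load_montage(path)


# ---------------------------------------------------------------------------
# session labels
# ---------------------------------------------------------------------------

LABEL_COLUMNS = ("participant_id", "session_id", "fma_ue", "group")


def read_labels(path) -> list[SessionLabel]:
    df = pd.read_csv(path, dtype={"participant_id": str, "session_id": str})
    missing = set(LABEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"label file missing columns: {sorted(missing)}")
    return [SessionLabel(row.participant_id, row.session_id,
                         int(row.fma_ue), str(row.group))
            for row in df.itertuples()]


def write_labels(labels, path):
    pd.DataFrame([{c: getattr(l, c) for c in LABEL_COLUMNS}
                  for l in labels]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# EDF+ writing (16-bit) and reading
# ---------------------------------------------------------------------------

def _ascii(value, width) -> bytes:
    s = str(value)[:width]
    return s.encode("ascii").ljust(width)


def _annotation_records(rec: Recording, n_records: int) -> list[bytes]:
    fs = rec.sampling_rate
    onsets = rec.events / fs
    per_record: list[bytes] = []
    for r in range(n_records):
        tals = [f"+{r}\x14\x14\x00".encode("ascii")]
        in_rec = onsets[(onsets >= r) & (onsets < r + 1)]
        for t in in_rec:
            tals.append(f"+{t:.4f}\x14Response\x14\x00".encode("ascii"))
        per_record.append(b"".join(tals))
    return per_record


def write_recording_edf(rec: Recording, path):
    """Write a Recording as 16-bit EDF+C with events as annotations.

    The recording is zero-padded to a whole number of 1 s data records.
    """
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n = rec.n_samples
    n_records = int(np.ceil(n / fs))
    pad = n_records * fs - n
    if pad:
        logger.warning("padding recording with %d zero samples to fill the "
                       "last EDF record", pad)
    sig = np.pad(rec.signals, ((0, 0), (0, pad)))

    ann = _annotation_records(rec, n_records)
    ann_bytes = max(max(len(a) for a in ann), 24)
    ann_bytes += ann_bytes % 2
    ann_samples = ann_bytes // 2

    ns = rec.n_channels + 1
    header_bytes = 256 * (1 + ns)

    pmin = np.minimum(sig.min(axis=1), -1.0)
    pmax = np.maximum(sig.max(axis=1), 1.0)
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)

    recording_field = (f"Startdate 01-JAN-2020 session={rec.session_id} "
                       f"side={rec.response_side}")
    with open(path, "wb") as fh:
        fh.write(_ascii("0", 8))
        fh.write(_ascii(rec.participant_id, 80))
        fh.write(_ascii(recording_field, 80))
        fh.write(_ascii("01.01.20", 8))
        fh.write(_ascii("00.00.00", 8))
        fh.write(_ascii(header_bytes, 8))
        fh.write(_ascii("EDF+C", 44))
        fh.write(_ascii(n_records, 8))
        fh.write(_ascii(1, 8))
        fh.write(_ascii(ns, 4))

        labels = list(rec.channel_labels) + ["EDF Annotations"]
        fh.write(b"".join(_ascii(l, 16) for l in labels))
        fh.write(b"".join(_ascii("", 80) for _ in labels))
        fh.write(b"".join(_ascii("uV", 8) for _ in rec.channel_labels)
                 + _ascii("", 8))
        fh.write(b"".join(_ascii(f"{v:.7g}"[:8], 8) for v in pmin)
                 + _ascii(-1, 8))
        fh.write(b"".join(_ascii(f"{v:.7g}"[:8], 8) for v in pmax)
                 + _ascii(1, 8))
        fh.write(b"".join(_ascii(dmin, 8) for _ in labels))
        fh.write(b"".join(_ascii(dmax, 8) for _ in labels))
        fh.write(b"".join(_ascii("", 80) for _ in labels))
        fh.write(b"".join(_ascii(fs, 8) for _ in rec.channel_labels)
                 + _ascii(ann_samples, 8))
        fh.write(b"".join(_ascii("", 32) for _ in labels))

        # re-read the physical extrema exactly as an EDF reader will parse
        # them, so quantisation is consistent with the truncated header text
        pmin_r = np.array([float(f"{v:.7g}"[:8]) for v in pmin])
        pmax_r = np.array([float(f"{v:.7g}"[:8]) for v in pmax])
        scale = (dmax - dmin) / (pmax_r - pmin_r)
        for r in range(n_records):
            chunk = sig[:, r * fs:(r + 1) * fs]
            dig = np.rint((chunk - pmin_r[:, None]) * scale[:, None] + dmin)
            dig = np.clip(dig, dmin, dmax).astype("<i2")
            fh.write(dig.tobytes())
            fh.write(ann[r].ljust(ann_bytes, b"\x00"))


def _parse_edf_metadata(path):
    with open(path, "rb") as fh:
        head = fh.read(168)
    participant = head[8:88].decode("ascii", "replace").strip()
    recording = head[88:168].decode("ascii", "replace").strip()
    session, side = "unknown", "right"
    for token in recording.split():
        if token.startswith("session="):
            session = token.split("=", 1)[1]
        elif token.startswith("side="):
            side = token.split("=", 1)[1]
    return participant, session, side


def read_recording_edf(path, montage: Montage | None = None) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    signals = raw.get_data() * 1e6          # mne returns volts
    labels = list(raw.ch_names)
    onsets = np.asarray(
        [a["onset"] for a in raw.annotations
         if a["description"].strip()], dtype=float)
    events = np.unique(np.rint(onsets * fs).astype(np.int64))
    participant, session, side = _parse_edf_metadata(path)
    rec = Recording(signals=signals, sampling_rate=fs, channel_labels=labels,
                    events=events, response_side=side,
                    participant_id=participant, session_id=session)
    _check_montage(rec, montage)
    return rec


# ---------------------------------------------------------------------------
# plain array container + CSV events
# ---------------------------------------------------------------------------

def write_recording_array(rec: Recording, base):
    """Write ``<base>.npz`` (signals + metadata) and ``<base>.events.csv``."""
    base = Path(base)
    np.savez(base.with_suffix(".npz"),
             signals=rec.signals,
             sampling_rate=np.float64(rec.sampling_rate),
             channel_labels=np.array(rec.channel_labels),
             response_side=np.array(rec.response_side),
             participant_id=np.array(rec.participant_id),
             session_id=np.array(rec.session_id))
    pd.DataFrame({"sample_index": rec.events}).to_csv(
        base.parent / (base.stem + ".events.csv"), index=False)


def read_recording_array(base, montage: Montage | None = None) -> Recording:
    base = Path(base)
    with np.load(base.with_suffix(".npz")) as z:
        rec = Recording(
            signals=z["signals"],
            sampling_rate=float(z["sampling_rate"]),
            channel_labels=[str(c) for c in z["channel_labels"]],
            events=_read_events_csv(base.parent / (base.stem + ".events.csv")),
            response_side=str(z["response_side"]),
            participant_id=str(z["participant_id"]),
            session_id=str(z["session_id"]))
    _check_montage(rec, montage)
    return rec


def _read_events_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    if "sample_index" not in df.columns:
        raise ValueError("event file must have a 'sample_index' column")
    return df["sample_index"].to_numpy(dtype=np.int64)


def _check_montage(rec: Recording, montage: Montage | None):
    if montage is None:
        return
    if rec.n_channels != len(montage.labels):
        raise ValueError(
            f"recording has {rec.n_channels} channels but montage declares "
            f"{len(montage.labels)}")
    unknown = set(rec.channel_labels) - set(montage.labels)
    if unknown:
        raise ValueError(f"channels absent from montage: {sorted(unknown)}")


def read_recording(path, format="edf", montage: Montage | None = None
                   ) -> Recording:
    if format == "edf":
        return read_recording_edf(path, montage)
    if format == "array":
        return read_recording_array(path, montage)
    raise ValueError(f"unknown recording format {format!r}")


def write_recording(rec: Recording, path, format="edf"):
    if format == "edf":
        return write_recording_edf(rec, path)
    if format == "array":
        return write_recording_array(rec, path)
    raise ValueError(f"unknown recording format {format!r}")


# ---------------------------------------------------------------------------
# HDF5 feature store
# ---------------------------------------------------------------------------

INDEX_COLUMNS = ("participant_id", "session_id", "event_index", "offset_s",
                 "trial_id")


def store_features(values: np.ndarray, index: pd.DataFrame, path,
                   bin_frequencies: np.ndarray | None = None):
    """Persist trial feature tensors plus per-trial provenance losslessly."""
    values = np.asarray(values)
    if values.ndim != 4 or values.shape[1:] != FEATURE_SHAPE:
        raise ValueError(f"feature tensors must have shape {FEATURE_SHAPE}")
    if len(index) != len(values):
        raise ValueError("index length must match number of trials")
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=values,
                         maxshape=(None,) + FEATURE_SHAPE)
        if bin_frequencies is not None:
            f.attrs["bin_frequencies"] = np.asarray(bin_frequencies)
        _write_index(f, index)


def _write_index(f, index: pd.DataFrame):
    grp = f.require_group("index")
    for col in index.columns:
        if col in grp:
            del grp[col]
        data = index[col].to_numpy()
        if data.dtype == object or data.dtype.kind in "U":
            data = np.array([str(v) for v in data],
                            dtype=h5py.string_dtype())
        grp.create_dataset(col, data=data, maxshape=(None,))


def append_features(path, values: np.ndarray, index: pd.DataFrame):
    values = np.asarray(values)
    if values.ndim == 3:
        values = values[None]
    if values.shape[1:] != FEATURE_SHAPE:
        raise ValueError(
            f"appended tensors have shape {values.shape[1:]}, "
            f"expected {FEATURE_SHAPE}")
    with h5py.File(path, "a") as f:
        ds = f["features"]
        n0 = ds.shape[0]
        ds.resize(n0 + len(values), axis=0)
        ds[n0:] = values
        grp = f["index"]
        for col in index.columns:
            d = grp[col]
            d.resize(n0 + len(index), axis=0)
            new = index[col].to_numpy()
            if new.dtype == object or new.dtype.kind in "U":
                new = np.array([str(v) for v in new],
                               dtype=h5py.string_dtype())
            d[n0:] = new


def load_features(path):
    """Return ``(values, index_df, bin_frequencies)``."""
    with h5py.File(path, "r") as f:
        values = f["features"][...]
        bins = f.attrs.get("bin_frequencies")
        cols = {}
        for col in f["index"]:
            data = f["index"][col][...]
            if data.dtype.kind in ("O", "S"):
                data = np.array([v.decode() if isinstance(v, bytes) else str(v)
                                 for v in data])
            cols[col] = data
    return values, pd.DataFrame(cols), None if bins is None else np.asarray(bins)
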