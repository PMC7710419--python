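"""Core containers for continuous EEG and fixed-length epochs, plus EDF I/O.

A :class:`Recording` is a channels × samples array of scalp potentials in µV
with a sampling rate and 10-20 channel labels.  An :class:`EpochSet` holds the
non-overlapping fixed-length segments cut from a recording, together with the
artifact-screening mask and provenance (which subject / seizure / state the
epochs came from).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

#: The 16-channel subset of the international 10-20 system used throughout.
CHANNELS_1020 = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "C3", "C4",
    "P3", "P4", "O1", "O2", "T3", "T4", "T5", "T6",
)


@dataclass
class Annotation:
    """A labelled time interval, in seconds from recording start."""

    label: str
    onset_s: float
    offset_s: float


@dataclass
class Recording:
    """Continuous multichannel EEG in µV.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Scalp potentials in µV.
    fs : float
        Sampling rate in Hz.
    channel_labels : sequence of str
        Unique channel names (10-20 convention).
    annotations : list of Annotation
        Event markers, e.g. seizure onset/offset.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = CHANNELS_1020
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains NaN or inf")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy(), annotations=list(self.annotations))


@dataclass
class EpochSet:
    """Fixed-length epochs cut from one recording.

    ``epochs`` holds only the *retained* epochs (shape n_epochs × channels ×
    samples); ``retained_mask`` records, per original consecutive epoch, whether
    it survived artifact screening.  Before screening the mask is all-True.
    """

    epochs: np.ndarray
    fs: float
    epoch_length: float
    channel_labels: tuple[str, ...]
    retained_mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epochs x channels x samples)")
        n_samp = int(round(self.epoch_length * self.fs))
        if self.epochs.shape[2] != n_samp:
            raise ValueError(
                f"epoch has {self.epochs.shape[2]} samples, expected "
                f"{n_samp} = epoch_length*fs"
            )
        self.retained_mask = np.asarray(self.retained_mask, dtype=bool)
        if int(self.retained_mask.sum()) != self.epochs.shape[0]:
            raise ValueError("retained_mask count does not match stored epochs")

    @property
    def n_epochs(self) -> int:
        """Number of retained epochs."""
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]


# ---------------------------------------------------------------------------
# Annotation sidecars (JSON or CSV with onset_s / offset_s columns)
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> list[Annotation]:
    """Read seizure annotations from a JSON or CSV sidecar.

    JSON: a list of objects with keys ``label`` (optional), ``onset_s``,
    ``offset_s``.  CSV: columns ``onset_s``, ``offset_s`` and optionally
    ``label``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        import pandas as pd

        rows = pd.read_csv(path).to_dict("records")
    out = []
    for k, row in enumerate(rows):
        out.append(
            Annotation(
                label=str(row.get("label", f"seizure_{k + 1}")),
                onset_s=float(row["onset_s"]),
                offset_s=float(row["offset_s"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# EDF I/O
# ---------------------------------------------------------------------------

def read_edf(path: str | Path, annotations: str | Path | None = None) -> Recording:
    """Load an EDF file into a :class:`Recording` (requires mne).

    Channel data are returned in µV.  If ``annotations`` is given, the sidecar
    is attached to the recording.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne uses volts internally
    rec = Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
    )
    if annotations is not None:
        rec.annotations = read_annotations(annotations)
    return rec


def write_edf(recording: Recording, path: str | Path) -> None:
    """Write a recording as EDF (16-bit fixed point, physical unit µV).

    The record length is 1 s, so fs must be an integer.  Physical limits are
    taken per channel with 1% headroom; digital range is the full int16 span.
    """
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    nchan = recording.n_channels
    n_records = recording.n_samples // fs
    if n_records * fs != recording.n_samples:
        raise ValueError("EDF writer requires a whole number of 1 s records")

    data = recording.data
    phys_max = np.maximum(np.abs(data).max(axis=1) * 1.01, 1.0)
    phys_min = -phys_max
    dig_min, dig_max = -32768, 32767

    def pad(text: str, n: int) -> bytes:
        return text.encode("ascii")[:n].ljust(n)

    header = b"".join(
        [
            pad("0", 8),                       # version
            pad("X X X X", 80),                # patient id (anonymous)
            pad("Startdate X X X X", 80),      # recording id
            pad("01.01.00", 8), pad("00.00.00", 8),
            pad(str(256 + nchan * 256), 8),    # header bytes
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),                       # record duration, s
            pad(str(nchan), 4),
        ]
    )
    header += b"".join(pad(lbl, 16) for lbl in recording.channel_labels)
    header += b"".join(pad("EEG", 80) for _ in range(nchan))
    header += b"".join(pad("uV", 8) for _ in range(nchan))
    header += b"".join(pad(f"{lo:.3f}"[:8], 8) for lo in phys_min)
    header += b"".join(pad(f"{hi:.3f}"[:8], 8) for hi in phys_max)
    header += b"".join(pad(str(dig_min), 8) for _ in range(nchan))
    header += b"".join(pad(str(dig_max), 8) for _ in range(nchan))
    header += b"".join(pad("", 80) for _ in range(nchan))
    header += b"".join(pad(str(fs), 8) for _ in range(nchan))
    header += b"".join(pad("", 32) for _ in range(nchan))

    # physical -> digital, per channel
    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((data - phys_min[:, None]) * gain[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for rec_idx in range(n_records):
            block = digital[:, rec_idx * fs : (rec_idx + 1) * fs]
            fh.write(block.tobytes())


def write_annotations(annotations: list[Annotation], path: str | Path) -> None:
    """Write annotations as a JSON sidecar."""
    rows = [
        {"label": a.label, "onset_s": a.onset_s, "offset_s": a.offset_s}
        for a in annotations
    ]
    Path(path).write_text(json.dumps(rows, indent=2, sort_keys=True) + "\n")
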