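"""Preprocessing chain: average re-reference → 1–45 Hz band-pass →
6 s segmentation → ±80 µV artifact rejection.

The chain order is fixed; :func:`preprocess` enforces it.  The band-pass is a
4th-order Butterworth applied forward-backward (zero phase), standard EEG
practice that preserves epoch alignment.  Rejection is strict: an epoch is
dropped iff any sample on any channel satisfies |x| > threshold, so a sample
at exactly the threshold is retained (configurable via ``inclusive``).
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
from scipy import signal

from .recording import EpochSet, Recording

DEFAULT_BAND = (1.0, 45.0)
DEFAULT_EPOCH_S = 6.0
DEFAULT_REJECT_UV = 80.0


def rereference_average(recording: Recording) -> Recording:
    """Re-reference to the common average: subtract the across-channel mean
    at every sample, so the montage mean is zero everywhere."""
    if recording.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = recording.data - recording.data.mean(axis=0, keepdims=True)
    return replace(recording, data=data, annotations=list(recording.annotations))


def bandpass(
    recording: Recording,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = 4,
) -> Recording:
    """Zero-phase Butterworth band-pass (forward-backward filtering)."""
    nyq = recording.fs / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(
            f"band edges must satisfy 0 < low < high < fs/2; got ({low}, {high}) at fs={recording.fs}"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=recording.fs, output="sos")
    data = signal.sosfiltfilt(sos, recording.data, axis=-1)
    return replace(recording, data=data, annotations=list(recording.annotations))


def segment(
    recording: Recording,
    epoch_length: float = DEFAULT_EPOCH_S,
    provenance: dict | None = None,
) -> EpochSet:
    """Cut into consecutive non-overlapping epochs; the trailing remainder
    shorter than one epoch is discarded."""
    n_samp = int(round(epoch_length * recording.fs))
    n_epochs = recording.n_samples // n_samp
    if n_epochs < 1:
        raise ValueError(
            f"recording of {recording.duration:.3f} s is shorter than one "
            f"{epoch_length} s epoch"
        )
    used = recording.data[:, : n_epochs * n_samp]
    epochs = used.reshape(recording.n_channels, n_epochs, n_samp).transpose(1, 0, 2)
    return EpochSet(
        epochs=epochs.copy(),
        fs=recording.fs,
        epoch_length=epoch_length,
        channel_labels=recording.channel_labels,
        retained_mask=np.ones(n_epochs, dtype=bool),
        provenance=dict(provenance or {}),
    )


def reject_artifacts(
    epochs: EpochSet,
    threshold: float = DEFAULT_REJECT_UV,
    inclusive: bool = False,
) -> EpochSet:
    """Drop epochs containing high-amplitude artifacts.

    An epoch is rejected iff any sample on any channel exceeds the threshold
    in absolute value (strictly, unless ``inclusive``).  The returned
    ``retained_mask`` is indexed over the epochs given, composed with any
    previous mask.
    """
    if threshold <= 0:
        raise ValueError("rejection threshold must be positive")
    peak = np.abs(epochs.epochs).max(axis=(1, 2))
    keep = peak <= threshold if not inclusive else peak < threshold
    if not keep.any():
        raise ValueError(
            f"all {epochs.n_epochs} epochs exceed ±{threshold} µV; "
            "downstream estimation needs at least 2 epochs"
        )
    # compose with the existing mask over original epochs
    mask = epochs.retained_mask.copy()
    mask[np.flatnonzero(epochs.retained_mask)] = keep
    return EpochSet(
        epochs=epochs.epochs[keep],
        fs=epochs.fs,
        epoch_length=epochs.epoch_length,
        channel_labels=epochs.channel_labels,
        retained_mask=mask,
        provenance=dict(epochs.provenance),
    )


def preprocess(
    recording: Recording,
    band: tuple[float, float] = DEFAULT_BAND,
    epoch_length: float = DEFAULT_EPOCH_S,
    reject_uv: float = DEFAULT_REJECT_UV,
    reject_inclusive: bool = False,
    provenance: dict | None = None,
) -> EpochSet:
    """Run the full chain in the fixed order: re-reference, band-pass,
    segment, reject."""
    rec = rereference_average(recording)
    rec = bandpass(rec, *band)
    epochs = segment(rec, epoch_length, provenance=provenance)
    n_total = epochs.n_epochs
    out = reject_artifacts(epochs, reject_uv, inclusive=reject_inclusive)
    n_dropped = n_total - out.n_epochs
    if n_dropped:
        warnings.warn(
            f"artifact rejection dropped {n_dropped}/{n_total} epochs",
            stacklevel=2,
        )
    return out
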