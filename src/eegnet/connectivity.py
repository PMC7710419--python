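"""Magnitude-squared coherence networks.

Coherence between channels x and y at frequency f is

    C(f) = |S_xy(f)|^2 / (S_xx(f) S_yy(f))  in [0, 1],

with cross- and auto-spectra estimated by Welch averaging of windowed FFT
segments, pooled across windows within epochs and across retained epochs.
Band-level connectivity is the mean of C(f) over the frequency bins inside
the band; matrices are symmetric with the diagonal set to 0 by convention so
graph metrics never traverse self-loops.

With L independent averaging segments the coherence of unrelated signals is
biased upward with expectation ≈ 1/L, so a single segment (identically 1) is
rejected as degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .recording import EpochSet
from .spectral import BandDefinition, DEFAULT_OVERLAP, DEFAULT_WINDOW_S


@dataclass
class ConnectivityMatrix:
    """Symmetric per-band coherence matrix over channels, zero diagonal."""

    C: np.ndarray
    band: BandDefinition
    n_epochs_used: int
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if C.min() < -1e-12 or C.max() > 1 + 1e-12:
            raise ValueError("coherence entries must lie in [0, 1]")
        np.fill_diagonal(C, 0.0)
        self.C = np.clip(C, 0.0, 1.0)


def _segment_ffts(
    epochs: EpochSet, window_s: float, overlap: float
) -> tuple[np.ndarray, np.ndarray, int]:
    """Hann-windowed FFTs of every Welch segment.

    Returns (freqs, Z, windows_per_epoch) with Z of shape
    (n_epochs, n_windows, n_channels, n_freqs).
    """
    nperseg = int(round(window_s * epochs.fs))
    step = nperseg - int(round(nperseg * overlap))
    n_samp = epochs.epochs.shape[-1]
    if nperseg > n_samp:
        raise ValueError("Welch window longer than the epoch")
    starts = np.arange(0, n_samp - nperseg + 1, step)
    win = _sig.get_window("hann", nperseg)
    # (E, C, W, nperseg) -> windowed -> rfft
    segs = np.stack([epochs.epochs[:, :, s : s + nperseg] for s in starts], axis=2)
    segs = segs - segs.mean(axis=-1, keepdims=True)  # per-segment detrend
    Z = np.fft.rfft(segs * win, axis=-1)
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / epochs.fs)
    return freqs, Z.transpose(0, 2, 1, 3), len(starts)


def coherence_spectrum(
    epochs: EpochSet,
    ch_i: int,
    ch_j: int,
    window_s: float = DEFAULT_WINDOW_S,
    overlap: float = DEFAULT_OVERLAP,
) -> tuple[np.ndarray, np.ndarray]:
    """Coherence between two channels at every frequency bin.

    Returns (freqs, coherence).  Needs at least two averaging segments in
    total — with a single segment the estimator is identically 1 regardless
    of the data (the coherence-bias degeneracy).
    """
    freqs, Z, n_win = _segment_ffts(epochs, window_s, overlap)
    n_segments = Z.shape[0] * Z.shape[1]
    if n_segments < 2:
        raise ValueError(
            "coherence needs >= 2 averaging segments; a single segment yields "
            "the degenerate estimate C(f) = 1"
        )
    zi = Z[:, :, ch_i, :].reshape(n_segments, -1)
    zj = Z[:, :, ch_j, :].reshape(n_segments, -1)
    s_ij = (zi * np.conj(zj)).mean(axis=0)
    s_ii = (np.abs(zi) ** 2).mean(axis=0)
    s_jj = (np.abs(zj) ** 2).mean(axis=0)
    denom = s_ii * s_jj
    coh = np.zeros_like(s_ii)
    ok = denom > 0
    coh[ok] = np.abs(s_ij[ok]) ** 2 / denom[ok]
    return freqs, np.clip(coh, 0.0, 1.0)


def _band_mask(freqs: np.ndarray, band: BandDefinition) -> np.ndarray:
    mask = (freqs >= band.low - 1e-9) & (freqs < band.high - 1e-9)
    if not mask.any():
        raise ValueError(
            f"band {band.name} ({band.low}-{band.high} Hz) contains no bins on the grid"
        )
    return mask


def _matrices_from_ffts(Zb: np.ndarray) -> np.ndarray:
    """Coherence matrix from segment FFTs restricted to band bins.

    Zb: (n_segments, n_channels, n_bins) -> (n_channels, n_channels) band-mean
    coherence.
    """
    s_xy = np.einsum("scf,sdf->cdf", Zb, np.conj(Zb)) / Zb.shape[0]
    auto = np.real(np.einsum("ccf->cf", s_xy))
    denom = auto[:, None, :] * auto[None, :, :]
    msc = np.zeros_like(denom)
    ok = denom > 0
    msc[ok] = np.abs(s_xy[ok]) ** 2 / denom[ok]
    C = np.clip(msc, 0.0, 1.0).mean(axis=-1)
    C = 0.5 * (C + C.T)  # exact symmetry against rounding
    np.fill_diagonal(C, 0.0)
    return C


def coherence_matrix(
    epochs: EpochSet,
    band: BandDefinition,
    window_s: float = DEFAULT_WINDOW_S,
    overlap: float = DEFAULT_OVERLAP,
) -> ConnectivityMatrix:
    """Band-mean coherence matrix pooled over all retained epochs."""
    freqs, Z, _ = _segment_ffts(epochs, window_s, overlap)
    n_segments = Z.shape[0] * Z.shape[1]
    if n_segments < 2:
        raise ValueError("coherence needs >= 2 averaging segments (bias degeneracy)")
    mask = _band_mask(freqs, band)
    Zb = Z[..., mask].reshape(n_segments, epochs.n_channels, -1)
    C = _matrices_from_ffts(Zb)
    return ConnectivityMatrix(
        C=C, band=band, n_epochs_used=epochs.n_epochs, channel_labels=epochs.channel_labels
    )


def per_epoch_coherence(
    epochs: EpochSet,
    band: BandDefinition,
    window_s: float = DEFAULT_WINDOW_S,
    overlap: float = DEFAULT_OVERLAP,
) -> np.ndarray:
    """One band-coherence matrix per epoch, shape (n_epochs, C, C).

    Each epoch's matrix averages only that epoch's windows; these are the
    sampling units for edge-wise paired statistics (the small-sample bias is
    identical across the compared states, so paired differences are unbiased
    under the null).
    """
    freqs, Z, n_win = _segment_ffts(epochs, window_s, overlap)
    if n_win < 2:
        raise ValueError("per-epoch coherence needs >= 2 windows per epoch")
    mask = _band_mask(freqs, band)
    Zb = Z[..., mask]
    out = np.empty((Zb.shape[0], epochs.n_channels, epochs.n_channels))
    for e in range(Zb.shape[0]):
        out[e] = _matrices_from_ffts(Zb[e])
    return out
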