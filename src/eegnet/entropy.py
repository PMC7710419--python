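"""Fuzzy entropy: a sample-entropy variant with a smooth similarity kernel.

For a series u(1..N), form the N-m templates of length m with their own mean
removed, X_i = [u(i), ..., u(i+m-1)] - mean.  With Chebyshev distance d_ij
between templates, each pair gets the fuzzy membership

    mu_ij = exp( -(d_ij / r_abs)^n_fuzz ),      r_abs = r * SD(u),

and phi^m is the mean membership over all pairs i != j.  Repeating at length
m+1 (same N-m templates), FuzzyEn = ln phi^m - ln phi^(m+1).

Baseline removal makes the measure invariant to additive offsets; scaling the
tolerance with the signal SD makes it invariant to positive rescaling.  A
noisier (less predictable) signal loses more similarity when templates grow,
so its entropy is higher.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .recording import EpochSet
from .spectral import BandDefinition


@dataclass(frozen=True)
class FuzzyEnParams:
    """m: embedding dimension; r: tolerance as a fraction of the signal SD;
    n_fuzz: exponent of the similarity kernel.  Defaults (2, 0.2, 2) are the
    dominant convention in the EEG fuzzy-entropy literature."""

    m: int = 2
    r: float = 0.2
    n_fuzz: float = 2.0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r <= 0:
            raise ValueError("tolerance r must be positive")
        if self.n_fuzz <= 0:
            raise ValueError("fuzzy exponent must be positive")


@dataclass
class EntropyResult:
    """Per-channel fuzzy entropy (nats), averaged over retained epochs."""

    values: np.ndarray
    params: FuzzyEnParams
    band: BandDefinition | None = None


def _phi(templates: np.ndarray, r_abs: float, n_fuzz: float) -> float:
    # mean pairwise membership over i != j; pdist enumerates each unordered
    # pair once, which equals the ordered mean by symmetry
    if templates.shape[1] == 1:
        d = pdist(templates, metric="euclidean")  # 1-D Chebyshev == |diff|
    else:
        d = pdist(templates, metric="chebyshev")
    return float(np.mean(np.exp(-((d / r_abs) ** n_fuzz))))


def _templates(x: np.ndarray, m: int, count: int) -> np.ndarray:
    idx = np.arange(count)[:, None] + np.arange(m)[None, :]
    t = x[idx]
    return t - t.mean(axis=1, keepdims=True)


def fuzzy_entropy(x: np.ndarray, params: FuzzyEnParams = FuzzyEnParams()) -> float:
    """Fuzzy entropy of a single-channel sample vector, in nats.

    A constant signal has zero complexity by convention (returned with a
    warning rather than raising, since flat channels do occur in practice).
    """
    x = np.asarray(x, dtype=float).ravel()
    m = params.m
    if x.size <= m + 1:
        raise ValueError(f"signal of length {x.size} too short for m={m}")
    sd = float(x.std())
    if sd == 0.0:
        warnings.warn("constant signal: fuzzy entropy defined as 0", stacklevel=2)
        return 0.0
    r_abs = params.r * sd
    # both template sets use the same N-m starting points, so phi^m and
    # phi^(m+1) are means over identically indexed pair sets
    count = x.size - m
    phi_m = _phi(_templates(x, m, count), r_abs, params.n_fuzz)
    phi_m1 = _phi(_templates(x, m + 1, count), r_abs, params.n_fuzz)
    return float(np.log(phi_m) - np.log(phi_m1))


def epoch_entropy(
    epochs: EpochSet,
    params: FuzzyEnParams = FuzzyEnParams(),
    band: BandDefinition | None = None,
) -> EntropyResult:
    """Per-channel fuzzy entropy, averaged over retained epochs.

    If a band is given, each epoch is zero-phase band-pass filtered to it
    first (the band-limited complexity reading); ``band=None`` computes
    broadband entropy of the epochs as given.
    """
    if epochs.n_epochs < 1:
        raise ValueError("epoch_entropy needs at least one retained epoch")
    data = epochs.epochs
    if band is not None:
        from scipy import signal as _sig

        sos = _sig.butter(4, [band.low, band.high], btype="bandpass", fs=epochs.fs, output="sos")
        data = _sig.sosfiltfilt(sos, data, axis=-1)
    values = np.empty(epochs.n_channels)
    for ch in range(epochs.n_channels):
        values[ch] = np.mean([fuzzy_entropy(data[e, ch], params) for e in range(data.shape[0])])
    return EntropyResult(values=values, params=params, band=band)
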