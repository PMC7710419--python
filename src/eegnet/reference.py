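"""Naive reference implementations for validation.

These deliberately literal, loop-based routines re-state the definitions used
elsewhere in the package (fuzzy entropy, shortest paths, weighted clustering,
step-up FDR) without sharing any code with the optimised implementations.
They exist solely as independent cross-checks and are O(N^2)-O(N^3); do not
use them on production-sized inputs.
"""

from __future__ import annotations

import math

import numpy as np


def fuzzy_entropy_naive(x, m: int = 2, r: float = 0.2, n_fuzz: float = 2.0) -> float:
    """Literal double-loop fuzzy entropy (nats).

    Templates are the N - m windows of length m and m + 1 with their own mean
    removed; similarity is exp(-(d/r_abs)^n_fuzz) on Chebyshev distances with
    r_abs = r * SD(x); phi is the mean over pairs i != j.
    """
    x = [float(v) for v in np.asarray(x).ravel()]
    N = len(x)
    mean = sum(x) / N
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / N)
    if sd == 0.0:
        return 0.0
    r_abs = r * sd

    def phi(mm: int) -> float:
        count = N - m  # same starting points for both dimensions
        templ = []
        for i in range(count):
            w = x[i : i + mm]
            mu = sum(w) / mm
            templ.append([v - mu for v in w])
        total = 0.0
        npairs = 0
        for i in range(count):
            for j in range(count):
                if i == j:
                    continue
                d = max(abs(a - b) for a, b in zip(templ[i], templ[j]))
                total += math.exp(-((d / r_abs) ** n_fuzz))
                npairs += 1
        return total / npairs

    return math.log(phi(m)) - math.log(phi(m + 1))


def floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    """Textbook Floyd-Warshall on a dense length matrix (0 = no edge,
    diagonal ignored)."""
    n = lengths.shape[0]
    d = np.full((n, n), np.inf)
    for i in range(n):
        d[i, i] = 0.0
        for j in range(n):
            if i != j and lengths[i, j] > 0:
                d[i, j] = lengths[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def cpl_naive(W: np.ndarray, length: str = "inverse") -> float:
    """CPL from the Floyd-Warshall distances of a weight matrix."""
    n = W.shape[0]
    L = np.zeros_like(np.asarray(W, dtype=float))
    for i in range(n):
        for j in range(n):
            if i != j and W[i, j] > 0:
                L[i, j] = 1.0 / W[i, j] if length == "inverse" else 1.0 - W[i, j]
    d = floyd_warshall(L)
    total, cnt = 0.0, 0
    for i in range(n):
        for j in range(n):
            if i != j:
                total += d[i, j]
                cnt += 1
    return total / cnt


def clustering_naive(W: np.ndarray, variant: str = "printed") -> float:
    """Literal triple-loop weighted clustering coefficient."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    acc = 0.0
    for i in range(n):
        tri = 0.0
        for j in range(n):
            for h in range(n):
                tri += (W[i, j] * W[i, h] * W[j, h]) ** (1.0 / 3.0)
        if variant == "printed":
            s = sum(W[i, j] for j in range(n))
            denom = s * (s - 1.0)
        else:
            k = sum(1 for j in range(n) if W[i, j] > 0)
            denom = k * (k - 1.0)
        acc += tri / denom if denom > 0 else 0.0
    return acc / n


def bh_adjust_naive(pvals) -> np.ndarray:
    """Step-up Benjamini-Hochberg by direct evaluation of
    adjusted_(i) = min_{j >= i} p_(j) * m / j."""
    p = list(map(float, pvals))
    m = len(p)
    order = sorted(range(m), key=lambda k: p[k])
    adj_sorted = [0.0] * m
    for rank_i in range(m):
        candidates = [p[order[j]] * m / (j + 1) for j in range(rank_i, m)]
        adj_sorted[rank_i] = min(1.0, min(candidates))
    out = [0.0] * m
    for rank_i, idx in enumerate(order):
        out[idx] = adj_sorted[rank_i]
    return np.array(out)


def coherence_naive(x: np.ndarray, y: np.ndarray, fs: float, nperseg: int, noverlap: int):
    """Direct FFT cross-spectrum accumulation for two 1-D signals.

    Hann-windowed, mean-removed segments; returns (freqs, coherence).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    step = nperseg - noverlap
    win = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(nperseg) / nperseg)
    sxx = syy = sxy = 0.0
    count = 0
    for start in range(0, x.size - nperseg + 1, step):
        xs = x[start : start + nperseg]
        ys = y[start : start + nperseg]
        X = np.fft.rfft((xs - xs.mean()) * win)
        Y = np.fft.rfft((ys - ys.mean()) * win)
        sxx = sxx + np.abs(X) ** 2
        syy = syy + np.abs(Y) ** 2
        sxy = sxy + X * np.conj(Y)
        count += 1
    if count < 2:
        raise ValueError("need >= 2 segments")
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    coh = np.abs(sxy / count) ** 2 / ((sxx / count) * (syy / count))
    return freqs, coh
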