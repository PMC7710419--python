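"""Weighted graph metrics of coherence networks.

Characteristic path length (CPL) is the mean shortest weighted path length
over ordered node pairs,

    CPL = (1/n) sum_i sum_{j != i} d_ij / (n - 1),

where edge lengths are the reciprocal of the coherence weights (d = 1/w, the
standard convention for similarity-weighted networks; strong synchrony =
short path).  Lower CPL indicates stronger global integration.

The clustering coefficient is computed in two variants that differ in the
per-node denominator:

* ``printed`` — strength-based:  CC_i = T_i / [ s_i (s_i - 1) ] with node
  strength s_i = sum_j w_ij and triangle intensity
  T_i = sum_{j,h} (w_ij w_ih w_jh)^(1/3);
* ``standard`` — degree-based (the conventional weighted form):
  CC_i = T_i / [ k_i (k_i - 1) ] with k_i the count of nonzero edges at i.

The two coincide on binary graphs (e.g. a complete graph of unit weights has
CC = 1 under both) but differ on general weighted graphs; the strength form
is not invariant to uniform weight rescaling, so both are always reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .connectivity import ConnectivityMatrix
from .spectral import BandDefinition


@dataclass
class NetworkMetrics:
    """CPL and CC of one band's coherence network."""

    cpl: float
    cc: float
    band: BandDefinition | None
    variant: str = "printed"


def _as_weight_matrix(C) -> np.ndarray:
    W = C.C if isinstance(C, ConnectivityMatrix) else np.asarray(C, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    if np.any(W < 0):
        raise ValueError("weights must be nonnegative")
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    return W


def shortest_path_lengths(C, length: str = "inverse") -> np.ndarray:
    """All-pairs shortest weighted path lengths d_ij.

    ``length`` maps weights to edge lengths: "inverse" (1/w) or
    "one_minus" (1 - w).  Absent edges (w = 0) carry no length.
    """
    W = _as_weight_matrix(C)
    with np.errstate(divide="ignore"):
        if length == "inverse":
            L = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), 0.0)
        elif length == "one_minus":
            L = np.where(W > 0, 1.0 - W, 0.0)
        else:
            raise ValueError("length must be 'inverse' or 'one_minus'")
    # csgraph treats explicit zeros as absent edges in dense input
    return shortest_path(L, method="D", directed=False)


def characteristic_path_length(
    C, length: str = "inverse", on_disconnected: str = "error"
) -> float:
    """Mean shortest weighted path length over ordered node pairs.

    A disconnected graph has infinite path lengths; by default this raises.
    ``on_disconnected="efficiency"`` instead returns the harmonic mean of the
    finite-path reciprocal lengths (global-efficiency reading), reported as
    such by the caller.
    """
    d = shortest_path_lengths(C, length=length)
    n = d.shape[0]
    if n < 2:
        raise ValueError("CPL needs at least 2 nodes")
    off = ~np.eye(n, dtype=bool)
    vals = d[off]
    if np.isinf(vals).any():
        if on_disconnected == "error":
            raise ValueError(
                "graph is disconnected (infinite path lengths); pass "
                "on_disconnected='efficiency' for the harmonic-mean reading"
            )
        with np.errstate(divide="ignore"):
            inv = np.where(vals > 0, 1.0 / vals, np.inf)
        eff = inv[np.isfinite(inv)].sum() / vals.size if vals.size else 0.0
        return float(1.0 / eff) if eff > 0 else float("inf")
    return float(vals.mean())


def clustering_coefficient(C, variant: str = "printed") -> float:
    """Mean weighted clustering coefficient (see module docstring).

    Under the ``printed`` (strength-denominator) variant a node with strength
    <= 1 would have a nonpositive denominator; its term is set to 0 with a
    warning.
    """
    W = _as_weight_matrix(C)
    n = W.shape[0]
    if n < 3:
        raise ValueError("clustering needs at least 3 nodes")
    W13 = np.cbrt(W)
    # T_i = (W^(1/3))^3 diagonal: sums (w_ij w_jh w_hi)^(1/3) over ordered (j, h)
    T = np.diag(W13 @ W13 @ W13)
    terms = np.zeros(n)
    if variant == "printed":
        s = W.sum(axis=1)
        denom = s * (s - 1.0)
        bad = (denom <= 0) & (T > 0)
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} node(s) with strength <= 1 under the "
                "strength-denominator clustering variant; their terms are set to 0",
                stacklevel=2,
            )
        ok = denom > 0
        terms[ok] = T[ok] / denom[ok]
    elif variant == "standard":
        k = (W > 0).sum(axis=1)
        denom = k * (k - 1.0)
        ok = denom > 0
        terms[ok] = T[ok] / denom[ok]
    else:
        raise ValueError("variant must be 'printed' or 'standard'")
    return float(terms.mean())


def network_metrics(
    C,
    band: BandDefinition | None = None,
    variant: str = "printed",
    length: str = "inverse",
    on_disconnected: str = "error",
) -> NetworkMetrics:
    """CPL and CC of one connectivity matrix."""
    return NetworkMetrics(
        cpl=characteristic_path_length(C, length=length, on_disconnected=on_disconnected),
        cc=clustering_coefficient(C, variant=variant),
        band=band,
        variant=variant,
    )


def band_metrics(
    matrices: dict | list,
    variant: str = "printed",
    length: str = "inverse",
) -> list[NetworkMetrics]:
    """Metrics for a collection of per-band connectivity matrices.

    Accepts a dict band-name -> ConnectivityMatrix or a list of
    ConnectivityMatrix; returns one NetworkMetrics per band, in order.
    """
    items = matrices.values() if isinstance(matrices, dict) else matrices
    out = []
    for cm in items:
        band = cm.band if isinstance(cm, ConnectivityMatrix) else None
        out.append(network_metrics(cm, band=band, variant=variant, length=length))
    return out


def proportional_threshold(C, density: float) -> np.ndarray:
    """Keep the strongest ``density`` fraction of edges (sensitivity analysis
    only; the headline analysis uses the full weighted matrix)."""
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    W = _as_weight_matrix(C)
    n = W.shape[0]
    iu = np.triu_indices(n, k=1)
    w = W[iu]
    keep = max(1, int(round(density * w.size)))
    cut = np.sort(w)[::-1][keep - 1]
    out = np.where(W >= cut, W, 0.0)
    np.fill_diagonal(out, 0.0)
    return out
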