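"""Paired pre/post statistics with FDR control, and the seizure-number trend.

Channel- and edge-wise contrasts use the classical paired t-test on matched
sampling units (epoch index within a pre/post pair, or subject), with
Benjamini–Hochberg step-up adjustment across the tested features where FDR
control is requested.  The relation between a network metric and consecutive
seizure segments (1-pre, 1-post, 2-pre, ...) is summarised by the Pearson
correlation of the metric against segment rank.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

from .connectivity import per_epoch_coherence
from .recording import EpochSet
from .spectral import BandDefinition


@dataclass
class TrendResult:
    """Pearson correlation of a network metric against segment order."""

    metric: str
    band: str
    r: float
    p: float
    n_points: int


def paired_ttest(pre: np.ndarray, post: np.ndarray) -> tuple[float, float]:
    """Classical paired t-test on post - pre differences.

    Returns (t, two-sided p) with n - 1 degrees of freedom.  Identical
    samples give t = 0, p = 1; zero-variance *nonzero* differences have no
    defined t and raise.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    if pre.size < 3:
        raise ValueError("paired t-test needs at least 3 pairs")
    diff = post - pre
    if np.all(diff == diff[0]):
        if diff[0] == 0.0:
            return 0.0, 1.0
        raise ValueError("differences have zero variance; t statistic undefined")
    res = _st.ttest_rel(post, pre)
    return float(res.statistic), float(res.pvalue)


def fdr_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Monotone in the input order statistics: adjusted_(i) = min_{j >= i}
    p_(j) * m / j, capped at 1.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("fdr_adjust needs at least one p-value")
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def _results_frame(
    feature_ids: list, tvals: np.ndarray, pvals: np.ndarray, diffs: np.ndarray,
    alpha: float, use_fdr: bool,
) -> pd.DataFrame:
    p_adj = fdr_adjust(pvals)
    decided = p_adj if use_fdr else pvals
    return pd.DataFrame(
        {
            "feature_id": feature_ids,
            "t": tvals,
            "p": pvals,
            "p_adj": p_adj,
            "significant": decided < alpha,
            "direction": np.sign(diffs).astype(int),
        }
    )


def channel_tests(
    pre_values: np.ndarray,
    post_values: np.ndarray,
    channel_labels: tuple[str, ...],
    alpha: float = 0.05,
    use_fdr: bool = True,
) -> pd.DataFrame:
    """Per-channel paired tests on epoch-matched feature values.

    ``pre_values``/``post_values``: (n_units, n_channels) arrays of a scalar
    feature (e.g. log10 delta power, or fuzzy entropy) per sampling unit per
    channel; units are truncated to the shorter state.  Direction is the sign
    of mean(post - pre).
    """
    pre_values = np.asarray(pre_values, dtype=float)
    post_values = np.asarray(post_values, dtype=float)
    n = min(pre_values.shape[0], post_values.shape[0])
    pre_values, post_values = pre_values[:n], post_values[:n]
    tvals, pvals, diffs = [], [], []
    for ch in range(pre_values.shape[1]):
        t, p = paired_ttest(pre_values[:, ch], post_values[:, ch])
        tvals.append(t)
        pvals.append(p)
        diffs.append(float(np.mean(post_values[:, ch] - pre_values[:, ch])))
    return _results_frame(
        list(channel_labels), np.array(tvals), np.array(pvals), np.array(diffs), alpha, use_fdr
    )


def edge_tests(
    pre_epochs: EpochSet,
    post_epochs: EpochSet,
    band: BandDefinition,
    alpha: float = 0.05,
    use_fdr: bool = False,
    window_s: float = 2.0,
    overlap: float = 0.5,
) -> pd.DataFrame:
    """Edge-wise paired tests on per-epoch band coherence.

    One test per channel pair (C(16,2) = 120 edges for 16 channels), paired
    by epoch index after truncation to the shorter state.  The default
    decision uses raw p < alpha; FDR-adjusted p-values are always co-reported
    in ``p_adj``.
    """
    pre_mats = per_epoch_coherence(pre_epochs, band, window_s, overlap)
    post_mats = per_epoch_coherence(post_epochs, band, window_s, overlap)
    n = min(len(pre_mats), len(post_mats))
    if n < 3:
        raise ValueError("edge tests need at least 3 paired epochs")
    labels = pre_epochs.channel_labels
    ids, tvals, pvals, diffs = [], [], [], []
    for i, j in combinations(range(pre_epochs.n_channels), 2):
        t, p = paired_ttest(pre_mats[:n, i, j], post_mats[:n, i, j])
        ids.append(f"{labels[i]}-{labels[j]}")
        tvals.append(t)
        pvals.append(p)
        diffs.append(float(np.mean(post_mats[:n, i, j] - pre_mats[:n, i, j])))
    return _results_frame(ids, np.array(tvals), np.array(pvals), np.array(diffs), alpha, use_fdr)


def seizure_trend(
    values: np.ndarray,
    metric: str = "cpl",
    band: str = "delta",
) -> TrendResult:
    """Pearson correlation of a metric series against segment rank 1..len.

    ``values`` must be ordered 1-pre, 1-post, 2-pre, 2-post, ...; a constant
    series has no defined correlation and raises.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("trend needs at least 3 segments in temporal order")
    if np.all(values == values[0]):
        raise ValueError("metric series is constant; correlation undefined")
    rank = np.arange(1, values.size + 1, dtype=float)
    r, p = _st.pearsonr(values, rank)
    return TrendResult(metric=metric, band=band, r=float(r), p=float(p), n_points=values.size)
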