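"""Synthetic 16-channel scalp EEG with planted ground truth.

Every channel is a sum of five narrowband oscillatory components (filtered
white noise, one per analysis band) plus broadband sensor noise.  Pairwise
synchrony is planted by *shared-source mixing*: within a band, a coupled
channel pair (i, j) receives a common narrowband source alongside each
channel's private source,

    x_i(band) = sigma_i * [ sqrt(1 - sum_j g_ij) * u_i + sum_j sqrt(g_ij) * v_ij ]

with u_i, v_ij independent unit-variance narrowband processes.  Because all
band sources share one spectral shape P(f), the magnitude-squared coherence
at the band's peak frequency f* is, in closed form,

    C(f*) = g_ij^2 / [ (1 + N_i/(sigma_i^2 P(f*))) (1 + N_j/(sigma_j^2 P(f*))) ]

where N is the broadband-noise PSD at f*.  Inverting for the requested
coupling kappa gives the mixing fraction

    g_ij = sqrt( kappa * (1 + N_i/(sigma_i^2 P*)) * (1 + N_j/(sigma_j^2 P*)) ),

so the analytic coherence at band centre equals kappa exactly.  A requested
coupling is *infeasible* when g_ij > 1 or when a channel's mixing fractions
sum past 1 (no private-source variance left); this is reported with the
offending pair.

Pre/post-seizure contrasts are planted through :class:`PrePostEffect`:
a multiplicative post/pre delta-variance factor, a change in the broadband
noise-to-oscillation ratio (fuzzy entropy of noisier signals is higher, so
this is a monotone complexity handle), additive per-edge coupling shifts, and
a per-seizure-index trend that accumulates those shifts across consecutive
seizures (segment order 1-pre, 1-post, 2-pre, ... gets shift scales
t*(k-1), t*(k-1)+1, t*k, ... — monotone for t >= 0 edge damage).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .recording import CHANNELS_1020, Recording
from .spectral import BandDefinition, DEFAULT_BANDS

#: Per-channel band variances in µV² chosen to mimic resting scalp EEG:
#: delta-dominant spectrum, visible alpha, modest beta/gamma; total SD ≈ 7 µV.
DEFAULT_BAND_POWERS = {
    "delta": 20.0,
    "theta": 8.0,
    "alpha": 15.0,
    "beta": 5.0,
    "low_gamma": 2.0,
}


@dataclass
class PrePostEffect:
    """Plantable pre→post seizure contrasts.

    delta_power_ratio : float or per-channel array
        Multiplicative post/pre delta-band variance factor (> 0).
    entropy_shift : float or per-channel array
        Relative change of the broadband noise amplitude post vs pre
        (post noise_sd = (1 + entropy_shift) * noise_sd); negative values
        lower the noise-to-oscillation ratio and hence fuzzy entropy.
    edge_shifts : dict (i, j) -> float
        Additive coupling change post vs pre on the named channel pairs
        (integer indices or channel labels), applied in ``edge_shift_band``.
    seizure_trend : float
        Per-seizure accumulation of ``edge_shifts``: segment k-pre carries
        shift scale trend*(k-1), segment k-post carries trend*(k-1) + 1.
    """

    delta_power_ratio: float | np.ndarray = 1.0
    entropy_shift: float | np.ndarray = 0.0
    edge_shifts: dict = field(default_factory=dict)
    edge_shift_band: str = "delta"
    seizure_trend: float = 0.0


@dataclass
class SyntheticConfig:
    """Generator settings; defaults emulate the 16-channel, 256 Hz, 10 min
    peri-ictal recording regime."""

    n_channels: int = 16
    fs: float = 256.0
    duration: float = 600.0
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    band_powers: dict = field(default_factory=lambda: dict(DEFAULT_BAND_POWERS))
    coupling: dict | np.ndarray | None = None
    noise_sd: float = 2.0
    noise_color: str = "white"  # "white" or "pink" (1/f above 1 Hz)
    artifact_rate: float = 0.0
    artifact_amplitude: float = 200.0
    effect: PrePostEffect = field(default_factory=PrePostEffect)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        highest = max(b.high for b in self.bands)
        if self.fs <= 2 * highest:
            raise ValueError(
                f"fs={self.fs} must exceed twice the highest band edge ({highest} Hz)"
            )
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration * fs must be an integer sample count")
        if not 0 <= self.artifact_rate <= 1:
            raise ValueError("artifact_rate must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.noise_color not in ("white", "pink"):
            raise ValueError("noise_color must be 'white' or 'pink'")

    @property
    def channel_labels(self) -> tuple[str, ...]:
        if self.n_channels == 16:
            return CHANNELS_1020
        return tuple(f"ch{i}" for i in range(self.n_channels))

    # -- helpers -----------------------------------------------------------

    def coupling_for(self, band_name: str) -> np.ndarray:
        """Coupling matrix for one band (zeros when unspecified)."""
        C = self.n_channels
        if self.coupling is None:
            return np.zeros((C, C))
        if isinstance(self.coupling, dict):
            mat = self.coupling.get(band_name)
            if mat is None:
                return np.zeros((C, C))
        else:
            mat = self.coupling
        mat = np.asarray(mat, dtype=float)
        _validate_coupling(mat, C, band_name)
        return mat

    def band_variance(self, band_name: str) -> np.ndarray:
        """Per-channel variance (µV²) of one band's oscillatory component."""
        val = self.band_powers.get(band_name, 0.0)
        return np.broadcast_to(np.asarray(val, dtype=float), (self.n_channels,)).copy()


def _validate_coupling(mat: np.ndarray, n_channels: int, band_name: str) -> None:
    if mat.shape != (n_channels, n_channels):
        raise ValueError(f"coupling matrix for {band_name} must be {n_channels}x{n_channels}")
    if not np.allclose(mat, mat.T):
        raise ValueError(f"coupling matrix for {band_name} must be symmetric")
    if np.any(np.abs(np.diag(mat)) > 0):
        raise ValueError(f"coupling matrix for {band_name} must have a zero diagonal")
    if np.any(mat < 0) or np.any(mat >= 1):
        raise ValueError(f"coupling entries for {band_name} must lie in [0, 1)")


class InfeasibleCouplingError(ValueError):
    """Requested coherence not achievable with the configured power/noise."""


# ---------------------------------------------------------------------------
# narrowband sources
# ---------------------------------------------------------------------------

def _band_filter(band: BandDefinition, fs: float):
    """4th-order Butterworth band-pass plus its variance gain and peak PSD.

    Returns (sos, var_gain, p_star): ``var_gain`` is the variance of the
    filter's response to unit-variance white noise, ``p_star`` the one-sided
    PSD at the response peak of a *unit-variance* narrowband source (µV²/Hz
    per unit variance).
    """
    sos = signal.butter(4, [band.low, band.high], btype="bandpass", fs=fs, output="sos")
    w, h = signal.sosfreqz(sos, worN=8192, fs=fs)
    h2 = np.abs(h) ** 2
    var_gain = h2.mean()  # = (2/fs) * integral of |H|^2 over [0, fs/2]
    p_star = h2.max() / var_gain * (2.0 / fs)
    return sos, var_gain, p_star


def _band_peak_freq(band: BandDefinition, fs: float) -> float:
    sos = signal.butter(4, [band.low, band.high], btype="bandpass", fs=fs, output="sos")
    w, h = signal.sosfreqz(sos, worN=8192, fs=fs)
    return float(w[np.argmax(np.abs(h))])


def _narrowband_sources(rng, n_sources: int, n_samples: int, sos, var_gain: float) -> np.ndarray:
    """Independent unit-variance narrowband processes (2 s warm-up trimmed)."""
    pad = min(n_samples, 512)
    white = rng.standard_normal((n_sources, n_samples + pad))
    out = signal.sosfilt(sos, white, axis=-1)[:, pad:]
    return out / np.sqrt(var_gain)


def _broadband_noise(rng, shape: tuple, fs: float, color: str) -> tuple[np.ndarray, callable]:
    """Unit-variance broadband noise plus its one-sided PSD as a function of
    frequency (for coherence calibration)."""
    if color == "white":
        return rng.standard_normal(shape), lambda f: 2.0 / fs
    # pink: 1/f above 1 Hz, flat below, shaped exactly in the Fourier domain
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    weight = 1.0 / np.maximum(freqs, 1.0)
    # normalise so total variance is 1 (mean of the shaped periodogram)
    spec_gain = np.sqrt(weight)
    white = rng.standard_normal(shape)
    shaped = np.fft.irfft(np.fft.rfft(white, axis=-1) * spec_gain, n=n, axis=-1)
    shaped /= shaped.std(axis=-1, keepdims=True)
    norm = np.trapezoid(weight, freqs)

    def psd(f: float) -> float:
        return float(1.0 / max(f, 1.0) / norm)

    return shaped, psd


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _effect_scale(state: str, seizure_index: int, trend: float) -> float:
    """Edge-shift scale for a segment: damage accumulates across seizures and
    each post segment carries one additional unit of acute shift."""
    base = trend * (seizure_index - 1)
    return base + (1.0 if state == "post" else 0.0)


def generate_recording(
    config: SyntheticConfig,
    state: str = "pre",
    seizure_index: int = 1,
) -> Recording:
    """Generate one peri-ictal recording with the configured ground truth.

    ``state`` selects whether the :class:`PrePostEffect` contrasts are applied
    ("post") or not ("pre"); ``seizure_index`` (1-based) scales the planted
    edge shifts through ``seizure_trend``.  Output is a pure function of
    (config, state, seizure_index).
    """
    if state not in ("pre", "post"):
        raise ValueError("state must be 'pre' or 'post'")
    if seizure_index < 1:
        raise ValueError("seizure_index must be >= 1")

    C = config.n_channels
    n = int(round(config.duration * config.fs))
    labels = config.channel_labels
    eff = config.effect

    # independent substreams per (seed, state, seizure) keep pre/post windows
    # statistically independent, as distinct time windows of a recording are
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 0 if state == "pre" else 1, int(seizure_index)])
    )

    # state-dependent parameters
    noise_sd = np.broadcast_to(np.asarray(config.noise_sd, dtype=float), (C,)).astype(float).copy()
    if state == "post":
        shift = np.broadcast_to(np.asarray(eff.entropy_shift, dtype=float), (C,))
        noise_sd = noise_sd * np.clip(1.0 + shift, 0.0, None)

    edge_scale = _effect_scale(state, seizure_index, eff.seizure_trend)
    shift_mat = _edge_shift_matrix(eff.edge_shifts, labels, C)

    noise, noise_psd = _broadband_noise(rng, (C, n), config.fs, config.noise_color)
    data = noise * noise_sd[:, None]

    for band in config.bands:
        sigma2 = config.band_variance(band.name)
        if state == "post" and band.name == "delta":
            ratio = np.broadcast_to(np.asarray(eff.delta_power_ratio, dtype=float), (C,))
            if np.any(ratio <= 0):
                raise ValueError("delta_power_ratio must be positive")
            sigma2 = sigma2 * ratio

        kappa = config.coupling_for(band.name)
        if band.name == eff.edge_shift_band and edge_scale != 0.0 and shift_mat.any():
            kappa = kappa + shift_mat * edge_scale
            try:
                _validate_coupling(kappa, C, band.name)
            except ValueError as exc:
                raise InfeasibleCouplingError(
                    f"edge shifts at scale {edge_scale} push coupling out of [0,1): {exc}"
                ) from exc

        sos, var_gain, p_star = _band_filter(band, config.fs)
        f_star = _band_peak_freq(band, config.fs)

        # mixing fractions g_ij from the closed-form coherence target (module
        # docstring): g = sqrt(kappa * (1+a_i)(1+a_j)), a = N(f*)/(sigma^2 P*)
        gamma = np.zeros((C, C))
        pairs = [(i, j) for i in range(C) for j in range(i + 1, C) if kappa[i, j] > 0]
        for i, j in pairs:
            for ch in (i, j):
                if sigma2[ch] <= 0:
                    raise InfeasibleCouplingError(
                        f"coupling {kappa[i, j]:.3f} requested between {labels[i]} and "
                        f"{labels[j]} in {band.name}, but {labels[ch]} has zero "
                        f"{band.name} power"
                    )
            a_i = noise_sd[i] ** 2 * noise_psd(f_star) / (sigma2[i] * p_star)
            a_j = noise_sd[j] ** 2 * noise_psd(f_star) / (sigma2[j] * p_star)
            g = np.sqrt(kappa[i, j] * (1.0 + a_i) * (1.0 + a_j))
            if g >= 1.0:
                raise InfeasibleCouplingError(
                    f"coupling {kappa[i, j]:.3f} between {labels[i]} and {labels[j]} "
                    f"in {band.name} is not achievable with noise_sd={noise_sd[i]:.3g}: "
                    f"required mixing fraction {g:.3f} >= 1"
                )
            gamma[i, j] = gamma[j, i] = g

        row_sum = gamma.sum(axis=1)
        over = np.flatnonzero(row_sum > 1.0)
        if over.size:
            ch = over[0]
            raise InfeasibleCouplingError(
                f"channel {labels[ch]} needs total mixing fraction "
                f"{row_sum[ch]:.3f} > 1 in {band.name}; reduce the requested couplings"
            )

        own = _narrowband_sources(rng, C, n, sos, var_gain)
        comp = np.sqrt(np.clip(1.0 - row_sum, 0.0, None))[:, None] * own
        if pairs:
            shared = _narrowband_sources(rng, len(pairs), n, sos, var_gain)
            for k, (i, j) in enumerate(pairs):
                comp[i] += np.sqrt(gamma[i, j]) * shared[k]
                comp[j] += np.sqrt(gamma[j, i]) * shared[k]
        data += np.sqrt(sigma2)[:, None] * comp

    return Recording(data=data, fs=config.fs, channel_labels=labels)


def _edge_shift_matrix(edge_shifts: dict, labels: tuple[str, ...], C: int) -> np.ndarray:
    mat = np.zeros((C, C))
    index = {lbl: k for k, lbl in enumerate(labels)}
    for (a, b), delta in edge_shifts.items():
        i = index[a] if isinstance(a, str) else int(a)
        j = index[b] if isinstance(b, str) else int(b)
        if i == j:
            raise ValueError("edge shifts must name two distinct channels")
        mat[i, j] = mat[j, i] = float(delta)
    return mat


def generate_seizure_series(
    config: SyntheticConfig, n_seizures: int
) -> list[tuple[Recording, Recording]]:
    """Pre/post recording pairs for consecutive seizures.

    With a nonzero ``seizure_trend`` the planted edge shifts accumulate so the
    network degradation is monotone in segment order 1-pre, 1-post, 2-pre, ...
    (see :func:`segment_labels`).
    """
    if n_seizures < 2:
        raise ValueError("a seizure series needs at least 2 seizures")
    return [
        (
            generate_recording(config, "pre", seizure_index=k),
            generate_recording(config, "post", seizure_index=k),
        )
        for k in range(1, n_seizures + 1)
    ]


def segment_labels(n_seizures: int) -> list[str]:
    """Segment labels in temporal order: 1-pre, 1-post, ..., n-pre, n-post."""
    return [f"{k}-{state}" for k in range(1, n_seizures + 1) for state in ("pre", "post")]


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------

def inject_artifacts(
    recording: Recording,
    rate: float,
    amplitude: float = 200.0,
    seed: int = 0,
    epoch_length: float = 6.0,
) -> tuple[Recording, np.ndarray]:
    """Plant high-amplitude artifacts into randomly chosen epochs.

    Exactly ``round(rate * n_windows)`` of the recording's consecutive
    ``epoch_length`` windows are chosen without replacement (so the corrupted
    fraction equals the requested rate up to rounding); each receives a 0.5 s
    square pulse or a 1 s ramp of the given peak amplitude (random sign,
    random channel).  Returns the corrupted recording and the sorted indices
    of the planted windows, so rejection counts can be verified exactly.

    The amplitude must exceed 80 µV — an artifact that cannot trip the
    rejection rule is a contradiction in terms here.
    """
    if not 0 <= rate <= 1:
        raise ValueError("artifact rate must lie in [0, 1]")
    if amplitude <= 80.0:
        raise ValueError(
            f"artifact amplitude {amplitude} µV would not exceed the ±80 µV rejection threshold"
        )
    win = int(round(epoch_length * recording.fs))
    n_windows = recording.n_samples // win
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA27]))
    n_planted = int(round(rate * n_windows))
    planted = np.sort(rng.choice(n_windows, size=n_planted, replace=False))

    out = recording.copy()
    fs = recording.fs
    for w in planted:
        ch = int(rng.integers(recording.n_channels))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        kind = "pulse" if rng.random() < 0.5 else "ramp"
        if kind == "pulse":
            dur = int(round(0.5 * fs))
            shape = np.full(dur, amplitude)
        else:
            dur = int(round(1.0 * fs))
            shape = np.linspace(0.0, amplitude, dur)
        start = w * win + int(rng.integers(0, win - dur + 1))
        out.data[ch, start : start + dur] += sign * shape
    return out, planted


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_recording(
    recording: Recording,
    out_dir: str | Path,
    stem: str,
    ground_truth: dict | None = None,
) -> dict:
    """Write a recording as EDF plus a JSON ground-truth sidecar.

    Returns the paths written.  ``ground_truth`` may carry the planted
    coupling, artifact windows and effect settings for downstream validation.
    """
    from .recording import write_edf

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    edf_path = out_dir / f"{stem}.edf"
    write_edf(recording, edf_path)
    paths = {"edf": str(edf_path)}
    if ground_truth is not None:
        sidecar = out_dir / f"{stem}.ground_truth.json"
        sidecar.write_text(json.dumps(_jsonable(ground_truth), indent=2, sort_keys=True) + "\n")
        paths["sidecar"] = str(sidecar)
    return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
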