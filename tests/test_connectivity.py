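import numpy as np
import pytest
from scipy import signal as sig

from eegnet.connectivity import (
    coherence_matrix,
    coherence_spectrum,
    per_epoch_coherence,
)
from eegnet.reference import coherence_naive
from eegnet.spectral import BAND_BY_NAME, BandDefinition

from conftest import make_epochs

FS = 256.0


class TestCoherenceSpectrum:
    def test_self_coherence_is_one(self, white_epochs):
        freqs, coh = coherence_spectrum(white_epochs, 0, 0)
        assert np.allclose(coh, 1.0)

    def test_independent_channels_near_floor(self, white_epochs):
        _, coh = coherence_spectrum(white_epochs, 0, 1)
        assert coh.mean() < 0.1

    def test_pure_delay_is_transparent(self, rng):
        # |e^{-iwt}| = 1: magnitude-squared coherence ignores delays
        x = rng.standard_normal(1536 * 10 + 3)
        data = np.stack([x[3:], x[:-3]]).reshape(2, 10, 1536).transpose(1, 0, 2)
        es = make_epochs(data)
        freqs, coh = coherence_spectrum(es, 0, 1)
        inner = (freqs > 2) & (freqs < 100)
        assert coh[inner].min() > 0.99

    def test_single_segment_degenerate(self, rng):
        es = make_epochs(rng.standard_normal((1, 2, 512)))
        with pytest.raises(ValueError, match="segment"):
            coherence_spectrum(es, 0, 1, window_s=2.0, overlap=0.0)

    def test_matches_scipy_welch_coherence(self, rng):
        x = rng.standard_normal((1, 2, 2560))
        es = make_epochs(x)
        freqs, coh = coherence_spectrum(es, 0, 1, window_s=2.0, overlap=0.5)
        f_ref, c_ref = sig.coherence(
            x[0, 0], x[0, 1], fs=FS, window="hann", nperseg=512, noverlap=256,
            detrend="constant",
        )
        assert np.allclose(freqs, f_ref)
        assert np.allclose(coh, c_ref, rtol=1e-8, atol=1e-10)

    def test_matches_naive_fft_accumulation(self, rng):
        x = rng.standard_normal((1, 2, 2048))
        es = make_epochs(x)
        freqs, coh = coherence_spectrum(es, 0, 1, window_s=1.0, overlap=0.5)
        f_ref, c_ref = coherence_naive(x[0, 0], x[0, 1], FS, nperseg=256, noverlap=128)
        assert np.allclose(freqs, f_ref)
        assert np.allclose(coh, c_ref, rtol=1e-8, atol=1e-10)

    def test_small_sample_bias_scales_inversely_with_segments(self, rng):
        # independent signals: E[coherence] ~ 1/L for L averaged segments
        L = 10
        means = []
        for _ in range(20):
            es = make_epochs(rng.standard_normal((2, 2, 1536)))  # 2 epochs x 5 windows
            _, coh = coherence_spectrum(es, 0, 1)
            means.append(coh.mean())
        assert 0.5 / L < np.mean(means) < 1.5 / L


class TestCoherenceMatrix:
    def test_identical_channels_full_offdiagonal(self, rng):
        x = rng.standard_normal((5, 1, 1536))
        data = np.repeat(x, 3, axis=1)
        cm = coherence_matrix(make_epochs(data), BAND_BY_NAME["alpha"])
        off = cm.C[np.triu_indices(3, k=1)]
        assert np.allclose(off, 1.0)
        assert np.allclose(np.diag(cm.C), 0.0)

    def test_epoch_order_invariance(self, rng):
        data = rng.standard_normal((8, 3, 1536))
        a = coherence_matrix(make_epochs(data), BAND_BY_NAME["beta"]).C
        b = coherence_matrix(make_epochs(data[::-1]), BAND_BY_NAME["beta"]).C
        assert np.allclose(a, b)

    def test_symmetry_and_range(self, rng):
        cm = coherence_matrix(
            make_epochs(rng.standard_normal((6, 4, 1536))), BAND_BY_NAME["delta"]
        )
        assert np.allclose(cm.C, cm.C.T)
        assert cm.C.min() >= 0.0 and cm.C.max() <= 1.0

    def test_empty_band_rejected(self, rng):
        es = make_epochs(rng.standard_normal((4, 2, 1536)))
        with pytest.raises(ValueError, match="no bins"):
            coherence_matrix(es, BandDefinition("sub", 0.05, 0.2))

    def test_planted_single_pair_recovered(self):
        from eegnet.preprocess import bandpass, segment
        from eegnet.synthetic import SyntheticConfig, generate_recording

        kappa = np.zeros((16, 16))
        kappa[2, 5] = kappa[5, 2] = 0.5
        cfg = SyntheticConfig(
            duration=600.0,
            band_powers={"alpha": 15.0},
            coupling={"alpha": kappa},
            seed=21,
        )
        es = segment(bandpass(generate_recording(cfg)))
        cm = coherence_matrix(es, BAND_BY_NAME["alpha"])
        assert cm.C[2, 5] == pytest.approx(0.5, abs=0.1)
        others = cm.C.copy()
        others[2, 5] = others[5, 2] = 0.0
        assert others.max() < 0.1


class TestPerEpochCoherence:
    def test_mean_tracks_pooled_estimate_loosely(self, rng):
        data = rng.standard_normal((20, 3, 1536))
        es = make_epochs(data)
        per = per_epoch_coherence(es, BAND_BY_NAME["alpha"])
        assert per.shape == (20, 3, 3)
        # per-epoch estimates carry the 1/5 small-sample bias
        assert per[:, 0, 1].mean() == pytest.approx(0.2, abs=0.1)

    def test_needs_multiple_windows(self, rng):
        es = make_epochs(rng.standard_normal((3, 2, 512)))
        with pytest.raises(ValueError, match="windows"):
            per_epoch_coherence(es, BAND_BY_NAME["alpha"], window_s=2.0, overlap=0.0)
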