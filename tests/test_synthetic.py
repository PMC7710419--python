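import numpy as np
import pytest

from eegnet.connectivity import coherence_matrix
from eegnet.preprocess import bandpass, segment
from eegnet.spectral import BAND_BY_NAME, DEFAULT_BANDS
from eegnet.synthetic import (
    DEFAULT_BAND_POWERS,
    InfeasibleCouplingError,
    PrePostEffect,
    SyntheticConfig,
    generate_recording,
    generate_seizure_series,
    inject_artifacts,
    segment_labels,
)


class TestDeterminism:
    def test_identical_config_and_seed_bitwise_equal(self):
        cfg = SyntheticConfig(duration=12.0, seed=42)
        a = generate_recording(cfg, "post", seizure_index=2)
        b = generate_recording(cfg, "post", seizure_index=2)
        assert np.array_equal(a.data, b.data)

    def test_states_and_indices_differ(self):
        cfg = SyntheticConfig(duration=12.0, seed=42)
        pre = generate_recording(cfg, "pre")
        post = generate_recording(cfg, "post")
        assert not np.array_equal(pre.data, post.data)


class TestPowerCalibration:
    def test_band_variances_match_config_within_10pct(self):
        # configure one band at a time with zero noise: the total sample
        # variance is then exactly that band's planted variance
        for b in DEFAULT_BANDS:
            target = DEFAULT_BAND_POWERS[b.name]
            est = []
            for seed in range(5):
                cfg = SyntheticConfig(
                    duration=600.0,
                    noise_sd=0.0,
                    band_powers={b.name: target},
                    seed=seed,
                )
                est.append(generate_recording(cfg).data.var(axis=-1).mean())
            assert np.mean(est) == pytest.approx(target, rel=0.10)

    def test_delta_power_ratio_planted_at_two(self):
        eff = PrePostEffect(delta_power_ratio=2.0)
        cfg = SyntheticConfig(
            duration=600.0,
            noise_sd=0.0,
            band_powers={"delta": 20.0},
            effect=eff,
            seed=3,
        )
        var = {
            st: generate_recording(cfg, st).data.var(axis=-1).mean()
            for st in ("pre", "post")
        }
        assert var["post"] / var["pre"] == pytest.approx(2.0, rel=0.10)


class TestCouplingLimits:
    def test_identical_channel_limit_gives_unit_coherence(self):
        kappa = np.zeros((16, 16))
        kappa[0, 1] = kappa[1, 0] = 0.998
        cfg = SyntheticConfig(
            duration=120.0, coupling=kappa, noise_sd=0.0, seed=1
        )
        rec = generate_recording(cfg)
        es = segment(bandpass(rec))
        for name in ("delta", "alpha"):
            cm = coherence_matrix(es, BAND_BY_NAME[name])
            assert cm.C[0, 1] > 0.97

    def test_zero_coupling_coherence_floor(self):
        cfg = SyntheticConfig(duration=300.0, seed=2)
        rec = generate_recording(cfg)
        es = segment(bandpass(rec))
        cm = coherence_matrix(es, BAND_BY_NAME["alpha"])
        off = cm.C[np.triu_indices(16, k=1)]
        assert off.mean() < 0.1

    def test_infeasible_coupling_names_the_pair(self):
        kappa = np.zeros((16, 16))
        kappa[0, 1] = kappa[1, 0] = 0.95
        cfg = SyntheticConfig(
            duration=6.0, coupling={"low_gamma": kappa}, noise_sd=30.0, seed=0
        )
        with pytest.raises(InfeasibleCouplingError, match="Fp1.*Fp2"):
            generate_recording(cfg)

    def test_oversubscribed_channel_names_the_channel(self):
        kappa = np.zeros((16, 16))
        for j in (1, 2, 3, 4):  # four strong partners exceed channel 0's budget
            kappa[0, j] = kappa[j, 0] = 0.4
        cfg = SyntheticConfig(duration=6.0, coupling={"alpha": kappa}, seed=0)
        with pytest.raises(InfeasibleCouplingError, match="mixing fraction"):
            generate_recording(cfg)


class TestArtifacts:
    def test_zero_rate_leaves_recording_unchanged(self):
        cfg = SyntheticConfig(duration=30.0, seed=7)
        rec = generate_recording(cfg)
        out, planted = inject_artifacts(rec, rate=0.0, amplitude=150.0, seed=1)
        assert planted.size == 0
        assert np.array_equal(out.data, rec.data)

    def test_rate_plants_exact_window_count(self):
        cfg = SyntheticConfig(duration=600.0, seed=7)
        rec = generate_recording(cfg)
        out, planted = inject_artifacts(rec, rate=0.1, amplitude=150.0, seed=1)
        assert planted.size == 10
        win = 6 * 256
        for w in planted:
            assert np.abs(out.data[:, w * win : (w + 1) * win]).max() > 80.0

    def test_subthreshold_amplitude_rejected(self):
        cfg = SyntheticConfig(duration=30.0, seed=7)
        rec = generate_recording(cfg)
        with pytest.raises(ValueError, match="80"):
            inject_artifacts(rec, rate=0.1, amplitude=79.0, seed=1)

    @pytest.mark.parametrize("rate", [-0.1, 1.5])
    def test_rate_out_of_bounds_rejected(self, rate):
        cfg = SyntheticConfig(duration=30.0, seed=7)
        rec = generate_recording(cfg)
        with pytest.raises(ValueError, match="rate"):
            inject_artifacts(rec, rate=rate, amplitude=150.0, seed=1)


class TestSeizureSeries:
    def test_four_seizures_give_eight_labeled_segments(self):
        cfg = SyntheticConfig(duration=12.0, seed=5)
        series = generate_seizure_series(cfg, n_seizures=4)
        assert len(series) == 4 and all(len(pair) == 2 for pair in series)
        assert segment_labels(4) == [
            "1-pre", "1-post", "2-pre", "2-post", "3-pre", "3-post", "4-pre", "4-post",
        ]

    def test_trend_escaping_unit_interval_raises(self):
        kappa = np.zeros((16, 16))
        kappa[0, 1] = kappa[1, 0] = 0.5
        eff = PrePostEffect(
            edge_shifts={(0, 1): 0.2}, edge_shift_band="alpha", seizure_trend=1.0
        )
        cfg = SyntheticConfig(
            duration=6.0, coupling={"alpha": kappa}, effect=eff, seed=1
        )
        with pytest.raises(InfeasibleCouplingError, match="out of"):
            generate_seizure_series(cfg, n_seizures=4)

    def test_minimum_two_seizures(self):
        cfg = SyntheticConfig(duration=6.0, seed=1)
        with pytest.raises(ValueError, match="at least 2"):
            generate_seizure_series(cfg, n_seizures=1)


class TestConfigValidation:
    def test_fs_must_cover_highest_band(self):
        with pytest.raises(ValueError, match="twice"):
            SyntheticConfig(fs=80.0)

    def test_asymmetric_coupling_rejected(self):
        kappa = np.zeros((16, 16))
        kappa[0, 1] = 0.5  # not symmetrised
        cfg = SyntheticConfig(duration=6.0, coupling={"alpha": kappa})
        with pytest.raises(ValueError, match="symmetric"):
            generate_recording(cfg)

    def test_nonzero_diagonal_rejected(self):
        kappa = np.eye(16) * 0.5
        cfg = SyntheticConfig(duration=6.0, coupling={"alpha": kappa})
        with pytest.raises(ValueError, match="diagonal"):
            generate_recording(cfg)
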