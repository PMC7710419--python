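import numpy as np
import pytest

from eegnet.preprocess import (
    bandpass,
    preprocess,
    reject_artifacts,
    rereference_average,
    segment,
)

from conftest import make_epochs, make_recording


class TestRereference:
    def test_two_channel_mean_subtraction(self):
        rec = make_recording(np.array([[1.0], [3.0]]))
        out = rereference_average(rec)
        assert np.allclose(out.data[:, 0], [-1.0, 1.0])

    def test_column_means_vanish(self, rng):
        rec = make_recording(rng.normal(0, 10, (16, 1000)))
        out = rereference_average(rec)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-9

    def test_idempotent(self, rng):
        rec = make_recording(rng.normal(0, 10, (8, 500)))
        once = rereference_average(rec)
        twice = rereference_average(once)
        assert np.allclose(once.data, twice.data)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError, match="2 channels"):
            rereference_average(make_recording(np.zeros((1, 100))))


class TestBandpass:
    fs = 256.0

    def _sine(self, freq, n=256 * 20):
        t = np.arange(n) / self.fs
        return make_recording(np.tile(np.sin(2 * np.pi * freq * t), (2, 1)), fs=self.fs)

    def test_stopband_60hz_suppressed(self):
        rec = self._sine(60.0)
        out = bandpass(rec)
        sl = slice(512, -512)  # ignore filter edge transients
        assert out.data[0, sl].std() < 0.1 * rec.data[0, sl].std()

    def test_passband_10hz_preserved(self):
        rec = self._sine(10.0)
        out = bandpass(rec)
        sl = slice(512, -512)
        assert abs(out.data[0, sl].std() - rec.data[0, sl].std()) < 0.05 * rec.data[0, sl].std()

    def test_dc_offset_removed(self):
        rec = make_recording(np.full((2, 256 * 10), 50.0), fs=self.fs)
        out = bandpass(rec)
        assert abs(out.data.mean()) < 0.5

    @pytest.mark.parametrize("low,high", [(0, 45), (45, 1), (1, 200)])
    def test_invalid_edges_rejected(self, low, high):
        rec = self._sine(10.0)
        with pytest.raises(ValueError):
            bandpass(rec, low, high)


class TestSegment:
    def test_600s_gives_100_epochs_of_1536_samples(self, rng):
        rec = make_recording(rng.normal(0, 5, (4, 256 * 600)))
        es = segment(rec)
        assert es.epochs.shape == (100, 4, 1536)

    def test_trailing_remainder_dropped(self, rng):
        rec = make_recording(rng.normal(0, 5, (2, 256 * 601)))
        assert segment(rec).epochs.shape[0] == 100

    def test_too_short_recording_rejected(self, rng):
        rec = make_recording(rng.normal(0, 5, (2, 256 * 5)))
        with pytest.raises(ValueError, match="shorter"):
            segment(rec)

    def test_sample_conservation(self, rng):
        n = 256 * 601
        rec = make_recording(rng.normal(0, 5, (2, n)))
        es = segment(rec)
        retained = es.epochs.shape[0] * es.epochs.shape[2]
        remainder = n - es.retained_mask.size * 1536
        assert retained + remainder == n


class TestRejectArtifacts:
    def test_boundary_is_strict(self):
        data = np.zeros((3, 2, 1536))
        data[0, 0, 10] = 81.0   # above threshold -> rejected
        data[1, 1, 20] = 80.0   # exactly at threshold -> retained
        data[2, 0, 30] = 79.0
        out = reject_artifacts(make_epochs(data))
        assert list(out.retained_mask) == [False, True, True]

    def test_inclusive_mode_drops_exact_threshold(self):
        data = np.zeros((2, 1, 1536))
        data[0, 0, 0] = 80.0
        out = reject_artifacts(make_epochs(data), inclusive=True)
        assert list(out.retained_mask) == [False, True]

    def test_all_within_bounds_all_retained(self, rng):
        out = reject_artifacts(make_epochs(rng.uniform(-79, 79, (10, 2, 1536))))
        assert out.retained_mask.all() and out.n_epochs == 10

    def test_all_rejected_raises(self):
        data = np.full((3, 1, 1536), 100.0)
        with pytest.raises(ValueError, match="exceed"):
            reject_artifacts(make_epochs(data))

    def test_planted_artifact_windows_rejected_exactly(self, rng):
        from eegnet.synthetic import SyntheticConfig, generate_recording, inject_artifacts

        cfg = SyntheticConfig(duration=120.0, seed=11)
        rec = generate_recording(cfg)
        corrupted, planted = inject_artifacts(rec, rate=0.25, amplitude=200.0, seed=4)
        with pytest.warns(UserWarning, match="dropped"):
            es = preprocess(corrupted)
        rejected = np.flatnonzero(~es.retained_mask)
        assert set(rejected.tolist()) == set(planted.tolist())
        assert planted.size == 5  # round(0.25 * 20)


def test_chain_preserves_epoch_geometry(rng):
    rec = make_recording(rng.normal(0, 5, (4, 256 * 60)))
    es = preprocess(rec)
    assert es.epochs.shape == (10, 4, 1536)
    assert np.abs(es.epochs.mean(axis=1)).max() < 1e-6  # reref survives the chain
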