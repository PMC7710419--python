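import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegnet.netmetrics import (
    band_metrics,
    characteristic_path_length,
    clustering_coefficient,
    network_metrics,
    proportional_threshold,
)
from eegnet.reference import clustering_naive, cpl_naive


def random_weights(seed, n=16, sparsity=0.0):
    rng = np.random.default_rng(seed)
    W = rng.uniform(0, 1, (n, n))
    if sparsity:
        W[rng.random((n, n)) < sparsity] = 0.0
    W = np.maximum(W, W.T)  # keep connectivity likely
    np.fill_diagonal(W, 0.0)
    return W


class TestCharacteristicPathLength:
    def test_complete_unit_graph_is_one(self):
        for n in (3, 8, 16):
            W = np.ones((n, n)) - np.eye(n)
            assert characteristic_path_length(W) == pytest.approx(1.0)

    def test_three_node_path_hand_computed(self):
        # A-B and B-C at weight 0.5 (length 2); A-C only via B (length 4)
        W = np.array([[0, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0]])
        assert characteristic_path_length(W) == pytest.approx(8.0 / 3.0)
        assert cpl_naive(W) == pytest.approx(8.0 / 3.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_floyd_warshall(self, seed):
        W = random_weights(seed)
        assert characteristic_path_length(W) == pytest.approx(cpl_naive(W), rel=1e-12)

    def test_disconnected_graph_raises_by_default(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0  # component {0,1}; nodes 2,3 isolated
        with pytest.raises(ValueError, match="disconnected"):
            characteristic_path_length(W)

    def test_disconnected_efficiency_fallback_finite(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        val = characteristic_path_length(W, on_disconnected="efficiency")
        assert np.isfinite(val) and val > 1.0

    def test_uniform_scaling_scales_inverse(self, rng):
        W = random_weights(3)
        base = characteristic_path_length(W)
        assert characteristic_path_length(2.5 * W / W.max()) == pytest.approx(
            base * W.max() / 2.5
        )

    def test_one_minus_length_mapping(self):
        W = np.array([[0, 0.9, 0], [0.9, 0, 0.9], [0, 0.9, 0]])
        got = characteristic_path_length(W, length="one_minus")
        # hops of length 0.1; the end pair travels two hops
        assert got == pytest.approx((0.1 + 0.1 + 0.2) / 3)


class TestClusteringCoefficient:
    def test_complete_unit_graph_is_one_both_variants(self):
        W = np.ones((16, 16)) - np.eye(16)
        assert clustering_coefficient(W, "printed") == pytest.approx(1.0)
        assert clustering_coefficient(W, "standard") == pytest.approx(1.0)

    def test_empty_graph_is_zero(self):
        Z = np.zeros((5, 5))
        assert clustering_coefficient(Z, "printed") == 0.0
        assert clustering_coefficient(Z, "standard") == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), variant=st.sampled_from(["printed", "standard"]))
    def test_matches_triple_loop(self, seed, variant):
        W = random_weights(seed)
        assert clustering_coefficient(W, variant) == pytest.approx(
            clustering_naive(W, variant), rel=1e-12, abs=1e-13
        )

    def test_standard_variant_scales_linearly(self):
        W = random_weights(5)
        base = clustering_coefficient(W, "standard")
        assert clustering_coefficient(0.5 * W, "standard") == pytest.approx(0.5 * base)

    def test_printed_variant_not_scale_invariant(self):
        # the strength denominator breaks invariance on non-unit weights
        W = random_weights(5)
        a = clustering_coefficient(W, "printed")
        b = clustering_coefficient(0.5 * W, "printed")
        assert not np.isclose(a, b)
        assert not np.isclose(b, 0.5 * a)

    def test_low_strength_nodes_zeroed_with_warning(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.3
        W[1, 2] = W[2, 1] = 0.3
        W[0, 2] = W[2, 0] = 0.3  # triangle, strengths 0.6 <= 1
        with pytest.warns(UserWarning, match="strength"):
            assert clustering_coefficient(W, "printed") == 0.0


class TestInvariancesAndAggregation:
    def test_node_relabeling_invariance(self):
        W = random_weights(8)
        perm = np.random.default_rng(1).permutation(W.shape[0])
        Wp = W[np.ix_(perm, perm)]
        assert characteristic_path_length(Wp) == pytest.approx(
            characteristic_path_length(W), rel=1e-12
        )
        for v in ("printed", "standard"):
            assert clustering_coefficient(Wp, v) == pytest.approx(
                clustering_coefficient(W, v), rel=1e-12
            )

    def test_five_bands_in_five_metrics_out(self, rng):
        from eegnet.connectivity import coherence_matrix
        from eegnet.spectral import DEFAULT_BANDS

        from conftest import make_epochs

        es = make_epochs(rng.standard_normal((6, 4, 1536)))
        mats = {b.name: coherence_matrix(es, b) for b in DEFAULT_BANDS}
        out = band_metrics(mats, variant="standard")
        assert len(out) == 5
        assert [m.band.name for m in out] == [b.name for b in DEFAULT_BANDS]

    def test_global_coupling_increase_moves_metrics_oppositely(self):
        lo = 0.3 * (np.ones((16, 16)) - np.eye(16))
        hi = 0.6 * (np.ones((16, 16)) - np.eye(16))
        m_lo = network_metrics(lo, variant="standard")
        m_hi = network_metrics(hi, variant="standard")
        assert m_hi.cpl < m_lo.cpl
        assert m_hi.cc > m_lo.cc

    def test_proportional_threshold_keeps_strongest_edges(self):
        W = random_weights(4)
        out = proportional_threshold(W, 0.25)
        kept = (out[np.triu_indices_from(out, k=1)] > 0).sum()
        assert kept == round(0.25 * 120)
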