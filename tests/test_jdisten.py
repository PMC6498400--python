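"""Joint-distribution-entropy coupling: embedding through the full matrix."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from numpy.testing import assert_allclose

from _oracles import coupling_matrix_oracle
from jdnet.errors import DomainError, NormalizationError, TooFewObservationsError, TooShortSeriesError
from jdnet.jdisten import (
    EmbeddingConfig,
    JointHistogram,
    channel_distance_matrix,
    coupling_matrix,
    doane_bins,
    embed,
    jdisten_from_histogram,
    joint_distance_matrix,
    joint_histogram,
    off_diagonal,
)


class TestEmbed:
    def test_two_dim_delay_one(self):
        X = embed(np.array([0, 1, 0.5, 0.25]), EmbeddingConfig(m=2, tau=1))
        assert X.shape == (2, 2)
        assert_allclose(X[:, 0], [0, 1])
        assert_allclose(X[:, 1], [1, 0.5])

    def test_m_one_passthrough(self):
        u = np.array([0.1, 0.9, 0.4, 0.6])
        X = embed(u, EmbeddingConfig(m=1, tau=1))
        assert_allclose(X, u[None, :3])

    def test_too_short_series(self):
        with pytest.raises(TooShortSeriesError):
            embed(np.array([0.0, 1.0]), EmbeddingConfig(m=2, tau=1))


class TestDistance:
    def test_printed_formula_off_diagonal(self):
        X = np.array([[0.2, 0.3], [0.4, 0.5]])  # columns (0.2,0.4), (0.3,0.5)
        d = channel_distance_matrix(X)
        assert_allclose(d[0, 1], 0.3)  # max(0.4-0.3, 0.5-0.2)
        assert_allclose(d, d.T)

    def test_diagonal_is_column_range(self):
        X = np.array([[0.2], [0.4]])
        assert_allclose(channel_distance_matrix(X)[0, 0], 0.2)

    def test_constant_equal_columns_zero(self):
        X = 0.5 * np.ones((2, 4))
        assert_allclose(channel_distance_matrix(X), np.zeros((4, 4)))

    def test_chebyshev_variant_differs(self):
        X = np.array([[0.2, 0.3], [0.4, 0.5]])
        cheb = channel_distance_matrix(X, norm="chebyshev")
        assert_allclose(cheb[0, 1], 0.1)  # max(|0.2-0.3|, |0.4-0.5|)
        assert cheb[0, 0] == 0.0


class TestJointDistance:
    def test_self_combination_is_identity(self, rng):
        d = rng.uniform(size=(6, 6))
        d = (d + d.T) / 2
        assert_allclose(joint_distance_matrix(d, d), d, atol=1e-15)

    def test_one_zero_pair(self):
        jd = joint_distance_matrix(np.array([[1.0]]), np.array([[0.0]]))
        assert_allclose(jd, [[1.0]])

    def test_zeros(self):
        z = np.zeros((3, 3))
        assert_allclose(joint_distance_matrix(z, z), z)

    def test_entries_above_one_rejected(self):
        with pytest.raises(DomainError):
            joint_distance_matrix(np.array([[1.5]]), np.array([[0.5]]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=2, max_value=8), st.integers(min_value=0, max_value=2**31 - 1))
    def test_range_and_symmetry_property(self, size, seed):
        r = np.random.default_rng(seed)
        d1 = r.uniform(size=(size, size))
        d2 = r.uniform(size=(size, size))
        d1, d2 = (d1 + d1.T) / 2, (d2 + d2.T) / 2
        jd = joint_distance_matrix(d1, d2)
        assert np.all(jd >= -1e-15) and np.all(jd <= 1 + 1e-15)
        assert_allclose(jd, jd.T)


class TestDoane:
    def test_symmetric_values_sturges_limit(self):
        values = np.linspace(0.0, 1.0, 20)  # zero skew: reduces to Sturges
        h = doane_bins(values)
        assert h.g1 == pytest.approx(0.0, abs=1e-12)
        assert h.b_raw == pytest.approx(1 + math.log2(20), abs=1e-12)
        assert h.bins == 5

    def test_sigma_g1_formula(self):
        h = doane_bins(np.linspace(0, 1, 20))
        assert h.sigma_g1 == pytest.approx(math.sqrt(6 * 18 / (21 * 23)), abs=1e-12)
        assert h.sigma_g1 == pytest.approx(0.4729, abs=5e-5)

    def test_constant_values_use_zero_skew(self):
        h = doane_bins(np.full(20, 0.3))
        assert h.g1 == 0.0
        assert h.bins == round(1 + math.log2(20))

    def test_too_few_observations(self):
        with pytest.raises(TooFewObservationsError):
            doane_bins(np.array([0.1, 0.2, 0.3]))


class TestEntropy:
    def test_uniform_histogram_gives_one(self):
        for bins in (2, 5, 9):
            h = JointHistogram(bins=bins, b_raw=0, g1=0, sigma_g1=1, n_obv=bins,
                               rho=np.full(bins, 1.0 / bins))
            assert jdisten_from_histogram(h) == pytest.approx(1.0, abs=1e-15)

    def test_single_bin_mass_gives_zero(self):
        h = JointHistogram(bins=4, b_raw=0, g1=0, sigma_g1=1, n_obv=10,
                           rho=np.array([0.0, 1.0, 0.0, 0.0]))
        assert jdisten_from_histogram(h) == 0.0

    def test_two_equal_bins(self):
        h = JointHistogram(bins=2, b_raw=0, g1=0, sigma_g1=1, n_obv=2,
                           rho=np.array([0.5, 0.5]))
        assert jdisten_from_histogram(h) == pytest.approx(1.0)

    def test_degenerate_bin_count_rejected(self):
        h = JointHistogram(bins=1, b_raw=0, g1=0, sigma_g1=1, n_obv=4,
                           rho=np.ones(1))
        with pytest.raises(NormalizationError):
            jdisten_from_histogram(h)

    def test_histogram_mass_conservation(self, rng):
        values = rng.uniform(size=90)
        h = joint_histogram(values)
        assert h.rho.sum() == pytest.approx(1.0, abs=1e-12)
        assert h.counts.sum() == h.n_obv


class TestCouplingMatrix:
    def test_identical_channels_reduce_to_single_channel_case(self, rng):
        u = rng.uniform(size=12)
        w = coupling_matrix(np.vstack([u, u]))
        from jdnet.jdisten import pair_jdisten

        d = channel_distance_matrix(embed(u))
        assert w[0, 1] == pytest.approx(pair_jdisten(d, d), abs=1e-15)

    def test_symmetric_zero_diagonal_unit_range(self, rng):
        data = rng.uniform(size=(5, 30))
        w = coupling_matrix(data)
        assert_allclose(w, w.T)
        assert_allclose(np.diag(w), 0)
        off = off_diagonal(w)
        assert np.all(off >= 0) and np.all(off <= 1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_straight_line_oracle(self, seed, random_recording):
        raw = random_recording(n_channels=3, n_samples=8, seed=seed)
        w = coupling_matrix(np.array([np.interp(c, (c.min(), c.max()), (0, 1)) for c in raw]))
        expected = np.array(coupling_matrix_oracle([list(c) for c in raw]))
        assert_allclose(w, expected, atol=1e-12)

    def test_affine_invariance_of_raw_channels(self, rng):
        raw = rng.normal(size=(3, 20))
        scaled = raw.copy()
        scaled[1] = 5.0 * scaled[1] - 2.0  # positive gain + offset
        def pipe(x):
            return coupling_matrix(
                np.array([(c - c.min()) / (c.max() - c.min()) for c in x])
            )
        assert_allclose(pipe(raw), pipe(scaled), atol=1e-12)
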