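"""Binning, Renyi entropies, generalized dimensions and their oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import preictal as p
from preictal.fractal import (binomial_cascade_dimension,
                              binomial_cascade_series)
from preictal.io import EEGRecord


class TestBinProbabilities:
    def test_constant_series_single_unit_bin(self):
        dist = p.bin_probabilities(np.full(50, 3.0), 0.5)
        assert dist.n_bins == 1
        np.testing.assert_allclose(dist.weights, [1.0])

    def test_alternating_series_splits_evenly(self):
        dist = p.bin_probabilities(np.array([0, 1, 0, 1.0]), 0.5)
        occ = dist.weights[dist.weights > 0]
        np.testing.assert_allclose(sorted(occ), [0.5, 0.5])

    def test_bin_count_formula(self):
        x = np.linspace(0.0, 10.0, 1000)
        assert p.bin_probabilities(x, 1.0).n_bins == 10

    def test_nonpositive_bin_size_rejected(self):
        with pytest.raises(ValueError):
            p.bin_probabilities([1.0, 2.0], 0.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.25, 4.0), st.floats(-5.0, 5.0))
    def test_normalization_and_affine_covariance(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=100)
        d0 = p.bin_probabilities(x, 0.3)
        assert d0.weights.sum() == pytest.approx(1.0, abs=1e-12)
        d1 = p.bin_probabilities(a * x + b, a * 0.3)
        np.testing.assert_array_equal(d0.counts, d1.counts)


class TestRenyiEntropy:
    def test_uniform_equals_log2_n_at_any_q(self):
        w = np.full(8, 0.125)
        for q in (-5.0, 0.0, 0.5, 1.0, 2.0, 5.0):
            assert p.renyi_entropy(w, q) == pytest.approx(3.0, abs=1e-9)

    def test_hand_evaluated_collision_entropy(self):
        assert p.renyi_entropy(np.array([0.5, 0.25, 0.25]), 2.0) == \
            pytest.approx(-np.log2(0.375), abs=1e-12)

    def test_shannon_limit(self):
        assert p.renyi_entropy(np.array([0.5, 0.5]), 1.0) == pytest.approx(1.0)

    def test_continuous_through_q_equals_one(self):
        w = np.array([0.6, 0.3, 0.1])
        e1 = p.renyi_entropy(w, 1.0)
        assert abs(p.renyi_entropy(w, 1.0 + 1e-6) - e1) < 1e-4
        assert abs(p.renyi_entropy(w, 1.0 - 1e-6) - e1) < 1e-4

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=20),
           st.floats(-8.0, 8.0), st.floats(-8.0, 8.0))
    def test_nonincreasing_in_q(self, raw, q1, q2):
        w = np.asarray(raw) / np.sum(raw)
        lo, hi = sorted((q1, q2))
        assert p.renyi_entropy(w, lo) >= p.renyi_entropy(w, hi) - 1e-9


class TestGeneralizedDimension:
    def test_constant_series_dimension_zero(self):
        fit = p.generalized_dimension(np.full(256, 1.5), 2.0,
                                      delta_v_grid=[0.1, 0.2, 0.4, 0.8])
        assert fit.d == 0.0
        assert np.isnan(fit.r2)

    @pytest.mark.parametrize("q", [0.0, 1.0, 2.0])
    def test_uniform_marginal_fills_one_dimension(self, q):
        x = np.random.default_rng(0).uniform(size=16384)
        assert p.generalized_dimension(x, q).d == pytest.approx(1.0, abs=0.1)

    def test_cascade_matches_closed_form(self):
        x = binomial_cascade_series(levels=7, p=0.7, total=200_000)
        grid = 2.0 ** -np.arange(1, 8)
        for q in range(-5, 6):
            ref = binomial_cascade_dimension(q, 0.7)
            assert p.generalized_dimension(x, float(q), grid).d == \
                pytest.approx(ref, abs=0.05)

    def test_grid_validation(self):
        x = np.random.default_rng(1).normal(size=256)
        with pytest.raises(ValueError):
            p.generalized_dimension(x, 1.0, delta_v_grid=[0.1, 0.11, 0.12, 0.13])


class TestFractalSpectrum:
    def test_constant_series_flat_zero(self):
        sp = p.fractal_spectrum(np.full(128, 2.0))
        assert np.all(sp.dimensions == 0.0)
        assert sp.spectrum_range == 0.0

    def test_uniform_series_is_monofractal(self):
        x = np.random.default_rng(2).uniform(size=32768)
        sp = p.fractal_spectrum(x, q_grid=np.arange(-5.0, 6.0))
        assert sp.spectrum_range <= 0.15
        assert sp.spectrum_range >= -0.02

    def test_cascade_is_multifractal_and_monotone(self):
        x = binomial_cascade_series(levels=7, p=0.7, total=200_000)
        sp = p.fractal_spectrum(x, q_grid=np.arange(-5.0, 6.0),
                                delta_v_grid=2.0 ** -np.arange(1, 8))
        assert sp.spectrum_range >= 0.3
        assert np.all(np.diff(sp.dimensions) <= 0.02)

    def test_entropy_at_q0_counts_occupied_bins(self):
        x = np.random.default_rng(3).normal(size=512)
        sp = p.fractal_spectrum(x, q_grid=np.array([0.0]))
        finest = p.bin_probabilities(x, float(sp.delta_v_grid.min()))
        assert sp.entropies[0] == pytest.approx(
            np.log2(np.count_nonzero(finest.counts)), abs=1e-9)


class TestSlidingFd:
    def test_trajectory_length(self, seizure_decimated):
        dec, _ = seizure_decimated
        traj = p.sliding_fd(dec, 0)
        assert len(traj) == 171

    def test_constant_record_all_zero(self):
        rec = EEGRecord(data=np.full((1, 3500), 1.0), fs=35.0)
        traj = p.sliding_fd(rec, 0)
        assert np.all(traj.values == 0.0)

    def test_seizure_record_shows_fd_rise(self, seizure_decimated):
        dec, ann = seizure_decimated
        traj = p.sliding_fd(dec, p.select_dominant_channel(dec))
        before = traj.values[traj.times < ann.t_precursor - 5]
        after = traj.values[(traj.times > ann.t_precursor + 5)
                            & (traj.times < ann.t_onset)]
        assert np.nanmean(after) > np.nanmean(before)
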