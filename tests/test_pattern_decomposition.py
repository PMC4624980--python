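"""Pattern transform, SVD truncation, spherical leadfield, MUSIC."""

import numpy as np
import pytest

from cacor import (
    SpatioTemporalPattern,
    build_leadfield,
    dipole_field,
    filter_to_pattern,
    fit_ridge,
    match_component,
    music_decompose,
    reference_pattern,
    standard_positions,
    svd_reduce,
)
from cacor.data_io import STANDARD_61
from cacor.eeg_regression import EmbeddedDesign, SpatioTemporalFilter
from cacor.pattern_decomposition import MusicComponent, pattern_to_filter
from conftest import MONTAGE_19


def _design(M, n_ch, L, labels=None):
    return EmbeddedDesign(
        matrix=M,
        n_lags=L,
        source_rate=100.0,
        channel_labels=labels or [f"ch{i}" for i in range(n_ch)],
    )


def _cos(a, b):
    a, b = np.ravel(a), np.ravel(b)
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


class TestFilterToPattern:
    def test_whitened_design_pattern_proportional_to_filter(self):
        rng = np.random.default_rng(0)
        M = rng.standard_normal((20000, 6))  # empirical covariance ~ I
        X = _design(M, 3, 1)
        w = rng.standard_normal(6)
        f = SpatioTemporalFilter(
            weights=w.reshape(3, 2), intercept=0.0, shrinkage=0.0,
            channel_labels=X.channel_labels, source_rate=100.0,
        )
        A = filter_to_pattern(f, X).pattern
        assert abs(_cos(A, w.reshape(3, 2))) > 0.99

    def test_single_source_forward_model_recovery(self):
        # x = a s + noise with uncorrelated noise: pattern ~ a
        rng = np.random.default_rng(1)
        n, n_ch = 5000, 8
        s = rng.standard_normal(n)
        a = rng.standard_normal(n_ch)
        Xm = np.outer(s, a) + 0.5 * rng.standard_normal((n, n_ch))
        X = _design(Xm, n_ch, 0)
        f = fit_ridge(X, s, shrinkage=0.0)
        A = filter_to_pattern(f, X).pattern.ravel()
        assert abs(_cos(A, a)) >= 0.95

    def test_invariant_to_filter_rescaling(self):
        rng = np.random.default_rng(2)
        M = rng.standard_normal((1000, 6))
        X = _design(M, 3, 1)
        w = rng.standard_normal(6)
        mk = lambda wv: SpatioTemporalFilter(
            weights=wv.reshape(3, 2), intercept=0.0, shrinkage=0.0,
            channel_labels=X.channel_labels, source_rate=100.0,
        )
        A1 = filter_to_pattern(mk(w), X).pattern
        A2 = filter_to_pattern(mk(3.7 * w), X).pattern
        np.testing.assert_allclose(A1, A2 * np.linalg.norm(A1) / np.linalg.norm(A2), atol=1e-9)

    def test_zero_variance_output_errors(self):
        X = _design(np.random.default_rng(3).standard_normal((100, 4)), 2, 1)
        f = SpatioTemporalFilter(
            weights=np.zeros((2, 2)), intercept=0.0, shrinkage=0.0,
            channel_labels=X.channel_labels, source_rate=100.0,
        )
        with pytest.raises(ValueError):
            filter_to_pattern(f, X)

    def test_inverse_transform_recovers_filter_direction(self):
        rng = np.random.default_rng(4)
        M = rng.standard_normal((2000, 8)) * np.linspace(0.5, 2.0, 8)
        X = _design(M, 4, 1)
        w = rng.standard_normal(8)
        f = SpatioTemporalFilter(
            weights=w.reshape(4, 2), intercept=0.0, shrinkage=0.0,
            channel_labels=X.channel_labels, source_rate=100.0,
        )
        P = filter_to_pattern(f, X)
        w_back = pattern_to_filter(P, X)
        assert abs(_cos(w_back, w)) >= 1 - 1e-6


class TestSvdReduce:
    def _pat(self, M):
        return SpatioTemporalPattern(M, [f"ch{i}" for i in range(M.shape[0])])

    def test_rank_one_needs_one_factor(self):
        M = np.outer(np.arange(1.0, 5.0), np.arange(1.0, 7.0))
        fac = svd_reduce(self._pat(M), 0.98)
        assert fac.k == 1
        assert fac.retained_fraction > 0.999999

    def test_singular_value_arithmetic(self):
        # singular values 3 and 1: one factor covers 9/10 of the squared mass
        M = np.zeros((4, 6))
        M[0, 0], M[1, 1] = 3.0, 1.0
        fac = svd_reduce(self._pat(M), var_frac=0.9)
        assert fac.k == 1
        fac2 = svd_reduce(self._pat(M), var_frac=0.91)
        assert fac2.k == 2

    def test_reconstruction_error_bound(self):
        rng = np.random.default_rng(0)
        M = rng.standard_normal((8, 31))
        for frac in (0.5, 0.9, 0.98):
            fac = svd_reduce(self._pat(M), frac)
            err = np.linalg.norm(M - fac.reconstruct()) / np.linalg.norm(M)
            assert err <= np.sqrt(1 - frac) + 1e-9

    def test_retained_variance_monotone_in_var_frac(self):
        rng = np.random.default_rng(1)
        M = rng.standard_normal((8, 31))
        fracs = [0.3, 0.6, 0.9, 0.98, 1.0]
        retained = [svd_reduce(self._pat(M), f).retained_fraction for f in fracs]
        assert np.all(np.diff(retained) >= -1e-12)

    def test_zero_matrix_errors(self):
        with pytest.raises(ValueError):
            svd_reduce(self._pat(np.zeros((4, 5))), 0.98)


class TestLeadfield:
    @pytest.fixture(scope="class")
    def head(self):
        pos = standard_positions(MONTAGE_19)
        return build_leadfield(pos, grid_spacing=0.2, channel_labels=MONTAGE_19)

    def test_gain_finite_and_nonzero(self, head):
        assert np.all(np.isfinite(head.gain))
        norms = np.linalg.norm(head.gain, axis=0)
        assert np.all(norms > 0)

    def test_average_reference_columns_sum_to_zero(self, head):
        np.testing.assert_allclose(head.gain.sum(axis=0), 0.0, atol=1e-10)

    def test_radial_vertex_dipole_peaks_at_cz(self):
        pos = standard_positions(STANDARD_61)
        v = dipole_field(pos, [0.0, 0.0, 0.7], [0.0, 0.0, 1.0])
        assert STANDARD_61[int(np.argmax(np.abs(v)))] == "Cz"
        assert v[STANDARD_61.index("Cz")] > 0

    def test_off_sphere_electrode_rejected(self):
        pos = standard_positions(MONTAGE_19)
        bad = pos.copy()
        bad[0] *= 1.01
        with pytest.raises(ValueError):
            build_leadfield(bad, grid_spacing=0.2)

    def test_grid_radii_bounded(self, head):
        r = np.linalg.norm(head.grid, axis=1)
        assert r.min() >= 0.3 - 1e-9
        assert r.max() <= 0.85 + 1e-9


class TestMusic:
    @pytest.fixture(scope="class")
    def head(self):
        pos = standard_positions(STANDARD_61)
        return build_leadfield(pos, grid_spacing=0.15, channel_labels=STANDARD_61)

    def test_single_dipole_recovered_exactly(self, head):
        rng = np.random.default_rng(0)
        gi = rng.integers(len(head.grid))
        o = rng.standard_normal(3)
        o /= np.linalg.norm(o)
        field = head.gain_at(gi) @ o
        P = np.outer(field, rng.standard_normal(31))
        fac = svd_reduce(SpatioTemporalPattern(P, list(STANDARD_61)), 0.98)
        comps = music_decompose(fac, head)
        assert len(comps) == 1
        assert abs(_cos(comps[0].spatial_map, field)) >= 0.99
        assert np.linalg.norm(comps[0].dipole_location - head.grid[gi]) <= head.grid_spacing

    def test_two_separated_dipoles_recovered(self, head):
        rng = np.random.default_rng(1)
        # anterior and posterior dipoles, equal power
        i1 = int(np.argmin(np.linalg.norm(head.grid - [0, 0.5, 0.4], axis=1)))
        i2 = int(np.argmin(np.linalg.norm(head.grid - [0, -0.5, 0.4], axis=1)))
        f1 = head.gain_at(i1) @ np.array([0.0, 0.6, 0.8])
        f2 = head.gain_at(i2) @ np.array([0.0, -0.6, 0.8])
        f1, f2 = f1 / np.linalg.norm(f1), f2 / np.linalg.norm(f2)
        t1, t2 = rng.standard_normal(31), rng.standard_normal(31)
        P = np.outer(f1, t1) + np.outer(f2, t2)
        fac = svd_reduce(SpatioTemporalPattern(P, list(STANDARD_61)), 0.999)
        comps = music_decompose(fac, head)
        assert len(comps) >= 2
        best1 = max(abs(_cos(c.spatial_map, f1)) for c in comps)
        best2 = max(abs(_cos(c.spatial_map, f2)) for c in comps)
        assert best1 >= 0.95 and best2 >= 0.95

    def test_component_count_within_bounds(self, head):
        rng = np.random.default_rng(2)
        P = rng.standard_normal((61, 31))
        fac = svd_reduce(SpatioTemporalPattern(P, list(STANDARD_61)), 0.5)
        comps = music_decompose(fac, head, n_max=4)
        assert 1 <= len(comps) <= 4
        for c in comps:
            np.testing.assert_allclose(np.linalg.norm(c.spatial_map), 1.0, atol=1e-9)
            assert 0 < c.explained_variance <= 1 + 1e-9


class TestReferencePattern:
    def _epoch(self, topo, peak_idx, n=30):
        tc = np.zeros(n)
        tc[peak_idx] = 1.0
        return np.outer(topo, tc)

    def test_single_subject_peak_topography(self):
        topo = np.array([1.0, 0.5, -0.3, 0.1])
        labels = ["Fz", "Cz", "Pz", "Oz"]
        erps = {"S1": self._epoch(topo, 20)}
        ref = reference_pattern(erps, labels, rate=100.0)
        assert abs(_cos(ref, topo)) > 0.999

    def test_different_latencies_same_topography(self):
        topo = np.array([1.0, 0.5, -0.3, 0.1])
        labels = ["Fz", "Cz", "Pz", "Oz"]
        erps = {"S1": self._epoch(topo, 15), "S2": self._epoch(topo, 25)}
        ref = reference_pattern(erps, labels, rate=100.0)
        assert abs(_cos(ref, topo)) > 0.999

    def test_planted_dipole_erp_recovered(self):
        pos = standard_positions(STANDARD_61)
        field = dipole_field(pos, [0.0, 0.3, 0.65], [0.0, 0.42, 0.91])
        rng = np.random.default_rng(0)
        erps = {}
        for s in range(5):
            tc = np.zeros(30)
            peak = 16 + s
            tc[peak] = 1.0
            erps[f"S{s}"] = np.outer(field, tc) + 0.01 * rng.standard_normal((61, 30))
        ref = reference_pattern(erps, STANDARD_61, rate=100.0)
        assert abs(_cos(ref, field)) >= 0.98

    def test_missing_channel_errors(self):
        with pytest.raises(ValueError):
            reference_pattern({"S1": np.zeros((2, 30))}, ["Cz", "Pz"], 100.0)


class TestMatchComponent:
    def _comp(self, vec, ev):
        v = np.asarray(vec, float)
        return MusicComponent(
            spatial_map=v / np.linalg.norm(v),
            time_course=np.zeros(31),
            dipole_location=np.zeros(3),
            dipole_orientation=np.array([0, 0, 1.0]),
            explained_variance=ev,
            subspace_correlation=0.9,
        )

    def test_exact_match_selected_with_similarity_one(self):
        ref = np.array([1.0, 2.0, -1.0, 0.5])
        comps = [self._comp([0, 1, 0, 0.0], 0.5), self._comp(ref, 0.3)]
        chosen, sim = match_component(comps, ref)
        assert chosen is comps[1]
        assert sim == pytest.approx(1.0)

    def test_orthogonal_reference_falls_back_to_variance(self):
        comps = [self._comp([1, 0, 0, 0.0], 0.2), self._comp([0, 1, 0, 0.0], 0.7)]
        ref = np.array([0.0, 0.0, 0.0, 1.0])
        chosen, sim = match_component(comps, ref)
        assert sim == pytest.approx(0.0)
        assert chosen is comps[1]  # larger explained variance

    def test_selection_invariant_to_sign_flips(self):
        ref = np.array([1.0, 1.0, 0.0, 0.0])
        comps = [self._comp([1, 0.9, 0, 0.0], 0.5), self._comp([0, 0, 1, 1.0], 0.5)]
        flipped = [self._comp(-np.asarray([1, 0.9, 0, 0.0]), 0.5), comps[1]]
        c1, s1 = match_component(comps, ref)
        c2, s2 = match_component(flipped, ref)
        assert s1 == pytest.approx(s2)
        assert np.allclose(np.abs(c1.spatial_map), np.abs(c2.spatial_map))
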