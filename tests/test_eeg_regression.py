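"""Preprocessing, temporal embedding, shrinkage-ridge regression."""

import numpy as np
import pytest

from cacor import (
    EEGRecording,
    analytic_shrinkage,
    apply_filter,
    cacor,
    crossval_projections,
    embed,
    embed_concat,
    erp_average,
    fit_ridge,
    load_filter,
    preprocess,
    save_filter,
)
from cacor.data_io import STANDARD_61
from cacor.eeg_regression import SpatioTemporalFilter
from conftest import MONTAGE_8


def _rec(data, rate=100.0, labels=None):
    labels = labels or MONTAGE_8[: data.shape[0]]
    return EEGRecording(data, rate, labels)


class TestPreprocess:
    def test_output_rate_is_100(self):
        rec = _rec(np.random.default_rng(0).standard_normal((4, 5000)), rate=500.0,
                   labels=MONTAGE_8[:4])
        out = preprocess(rec)
        assert out.rate == 100.0
        assert out.n_samples == 1000

    def test_dc_offset_removed(self):
        rec = _rec(np.full((4, 4000), 35.0) , rate=200.0, labels=MONTAGE_8[:4])
        out = preprocess(rec)
        assert np.max(np.abs(out.data.mean(axis=1))) < 0.1

    def test_passband_and_stopband_gains(self):
        rate = 500.0
        t = np.arange(int(20 * rate)) / rate
        for freq, check in [(10.0, "pass"), (60.0, "stop")]:
            sig = np.sin(2 * np.pi * freq * t)
            out = preprocess(_rec(np.tile(sig, (4, 1)), rate=rate, labels=MONTAGE_8[:4]))
            core = out.data[0][100:-100]  # ignore filter edges
            gain = core.std() / sig.std()
            if check == "pass":
                assert 0.9 <= gain <= 1.1
            else:
                assert gain < 0.1  # > 20 dB attenuation

    def test_rate_below_target_errors(self):
        with pytest.raises(ValueError):
            preprocess(_rec(np.zeros((4, 100)), rate=50.0, labels=MONTAGE_8[:4]))


class TestEmbed:
    def test_zero_lags_is_transposed_data(self):
        data = np.random.default_rng(0).standard_normal((4, 50))
        X = embed(_rec(data, labels=MONTAGE_8[:4]), n_lags=0)
        np.testing.assert_allclose(X.matrix, data.T)

    def test_61_channels_30_lags_gives_1891_columns(self):
        data = np.zeros((61, 40))
        X = embed(EEGRecording(data, 100.0, STANDARD_61), n_lags=30)
        assert X.matrix.shape[1] == 61 * 31 == 1891

    def test_latency_convention(self):
        # column (c, l=5) at row 100 holds channel c at sample 105
        data = np.random.default_rng(1).standard_normal((3, 200))
        X = embed(_rec(data, labels=MONTAGE_8[:3]), n_lags=6)
        for c in range(3):
            assert X.matrix[100, c * 7 + 5] == data[c, 105]

    def test_padding_rows_marked_invalid(self):
        data = np.random.default_rng(2).standard_normal((2, 50))
        X = embed(_rec(data, labels=MONTAGE_8[:2]), n_lags=10)
        assert X.valid.sum() == 40
        assert not X.valid[-1]
        # padded region reads zeros beyond the end
        assert X.matrix[49, 0 * 11 + 10] == 0.0

    def test_lag_count_exceeding_samples_errors(self):
        with pytest.raises(ValueError):
            embed(_rec(np.zeros((2, 10)), labels=MONTAGE_8[:2]), n_lags=10)

    def test_concat_never_spans_boundary(self):
        rng = np.random.default_rng(3)
        recs = [_rec(rng.standard_normal((2, 30)), labels=MONTAGE_8[:2]) for _ in range(2)]
        X = embed_concat(recs, n_lags=5)
        assert X.matrix.shape == (60, 12)
        assert X.segments == [(0, 30), (30, 60)]
        # final rows of the first segment are invalid and zero-padded
        assert not X.valid[29]
        assert X.matrix[29, 5] == 0.0  # lag-5 column past the segment end


class TestAnalyticShrinkage:
    def test_consistency_anisotropic_large_sample(self):
        # with n >> p and an anisotropic covariance the empirical
        # covariance is reliable, so the analytic shrinkage vanishes
        rng = np.random.default_rng(0)
        X = rng.standard_normal((5000, 20)) * np.linspace(0.2, 3.0, 20)
        assert analytic_shrinkage(X) < 0.05

    def test_isotropic_data_shrinks_fully(self):
        # the target nu*I equals the true covariance of isotropic data:
        # full shrinkage is the optimal estimate
        X = np.random.default_rng(1).standard_normal((2000, 20))
        assert analytic_shrinkage(X) > 0.9

    def test_tiny_sample_shrinkage_near_one(self):
        X = np.random.default_rng(2).standard_normal((2, 1891))
        assert analytic_shrinkage(X) == 1.0

    def test_zero_variance_design_full_shrinkage(self):
        X = np.ones((50, 10))
        assert analytic_shrinkage(X) == 1.0

    def test_duplicated_rows_do_not_crash(self):
        row = np.random.default_rng(3).standard_normal(30)
        lam = analytic_shrinkage(np.tile(row, (40, 1)))
        assert lam == 1.0


def _toy_design(n, p, seed=0, labels=None):
    """Plain (lag-free) design wrapped as an EmbeddedDesign."""
    from cacor.eeg_regression import EmbeddedDesign

    rng = np.random.default_rng(seed)
    M = rng.standard_normal((n, p))
    labels = labels or [f"ch{i}" for i in range(p)]
    return EmbeddedDesign(
        matrix=M, n_lags=0, source_rate=100.0, channel_labels=labels
    )


class TestFitRidge:
    def test_exact_interpolation_at_zero_shrinkage(self):
        X = _toy_design(10, 3, seed=0)
        beta = np.array([1.5, -2.0, 0.5])
        y = X.matrix @ beta
        f = fit_ridge(X, y, shrinkage=0.0)
        resid = X.matrix @ f.flat + f.intercept - y
        assert np.max(np.abs(resid)) < 1e-8

    def test_matches_ols_oracle(self):
        rng = np.random.default_rng(1)
        X = _toy_design(200, 5, seed=1)
        y = X.matrix @ rng.standard_normal(5) + rng.standard_normal(200)
        f = fit_ridge(X, y, shrinkage=0.0)
        # normal-equations oracle on the centred problem
        Mc = X.matrix - X.matrix.mean(axis=0)
        yc = y - y.mean()
        beta = np.linalg.solve(Mc.T @ Mc, Mc.T @ yc)
        np.testing.assert_allclose(f.flat, beta, rtol=1e-6, atol=1e-9)

    def test_full_shrinkage_closed_form(self):
        X = _toy_design(300, 4, seed=2)
        y = np.random.default_rng(3).standard_normal(300)
        f = fit_ridge(X, y, shrinkage=1.0)
        Mc = X.matrix - X.matrix.mean(axis=0)
        yc = y - y.mean()
        S = Mc.T @ Mc / 299
        cxy = Mc.T @ yc / 299
        nu = np.trace(S) / 4
        np.testing.assert_allclose(f.flat, cxy / nu, rtol=1e-9)

    def test_length_mismatch_and_nonfinite_errors(self):
        X = _toy_design(50, 3)
        with pytest.raises(ValueError):
            fit_ridge(X, np.zeros(40))
        with pytest.raises(ValueError):
            fit_ridge(X, np.full(50, np.nan))

    def test_oracle_equivalence_larger_instances(self):
        # covariance-form ridge at zero shrinkage == OLS up to 500 x 50
        rng = np.random.default_rng(4)
        for n, p in [(100, 10), (500, 50)]:
            X = _toy_design(n, p, seed=n)
            y = X.matrix @ rng.standard_normal(p) + 0.3 * rng.standard_normal(n)
            f = fit_ridge(X, y, shrinkage=0.0)
            Mc = X.matrix - X.matrix.mean(axis=0)
            beta = np.linalg.solve(Mc.T @ Mc, Mc.T @ (y - y.mean()))
            assert np.linalg.norm(f.flat - beta) / np.linalg.norm(beta) < 1e-6


class TestApplyFilter:
    def _unit_filter(self, n_ch, L, c, lag, labels):
        w = np.zeros((n_ch, L + 1))
        w[c, lag] = 1.0
        return SpatioTemporalFilter(
            weights=w, intercept=0.0, shrinkage=0.0,
            channel_labels=labels, source_rate=100.0,
        )

    def test_weight_at_lag_zero_reproduces_channel(self):
        data = np.random.default_rng(0).standard_normal((3, 100))
        rec = _rec(data, labels=MONTAGE_8[:3])
        f = self._unit_filter(3, 4, c=1, lag=0, labels=MONTAGE_8[:3])
        proj = apply_filter(f, rec)
        np.testing.assert_allclose(proj.values, data[1])

    def test_weight_at_lag_k_advances_channel(self):
        data = np.random.default_rng(1).standard_normal((3, 100))
        rec = _rec(data, labels=MONTAGE_8[:3])
        f = self._unit_filter(3, 4, c=2, lag=3, labels=MONTAGE_8[:3])
        proj = apply_filter(f, rec)
        np.testing.assert_allclose(proj.values[:97], data[2, 3:])
        np.testing.assert_allclose(proj.values[97:], 0.0)

    def test_channel_mismatch_errors(self):
        rec = _rec(np.zeros((3, 50)), labels=MONTAGE_8[:3])
        f = self._unit_filter(3, 2, 0, 0, labels=["Cz", "Fz", "Pz"])
        with pytest.raises(ValueError):
            apply_filter(f, rec)

    def test_training_prediction_matches_ols_correlation(self):
        # applying the zero-shrinkage filter to its own training recording
        # performs at least as well as the OLS oracle prediction
        rng = np.random.default_rng(5)
        data = rng.standard_normal((4, 300))
        rec = _rec(data, labels=MONTAGE_8[:4])
        X = embed(rec, n_lags=5)
        y = rng.standard_normal(300) + X.matrix[:, 2]
        f = fit_ridge(X, y, shrinkage=0.0)
        proj = apply_filter(f, rec)
        v = X.valid
        r_fit = np.corrcoef(proj.values[v], y[v])[0, 1]
        Mc = X.matrix[v] - X.matrix[v].mean(axis=0)
        beta = np.linalg.lstsq(Mc, y[v] - y[v].mean(), rcond=None)[0]
        r_ols = np.corrcoef(Mc @ beta, y[v] - y[v].mean())[0, 1]
        assert r_fit >= r_ols - 1e-9


class TestCrossval:
    def test_planted_response_recovered(self, chord_stimulus, coupled_recordings):
        _, _, slope = chord_stimulus
        projs, filters = crossval_projections(coupled_recordings, slope)
        rs = [cacor(p, slope) for p in projs]
        assert all(r > 0.9 for r in rs)

    def test_training_ids_exclude_held_out(self, chord_stimulus, coupled_recordings):
        _, _, slope = chord_stimulus
        _, filters = crossval_projections(coupled_recordings, slope)
        for k, f in enumerate(filters):
            assert (k + 1) not in f.training_ids
            assert len(f.training_ids) == 2

    def test_shuffled_target_gives_null_correlations(self, chord_stimulus, coupled_recordings):
        _, _, slope = chord_stimulus
        rng = np.random.default_rng(0)
        y = rng.permutation(slope)
        projs, _ = crossval_projections(coupled_recordings, y)
        rs = [cacor(p, y) for p in projs]
        assert np.max(np.abs(rs)) < 0.12

    def test_requires_three_recordings(self, chord_stimulus, coupled_recordings):
        _, _, slope = chord_stimulus
        with pytest.raises(ValueError):
            crossval_projections(coupled_recordings[:2], slope)

    def test_shrinkage_path_is_continuous(self, chord_stimulus, coupled_recordings):
        # held-out correlation is a smooth function of the shrinkage
        _, _, slope = chord_stimulus
        grid = [0.001, 0.01, 0.1, 0.3, 0.6, 1.0]
        rs = []
        for lam in grid:
            projs, _ = crossval_projections(
                coupled_recordings[:3], slope, shrinkage=lam
            )
            rs.append(cacor(projs[0], slope))
        assert np.all(np.isfinite(rs))
        assert np.max(np.abs(np.diff(rs))) < 0.5


class TestFilterSerialization:
    def test_round_trip(self, tmp_path, chord_stimulus, coupled_recordings):
        _, _, slope = chord_stimulus
        _, filters = crossval_projections(coupled_recordings, slope)
        save_filter(filters[0], tmp_path / "f.json")
        back = load_filter(tmp_path / "f.json")
        np.testing.assert_allclose(back.weights, filters[0].weights)
        assert back.channel_labels == filters[0].channel_labels
        assert back.training_ids == filters[0].training_ids


class TestERPAverage:
    def test_identical_epochs_average_to_one_epoch(self):
        epoch = np.random.default_rng(0).standard_normal((2, 30))
        data = np.tile(epoch, (1, 5))
        rec = _rec(data, labels=MONTAGE_8[:2])
        avg = erp_average(rec, onsets=np.arange(5) * 0.3, epoch_len=0.3)
        np.testing.assert_allclose(avg, epoch)

    def test_epoch_length_in_samples(self):
        rec = _rec(np.zeros((2, 200)), labels=MONTAGE_8[:2])
        avg = erp_average(rec, onsets=[0.0, 0.5], epoch_len=0.3)
        assert avg.shape == (2, 30)

    def test_noise_averages_toward_planted_response(self):
        rng = np.random.default_rng(1)
        template = np.sin(2 * np.pi * 5 * np.arange(30) / 100)
        n_ep = 200
        data = rng.standard_normal((2, 30 * n_ep)) * 3.0
        for k in range(n_ep):
            data[:, 30 * k : 30 * k + 30] += template
        rec = _rec(data, labels=MONTAGE_8[:2])
        avg = erp_average(rec, onsets=np.arange(n_ep) * 0.3, epoch_len=0.3)
        assert np.max(np.abs(avg - template)) < 3 * 3.0 / np.sqrt(n_ep) * 3

    def test_out_of_range_epochs_dropped_and_empty_errors(self):
        rec = _rec(np.zeros((2, 50)), labels=MONTAGE_8[:2])
        avg = erp_average(rec, onsets=[0.0, 0.4], epoch_len=0.3)  # second dropped
        assert avg.shape == (2, 30)
        with pytest.raises(ValueError):
            erp_average(rec, onsets=[0.4], epoch_len=0.3)
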