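"""Moving-window PCA tests: windows, loadings, dissimilarity, stages, variance."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fermnir import (
    MwpcaResult,
    SimulationConfig,
    SpectralSeries,
    ZeroVarianceWindowError,
    dissimilarity_index,
    extract_windows,
    first_pc,
    loading_variance,
    run_mwpca,
    segment_stages,
    simulate_spectra,
)
from fermnir.mwpca import StageSegmentation


def _series(matrix):
    matrix = np.asarray(matrix, dtype=float)
    return SpectralSeries(
        900.0 + np.arange(matrix.shape[1], dtype=float),
        np.arange(matrix.shape[0]) * 0.25,
        matrix,
    )


def _fake_result(dissimilarity, n_channels=10, loadings=None):
    n = len(dissimilarity)
    if loadings is None:
        loadings = np.tile(np.eye(1, n_channels), (n, 1))
    return MwpcaResult(
        window_size=5,
        window_starts=np.arange(1, n + 1),
        window_start_times_h=np.arange(n) * 0.25,
        wavelengths_nm=900.0 + np.arange(n_channels, dtype=float),
        loadings=np.asarray(loadings, dtype=float),
        reference_window=1,
        reference_loading=np.asarray(loadings, dtype=float)[0],
        dissimilarity=np.asarray(dissimilarity, dtype=float),
    )


class TestExtractWindows:
    def test_default_protocol_window_count(self, default_run):
        """33 spectra with h_s = 5 give 29 windows; the last is the 29th."""
        _, _, _, pre, *_ = default_run
        windows = extract_windows(pre, 5)
        assert len(windows) == 29
        np.testing.assert_array_equal(windows[28], pre.absorbance[28:33, :])

    def test_window_contents(self):
        series = _series(np.arange(12.0).reshape(6, 2))
        windows = extract_windows(series, 3)
        assert len(windows) == 4
        np.testing.assert_array_equal(windows[1], series.absorbance[1:4])

    def test_degenerate_and_invalid_sizes(self):
        series = _series(np.ones((5, 3)))
        assert len(extract_windows(series, 5)) == 1
        with pytest.raises(ValueError):
            extract_windows(series, 6)
        with pytest.raises(ValueError):
            extract_windows(series, 1)


class TestFirstPc:
    def test_rank_one_window(self, rng):
        v = rng.normal(0, 1, 20)
        loading = first_pc(np.vstack([v, -v]), center=False)
        expected = v / np.linalg.norm(v)
        if expected[np.argmax(np.abs(expected))] < 0:
            expected = -expected
        np.testing.assert_allclose(loading, expected, atol=1e-12)

    def test_matches_covariance_eigendecomposition(self, rng):
        """Dense eigendecomposition of the window covariance as oracle."""
        for _ in range(50):
            X = rng.normal(0, 1, (5, 20))
            loading = first_pc(X)
            Xc = X - X.mean(axis=0)
            evals, evecs = np.linalg.eigh(Xc.T @ Xc)
            oracle = evecs[:, np.argmax(evals)]
            assert abs(loading @ oracle) > 1 - 1e-10

    def test_unit_norm_and_sign_convention(self, rng):
        loading = first_pc(rng.normal(0, 1, (6, 30)))
        assert np.linalg.norm(loading) == pytest.approx(1.0, abs=1e-12)
        assert loading[np.argmax(np.abs(loading))] > 0

    def test_constant_window_rejected(self):
        with pytest.raises(ZeroVarianceWindowError):
            first_pc(np.full((4, 10), 3.3))

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            first_pc(np.ones((1, 10)))


class TestDissimilarityIndex:
    def test_identical_loadings_zero(self, rng):
        p = rng.normal(0, 1, 40)
        p /= np.linalg.norm(p)
        assert dissimilarity_index(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_loadings_one(self):
        p0 = np.zeros(10)
        p0[0] = 1.0
        p1 = np.zeros(10)
        p1[3] = 1.0
        assert dissimilarity_index(p1, p0) == 1.0

    def test_sixty_degrees_half(self):
        p0 = np.array([1.0, 0.0])
        p1 = np.array([0.5, np.sqrt(3) / 2])
        assert dissimilarity_index(p1, p0) == pytest.approx(0.5, abs=1e-12)

    def test_sign_alignment(self, rng):
        """A flipped loading is the same direction: A must not change."""
        p = rng.normal(0, 1, 25)
        p /= np.linalg.norm(p)
        q = rng.normal(0, 1, 25)
        q /= np.linalg.norm(q)
        assert dissimilarity_index(-q, p) == pytest.approx(dissimilarity_index(q, p))

    @given(st.integers(2, 50))
    def test_bounds_for_random_unit_vectors(self, dim):
        rng = np.random.default_rng(dim)
        p = rng.normal(0, 1, dim)
        q = rng.normal(0, 1, dim)
        p /= np.linalg.norm(p)
        q /= np.linalg.norm(q)
        assert 0.0 <= dissimilarity_index(p, q) <= 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dissimilarity_index(np.ones(3), np.ones(4))

    def test_non_unit_inputs_normalized_with_warning(self):
        with pytest.warns(UserWarning, match="normalized"):
            value = dissimilarity_index(np.array([2.0, 0.0]), np.array([0.0, 3.0]))
        assert value == 1.0


class TestRunMwpca:
    def test_single_direction_series_all_zero(self):
        """Spectra that are scalar multiples of one direction give A == 0."""
        v = np.sin(np.linspace(0, 3, 40)) + 2.0
        scales = np.linspace(1.0, 2.0, 12)
        series = _series(np.outer(scales, v))
        result = run_mwpca(series, h_s=4)
        np.testing.assert_allclose(result.dissimilarity, 0.0, atol=1e-9)

    def test_result_shapes_and_reference(self, default_run):
        *_, result, _ = default_run
        assert result.dissimilarity.size == 33 - 5 + 1
        assert result.dissimilarity[result.reference_window - 1] == 0.0
        assert np.all((result.dissimilarity >= 0) & (result.dissimilarity <= 1))
        norms = np.linalg.norm(result.loadings, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-8)

    def test_scale_invariance(self, default_run):
        *_, pre, result, _ = default_run
        scaled = SpectralSeries(
            pre.wavelengths_nm, pre.times_h, pre.absorbance * 7.5
        )
        result2 = run_mwpca(scaled, h_s=5)
        np.testing.assert_allclose(result2.loadings, result.loadings, atol=1e-9)
        np.testing.assert_allclose(result2.dissimilarity, result.dissimilarity, atol=1e-9)

    def test_abrupt_band_change_localized(self):
        """A step change in band composition at time index c is flagged by the
        largest jump of A within windows overlapping c."""
        rng = np.random.default_rng(7)
        n, m, c, h_s = 60, 20, 12, 5
        lam = np.arange(n, dtype=float)
        base = np.exp(-0.5 * ((lam - 20) / 5.0) ** 2)
        new = np.exp(-0.5 * ((lam - 45) / 5.0) ** 2)
        drift = np.linspace(0, 1, m)
        X = np.outer(drift, base)
        X[c:, :] += np.outer(np.linspace(0.1, 1.0, m - c), new)
        X += rng.normal(0, 1e-4, X.shape)
        series = _series(X + 1.0)
        result = run_mwpca(series, h_s=h_s)
        jump_window = int(np.argmax(np.diff(result.dissimilarity))) + 2  # 1-based, post-jump
        overlapping = range(c - h_s + 1 + 1, c + 2)  # 1-based windows containing row c
        assert jump_window in overlapping

    def test_zero_variance_window_reported_with_index(self):
        X = np.ones((8, 12))
        X[5:, :] += np.outer(np.arange(3), np.sin(np.arange(12)))
        series = _series(X)
        with pytest.raises(ZeroVarianceWindowError, match="window 1"):
            run_mwpca(series, h_s=4)

    def test_invalid_reference_rejected(self, default_run):
        *_, pre, _, _ = default_run
        with pytest.raises(ValueError):
            run_mwpca(pre, h_s=5, reference_window=30)


class TestSegmentStages:
    def test_manual_breakpoints_match_protocol(self):
        """Breakpoints (10, 17) on 29 windows: stages 1-10, 11-17, 18-29."""
        result = _fake_result(np.linspace(0, 1, 29))
        seg = segment_stages(result, method="manual", breakpoints=(10, 17))
        assert np.all(seg.labels[:10] == 1)
        assert np.all(seg.labels[10:17] == 2)
        assert np.all(seg.labels[17:] == 3)

    def test_rise_fraction_on_clean_sigmoid(self):
        """Stages are contiguous, nonempty, and stage 2 brackets the midpoint."""
        x = np.arange(29, dtype=float)
        A = 1.0 / (1.0 + np.exp(-(x - 14.0)))
        result = _fake_result(A)
        seg = segment_stages(result)
        assert list(np.unique(seg.labels)) == [1, 2, 3]
        assert np.all(np.diff(seg.labels) >= 0)
        idx2 = seg.windows_in_stage(2)
        assert idx2[0] <= 14 <= idx2[-1]
        # analytic thresholds: A crosses f*(max-min)+min where the logistic
        # inverse gives x = 14 + log(f'/(1-f')) with f' rescaled
        lo = A.min() + 0.1 * (A.max() - A.min())
        assert idx2[0] == int(np.argmax(A > lo))

    def test_constant_series_single_stage_with_warning(self):
        result = _fake_result(np.zeros(10))
        with pytest.warns(UserWarning, match="constant"):
            seg = segment_stages(result)
        assert list(np.unique(seg.labels)) == [1]

    def test_monotone_labels_property(self, default_run):
        *_, seg = default_run
        assert np.all(np.diff(seg.labels) >= 0)
        assert seg.labels.min() == 1

    def test_invalid_breakpoints_rejected(self):
        result = _fake_result(np.linspace(0, 1, 10))
        with pytest.raises(ValueError):
            segment_stages(result, method="manual", breakpoints=(5, 3))
        with pytest.raises(ValueError):
            segment_stages(result, method="manual")


class TestLoadingVariance:
    def test_identical_loadings_zero_variance(self):
        p = np.full(8, 1 / np.sqrt(8))
        result = _fake_result(np.zeros(4), n_channels=8, loadings=np.tile(p, (4, 1)))
        seg = StageSegmentation(labels=np.ones(4, dtype=int), breakpoints=())
        (vs,) = loading_variance(result, seg)
        np.testing.assert_allclose(vs.variance, 0.0, atol=1e-15)

    def test_two_loading_stage_formula(self, rng):
        """Sample variance of two vectors u, w is (u - w)^2 / 2 per channel."""
        u = rng.normal(0, 1, 12)
        u /= np.linalg.norm(u)
        w = u + 0.05 * rng.normal(0, 1, 12)
        w /= np.linalg.norm(w)
        result = _fake_result(np.zeros(2), n_channels=12, loadings=np.vstack([u, w]))
        seg = StageSegmentation(labels=np.ones(2, dtype=int), breakpoints=())
        (vs,) = loading_variance(result, seg)
        np.testing.assert_allclose(vs.variance, (u - w) ** 2 / 2.0, atol=1e-12)

    def test_matches_two_pass_oracle(self, rng):
        """Brute-force two-pass variance over random sign-stable loadings."""
        loadings = rng.normal(0.5, 0.1, (6, 15))
        loadings /= np.linalg.norm(loadings, axis=1, keepdims=True)
        result = _fake_result(np.zeros(6), n_channels=15, loadings=loadings)
        seg = StageSegmentation(labels=np.ones(6, dtype=int), breakpoints=())
        (vs,) = loading_variance(result, seg)
        mean = loadings.mean(axis=0)
        oracle = ((loadings - mean) ** 2).sum(axis=0) / (6 - 1)
        np.testing.assert_allclose(vs.variance, oracle, atol=1e-12)

    def test_sign_flips_do_not_inflate_variance(self, rng):
        """Chain alignment removes arbitrary SVD sign flips inside a stage."""
        u = rng.normal(0, 1, 10)
        u /= np.linalg.norm(u)
        loadings = np.vstack([u, -u, u, -u])
        result = _fake_result(np.zeros(4), n_channels=10, loadings=loadings)
        seg = StageSegmentation(labels=np.ones(4, dtype=int), breakpoints=())
        (vs,) = loading_variance(result, seg)
        np.testing.assert_allclose(vs.variance, 0.0, atol=1e-15)

    def test_singleton_stage_rejected_by_name(self):
        result = _fake_result(np.linspace(0, 1, 5))
        seg = StageSegmentation(labels=np.array([1, 1, 1, 1, 2]), breakpoints=(4,))
        with pytest.raises(ValueError, match="stage 2"):
            loading_variance(result, seg)

    def test_variance_nonnegative_on_default_run(self, default_run):
        *_, result, seg = default_run
        for vs in loading_variance(result, seg):
            assert np.all(vs.variance >= 0)
            assert vs.variance.size == result.wavelengths_nm.size
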