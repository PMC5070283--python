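import numpy as np
import pytest

from mmfnc.gica import (
    GroupICA,
    amari_index,
    back_reconstruct,
    component_spectral_metrics,
    icasso_stability,
    reduce_group_empca,
    reduce_subject_pca,
    run_infomax,
    select_components,
    whiten,
)


def _principal_angle(A, B):
    qa, _ = np.linalg.qr(A)
    qb, _ = np.linalg.qr(B)
    s = np.linalg.svd(qa.T @ qb, compute_uv=False)
    return float(np.max(np.arccos(np.clip(s, -1.0, 1.0))))


class TestSubjectPCA:
    def test_exact_rank_reconstruction(self, rng):
        low = rng.normal(size=(30, 2)) @ rng.normal(size=(2, 50))
        model, reduced = reduce_subject_pca(low, 2)
        xc = low - low.mean(axis=1, keepdims=True)
        recon = model.basis @ reduced
        np.testing.assert_allclose(recon, xc, atol=1e-8)

    def test_matches_dense_eigensolver(self, rng):
        x = rng.normal(size=(40, 200))
        model, _ = reduce_subject_pca(x, 10)
        xc = x - x.mean(axis=1, keepdims=True)
        w, v = np.linalg.eigh(xc @ xc.T)
        direct = v[:, ::-1][:, :10]
        assert _principal_angle(model.basis, direct) < 1e-6

    def test_variances_non_increasing_and_r_bounds(self, rng):
        x = rng.normal(size=(20, 30))
        model, _ = reduce_subject_pca(x, 8)
        assert np.all(np.diff(model.variances) <= 1e-12)
        with pytest.raises(ValueError, match="exceeds"):
            reduce_subject_pca(x, 25)


class TestGroupEmPca:
    def test_matches_direct_pca_on_small_stack(self, rng):
        y = rng.normal(size=(60, 20))
        model, _ = reduce_group_empca(y, 5, seed=0)
        yc = y - y.mean(axis=1, keepdims=True)
        w, v = np.linalg.eigh(yc @ yc.T)
        assert _principal_angle(model.basis, v[:, ::-1][:, :5]) < 1e-4

    def test_full_rank_captures_total_variance(self, rng):
        y = rng.normal(size=(10, 40))
        model, reduced = reduce_group_empca(y, 10, seed=0)
        yc = y - y.mean(axis=1, keepdims=True)
        assert (reduced**2).sum() == pytest.approx((yc**2).sum(), rel=1e-8)

    def test_deterministic_given_seed(self, rng):
        y = rng.normal(size=(30, 25))
        a, _ = reduce_group_empca(y, 4, seed=7)
        b, _ = reduce_group_empca(y, 4, seed=7)
        np.testing.assert_array_equal(a.basis, b.basis)


class TestInfomax:
    def test_whitening_gives_identity_covariance(self, rng):
        x = rng.normal(size=(6, 500)) * np.arange(1, 7)[:, None]
        white, _ = whiten(x)
        cov = white @ white.T / 500
        np.testing.assert_allclose(cov, np.eye(6), atol=1e-6)

    def test_laplacian_mixture_recovered(self, rng):
        S = rng.laplace(size=(3, 5000))
        A = rng.normal(size=(3, 3))
        white, Wm = whiten(A @ S)
        dec = run_infomax(white, seed=1)
        assert amari_index(dec.unmixing @ Wm @ A) < 0.05

    def test_independent_white_input_gives_signed_permutation(self, rng):
        S = rng.laplace(size=(4, 8000))
        white, Wm = whiten(S)
        dec = run_infomax(white, seed=2)
        P = np.abs(dec.unmixing @ Wm)
        # each row dominated by a single source
        assert np.all(P.max(axis=1) / P.sum(axis=1) > 0.95)

    def test_fixed_seed_reproduces_weights(self, rng):
        x = rng.laplace(size=(3, 2000))
        white, _ = whiten(x)
        a = run_infomax(white, seed=5)
        b = run_infomax(white, seed=5)
        np.testing.assert_array_equal(a.unmixing, b.unmixing)
        assert a.lr_trace == b.lr_trace


class TestIcasso:
    def test_stable_problem_yields_high_quality_and_full_clustering(self, rng):
        S = rng.laplace(size=(3, 3000))
        A = rng.normal(size=(3, 3))
        white, _ = whiten(A @ S)
        report, dec = icasso_stability(white, 3, n_runs=5, seed=0)
        assert report.quality.shape == (3,)
        assert np.all(report.quality > 0.9)
        assert np.unique(report.assignments).size == 3
        assert dec.maps.shape == (3, 3000)

    def test_single_run_rejected(self, rng):
        with pytest.raises(ValueError, match="2 runs"):
            icasso_stability(rng.normal(size=(3, 100)), 3, n_runs=1)


class TestBackReconstruction:
    def test_forward_model_inverted(self, rng):
        maps, _ = np.linalg.qr(rng.normal(size=(200, 4)))
        maps = maps.T  # 4 x 200 orthonormal rows
        tc_true = rng.normal(size=(50, 4))
        data = tc_true @ maps
        tc_est = back_reconstruct(maps, data)
        assert tc_est.shape == (50, 4)
        for j in range(4):
            assert abs(np.corrcoef(tc_est[:, j], tc_true[:, j])[0, 1]) > 0.999

    def test_orthonormal_maps_reduce_to_projection(self, rng):
        maps, _ = np.linalg.qr(rng.normal(size=(100, 3)))
        maps = maps.T
        data = rng.normal(size=(20, 100))
        np.testing.assert_allclose(back_reconstruct(maps, data), data @ maps.T, atol=1e-10)

    def test_global_scaling_leaves_timecourse_correlations_unchanged(self, rng):
        maps = rng.normal(size=(3, 80))
        data = rng.normal(size=(40, 80))
        a = back_reconstruct(maps, data)
        b = back_reconstruct(maps, 10.0 * data)
        np.testing.assert_allclose(np.corrcoef(a.T), np.corrcoef(b.T), atol=1e-12)

    def test_rank_deficient_maps_rejected(self, rng):
        maps = np.vstack([np.ones(50), np.ones(50)])
        with pytest.raises(ValueError, match="rank"):
            back_reconstruct(maps, rng.normal(size=(10, 50)))


class TestSpectralScreening:
    def test_slow_oscillation_has_high_lf_hf_ratio(self, rng):
        t = np.arange(2000) * 2.0  # fs = 0.5 Hz
        x = np.sin(2 * np.pi * 0.05 * t) + 0.01 * rng.normal(size=2000)
        m = component_spectral_metrics(x, fs=0.5)
        assert m.lf_hf_ratio > 10
        assert m.dynamic_range > 0

    def test_white_noise_ratio_near_band_width_ratio(self):
        rng = np.random.default_rng(1)
        ratios = [
            component_spectral_metrics(rng.normal(size=2000), fs=0.5).lf_hf_ratio
            for _ in range(100)
        ]
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.3)

    def test_flat_spectrum_dynamic_range_near_zero(self):
        rng = np.random.default_rng(2)
        m = component_spectral_metrics(rng.normal(size=4096), fs=0.5, nperseg=64)
        assert m.dynamic_range < 10 * np.mean(
            [component_spectral_metrics(rng.normal(size=4096), 0.5, nperseg=64).dynamic_range
             for _ in range(5)]
        )  # no isolated spectral peak dominates

    def test_insufficient_bandwidth_rejected(self, rng):
        with pytest.raises(ValueError, match="0.15-0.25"):
            component_spectral_metrics(rng.normal(size=100), fs=0.3)

    def test_selection_rules(self, rng):
        t = np.arange(512) * 2.0
        slow = np.sin(2 * np.pi * 0.04 * t) + 0.05 * rng.normal(size=512)
        fast = np.sin(2 * np.pi * 0.2 * t) + 0.05 * rng.normal(size=512)
        metrics = [component_spectral_metrics(x, 0.5) for x in (slow, fast, slow)]
        assert select_components(metrics, lf_hf_threshold=2.0) == [0, 2]
        assert select_components(metrics, lf_hf_threshold=0.0,
                                 dynamic_range_threshold=0.0) == [0, 1, 2]


class TestGroupICAEstimator:
    def test_recovers_shared_spatial_maps(self, rng):
        # shared maps, subject-specific timecourses
        V, C = 2000, 3
        maps = rng.laplace(size=(C, V))
        subjects = [rng.normal(size=(40, C)) @ maps + 0.01 * rng.normal(size=(40, V))
                    for _ in range(4)]
        ica = GroupICA(n_components=C, subject_pcs=10, n_runs=3, seed=0).fit(subjects)
        corr = np.abs(np.corrcoef(np.vstack([ica.components_, maps]))[:C, C:])
        assert np.all(corr.max(axis=1) > 0.95)
        tc = ica.transform(subjects[0])
        assert tc.shape == (40, C)
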