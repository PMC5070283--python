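import numpy as np
import pytest

from mmfnc.dataio import Band, ComponentTimecourseSet, GroupLabel, Modality, vectorize_upper
from mmfnc.dynamic_fnc import (
    DynamicStateFeaturizer,
    WindowSpec,
    centroid_regression,
    cluster_states,
    compute_dfnc,
    dfnc_features,
    graphical_lasso,
    make_taper,
    select_lambda,
    sliding_windows,
    validity_elbow,
    weighted_covariance,
)
from mmfnc.static_fnc import static_fnc
from _oracles import admm_glasso, match_centroids, random_spd


def _tc(data, modality=Modality.FMRI, band=Band.NONE):
    return ComponentTimecourseSet(
        subject_id="s", group=GroupLabel.HC, modality=modality, band=band,
        data=data, sampling_rate=0.5,
    )


class TestTaper:
    def test_symmetric_with_central_peak(self):
        spec = make_taper(31, 3.0)
        w = spec.weights
        np.testing.assert_allclose(w, w[::-1], atol=1e-12)
        assert w[15] == pytest.approx(w.max())  # peak plateau covers the center
        assert w[0] < w[15]  # edges tapered
        assert w.sum() == pytest.approx(31.0)

    def test_zero_sigma_limit_is_rectangular(self):
        np.testing.assert_array_equal(make_taper(11, 0.0).weights, np.ones(11))

    def test_tiny_sigma_approaches_rectangle(self):
        w = make_taper(11, 1e-3).weights
        np.testing.assert_allclose(w, np.ones(11), atol=1e-6)


class TestSlidingWindows:
    @pytest.mark.parametrize("T,expected", [(149, 119), (300, 270)])
    def test_study_window_counts(self, T, expected):
        assert len(sliding_windows(T, WindowSpec(width=31, step=1))) == expected

    def test_single_window_when_t_equals_width(self):
        wins = sliding_windows(31, WindowSpec(width=31))
        assert len(wins) == 1 and wins[0][0] == 0

    def test_count_formula_matches_enumeration_grid(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            w = int(rng.integers(3, 40))
            T = int(rng.integers(w, 400))
            step = int(rng.integers(1, 10))
            brute = [s for s in range(0, T) if s + w <= T and s % step == 0]
            wins = sliding_windows(T, WindowSpec(width=w, step=step, sigma=1.0))
            assert len(wins) == len(brute) == (T - w) // step + 1

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            sliding_windows(10, WindowSpec(width=31))


class TestWeightedCovariance:
    def test_uniform_weights_equal_sample_covariance(self, rng):
        x = rng.normal(size=(40, 4))
        np.testing.assert_allclose(
            weighted_covariance(x, np.ones(40)), np.cov(x.T, bias=True), atol=1e-12
        )

    def test_one_hot_weights_give_zero_matrix(self, rng):
        x = rng.normal(size=(10, 3))
        w = np.zeros(10)
        w[4] = 1.0
        np.testing.assert_allclose(weighted_covariance(x, w), 0.0, atol=1e-15)

    def test_matches_double_loop_oracle(self, rng):
        x = rng.normal(size=(20, 5))
        w = rng.uniform(0.1, 1.0, size=20)
        wn = w / w.sum()
        mu = (wn[:, None] * x).sum(axis=0)
        oracle = np.zeros((5, 5))
        for i in range(5):
            for j in range(5):
                oracle[i, j] = np.sum(wn * (x[:, i] - mu[i]) * (x[:, j] - mu[j]))
        np.testing.assert_allclose(weighted_covariance(x, w), oracle, atol=1e-10)


class TestGraphicalLasso:
    def test_unpenalized_limit_inverts_covariance(self, rng):
        S = random_spd(5, rng)
        prec, cov = graphical_lasso(S, 0.0)
        np.testing.assert_allclose(prec, np.linalg.inv(S), atol=1e-4)

    def test_kkt_threshold_fully_sparsifies(self, rng):
        S = random_spd(5, rng)
        lam = np.abs(S - np.diag(np.diag(S))).max() * 1.01
        prec, _ = graphical_lasso(S, lam)
        off = prec - np.diag(np.diag(prec))
        np.testing.assert_allclose(off, 0.0, atol=1e-8)
        np.testing.assert_allclose(np.diag(prec), 1.0 / np.diag(S), atol=1e-6)

    def test_matches_independent_admm_solver(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            S = random_spd(5, rng)
            prec, _ = graphical_lasso(S, 0.1, max_iter=1000, tol=1e-8, enet_tol=1e-10)
            oracle = admm_glasso(S, 0.1)
            np.testing.assert_allclose(prec, oracle, atol=1e-4)

    def test_sparsity_monotone_in_penalty(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            S = random_spd(6, rng, cond=5)
            nnz = []
            for lam in (0.02, 0.05, 0.1, 0.2, 0.4):
                prec, _ = graphical_lasso(S, lam)
                off = prec[~np.eye(6, dtype=bool)]
                nnz.append(int(np.sum(np.abs(off) > 1e-6)))
            assert all(a >= b for a, b in zip(nnz, nnz[1:]))

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            graphical_lasso(np.eye(3), -0.1)


class TestSelectLambda:
    def test_singleton_grid_returned(self, rng):
        covs = [random_spd(4, rng) for _ in range(6)]
        assert select_lambda(covs, grid=(0.3,)) == 0.3

    def test_deterministic(self, rng):
        covs = [random_spd(4, rng) for _ in range(9)]
        grid = (0.01, 0.1, 0.5)
        assert select_lambda(covs, grid) == select_lambda(covs, grid)

    def test_sparse_truth_prefers_interior_penalty(self):
        # data from a sparse precision: held-out LL at lambda* beats extremes
        rng = np.random.default_rng(4)
        theta = np.eye(8)
        theta[0, 1] = theta[1, 0] = 0.4
        sigma = np.linalg.inv(theta)
        covs = []
        for _ in range(12):
            x = rng.multivariate_normal(np.zeros(8), sigma, size=15)
            covs.append(np.cov(x.T, bias=True))
        grid = (1e-4, 0.01, 0.03, 0.1, 0.3, 1.0)
        lam = select_lambda(covs, grid)
        assert grid[0] < lam < grid[-1]


class TestComputeDfnc:
    def test_window_count_and_metadata(self, rng):
        tc = _tc(rng.normal(size=(60, 5)))
        stack = compute_dfnc(tc, WindowSpec(width=21), lam=0.05)
        assert stack.n_windows == 40
        assert stack.z.shape == (40, 5, 5)
        assert stack.pair_vectors.shape == (40, 10)
        assert stack.lam == 0.05

    def test_single_full_window_reproduces_static_fnc(self, rng):
        data = rng.normal(size=(120, 5))
        data[:, 1] = 0.8 * data[:, 0] + 0.6 * rng.normal(size=120)
        tc = _tc(data)
        stack = compute_dfnc(tc, WindowSpec(width=120, sigma=3.0), lam=0.0)
        z_static = vectorize_upper(static_fnc(tc).z)
        np.testing.assert_allclose(stack.pair_vectors[0], z_static, atol=0.02)

    def test_two_state_data_has_larger_window_variance(self):
        rng = np.random.default_rng(5)
        T, C = 160, 4
        s_a = np.eye(C)
        s_a[0, 1] = s_a[1, 0] = 0.8
        s_a[2, 3] = s_a[3, 2] = -0.8
        s_b = np.eye(C)
        one = rng.multivariate_normal(np.zeros(C), s_a, size=T)
        halves = [rng.multivariate_normal(np.zeros(C), s, size=T // 4)
                  for s in (s_a, s_b, s_a, s_b)]
        two = np.vstack(halves)
        var_one = compute_dfnc(_tc(one), WindowSpec(21), lam=0.05).pair_vectors.var(0).mean()
        var_two = compute_dfnc(_tc(two), WindowSpec(21), lam=0.05).pair_vectors.var(0).mean()
        assert var_two > var_one


def _planted_windows(rng, k, n_pairs=20, per_state=150, sep_factor=5.0):
    """Window vectors from k well-separated states; returns (X, centroids, labels)."""
    centroids = rng.normal(size=(k, n_pairs))
    d_min = min(
        np.linalg.norm(centroids[i] - centroids[j])
        for i in range(k) for j in range(i + 1, k)
    )
    sigma = d_min / (sep_factor * np.sqrt(n_pairs) * 1.2)
    labels = np.repeat(np.arange(k), per_state)
    X = centroids[labels] + sigma * rng.normal(size=(k * per_state, n_pairs))
    return X, centroids, labels


class TestClusterStates:
    def test_k1_centroid_is_mean(self, rng):
        X = rng.normal(size=(30, 6))
        st = cluster_states(X, 1, seed=0)
        np.testing.assert_allclose(st.centroids[0], X.mean(axis=0), atol=1e-10)

    def test_separated_states_recovered_exactly(self, rng):
        X, true_c, true_labels = _planted_windows(rng, 3)
        st = cluster_states(X, 3, seed=0)
        corr = match_centroids(st.centroids, true_c)
        assert np.all(corr > 0.99)
        # partition identical up to relabeling
        for j in range(3):
            assert len(set(st.labels[true_labels == j])) == 1
        assert st.occupancy.sum() == X.shape[0]

    def test_fewer_windows_than_k_rejected(self, rng):
        with pytest.raises(ValueError, match="windows"):
            cluster_states(rng.normal(size=(3, 5)), 5)


class TestValidityElbow:
    def test_four_planted_states_found_across_replicates(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X, _, _ = _planted_windows(rng, 4, per_state=80)
            k_star, _ = validity_elbow(X, range(2, 9), seed=seed)
            hits += k_star == 4
        assert hits == 10

    def test_index_decreases_with_k_on_random_data(self, rng):
        X = rng.normal(size=(150, 10))
        _, index = validity_elbow(X, range(2, 7), seed=0)
        vals = [index[k] for k in sorted(index)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_singleton_range_returned(self, rng):
        X = rng.normal(size=(40, 5))
        k_star, _ = validity_elbow(X, [3], seed=0)
        assert k_star == 3


class TestCentroidRegression:
    def _orthogonal_centroids(self, n_pairs=16, k2=4):
        C = np.zeros((k2, n_pairs))
        for j in range(k2):
            C[j, j * 4 : (j + 1) * 4] = [1.0, -1.0, 2.0, -2.0]  # zero-mean rows
        return C

    def test_pure_state_window_projects_to_unit_beta(self):
        C = self._orthogonal_centroids()
        betas = centroid_regression(C[1][None, :], C)
        np.testing.assert_allclose(betas, [0, 1, 0, 0], atol=1e-10)

    def test_mixture_window_is_linear(self):
        C = self._orthogonal_centroids()
        win = 0.5 * C[0] + 0.5 * C[1]
        betas = centroid_regression(win[None, :], C)
        np.testing.assert_allclose(betas, [0.5, 0.5, 0, 0], atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        Cmat = rng.normal(size=(6, 40))
        Y = rng.normal(size=(25, 40))
        betas = centroid_regression(Y, Cmat)
        X = (Cmat - Cmat.mean(axis=1, keepdims=True)).T
        Yc = Y - Y.mean(axis=1, keepdims=True)
        oracle = np.linalg.solve(X.T @ X, X.T @ Yc.T).mean(axis=1)
        np.testing.assert_allclose(betas, oracle, atol=1e-8)

    def test_rank_deficient_design_warns_and_falls_back(self, rng):
        Cmat = rng.normal(size=(3, 20))
        Cmat[2] = Cmat[0] + Cmat[1]
        with pytest.warns(UserWarning, match="ridge"):
            betas = centroid_regression(rng.normal(size=(4, 20)), Cmat)
        assert np.all(np.isfinite(betas))


class TestDfncFeatures:
    def _two_group_stacks(self, rng, n_per_group=6, k=2, n_pairs=18, disjoint=True):
        c_a = rng.normal(size=(k, n_pairs))
        c_b = rng.normal(size=(k, n_pairs)) if disjoint else c_a
        stacks, labels = [], []
        for g, cents in (("HC", c_a), ("SZ", c_b)):
            for _ in range(n_per_group):
                idx = rng.integers(k, size=40)
                stacks.append(cents[idx] + 0.05 * rng.normal(size=(40, n_pairs)))
                labels.append(g)
        return stacks, np.array(labels)

    def test_feature_length_is_2k(self, rng):
        stacks, labels = self._two_group_stacks(rng, k=5, n_pairs=30)
        tr, te, feat = dfnc_features(stacks[:-1], labels[:-1], stacks[-1:], k=5, seed=0)
        assert tr.shape == (11, 10) and te.shape == (1, 10)
        assert feat.centroids_.shape == (10, 30)

    def test_beta_mass_concentrates_on_own_group_states(self, rng):
        stacks, labels = self._two_group_stacks(rng, k=2)
        feat = DynamicStateFeaturizer(k=2, seed=0).fit(stacks, labels)
        B = feat.transform(stacks)
        mass = np.abs(B)
        hc = labels == "HC"
        own_hc = mass[hc][:, :2].sum() / mass[hc].sum()
        own_sz = mass[~hc][:, 2:].sum() / mass[~hc].sum()
        assert own_hc > 0.6 and own_sz > 0.6

    def test_training_order_permutation_invariance(self, rng):
        stacks, labels = self._two_group_stacks(rng)
        feat_a = DynamicStateFeaturizer(k=2, seed=0).fit(stacks, labels)
        perm = rng.permutation(len(stacks))
        feat_b = DynamicStateFeaturizer(k=2, seed=0).fit(
            [stacks[i] for i in perm], labels[perm]
        )
        # centroids equal up to within-group state relabeling
        for g in ("HC", "SZ"):
            ca = feat_a.state_sets_[g].centroids
            cb = feat_b.state_sets_[g].centroids
            assert np.all(match_centroids(ca, cb) > 0.999)
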