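"""Classifier unit tests: closed-form worked cases, independent oracles
(dual KKT solve, direction-grid search), symmetry properties."""

import numpy as np
import pytest

from p300speller.classifiers import (
    BayesianLDA,
    EmptyModelError,
    FisherLDA,
    KernelSVM,
    LinearLSSVM,
    NegentropyProjection,
    SigmoidNet,
    StepwiseLDA,
    mutual_information_objective,
    n_parameters,
    score,
)


def _four_point_classes():
    """Per class, four points whose sample covariance (ddof=1) is
    diag(1, 2); summed class covariances diag(2, 4), mean difference
    (2, 2), hence w = diag(2,4)^-1 (2,2) = (1, 0.5)."""
    a, b = np.sqrt(1.5), np.sqrt(3.0)
    base = np.array([[a, 0.0], [-a, 0.0], [0.0, b], [0.0, -b]])
    X = np.vstack([base + 2.0, base])
    y = np.concatenate([np.ones(4), -np.ones(4)])
    return X, y


class TestFisherLDA:
    def test_worked_two_dimensional_case(self):
        X, y = _four_point_classes()
        m = FisherLDA().fit(X, y)
        np.testing.assert_allclose(m.weights_, [1.0, 0.5], atol=1e-12)

    def test_spherical_gaussians_give_mean_difference_direction(self, gaussian_classes):
        X, y = gaussian_classes
        m = FisherLDA().fit(X, y)
        dmu = X[y > 0].mean(axis=0) - X[y < 0].mean(axis=0)
        cos = m.weights_ @ dmu / (
            np.linalg.norm(m.weights_) * np.linalg.norm(dmu)
        )
        assert cos > 0.97

    def test_equal_means_give_zero_weights(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(30, 4))
        X = np.vstack([pts, pts])  # identical class means and covariances
        y = np.concatenate([np.ones(30), -np.ones(30)])
        m = FisherLDA().fit(X, y)
        np.testing.assert_allclose(m.weights_, 0.0, atol=1e-10)

    def test_balanced_mean_score_is_zero(self, gaussian_classes):
        X, y = gaussian_classes
        m = FisherLDA().fit(X, y)
        assert np.mean(m.decision_function(X)) == pytest.approx(0.0, abs=1e-8)

    def test_feature_permutation_permutes_weights(self, gaussian_classes):
        X, y = gaussian_classes
        perm = np.random.default_rng(5).permutation(X.shape[1])
        w1 = FisherLDA().fit(X, y).weights_
        w2 = FisherLDA().fit(X[:, perm], y).weights_
        np.testing.assert_allclose(w2, w1[perm], atol=1e-8)

    def test_mirrored_labels_negate_scores_exactly(self, gaussian_classes):
        X, y = gaussian_classes
        s1 = FisherLDA().fit(X, y).decision_function(X)
        s2 = FisherLDA().fit(X, -y).decision_function(X)
        np.testing.assert_allclose(s2, -s1, atol=1e-8)


class TestStepwiseLDA:
    def test_informative_feature_enters_first(self):
        rng = np.random.default_rng(1)
        n = 2000
        y = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
        X = rng.normal(size=(n, 50))
        X[:, 17] += 1.5 * y  # the only informative feature
        m = StepwiseLDA().fit(X, y)
        assert m.selected_features_[0] == 17

    def test_null_labels_select_few_and_never_more_than_60(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(400, 300))
        y = np.concatenate([np.ones(200), -np.ones(200)])
        rng.shuffle(y)
        try:
            m = StepwiseLDA().fit(X, y)
            assert len(m.selected_features_) <= 60
            assert len(m.selected_features_) < 30  # null features enter rarely
        except EmptyModelError:
            pass  # also a legal null outcome

    def test_max_features_cap_is_enforced(self):
        rng = np.random.default_rng(3)
        n, N = 600, 150
        y = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
        # many weakly informative features so the forward step keeps going
        X = rng.normal(size=(n, N)) + 0.35 * y[:, None] * rng.uniform(
            0.5, 1.0, size=N
        )
        m = StepwiseLDA().fit(X, y)
        assert len(m.selected_features_) <= 60

    def test_duplicated_informative_feature_keeps_lower_index(self):
        rng = np.random.default_rng(4)
        n = 1000
        y = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
        X = rng.normal(size=(n, 10))
        X[:, 3] += 2.0 * y
        X[:, 7] = X[:, 3]  # exact duplicate
        m = StepwiseLDA().fit(X, y)
        assert 3 in m.selected_features_
        assert 7 not in m.selected_features_

    def test_no_signal_tiny_sample_raises_empty_model(self):
        X = np.array([[1.0], [1.0], [1.0], [1.0]])
        y = np.array([1.0, -1.0, 1.0, -1.0])
        with pytest.raises((EmptyModelError, Exception)):
            StepwiseLDA().fit(X, y)


class TestBayesianLDA:
    def test_fixed_hyperparameters_match_ridge_closed_form(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(80, 12))
        y = np.sign(rng.normal(size=80))
        y[y == 0] = 1.0
        for alpha, s2 in [(0.5, 1.0), (10.0, 0.1), (1e-3, 2.0)]:
            m = BayesianLDA(alpha=alpha, noise_variance=s2, optimize=False).fit(X, y)
            ridge = np.linalg.solve(
                X.T @ X + s2 * alpha * np.eye(12), X.T @ y
            )
            np.testing.assert_allclose(m.posterior_mean_, ridge, atol=1e-10)

    def test_vanishing_prior_precision_recovers_ols(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(100, 8))
        y = np.sign(rng.normal(size=100))
        y[y == 0] = 1.0
        m = BayesianLDA(alpha=1e-12, noise_variance=1.0, optimize=False).fit(X, y)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(m.posterior_mean_, ols, atol=1e-6)

    def test_posterior_covariance_matches_closed_form(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 6))
        y = np.sign(rng.normal(size=60))
        y[y == 0] = 1.0
        m = BayesianLDA(alpha=2.0, noise_variance=0.5, optimize=False).fit(X, y)
        expected = 0.5 * np.linalg.inv(X.T @ X + 0.5 * 2.0 * np.eye(6))
        np.testing.assert_allclose(m.posterior_covariance_, expected, atol=1e-10)

    def test_score_is_posterior_mean_inner_product(self, training_set):
        ts = training_set
        m = BayesianLDA().fit(ts.features, ts.labels)
        f = ts.features[3]
        assert score(m, f) == pytest.approx(float(m.posterior_mean_ @ f))

    def test_evidence_iteration_convergence_and_shrinkage(self):
        rng = np.random.default_rng(9)
        w_true = rng.normal(size=10)
        X = rng.normal(size=(500, 10))
        y_cont = X @ w_true + 0.5 * rng.normal(size=500)
        y = np.sign(y_cont)
        y[y == 0] = 1.0
        m = BayesianLDA().fit(X, y)
        assert len(m.iteration_trace_) < 500
        assert m.alpha_ > 0 and m.noise_variance_ > 0

    def test_nonconvergence_raises_with_trace(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(50, 5))
        y = np.sign(rng.normal(size=50))
        y[y == 0] = 1.0
        with pytest.raises(RuntimeError) as exc:
            BayesianLDA(max_iter=1, tol=1e-16).fit(X, y)
        assert hasattr(exc.value, "iteration_trace")
        assert len(exc.value.iteration_trace) >= 2


def _lssvm_dual_oracle(X, y, gamma):
    """Independent KKT solve of the constrained quadratic program in its
    dual variables: [[0, y^T], [y, Omega + I/(2 gamma)]] [b; a] = [0; 1]
    with Omega_ij = y_i y_j f_i . f_j, then w = sum_i a_i y_i f_i."""
    n = X.shape[0]
    Omega = (y[:, None] * y[None, :]) * (X @ X.T)
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = y
    A[1:, 0] = y
    A[1:, 1:] = Omega + np.eye(n) / (2.0 * gamma)
    rhs = np.concatenate([[0.0], np.ones(n)])
    sol = np.linalg.solve(A, rhs)
    b, a = sol[0], sol[1:]
    w = X.T @ (a * y)
    return w, b


class TestLinearLSSVM:
    def test_matches_dual_kkt_oracle_on_small_problems(self):
        rng = np.random.default_rng(11)
        for trial in range(5):
            n, N = 40, 5
            X = rng.normal(size=(n, N))
            y = np.sign(rng.normal(size=n))
            y[y == 0] = 1.0
            gamma = float(rng.uniform(0.05, 20.0))
            m = LinearLSSVM(gamma=gamma).fit(X, y)
            w, b = _lssvm_dual_oracle(X, y, gamma)
            np.testing.assert_allclose(m.weights_, w, atol=1e-6)
            assert m.bias_ == pytest.approx(b, abs=1e-6)

    def test_separable_points_midpoint_on_boundary(self):
        X = np.array([[1.0], [3.0]])
        y = np.array([-1.0, 1.0])
        m = LinearLSSVM(gamma=1e6).fit(X, y)
        assert m.decision_function(np.array([[2.0]]))[0] == pytest.approx(0.0, abs=1e-3)
        assert m.decision_function(np.array([[3.0]]))[0] > 0
        assert m.decision_function(np.array([[1.0]]))[0] < 0

    def test_vanishing_gamma_shrinks_weights_to_zero(self, gaussian_classes):
        X, y = gaussian_classes
        m = LinearLSSVM(gamma=1e-10).fit(X, y)
        assert np.linalg.norm(m.weights_) < 1e-6

    def test_cross_validated_gamma_is_from_grid(self, gaussian_classes):
        X, y = gaussian_classes
        idx = np.r_[0:50, 300:350]  # both classes represented
        m = LinearLSSVM().fit(X[idx], y[idx])
        assert m.gamma_ in m.gamma_grid


class TestKernelSVM:
    def test_grid_has_exactly_64_candidate_pairs(self):
        m = KernelSVM()
        assert len(m.param_grid_) == 8 * 8
        assert len(set(m.param_grid_)) == 64

    def test_xor_solved_by_kernel_but_not_linear(self):
        rng = np.random.default_rng(12)
        centers = np.array([[1, 1], [-1, -1], [1, -1], [-1, 1]], dtype=float)
        X = np.repeat(centers, 10, axis=0) + 0.15 * rng.normal(size=(40, 2))
        y = np.concatenate([np.ones(20), -np.ones(20)])
        km = KernelSVM().fit(X, y)
        assert np.mean(km.predict(X) == y) == 1.0
        assert np.mean(FisherLDA().fit(X, y).predict(X) == y) < 0.8

    def test_decision_function_matches_kernel_expansion_by_hand(self):
        rng = np.random.default_rng(13)
        X = np.vstack([rng.normal(size=(10, 3)) + 1.5, rng.normal(size=(10, 3))])
        y = np.concatenate([np.ones(10), -np.ones(10)])
        m = KernelSVM().fit(X, y)
        probe = rng.normal(size=(5, 3))
        d2 = ((probe[:, None, :] - m.support_vectors_[None, :, :]) ** 2).sum(-1)
        by_hand = np.exp(-m.gamma_ * d2) @ m.dual_weights_ + m.bias_
        np.testing.assert_allclose(m.decision_function(probe), by_hand, atol=1e-8)


class TestNegentropyProjection:
    def test_concentrates_on_informative_dimension(self):
        rng = np.random.default_rng(14)
        n = 400
        y = np.concatenate([np.ones(n), -np.ones(n)])
        X = np.column_stack([2.0 * y + 0.3 * rng.normal(size=2 * n),
                             rng.normal(size=2 * n)])
        m = NegentropyProjection(n_restarts=5, seed=0).fit(X, y)
        assert abs(m.weights_[0]) > 0.95
        assert not m.low_information_

    def test_matches_360_direction_grid_oracle(self):
        rng = np.random.default_rng(15)
        n = 300
        y = np.concatenate([np.ones(n), -np.ones(n)])
        X = np.column_stack([1.5 * y + 0.5 * rng.normal(size=2 * n),
                             0.8 * rng.normal(size=2 * n)])
        m = NegentropyProjection(n_restarts=5, seed=1).fit(X, y)
        angles = np.deg2rad(np.arange(360))
        dirs = np.column_stack([np.cos(angles), np.sin(angles)])
        objs = np.array(
            [mutual_information_objective(X @ d, y) for d in dirs]
        )
        assert m.objective_ >= objs.max() - 1e-3
        best = dirs[np.argmax(objs)]
        angle = np.rad2deg(np.arccos(min(1.0, abs(float(m.weights_ @ best)))))
        assert angle <= 1.0

    def test_identical_classes_flagged_low_information(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(600, 3))
        y = np.concatenate([np.ones(300), -np.ones(300)])
        m = NegentropyProjection(n_restarts=3, seed=2).fit(X, y)
        assert m.low_information_
        assert m.objective_ < 0.05


class TestSigmoidNet:
    def test_parameter_count_formula(self):
        assert n_parameters(216, 20) == 216 * 20 + 2 * 20 + 1
        rng = np.random.default_rng(17)
        X = np.vstack([rng.normal(size=(30, 4)) + 2, rng.normal(size=(30, 4))])
        y = np.concatenate([np.ones(30), -np.ones(30)])
        m = SigmoidNet(max_hidden=3, seed=0).fit(X, y)
        assert m._theta.size == n_parameters(4, m.n_hidden_)

    def test_separable_data_reaches_perfect_training_accuracy(self):
        rng = np.random.default_rng(18)
        X = np.vstack([rng.normal(size=(40, 2)) + 5, rng.normal(size=(40, 2))])
        y = np.concatenate([np.ones(40), -np.ones(40)])
        m = SigmoidNet(max_hidden=2, seed=1).fit(X, y)
        assert np.mean(m.predict(X) == y) == 1.0

    def test_default_line_search_space_is_20_sizes(self):
        assert SigmoidNet().candidate_hidden_sizes_ == list(range(1, 21))
        with pytest.raises(ValueError):
            SigmoidNet(max_hidden=25)

    def test_mirrored_labels_flip_score_signs(self):
        rng = np.random.default_rng(19)
        X = np.vstack([rng.normal(size=(40, 3)) + 2.5, rng.normal(size=(40, 3))])
        y = np.concatenate([np.ones(40), -np.ones(40)])
        s1 = SigmoidNet(max_hidden=2, seed=2).fit(X, y).decision_function(X)
        s2 = SigmoidNet(max_hidden=2, seed=2).fit(X, -y).decision_function(X)
        assert np.all(np.sign(s1) == -np.sign(s2))


class TestScoreContract:
    def test_linear_score_is_dot_product(self):
        m = FisherLDA()
        m.weights_ = np.array([1.0, 0.0])
        m.bias_ = 0.0
        m.n_features_in_ = 2
        assert score(m, np.array([2.0, 5.0])) == 2.0

    def test_length_mismatch_rejected(self, training_set):
        m = FisherLDA().fit(training_set.features, training_set.labels)
        with pytest.raises(ValueError, match="features"):
            score(m, np.zeros(3))

    def test_positive_score_means_target_class(self, training_set):
        ts = training_set
        m = BayesianLDA().fit(ts.features, ts.labels)
        s = m.decision_function(ts.features)
        # targets predominantly positive, nontargets negative
        assert np.mean(s[ts.labels == 1] > 0) > 0.9
        assert np.mean(s[ts.labels == -1] < 0) > 0.9
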