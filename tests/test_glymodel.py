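import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from sklearn.svm import OneClassSVM

from glyecg import PipelineConfig, TrainingError
from glyecg.fiducials import FEATURE_NAMES
from glyecg.glymodel import (
    BeatPrediction,
    SubjectModel,
    cohort_feature_importance,
    decision_values,
    feature_importance,
    fit_subject_model,
    predict_beats,
    vote_windows,
)


def ocsvm_dual_oracle(X: np.ndarray, nu: float):
    """Brute-force solution of the nu-one-class SVM dual with a linear
    kernel, in the libsvm normalization: minimize 1/2 a'XX'a subject to
    0 <= a_i <= 1, sum a = nu n. Independent of libsvm."""
    n = len(X)
    Q = X @ X.T
    scale = np.abs(Q).max()  # condition the objective; argmin unchanged
    Qs = Q / scale
    total = nu * n
    res = optimize.minimize(
        lambda a: 0.5 * a @ Qs @ a,
        x0=np.full(n, total / n),
        jac=lambda a: Qs @ a,
        bounds=[(0.0, 1.0)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a.sum() - total,
                      "jac": lambda a: np.ones(n)}],
        method="SLSQP",
        options={"maxiter": 5000, "ftol": 1e-14},
    )
    assert res.success
    alpha = res.x
    w = X.T @ alpha
    margins = X @ w
    free = (alpha > 1e-4) & (alpha < 1 - 1e-4)
    if free.any():
        # libsvm convention: rho is the average margin of free SVs
        rho = float(np.mean(margins[free]))
    else:
        # degenerate case (nu*n integer): rho only bracketed by the
        # bounded margins; take the midpoint of the KKT interval
        lo = float(np.max(margins[alpha > 1 - 1e-4]))
        hi = float(np.min(margins[alpha < 1e-4]))
        rho = 0.5 * (lo + hi)
    return w, rho


def _frame(X26: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(X26, columns=list(FEATURE_NAMES))


def _embed(points: np.ndarray, reps: int, rng) -> pd.DataFrame:
    """Tile a small point set into >= min_train_beats rows of a
    26-feature frame (unused features constant-jittered around 1)."""
    X = np.ones((len(points) * reps, 26))
    X[:, :points.shape[1]] = np.tile(points, (reps, 1))
    X[:, points.shape[1]:] += 0.01 * rng.normal(
        size=(X.shape[0], 26 - points.shape[1]))
    return _frame(X)


class TestOracleEquivalence:
    def test_four_point_toy_matches_qp(self):
        """The documented toy: {(0,0),(0,1),(1,0),(1,1)} x 25, nu = 0.5."""
        pts = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        X = np.tile(pts, (25, 1))
        nu = 0.5
        svm = OneClassSVM(kernel="linear", nu=nu, tol=1e-9).fit(X)
        w, rho = ocsvm_dual_oracle(X, nu)
        grid = np.array([[0.2, 0.3], [0.5, 0.5], [1.2, -0.1], [0.0, 1.0]])
        np.testing.assert_allclose(
            svm.decision_function(grid), grid @ w - rho, atol=1e-4)

    # nu*n deliberately non-integer so a free support vector exists and
    # the offset rho is uniquely determined
    @pytest.mark.parametrize("seed,n,nu", [(0, 6, 0.75), (1, 10, 0.55),
                                           (2, 8, 0.85), (3, 5, 0.35)])
    def test_random_small_sets_match_qp(self, seed, n, nu):
        rng = np.random.default_rng(seed)
        X = rng.normal(loc=2.0, size=(n, 3))
        svm = OneClassSVM(kernel="linear", nu=nu, tol=1e-9).fit(X)
        w, rho = ocsvm_dual_oracle(X, nu)
        probe = rng.normal(loc=2.0, size=(20, 3))
        np.testing.assert_allclose(
            svm.decision_function(probe), probe @ w - rho, atol=1e-4)

    def test_fitted_model_decision_matches_qp(self, cfg):
        """End to end through fit_subject_model: decision values on the
        duplicated toy set agree with the brute-force dual."""
        rng = np.random.default_rng(4)
        pts = rng.normal(loc=3.0, scale=0.7, size=(8, 4))
        train = _embed(pts, reps=10, rng=rng)
        model = fit_subject_model(train, cfg, "toy")
        scores = decision_values(model, train)
        w, rho = ocsvm_dual_oracle(train.to_numpy(float), cfg.nu)
        np.testing.assert_allclose(
            scores, -(train.to_numpy(float) @ w - rho), atol=1e-4)


class TestNuProperty:
    def test_bounds_on_fitted_models(self, cfg):
        rng = np.random.default_rng(7)
        for trial in range(3):
            train = _frame(rng.normal(loc=2.0, size=(400, 26)))
            m = fit_subject_model(train, cfg, f"t{trial}")
            assert m.train_outlier_fraction <= cfg.nu + 0.02
            assert m.sv_fraction >= cfg.nu - 0.02

    def test_duplication_invariance_of_boundary(self, cfg):
        """Duplicating every training beat rescales the dual but leaves
        the decision boundary (signed distance) unchanged."""
        rng = np.random.default_rng(8)
        train = _frame(rng.normal(loc=2.0, size=(200, 26)))
        doubled = pd.concat([train, train], ignore_index=True)
        m1 = fit_subject_model(train, cfg, "a")
        m2 = fit_subject_model(doubled, cfg, "b")
        probe = _frame(rng.normal(loc=2.0, size=(50, 26)))
        d1 = decision_values(m1, probe) / np.linalg.norm(m1.weights)
        d2 = decision_values(m2, probe) / np.linalg.norm(m2.weights)
        np.testing.assert_allclose(d1, d2, atol=1e-3)

    def test_too_few_beats_rejected(self, cfg):
        with pytest.raises(TrainingError):
            fit_subject_model(
                _frame(np.ones((10, 26))), cfg, "tiny")


class TestPrediction:
    @pytest.fixture(scope="class")
    def model(self, cfg):
        rng = np.random.default_rng(9)
        train = _frame(rng.normal(loc=2.0, scale=0.3, size=(500, 26)))
        return fit_subject_model(train, cfg, "m"), train

    def test_inlier_scores_negative(self, cfg, model):
        m, train = model
        scores = decision_values(m, train)
        # an interior training beat (deep inlier) scores negative = EU
        deepest = int(np.argmin(scores))
        assert scores[deepest] < 0
        preds = predict_beats(m, train)
        assert preds[deepest].label == "EU"
        # training outlier fraction respects nu
        assert np.mean(scores > 0) <= cfg.nu + 0.02

    def test_boundary_labeled_euglycemic(self):
        assert BeatPrediction(0.0, 0.0).label == "EU"
        assert BeatPrediction(0.0, 1e-9).label == "DYS"

    def test_shifted_outliers_score_higher(self, cfg, model):
        """The model separates the cloud from the origin, so novelty
        shows up as displacement toward the origin side of the plane."""
        m, train = model
        rng = np.random.default_rng(10)
        far = _frame(train.to_numpy() - rng.normal(1.0, 0.1, train.shape))
        assert decision_values(m, far).mean() > decision_values(m, train).mean()

    def test_model_json_round_trip(self, tmp_path, model):
        m, train = model
        path = tmp_path / "model.json"
        m.save(path)
        back = SubjectModel.load(path)
        np.testing.assert_allclose(decision_values(back, train),
                                   decision_values(m, train), atol=1e-12)


class TestVoting:
    def _preds(self, votes, t0=0.0, dt=0.7):
        return [BeatPrediction(r_time_s=t0 + i * dt,
                               score=1.0 if v else -1.0)
                for i, v in enumerate(votes)]

    def test_majority_and_score(self, cfg):
        preds = self._preds([1] * 7 + [0] * 5, dt=0.8)  # 12 beats in 10 s
        win = [w for w in vote_windows(preds, 0.0, cfg) if w.n_beats]
        assert win[0].n_beats == 12
        assert win[0].label == "DYS"
        assert win[0].window_score == pytest.approx(7 / 12)

    def test_tie_goes_to_dysglycemia(self, cfg):
        preds = self._preds([1] * 6 + [0] * 6, dt=0.8)
        win = [w for w in vote_windows(preds, 0.0, cfg) if w.n_beats]
        assert win[0].label == "DYS"

    def test_rule_matches_exhaustive_enumeration(self):
        from glyecg.glymodel import WindowPrediction

        for n in range(1, 9):
            for k in range(n + 1):
                assert WindowPrediction(0.0, n, k).label == (
                    "DYS" if k >= n - k else "EU")

    def test_monotone_voting(self, cfg):
        """Turning any euglycemic vote dysglycemic never flips a window
        from DYS to EU."""
        from glyecg.glymodel import WindowPrediction

        for n in range(1, 10):
            for k in range(n):
                before = WindowPrediction(0.0, n, k).label
                after = WindowPrediction(0.0, n, k + 1).label
                assert not (before == "DYS" and after == "EU")

    def test_full_strip_window_count(self, cfg):
        preds = self._preds([0] * 820, dt=0.73)  # ~600 s of beats
        wins = vote_windows(preds, 0.0, cfg, strip_duration_s=600.0)
        assert len(wins) == 60

    def test_empty_windows_flagged(self, cfg):
        preds = self._preds([1] * 5, dt=0.5)  # all in the first window
        wins = vote_windows(preds, 0.0, cfg, strip_duration_s=30.0)
        assert wins[0].n_beats == 5
        assert wins[1].n_beats == 0 and wins[1].label is None
        assert np.isnan(wins[1].window_score)


class TestImportance:
    def _model_with_weights(self, w):
        return SubjectModel(
            subject_id="x", feature_names=list(FEATURE_NAMES),
            weights=np.asarray(w, float), offset=0.0, nu=0.75,
            standardize="none", scaler_mean=np.zeros(26),
            scaler_sd=np.ones(26), dropped_features=[],
            train_outlier_fraction=0.7, sv_fraction=0.8, n_train_beats=100)

    def test_single_weight_ranks_first(self):
        w = np.zeros(26)
        w[0] = 3.0
        ranked = feature_importance(self._model_with_weights(w))
        assert ranked[0] == (FEATURE_NAMES[0], 3.0)

    def test_ties_broken_by_canonical_order(self):
        ranked = feature_importance(self._model_with_weights(np.ones(26)))
        assert [f for f, _ in ranked] == list(FEATURE_NAMES)

    def test_permutation_equivariance(self, cfg):
        rng = np.random.default_rng(11)
        train = _frame(rng.normal(loc=2.0, size=(300, 26)))
        shuffled = train[list(rng.permutation(FEATURE_NAMES))]
        m1 = fit_subject_model(train, cfg, "a")
        m2 = fit_subject_model(shuffled, cfg, "b")
        r1, r2 = feature_importance(m1), feature_importance(m2)
        assert [f for f, _ in r1] == [f for f, _ in r2]
        np.testing.assert_allclose([v for _, v in r1], [v for _, v in r2],
                                   atol=1e-9)

    def test_cohort_aggregate_tracks_shifted_feature(self):
        w1 = np.zeros(26); w1[10] = 2.0; w1[3] = 0.5
        w2 = np.zeros(26); w2[10] = 1.5; w2[5] = 0.4
        agg = cohort_feature_importance(
            [self._model_with_weights(w1), self._model_with_weights(w2)])
        assert agg[0][0] == FEATURE_NAMES[10]
        assert agg[0][1] == pytest.approx(1.75)
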