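"""Sparse PLS-DA core: dense-limit equivalence, sparsity contract, prediction."""

import numpy as np
import pandas as pd
import pytest

from conftest import dense_pls2_oracle, scale_xy

from mirisk.exceptions import MappingError, ParameterError
from mirisk.splsda import (
    SplsdaModel,
    fit_splsda,
    predict_splsda,
    risk_score,
    tune_splsda,
)


def _random_problem(seed, n=20, p=10, shift=1.5):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"f{i:02d}" for i in range(p)])
    y = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    X.iloc[: n // 2, 0] += shift
    return X, y


class TestDenseLimit:
    @pytest.mark.parametrize("seed,n,p,ncomp", [(0, 20, 10, 2), (1, 30, 15, 3),
                                                (2, 16, 25, 2)])
    def test_matches_independent_nipals_oracle(self, seed, n, p, ncomp):
        """With sparsity disabled the fit must equal classical dense PLS2."""
        X, y = _random_problem(seed, n, p)
        m = fit_splsda(X, y, ncomp=ncomp, keepX=None, positive_class="b")
        Xs, Ys, Y = scale_xy(X.to_numpy(), y, "b")
        W, P, D = dense_pls2_oracle(Xs, Ys, ncomp)
        for h in range(ncomp):
            sign = np.sign(W[:, h] @ m.x_weights[:, h])
            np.testing.assert_allclose(W[:, h] * sign, m.x_weights[:, h], atol=1e-6)
            np.testing.assert_allclose(P[:, h] * sign, m.x_loadings[:, h], atol=1e-6)
        # prediction equivalence on new data
        rng = np.random.default_rng(seed + 100)
        Xnew = pd.DataFrame(rng.normal(size=(6, p)), columns=X.columns)
        Wstar = W @ np.linalg.inv(P.T @ W)
        Xns = (Xnew.to_numpy() - X.to_numpy().mean(0)) / X.to_numpy().std(0, ddof=1)
        expected = (Xns @ Wstar @ D.T) * Y.std(0, ddof=1) + Y.mean(0)
        got, _ = predict_splsda(m, Xnew)
        np.testing.assert_allclose(got.to_numpy(), expected, atol=1e-6)


class TestSparsity:
    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("keepX", [1, 3, 7])
    def test_exactly_keepx_nonzero_loadings_per_component(self, seed, keepX):
        X, y = _random_problem(seed, n=24, p=15)
        m = fit_splsda(X, y, ncomp=3, keepX=keepX)
        nnz = (m.x_weights != 0.0).sum(axis=0)
        assert list(nnz) == [keepX] * 3
        # unit-norm sparse weights
        np.testing.assert_allclose(np.linalg.norm(m.x_weights, axis=0), 1.0,
                                   rtol=1e-9)

    def test_perfect_separator_is_selected(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(20, 8)),
                         columns=[f"f{i}" for i in range(8)])
        y = np.array(["a"] * 10 + ["b"] * 10)
        X["f5"] = np.where(y == "b", 10.0, -10.0) + rng.normal(scale=0.01, size=20)
        m = fit_splsda(X, y, ncomp=1, keepX=1)
        assert m.selected_features == ["f5"]

    def test_feature_permutation_equivariance(self):
        X, y = _random_problem(7, n=20, p=12)
        m1 = fit_splsda(X, y, ncomp=2, keepX=4)
        perm = list(X.columns[::-1])
        m2 = fit_splsda(X[perm], y, ncomp=2, keepX=4)
        w1 = pd.DataFrame(m1.x_weights, index=m1.feature_names)
        w2 = pd.DataFrame(m2.x_weights, index=m2.feature_names).loc[m1.feature_names]
        np.testing.assert_allclose(w1.to_numpy(), w2.to_numpy(), atol=1e-9)


class TestModelContracts:
    def test_score_orthogonality(self):
        X, y = _random_problem(9, n=30, p=20)
        m = fit_splsda(X, y, ncomp=3, keepX=5)
        G = m.scores.T @ m.scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_fit_and_predict_deterministic(self):
        X, y = _random_problem(11)
        m1, m2 = fit_splsda(X, y, ncomp=2, keepX=3), fit_splsda(X, y, ncomp=2, keepX=3)
        np.testing.assert_array_equal(m1.x_weights, m2.x_weights)
        p1, _ = predict_splsda(m1, X)
        p2, _ = predict_splsda(m2, X)
        pd.testing.assert_frame_equal(p1, p2)

    def test_training_accuracy_on_separable_toy(self):
        X, y = _random_problem(13, shift=6.0)
        m = fit_splsda(X, y, ncomp=1, keepX=2)
        _, pred = predict_splsda(m, X)
        assert (pred.to_numpy() == y).all()

    def test_duplicated_rows_predict_identically(self):
        X, y = _random_problem(15)
        m = fit_splsda(X, y, ncomp=2, keepX=3)
        dup = pd.concat([X.iloc[[0]], X.iloc[[0]]])
        got, _ = predict_splsda(m, dup)
        np.testing.assert_array_equal(got.iloc[0].to_numpy(), got.iloc[1].to_numpy())

    def test_missing_feature_raises_mapping_error(self):
        X, y = _random_problem(17)
        m = fit_splsda(X, y, ncomp=1, keepX=2)
        with pytest.raises(MappingError):
            predict_splsda(m, X.drop(columns=["f00"]))

    def test_single_class_rejected(self):
        X, _ = _random_problem(19)
        with pytest.raises(ParameterError):
            fit_splsda(X, ["a"] * len(X), ncomp=1)

    def test_constant_feature_dropped_with_warning(self):
        X, y = _random_problem(21)
        X["flat"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            m = fit_splsda(X, y, ncomp=1, keepX=None)
        assert "flat" not in m.feature_names

    def test_json_round_trip(self, tmp_path):
        X, y = _random_problem(23)
        m = fit_splsda(X, y, ncomp=2, keepX=3)
        path = tmp_path / "model.json"
        m.to_json(path)
        m2 = SplsdaModel.from_json(path)
        np.testing.assert_allclose(m.x_weights, m2.x_weights)
        p1, _ = predict_splsda(m, X)
        p2, _ = predict_splsda(m2, X)
        np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy())


class TestHandWorkedExample:
    def test_one_component_two_features_by_hand(self):
        """Tiny balanced problem checked against manual linear algebra.

        X has two features; feature g is pure noise-free group contrast, so
        the single PLS direction is g alone and predicted dummies follow the
        projection formula  yhat = t * d * sd_y + mean_y.
        """
        X = pd.DataFrame({"g": [-1.0, -1.0, 1.0, 1.0], "h": [0.5, -0.5, 0.5, -0.5]})
        y = ["a", "a", "b", "b"]
        m = fit_splsda(X, y, ncomp=1, keepX=1, positive_class="b")
        # scaled g column: [-1,-1,1,1] * (1/sd), sd = sqrt(4/3)
        sd_g = np.sqrt(4 / 3)
        assert m.selected_features == ["g"]
        np.testing.assert_allclose(np.abs(m.x_weights[:, 0]), [1.0, 0.0], atol=1e-12)
        # scores t = +-1/sd_g; y-loading d = Ys't/t't with Ys column b = dummy
        # scaled by its sd sqrt(1/3): d_b = (2*(1/sd_g)*(0.5/ sqrt(1/3)*... ))
        t = np.array([-1, -1, 1, 1]) / sd_g
        Yb = np.array([0, 0, 1, 1.0])
        Ys_b = (Yb - 0.5) / Yb.std(ddof=1)
        d_b = (Ys_b @ t) / (t @ t)
        sign = np.sign(m.x_weights[0, 0])
        np.testing.assert_allclose(m.y_loadings[1, 0] * sign, d_b, rtol=1e-12)
        # prediction on a fresh point x = (2, 0): t_new = (2-0)/sd_g * w
        got, lab = predict_splsda(m, pd.DataFrame({"g": [2.0], "h": [0.0]}))
        t_new = (2.0 - 0.0) / sd_g * sign
        expected_b = t_new * d_b * sign * Yb.std(ddof=1) + 0.5
        assert got["b"].iloc[0] == pytest.approx(expected_b, rel=1e-12)
        assert lab.iloc[0] == "b"


class TestRiskScore:
    def test_sign_matches_max_dist_label(self):
        X, y = _random_problem(25, n=30, p=12)
        m = fit_splsda(X, y, ncomp=2, keepX=4, positive_class="b")
        rng = np.random.default_rng(0)
        Xnew = pd.DataFrame(rng.normal(size=(40, 12)), columns=X.columns)
        s = risk_score(m, Xnew)
        _, lab = predict_splsda(m, Xnew, distance="max_dist")
        assert ((s > 0) == (lab == "b")).all()

    def test_antisymmetric_under_label_swap(self):
        X, y = _random_problem(27, n=20, p=10)
        m1 = fit_splsda(X, y, ncomp=1, keepX=3, positive_class="b")
        m2 = fit_splsda(X, y, ncomp=1, keepX=3, positive_class="a")
        s1, s2 = risk_score(m1, X), risk_score(m2, X)
        np.testing.assert_allclose(s1.to_numpy(), -s2.to_numpy(), atol=1e-9)


class TestAgainstMixOmics:
    """Frozen cross-check against mixOmics::splsda (run once externally).

    The fixture is regenerated deterministically; the expected selections
    and max.dist predictions below were produced by mixOmics 6.26.0 with
    ncomp=2, keepX=c(3,3), scale=TRUE on the identical matrices.
    """

    EXPECTED_SEL = [["f00", "f03", "f07"], ["f04", "f05", "f08"]]
    EXPECTED_PRED_HIGH = [-0.04911281, 0.5435838, 0.3332213,
                          0.9891945, 0.663986, 0.2920085]
    EXPECTED_CLASS = ["low", "high", "low", "high", "high", "low"]
    EXPECTED_ABS_W1 = {"f00": 0.5214541, "f03": 0.5937123, "f07": 0.6128551}

    def _fixture(self):
        rng = np.random.default_rng(2024)
        n, p = 24, 12
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"f{i:02d}" for i in range(p)])
        y = np.array(["low"] * 14 + ["high"] * 10)
        X.iloc[14:, 0] += 2.0
        X.iloc[14:, 3] += 1.2
        X.iloc[14:, 7] -= 1.5
        Xnew = pd.DataFrame(rng.normal(size=(6, p)), columns=X.columns)
        Xnew.iloc[3:, 0] += 2.0
        Xnew.iloc[3:, 3] += 1.2
        Xnew.iloc[3:, 7] -= 1.5
        return X, y, Xnew

    def test_selection_prediction_and_weights_match(self):
        X, y, Xnew = self._fixture()
        m = fit_splsda(X, y, ncomp=2, keepX=3, positive_class="high")
        assert [sorted(s) for s in m.selected_per_component()] == self.EXPECTED_SEL
        got, lab = predict_splsda(m, Xnew)
        np.testing.assert_allclose(got["high"], self.EXPECTED_PRED_HIGH, atol=1e-6)
        assert list(lab) == self.EXPECTED_CLASS
        w = dict(zip(m.feature_names, np.abs(m.x_weights[:, 0])))
        for f, expected in self.EXPECTED_ABS_W1.items():
            assert w[f] == pytest.approx(expected, abs=1e-6)


class TestTuning:
    def test_single_candidate_grid(self):
        X, y = _random_problem(29, n=24, p=10, shift=4.0)
        res = tune_splsda(X, y, keepX_grid=(4,), ncomp_grid=(2,), folds=4, seed=1)
        assert (res.best_keepX, res.best_ncomp) == (4, 2)

    def test_tie_breaks_toward_sparser_model(self):
        """On strongly separable data every keepX reaches zero CV error;
        the sparsest candidate must win."""
        rng = np.random.default_rng(31)
        X = pd.DataFrame(rng.normal(size=(30, 10)),
                         columns=[f"f{i:02d}" for i in range(10)])
        y = np.array(["a"] * 15 + ["b"] * 15)
        X.iloc[:15, :3] += 20.0  # three massive separators swamp the noise
        res = tune_splsda(X, y, keepX_grid=(2, 5, 8), ncomp_grid=(1,), folds=5, seed=2)
        assert res.best_error == 0.0
        assert res.best_keepX == 2

    def test_reproducible_from_seed(self):
        X, y = _random_problem(33, n=24, p=10, shift=0.0)
        r1 = tune_splsda(X, y, keepX_grid=(2, 4), ncomp_grid=(1,), folds=4, seed=5)
        r2 = tune_splsda(X, y, keepX_grid=(2, 4), ncomp_grid=(1,), folds=4, seed=5)
        pd.testing.assert_frame_equal(r1.grid, r2.grid)

    def test_pure_noise_cv_error_near_majority_rate(self):
        errs = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(40, 15)),
                             columns=[f"f{i}" for i in range(15)])
            y = np.array(["a"] * 20 + ["b"] * 20)
            res = tune_splsda(X, y, keepX_grid=(5,), ncomp_grid=(1,), folds=5,
                              seed=seed)
            errs.append(res.best_error)
        assert np.mean(errs) == pytest.approx(0.5, abs=0.12)

    def test_empty_grid_and_tiny_class_rejected(self):
        X, y = _random_problem(35)
        with pytest.raises(ParameterError):
            tune_splsda(X, y, keepX_grid=())
        with pytest.raises(ParameterError):
            tune_splsda(X, ["a"] * (len(X) - 1) + ["b"], keepX_grid=(2,))
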