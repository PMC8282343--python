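"""Elastic-net engine oracles and transcriptional-signature behaviour."""

import numpy as np
import pandas as pd
import pytest

from sigqtl import _enet, signatures
from sigqtl.preprocess import ExpressionMatrix
from sigqtl.signatures import (
    SignatureError,
    SignatureModel,
    compare_restricted,
    correlate_signatures,
    fit_signature,
    impute_signatures,
    validate_longitudinal,
)


def _expr_from_matrix(R: np.ndarray, genes=None, samples=None):
    genes = genes or [f"G{i}" for i in range(R.shape[0])]
    samples = samples or [f"S{i}" for i in range(R.shape[1])]
    resid = pd.DataFrame(R, index=genes, columns=samples)
    counts = pd.DataFrame(np.ones_like(R, dtype=int), index=genes,
                          columns=samples)
    return ExpressionMatrix(counts=counts, residual=resid)


class TestEnetEngine:
    """The hand-authored Gram coordinate-descent solver vs sklearn."""

    def test_path_matches_sklearn(self, rng):
        from sklearn.linear_model import enet_path

        n, p = 100, 30
        X = rng.standard_normal((n, p))
        X = (X - X.mean(0)) / X.std(0)
        y = X[:, :3] @ np.array([1.0, -0.5, 0.25]) + rng.standard_normal(n)
        y = y - y.mean()
        for alpha in (0.1, 0.5, 1.0):
            lams = _enet.lambda_grid(X, y, alpha, 50, 1e-2)
            B = _enet.enet_path_gram(X.T @ X, X.T @ y, n, lams, alpha,
                                     float(y @ y), tol=1e-12)
            _, C, _ = enet_path(X, y, l1_ratio=alpha, alphas=lams, tol=1e-12)
            assert np.abs(B - C).max() < 5e-6

    def test_loo_matches_bruteforce_per_fold_refits(self, rng):
        from sklearn.linear_model import enet_path

        n, p = 50, 80
        X = rng.standard_normal((n, p))
        X = (X - X.mean(0)) / X.std(0)
        y = X[:, :5] @ np.full(5, 0.6) + rng.standard_normal(n)
        y = y - y.mean()
        alpha = 0.1
        lams = _enet.lambda_grid(X, y, alpha, 30, 1e-2)
        _, _, pred = _enet.cv_path(X, y, lams, alpha,
                                   _enet.make_folds(n, n), tol=1e-12)
        brute = np.empty((n, len(lams)))
        for i in range(n):
            tr = np.delete(np.arange(n), i)
            mu = X[tr].mean(0)
            ybar = y[tr].mean()
            _, C, _ = enet_path(X[tr] - mu, y[tr] - ybar, l1_ratio=alpha,
                                alphas=lams, tol=1e-12)
            brute[i] = (X[i] - mu) @ C + ybar
        assert np.abs(pred - brute).max() < 1e-4

    def test_lambda_max_zeroes_all_coefficients(self, rng):
        n, p = 60, 40
        X = rng.standard_normal((n, p))
        X = (X - X.mean(0)) / X.std(0)
        y = rng.standard_normal(n)
        y -= y.mean()
        lams = _enet.lambda_grid(X, y, 0.1, 10, 1e-2)
        B = _enet.enet_path_gram(X.T @ X, X.T @ y, n, lams[:1], 0.1,
                                 float(y @ y))
        assert np.all(B == 0)


class TestFitSignature:
    def test_perfect_signal_limit(self, rng):
        R = rng.standard_normal((50, 100))
        expr = _expr_from_matrix(R)
        y = pd.Series(R[7], index=expr.residual.columns, name="v")
        m = fit_signature(y, expr, cv="loo")
        assert m.r2 >= 0.99
        pred = m.predict(expr)
        assert np.corrcoef(pred, y)[0, 1] >= 0.999

    def test_r2_definition_not_clamped(self, rng):
        # pure-noise target at modest n: r2 = 1 - cv_mse/var(y), often < 0
        R = rng.standard_normal((40, 30))
        expr = _expr_from_matrix(R)
        y = pd.Series(rng.standard_normal(30), index=expr.residual.columns,
                      name="noise")
        m = fit_signature(y, expr, cv="loo")
        var_y = float(np.var(y, ddof=1))
        assert m.r2 == pytest.approx(1 - m.cv_mse / var_y)

    def test_cv_r2_below_in_sample_r2(self, rng):
        R = rng.standard_normal((60, 80))
        expr = _expr_from_matrix(R)
        y = pd.Series(R[0] * 0.8 + rng.standard_normal(80),
                      index=expr.residual.columns, name="v")
        m = fit_signature(y, expr, cv="loo")
        assert m.r2 <= m.in_sample_r2 + 1e-12

    def test_missingness_and_min_train(self, rng):
        R = rng.standard_normal((20, 40))
        expr = _expr_from_matrix(R)
        y = pd.Series(R[0], index=expr.residual.columns, name="v")
        y.iloc[25:] = np.nan
        m = fit_signature(y, expr, cv="kfold", min_train=20)
        assert m.n_train == 25
        y.iloc[10:] = np.nan
        with pytest.raises(SignatureError):
            fit_signature(y, expr, min_train=20)

    def test_constant_target_rejected(self, rng):
        R = rng.standard_normal((10, 30))
        expr = _expr_from_matrix(R)
        y = pd.Series(np.ones(30), index=expr.residual.columns, name="v")
        with pytest.raises(SignatureError):
            fit_signature(y, expr)

    def test_lasso_limit_causal_gene_enters_first(self):
        # noiseless toy, alpha = 1: the causal gene is the first active
        rng = np.random.default_rng(5)
        R = rng.standard_normal((10, 60))
        expr = _expr_from_matrix(R)
        y = pd.Series(2.0 * R[3], index=expr.residual.columns, name="v")
        m = fit_signature(y, expr, alpha=1.0, cv="kfold")
        X = expr.residual.to_numpy().T
        Xs = (X - X.mean(0)) / X.std(0)
        yc = (y - y.mean()).to_numpy()
        lams = _enet.lambda_grid(Xs, yc, 1.0, 100, 1e-2)
        B = _enet.enet_path_gram(Xs.T @ Xs, Xs.T @ yc, len(yc), lams, 1.0,
                                 float(yc @ yc))
        active_per_lambda = (B != 0).sum(axis=0)
        first = np.argmax(active_per_lambda > 0)
        assert set(np.where(B[:, first] != 0)[0]) == {3}

    def test_noise_genes_do_not_inflate_cv_r2(self, rng):
        n = 60
        R = rng.standard_normal((30, n))
        y = pd.Series(R[0] + 0.7 * rng.standard_normal(n), name="v",
                      index=[f"S{i}" for i in range(n)])
        expr_small = _expr_from_matrix(R)
        m_small = fit_signature(y, expr_small, cv="loo")
        R_big = np.vstack([R, rng.standard_normal((150, n))])
        m_big = fit_signature(y, _expr_from_matrix(R_big), cv="loo")
        assert m_big.r2 <= m_small.r2 + 0.02


class TestImputation:
    def _toy_model(self, weights, intercept):
        return SignatureModel(
            variable="v", weights=pd.Series(weights), intercept=intercept,
            alpha=0.1, lambda_=1.0, cv_mse=1.0, cv_mse_sd=0.1, r2=0.5,
            n_train=10, in_sample_r2=0.6,
        )

    def test_zero_weight_model_returns_intercept(self, rng):
        expr = _expr_from_matrix(rng.standard_normal((5, 8)))
        m = self._toy_model({}, 2.5)
        assert (m.predict(expr) == 2.5).all()

    def test_hand_arithmetic(self):
        R = np.array([[1.0], [3.0]])
        expr = _expr_from_matrix(R, genes=["gA", "gB"], samples=["S0"])
        m = self._toy_model({"gA": 2.0, "gB": -1.0}, 0.5)
        assert m.predict(expr)["S0"] == pytest.approx(-0.5)

    def test_missing_gene_named_in_error(self, rng):
        expr = _expr_from_matrix(rng.standard_normal((3, 4)))
        m = self._toy_model({"ABSENT": 1.0}, 0.0)
        with pytest.raises(SignatureError, match="ABSENT"):
            m.predict(expr)

    def test_denoising_contract_training_samples_get_prediction(self, rng):
        R = rng.standard_normal((30, 50))
        expr = _expr_from_matrix(R)
        y = pd.Series(R[0] + rng.standard_normal(50) * 0.5,
                      index=expr.residual.columns, name="v")
        m = fit_signature(y, expr, cv="kfold")
        sig = impute_signatures([m], expr)
        vals = sig.values["v"]
        assert not np.allclose(vals, y)          # not the observed values
        assert np.allclose(vals, m.predict(expr))  # the model prediction

    def test_selection_threshold(self, rng):
        m_good = self._toy_model({}, 0.0)
        m_good.r2 = 0.05
        m_bad = self._toy_model({}, 0.0)
        m_bad.variable = "w"
        m_bad.r2 = 0.005
        expr = _expr_from_matrix(rng.standard_normal((3, 6)))
        sig = impute_signatures([m_good, m_bad], expr, r2_threshold=0.01)
        assert sig.selected == {"v": True, "w": False}
        assert set(sig.values.columns) == {"v", "w"}  # unselected still imputed

    def test_imputation_linearity(self, rng):
        R = rng.standard_normal((10, 20))
        expr = _expr_from_matrix(R)
        m = self._toy_model({"G0": 1.5, "G4": -2.0}, 0.7)
        base = m.predict(expr) - m.intercept
        expr2 = _expr_from_matrix(3.0 * R)
        scaled = m.predict(expr2) - m.intercept
        assert np.allclose(scaled, 3.0 * base)


class TestCompareRestricted:
    def test_full_subset_reproduces_full_fit(self, rng):
        R = rng.standard_normal((25, 60))
        expr = _expr_from_matrix(R)
        y = pd.Series(R[2] + 0.3 * rng.standard_normal(60),
                      index=expr.residual.columns, name="v")
        full = fit_signature(y, expr, cv="kfold")
        r2_full, r2_res, n_found = compare_restricted(
            y, expr, full, list(expr.residual.index), cv="kfold"
        )
        assert r2_res == pytest.approx(r2_full)
        assert n_found == 25

    def test_causal_genes_excluded_cripples_restricted_model(self, rng):
        R = rng.standard_normal((40, 80))
        expr = _expr_from_matrix(R)
        y = pd.Series(R[0] + R[1], index=expr.residual.columns, name="v")
        full = fit_signature(y, expr, cv="kfold")
        subset = [f"G{i}" for i in range(20, 40)]  # excludes G0, G1
        r2_full, r2_res, _ = compare_restricted(y, expr, full, subset,
                                                cv="kfold")
        assert r2_full >= 0.9
        assert r2_res <= 0.05

    def test_panel_intersection_count_reported(self, rng):
        # a 53-gene panel of which only 48 are measurable
        R = rng.standard_normal((60, 50))
        expr = _expr_from_matrix(R)
        y = pd.Series(R[0] + rng.standard_normal(50) * 2,
                      index=expr.residual.columns, name="v")
        full = fit_signature(y, expr, cv="kfold")
        panel = [f"G{i}" for i in range(48)] + [f"MISSING{i}" for i in range(5)]
        assert len(panel) == 53
        _, _, n_found = compare_restricted(y, expr, full, panel, cv="kfold")
        assert n_found == 48
        with pytest.raises(SignatureError):
            compare_restricted(y, expr, full, ["NOPE"], cv="kfold")


class TestCorrelateSignatures:
    def _sig(self, values: pd.DataFrame, selected=None):
        models = {}
        sel = {}
        for v in values.columns:
            m = SignatureModel(
                variable=v, weights=pd.Series(dtype=float), intercept=0.0,
                alpha=0.1, lambda_=1.0, cv_mse=1.0, cv_mse_sd=0.1, r2=0.5,
                n_train=10, in_sample_r2=0.6)
            models[v] = m
            sel[v] = True if selected is None else selected[v]
        return signatures.SignatureMatrix(values=values, selected=sel,
                                          source_models=models)

    def test_identical_signatures_correlate_perfectly(self, rng):
        x = rng.standard_normal(100)
        values = pd.DataFrame({"a": x, "b": x.copy()})
        r, p, masked = correlate_signatures(self._sig(values))
        assert r.loc["a", "a"] == 1.0
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert not masked.loc["a", "b"]
        assert np.allclose(r, r.T)

    def test_uncorrelated_pair_masked(self, rng):
        a = rng.standard_normal(200)
        b = rng.standard_normal(200)
        a -= a.mean()
        b -= b.mean()
        b -= a * (a @ b) / (a @ a)
        values = pd.DataFrame({"a": a, "b": b})
        _, p, masked = correlate_signatures(self._sig(values))
        assert masked.loc["a", "b"]

    def test_correlated_block_recovered(self, rng):
        f = rng.standard_normal(250)
        a = 0.77 * f + np.sqrt(1 - 0.77**2) * rng.standard_normal(250)
        b = 0.77 * f + np.sqrt(1 - 0.77**2) * rng.standard_normal(250)
        values = pd.DataFrame({"a": a, "b": b})
        r, p, masked = correlate_signatures(self._sig(values))
        assert 0.4 <= r.loc["a", "b"] <= 0.8
        assert p.loc["a", "b"] < 0.05

    def test_constant_signature_masked_with_warning(self, rng):
        values = pd.DataFrame({
            "a": rng.standard_normal(50),
            "b": rng.standard_normal(50),
            "c": np.ones(50),
        })
        with pytest.warns(UserWarning, match="constant"):
            r, p, masked = correlate_signatures(self._sig(values))
        assert masked.loc["a", "c"] and masked.loc["c", "b"]

    def test_needs_two_selected(self, rng):
        values = pd.DataFrame({"a": rng.standard_normal(10),
                               "b": rng.standard_normal(10)})
        sig = self._sig(values, selected={"a": True, "b": False})
        with pytest.raises(SignatureError):
            correlate_signatures(sig)


class TestValidateLongitudinal:
    def test_equal_deltas_give_rho_one(self):
        idx = [f"S{i}" for i in range(20)]
        rng = np.random.default_rng(0)
        o1 = pd.Series(rng.standard_normal(20), index=idx)
        o2 = pd.Series(rng.standard_normal(20), index=idx)
        rho, p = validate_longitudinal(o1, o2, o1.copy(), o2.copy())
        assert rho == pytest.approx(1.0)
        assert p < 1e-10

    def test_too_few_pairs_rejected(self):
        idx = ["S0", "S1", "S2"]
        s = pd.Series([1.0, 2.0, 3.0], index=idx)
        with pytest.raises(SignatureError):
            validate_longitudinal(s, s, s, s)

    def test_uses_common_samples_only(self, rng):
        idx1 = [f"S{i}" for i in range(30)]
        idx2 = idx1[:20]
        o1 = pd.Series(rng.standard_normal(30), index=idx1)
        o2 = pd.Series(rng.standard_normal(20), index=idx2)
        rho, _ = validate_longitudinal(o1, o2, o1, o2.reindex(idx2))
        assert np.isfinite(rho)
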