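"""Risk-model tests: Framingham equation fixtures, penalized-logistic
behavior against a Newton oracle, bootstrap feature selection, and
prediction plumbing."""

import numpy as np
import pandas as pd
import pytest

from lipidcad.errors import ConfigurationError, DataError
from lipidcad.risk import (
    RiskModel,
    fit_combined,
    fit_frs_model,
    fit_ridge_logistic,
    framingham_risk,
    predict_risk,
    select_lrs_features,
)

from conftest import make_clinical_frame

# 10-year risks for two reference profiles, computed once by an independent
# hand implementation of the published sex-specific equations and frozen.
REF_MALE = 0.1462818415  # 60 y M, TC 5.0, HDL 1.2 mmol/L, SBP 130 untreated
REF_FEMALE = 0.1592253691  # 55 y F, TC 5.5, HDL 1.5, SBP 140 treated, smoker


def _profile(**kw):
    base = dict(age=60.0, sex="M", sbp=130.0, tc=5.0, hdl=1.2,
                current_smoking=False, diabetes=False, hypertension=False)
    base.update(kw)
    return pd.Series(base)


class TestFramingham:
    def test_reference_profiles_match_frozen_oracle(self):
        assert framingham_risk(_profile()) == pytest.approx(REF_MALE, abs=1e-9)
        female = _profile(age=55.0, sex="F", tc=5.5, hdl=1.5, sbp=140.0,
                          hypertension=True, current_smoking=True)
        assert framingham_risk(female) == pytest.approx(REF_FEMALE, abs=1e-9)

    def test_risk_strictly_increases_with_age(self):
        risks = [framingham_risk(_profile(age=a)) for a in (40, 50, 60, 70)]
        assert all(a < b for a, b in zip(risks, risks[1:]))

    def test_risk_bounded_on_random_profiles(self, rng):
        frame = make_clinical_frame(10_000, seed=3)
        risks = framingham_risk(frame)
        assert ((risks > 0) & (risks < 1)).all()

    def test_missing_covariate_raises_by_name(self):
        with pytest.raises(DataError, match="hdl"):
            framingham_risk(_profile().drop("hdl"))

    def test_out_of_range_age_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            clamped = framingham_risk(_profile(age=90.0))
        assert clamped == pytest.approx(framingham_risk(_profile(age=74.0)), abs=1e-12)


def _toy_data(rng, n=400, p=2, beta=(1.0, -0.5), intercept=-0.3):
    X = rng.normal(size=(n, p))
    eta = intercept + X @ np.asarray(beta)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    ids = [f"S{i:04d}" for i in range(n)]
    return pd.DataFrame(X, index=ids, columns=[f"f{j}" for j in range(p)]), y


def _newton_logistic(X, y, tol=1e-12):
    """Unpenalized Newton-Raphson MLE oracle (intercept first)."""
    Z = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Z.shape[1])
    for _ in range(100):
        p = 1 / (1 + np.exp(-Z @ beta))
        W = p * (1 - p)
        grad = Z.T @ (y - p)
        hess = (Z * W[:, None]).T @ Z
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    return beta


class TestRidgeLogistic:
    def test_tiny_penalty_matches_newton_mle(self, rng):
        X, y = _toy_data(rng)
        model = fit_ridge_logistic(X, y, penalty=1e-6)
        # oracle operates on the same standardized design
        Xs = (X - X.mean()) / X.std(ddof=0)
        oracle = _newton_logistic(Xs.to_numpy(), y)
        np.testing.assert_allclose(model.intercept, oracle[0], atol=1e-3)
        np.testing.assert_allclose(model.coefficients, oracle[1:], atol=1e-3)

    def test_huge_penalty_shrinks_to_prevalence(self, rng):
        X, y = _toy_data(rng)
        model = fit_ridge_logistic(X, y, penalty=1e9)
        assert np.abs(model.coefficients).max() < 1e-4
        risk, _ = predict_risk(model, X)
        assert risk.to_numpy() == pytest.approx(y.mean(), abs=1e-3)

    def test_coefficient_norm_non_increasing_in_penalty(self, rng):
        X, y = _toy_data(rng)
        norms = [
            np.linalg.norm(fit_ridge_logistic(X, y, pen).coefficients)
            for pen in (0.01, 0.1, 1.0, 10.0, 100.0)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_parameter_recovery_at_large_n(self, rng):
        """With penalty -> 0 and n = 5000 the standardized coefficients
        approach the planted effects within 2 SE (inverse-Fisher oracle)."""
        X, y = _toy_data(rng, n=5000)
        model = fit_ridge_logistic(X, y, penalty=1e-6)
        Z = np.column_stack([np.ones(len(y)), (X - X.mean()) / X.std(ddof=0)])
        p = 1 / (1 + np.exp(-(Z @ np.r_[model.intercept, model.coefficients])))
        cov = np.linalg.inv((Z * (p * (1 - p))[:, None]).T @ Z)
        se = np.sqrt(np.diag(cov))[1:]
        np.testing.assert_array_less(np.abs(model.coefficients - [1.0, -0.5]), 2 * se)

    def test_zero_penalty_reserved_for_frs_kind(self, rng):
        X, y = _toy_data(rng)
        with pytest.raises(ConfigurationError):
            fit_ridge_logistic(X, y, penalty=0.0, kind="LRS")


class TestFrsAndCombined:
    def test_frs_model_is_monotone_in_frs(self, rng):
        frs = pd.Series(rng.random(300), index=[f"S{i:03d}" for i in range(300)])
        y = (rng.random(300) < 0.3 + 0.4 * frs).astype(float)
        model = fit_frs_model(frs, y)
        risk, _ = predict_risk(model, frs.to_frame("frs"))
        assert (risk.rank() == frs.rank()).all()

    def test_combined_reduces_to_frs_when_lipids_carry_no_signal(self, rng):
        from lipidcad.evaluation import _auc_mann_whitney

        n = 600
        ids = [f"S{i:04d}" for i in range(n)]
        frs = pd.Series(rng.random(n), index=ids)
        y = (rng.random(n) < 0.2 + 0.5 * frs).astype(float)
        X = pd.DataFrame(rng.normal(size=(n, 20)), index=ids,
                         columns=[f"sp{j}" for j in range(20)])
        train, test = ids[: n // 2], ids[n // 2 :]
        frs_model = fit_frs_model(frs[train], y[: n // 2])
        comb = fit_combined(X.loc[train], frs, y[: n // 2], penalty=10.0)
        r_frs, _ = predict_risk(frs_model, frs[test].to_frame("frs"))
        Xc = X.loc[test].copy()
        Xc["frs"] = frs[test]
        r_comb, _ = predict_risk(comb, Xc)
        auc_f = _auc_mann_whitney(r_frs.to_numpy(), y[n // 2 :])
        auc_c = _auc_mann_whitney(r_comb.to_numpy(), y[n // 2 :])
        assert abs(auc_c - auc_f) < 0.05

    def test_combined_not_worse_than_frs_with_lipid_signal(self, rng):
        from lipidcad.evaluation import _auc_mann_whitney

        n = 600
        ids = [f"S{i:04d}" for i in range(n)]
        frs = pd.Series(rng.random(n), index=ids)
        X = pd.DataFrame(rng.normal(size=(n, 10)), index=ids,
                         columns=[f"sp{j}" for j in range(10)])
        eta = -1 + 2 * frs + 1.5 * X["sp0"]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        frs_model = fit_frs_model(frs, y)
        comb = fit_combined(X, frs, y, penalty=1.0)
        r_frs, _ = predict_risk(frs_model, frs.to_frame("frs"))
        Xc = X.copy()
        Xc["frs"] = frs
        r_comb, _ = predict_risk(comb, Xc)
        assert _auc_mann_whitney(r_comb.to_numpy(), y) >= \
            _auc_mann_whitney(r_frs.to_numpy(), y) - 0.01


class TestFeatureSelection:
    def _one_strong_species(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 200, 201
        ids = [f"S{i:04d}" for i in range(n)]
        X = pd.DataFrame(rng.normal(size=(n, p)), index=ids,
                         columns=[f"sp_{j:03d}" for j in range(p)])
        y = (rng.random(n) < 0.5).astype(float)
        X["sp_000"] += 2.0 * y
        return X, y

    def test_strong_species_ranked_first_across_seeds(self):
        first = 0
        for seed in range(10):
            X, y = self._one_strong_species(seed)
            sel = select_lrs_features(X, y, grid=[(1.0, 10)], n_boot=5, seed=seed)
            first += sel.ranking[0] == "sp_000"
        assert first >= 9

    def test_same_seed_reproduces_selection(self):
        X, y = self._one_strong_species(0)
        a = select_lrs_features(X, y, grid=[(1.0, 10), (10.0, 20)], n_boot=5, seed=3)
        b = select_lrs_features(X, y, grid=[(1.0, 10), (10.0, 20)], n_boot=5, seed=3)
        assert a.ranking == b.ranking
        assert (a.chosen_penalty, a.chosen_n) == (b.chosen_penalty, b.chosen_n)

    def test_single_grid_point_returned(self):
        X, y = self._one_strong_species(1)
        sel = select_lrs_features(X, y, grid=[(2.0, 15)], n_boot=5, seed=0)
        assert (sel.chosen_penalty, sel.chosen_n) == (2.0, 15)

    def test_validation_rows_rejected(self):
        X, y = self._one_strong_species(2)
        with pytest.raises(DataError, match="discovery"):
            select_lrs_features(X, y, grid=[(1.0, 10)], n_boot=5, seed=0,
                                discovery_ids=set(X.index[:100]))


class TestPredict:
    def test_zero_coefficients_give_constant_sigmoid_intercept(self):
        model = RiskModel(
            kind="LRS", feature_names=["a", "b"], intercept=0.7,
            coefficients=np.zeros(2), feature_means=np.zeros(2),
            feature_sds=np.ones(2), l2_penalty=1.0, threshold=0.5,
        )
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 2)),
                         columns=["a", "b"])
        risk, call = predict_risk(model, X)
        assert risk.to_numpy() == pytest.approx(1 / (1 + np.exp(-0.7)))
        assert call.all()

    def test_missing_feature_raises(self):
        model = RiskModel(
            kind="LRS", feature_names=["a", "b"], intercept=0.0,
            coefficients=np.zeros(2), feature_means=np.zeros(2),
            feature_sds=np.ones(2), l2_penalty=1.0, threshold=0.5,
        )
        with pytest.raises(DataError, match="b"):
            predict_risk(model, pd.DataFrame({"a": [1.0]}))

    def test_training_auc_high_on_separable_toy(self, rng):
        from lipidcad.evaluation import _auc_mann_whitney

        n = 200
        y = np.repeat([0.0, 1.0], n // 2)
        X = pd.DataFrame({"f0": rng.normal(size=n) + 3 * y,
                          "f1": rng.normal(size=n)})
        model = fit_ridge_logistic(X, y, penalty=1.0)
        risk, _ = predict_risk(model, X)
        assert _auc_mann_whitney(risk.to_numpy(), y) > 0.9

    def test_model_json_round_trip(self, tmp_path, rng):
        X, y = _toy_data(rng)
        model = fit_ridge_logistic(X, y, penalty=2.0)
        model.to_json(tmp_path / "m.json")
        loaded = RiskModel.from_json(tmp_path / "m.json")
        np.testing.assert_allclose(loaded.coefficients, model.coefficients)
        r1, _ = predict_risk(model, X)
        r2, _ = predict_risk(loaded, X)
        np.testing.assert_allclose(r1.to_numpy(), r2.to_numpy())
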