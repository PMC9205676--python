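"""VIF, standardization, all-subsets AICc and multimodel averaging."""

import numpy as np
import pandas as pd
import pytest

from betanest import (
    all_subsets_aicc,
    average_parameters,
    environmental_deltas,
    explained_variability,
    relative_effects,
    standardize,
    vif,
)
from betanest.averaging import ModelSet, _FittedSubset


def correlated_design(rng, n=28, p=5, rho=0.3):
    cov = rho + (1 - rho) * np.eye(p)
    X = rng.normal(size=(n, p)) @ np.linalg.cholesky(cov).T
    return pd.DataFrame(X, columns=[f"x{i + 1}" for i in range(p)])


class TestStandardize:
    def test_zscore_and_idempotence(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 1.0, 0.0]})
        Z, center, scale = standardize(X)
        assert np.allclose(Z.mean(), 0, atol=1e-12)
        assert np.allclose(Z.std(ddof=1), 1, atol=1e-12)
        Z2, _, _ = standardize(Z)
        assert np.allclose(Z, Z2, atol=1e-12)

    def test_round_trip(self, rng):
        X = pd.DataFrame(rng.normal(2, 3, size=(20, 4)),
                         columns=list("abcd"))
        Z, center, scale = standardize(X)
        assert np.allclose(Z * scale + center, X, atol=1e-10)

    def test_zero_variance_column_named(self):
        X = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [4.0, 4.0, 4.0]})
        with pytest.raises(ValueError, match="flat"):
            standardize(X)


class TestVif:
    def test_orthogonal_design_gives_unit_vif(self, rng):
        raw = rng.normal(size=(30, 4))
        Q, _ = np.linalg.qr(raw - raw.mean(axis=0))  # centred orthogonal
        X = pd.DataFrame(Q, columns=list("abcd"))
        assert np.allclose(vif(X), 1.0, atol=1e-10)

    def test_duplicated_column_flagged_infinite(self, rng):
        X = correlated_design(rng, p=3)
        X["dup"] = X["x1"]
        with pytest.warns(UserWarning, match="collinear"):
            out = vif(X)
        assert np.isinf(out["dup"])

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.outliers_influence import (
            variance_inflation_factor,
        )
        import statsmodels.api as sm

        X = correlated_design(rng, n=40, rho=0.5)
        mine = vif(X)
        design = sm.add_constant(X).to_numpy()
        for j, col in enumerate(X.columns):
            ref = variance_inflation_factor(design, j + 1)
            assert mine[col] == pytest.approx(ref, rel=1e-8)

    def test_input_contract(self, rng):
        with pytest.raises(ValueError, match="2 predictors"):
            vif(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))


class TestAllSubsets:
    def test_five_predictors_give_32_models_weights_sum_to_one(self, rng):
        X = correlated_design(rng)
        y = rng.normal(size=28)
        ms = all_subsets_aicc(y, X)
        assert len(ms.models) == 32
        assert ms.table["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert ms.table["delta_aicc"].min() == 0.0

    def test_noiseless_signal_best_model_contains_driver(self, rng):
        X = correlated_design(rng)
        y = 2.0 * X["x1"].to_numpy()
        ms = all_subsets_aicc(y, X)
        assert "x1" in ms.best().predictors

    def test_small_sample_subsets_excluded_with_warning(self, rng):
        X = correlated_design(rng, n=7, p=5)
        y = rng.normal(size=7)
        with pytest.warns(UserWarning, match="dropped"):
            ms = all_subsets_aicc(y, X)
        assert len(ms.models) < 32

    def test_small_sample_correction_vanishes_for_large_n(self, rng):
        n = 10_000
        X = correlated_design(rng, n=n, p=3)
        y = (X["x1"] + rng.normal(size=n)).to_numpy()
        ms = all_subsets_aicc(y, X)
        full = ms.best()
        k = full.k
        correction = 2 * k * (k + 1) / (n - k - 1)
        assert correction < 1e-2


class TestAveraging:
    def _manual_modelset(self, aiccs, coefs):
        models = []
        for aicc, beta in zip(aiccs, coefs):
            preds = tuple(k for k in beta if k != "const")
            models.append(_FittedSubset(
                predictors=preds, k=len(beta) + 1, aicc=aicc,
                params=pd.Series(beta), bse=pd.Series({k: 0.0 for k in beta}),
                r2=0.5,
            ))
        aic = np.array(aiccs)
        delta = aic - aic.min()
        w = np.exp(-delta / 2)
        w /= w.sum()
        table = pd.DataFrame({
            "predictors": [",".join(m.predictors) for m in models],
            "k": [m.k for m in models], "r2": 0.5, "aicc": aic,
            "delta_aicc": delta, "weight": w,
        })
        return ModelSet(table=table, models=models, n=28,
                        predictor_names=("x1", "x2"))

    def test_single_model_in_set_returns_its_coefficients(self):
        ms = self._manual_modelset(
            [100.0, 120.0],
            [{"const": 0.1, "x1": 0.7, "x2": -0.2}, {"const": 0.0}],
        )
        avg = average_parameters(ms, delta_threshold=4)
        assert avg.n_models == 1
        assert avg.table.loc["x1", "estimate"] == pytest.approx(0.7)
        assert avg.table.loc["x2", "estimate"] == pytest.approx(-0.2)

    def test_equal_weights_zero_substitution_halves_estimate(self):
        ms = self._manual_modelset(
            [100.0, 100.0],
            [{"const": 0.0, "x1": 0.6}, {"const": 0.0}],
        )
        avg = average_parameters(ms, delta_threshold=4)
        assert avg.table.loc["x1", "estimate"] == pytest.approx(0.3)

    def test_weights_invariant_to_constant_aicc_shift(self):
        ms1 = self._manual_modelset([100.0, 101.5],
                                    [{"const": 0, "x1": 0.5}, {"const": 0}])
        ms2 = self._manual_modelset([400.0, 401.5],
                                    [{"const": 0, "x1": 0.5}, {"const": 0}])
        assert np.allclose(ms1.table["weight"], ms2.table["weight"])

    def test_full_averaging_shrinks_relative_to_conditional(self, rng):
        X = correlated_design(rng)
        Z, _, _ = standardize(X)
        y = (0.8 * Z["x1"] - 0.4 * Z["x2"]
             + rng.normal(0, 0.4, 28)).to_numpy()
        ms = all_subsets_aicc(y, Z)
        full = average_parameters(ms, method="full").table["estimate"]
        cond = average_parameters(ms, method="conditional").table["estimate"]
        assert (full.abs() <= cond.abs() + 1e-12).all()

    def test_parameter_recovery(self, rng):
        est1, est2 = [], []
        for _ in range(50):
            Z, _, _ = standardize(correlated_design(rng))
            y = (0.8 * Z["x1"] - 0.4 * Z["x2"]
                 + rng.normal(0, 0.4, 28)).to_numpy()
            avg = average_parameters(all_subsets_aicc(y, Z))
            est1.append(avg.table.loc["x1", "estimate"])
            est2.append(avg.table.loc["x2", "estimate"])
        assert abs(np.mean(est1) - 0.8) < 0.15
        assert abs(np.mean(est2) - (-0.4)) < 0.15


class TestRelativeEffects:
    def test_direct_ratio(self):
        out = relative_effects(pd.Series({"a": 2.0, "b": 1.0, "c": 1.0}))
        assert out.tolist() == [50.0, 25.0, 25.0]

    def test_single_predictor(self):
        assert relative_effects(pd.Series({"a": 0.3}))["a"] == 100.0

    def test_mixed_signs_use_absolute_values(self):
        out = relative_effects(pd.Series({"a": 2.0, "b": -2.0}))
        assert out.tolist() == [50.0, 50.0]

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            relative_effects(pd.Series({"a": 0.0, "b": 0.0}))

    def test_sums_to_100_in_averaged_table(self, rng):
        Z, _, _ = standardize(correlated_design(rng))
        y = (Z["x1"] + rng.normal(0, 0.5, 28)).to_numpy()
        avg = average_parameters(all_subsets_aicc(y, Z))
        assert avg.table["relative_effect"].sum() == pytest.approx(
            100.0, abs=1e-8
        )


class TestExplainedVariability:
    def test_exact_linear_response_is_100_percent(self, rng):
        X = correlated_design(rng)
        y = (X @ np.arange(1, 6)).to_numpy()
        ev = explained_variability(all_subsets_aicc(y, X))
        assert ev["global_r2_percent"] == pytest.approx(100.0, abs=1e-8)

    def test_null_response_r2_small_but_positive(self, rng):
        r2s = [
            explained_variability(
                all_subsets_aicc(rng.normal(size=28),
                                 correlated_design(rng))
            )["global_r2_percent"]
            for _ in range(30)
        ]
        # E[R2] = p/(n-1) = 5/27 under the null
        assert 0 < np.mean(r2s) < 40
        assert abs(np.mean(r2s) - 100 * 5 / 27) < 10

    def test_known_variance_split(self, rng):
        r2s = []
        for _ in range(40):
            Z, _, _ = standardize(correlated_design(rng, n=200, rho=0.0))
            signal = Z["x1"].to_numpy()
            y = signal + rng.normal(0, 1.0, 200)
            r2s.append(
                explained_variability(all_subsets_aicc(y, Z))
                ["global_r2_percent"]
            )
        assert abs(np.mean(r2s) - 50.0) < 5.0


class TestEnvironmentalDeltas:
    def test_deltas_are_treatment_minus_block_ambient(self):
        meta = pd.DataFrame({
            "sample": ["a0", "a1", "b0", "b1"],
            "block": ["b1", "b1", "b2", "b2"],
            "n_level": [0, 8, 0, 8],
            "group": "plant",
        })
        env = pd.DataFrame({
            "sample": ["a0", "a1", "b0", "b1"],
            "ph": [7.0, 6.0, 6.8, 5.5],
            "mn": [5.0, 9.0, 4.0, 10.0],
        })
        comp = pd.DataFrame({
            "group": "plant", "block": ["b1", "b2"],
            "n_level": [8, 8], "sample": ["a1", "b1"],
        })
        deltas = environmental_deltas(env, meta, comp)
        assert deltas["ph"].tolist() == pytest.approx([-1.0, -1.3])
        assert deltas["mn"].tolist() == pytest.approx([4.0, 6.0])
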