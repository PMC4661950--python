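import json

import numpy as np
import pandas as pd
import pytest

from fosbio.basis import CandidateBasis, expand_candidates
from fosbio.features_io import NormalizationParams, fit_normalization
from fosbio.fos_core import FOSModel, RankError, fos_fit, greedy_forward_ols, predict


def _identity_pool(p):
    return [CandidateBasis("identity", f"m{j}") for j in range(p)]


def _random_instance(rng, duplicate=False):
    n = int(rng.integers(10, 51))
    p = int(rng.integers(5, 41))
    order = int(rng.integers(1, 7))
    X = rng.standard_normal((n, p))
    if duplicate and p >= 2:
        X[:, 1] = X[:, 0]
    y = rng.standard_normal(n)
    return X, _identity_pool(p), y, order


class TestSelection:
    def test_constant_target_is_absorbed_by_the_first_term(self):
        X = np.random.default_rng(0).standard_normal((12, 4))
        y = np.full(12, 7.5)
        model = fos_fit(X, _identity_pool(4), y, 1)
        assert model.selected[0].kind == "constant"
        assert model.coefficients[0] == pytest.approx(7.5)
        assert model.train_mse_path[0] == pytest.approx(0.0, abs=1e-20)

    def test_exact_cubic_component_is_found_first(self):
        rng = np.random.default_rng(1)
        z = pd.DataFrame(rng.uniform(0, 1, (40, 5)), columns=[f"m{i}" for i in range(5)])
        candidates, design = expand_candidates(z)
        y = 2.0 + 3.0 * z["m3"].to_numpy() ** 3
        model = fos_fit(design, candidates, y, 2)
        term = model.selected[1]
        assert (term.kind, term.metric) == ("cube", "m3")
        assert model.train_mse_path[-1] <= 1e-12 * np.var(y)

    def test_order_one_model_is_the_mean_with_mse_equal_to_variance(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 6))
        y = rng.standard_normal(30)
        model = greedy_forward_ols(X, _identity_pool(6), y, 1)
        assert model.coefficients[0] == pytest.approx(y.mean())
        assert model.train_mse_path[0] == pytest.approx(np.var(y))

    def test_duplicate_column_never_selected_twice(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((25, 6))
        X[:, 1] = X[:, 0]
        y = X[:, 0] * 2.0 + rng.standard_normal(25) * 0.1
        model = fos_fit(X, _identity_pool(6), y, 4)
        idx = model.selected_indices[1:]
        assert not {0, 1} <= set(idx)

    def test_rank_error_reports_achievable_order(self):
        X = np.ones((10, 3))  # all candidates collinear with the constant
        y = np.random.default_rng(4).standard_normal(10)
        with pytest.raises(RankError) as err:
            fos_fit(X, _identity_pool(3), y, 3)
        assert err.value.achievable == 1

    def test_noise_free_recovery_of_generating_columns(self):
        rng = np.random.default_rng(5)
        for k in (1, 2, 3):
            X = rng.standard_normal((50, 20))
            sel = rng.choice(20, size=k, replace=False)
            y = 0.5 + X[:, sel] @ rng.uniform(1, 2, k)
            model = fos_fit(X, _identity_pool(20), y, k + 1)
            assert set(model.selected_indices[1:]) == set(sel.tolist())
            assert model.train_mse_path[-1] <= 1e-12 * np.var(y)


class TestOracleEquivalence:
    def test_selection_and_mse_paths_match_on_random_instances(self, rng):
        for trial in range(60):
            X, cands, y, order = _random_instance(rng, duplicate=trial % 3 == 0)
            a = fos_fit(X, cands, y, order)
            b = greedy_forward_ols(X, cands, y, order)
            assert a.selected_indices == b.selected_indices, f"trial {trial}"
            np.testing.assert_allclose(a.train_mse_path, b.train_mse_path, rtol=1e-10)
            np.testing.assert_allclose(a.coefficients, b.coefficients, rtol=1e-8, atol=1e-10)

    def test_mse_path_is_non_increasing(self, rng):
        for _ in range(20):
            X, cands, y, order = _random_instance(rng)
            model = fos_fit(X, cands, y, order)
            assert (np.diff(model.train_mse_path) <= 1e-12).all()

    def test_coefficients_solve_the_normal_equations(self, rng):
        X, cands, y, _ = _random_instance(rng)
        model = fos_fit(X, cands, y, 4)
        cols = np.column_stack(
            [np.ones(len(y))] + [X[:, j] for j in model.selected_indices[1:]]
        )
        residual = y - cols @ model.coefficients
        np.testing.assert_allclose(cols.T @ residual, 0.0, atol=1e-8)

    def test_candidate_permutation_changes_nothing_but_indices(self, rng):
        X, cands, y, order = _random_instance(rng)
        perm = rng.permutation(X.shape[1])
        a = fos_fit(X, cands, y, order)
        b = fos_fit(X[:, perm], [cands[j] for j in perm], y, order)
        assert [c.label for c in a.selected] == [c.label for c in b.selected]
        np.testing.assert_allclose(a.train_mse_path, b.train_mse_path, rtol=1e-10)


class TestPredict:
    def _exact_model(self, n=30, seed=6):
        rng = np.random.default_rng(seed)
        frame = pd.DataFrame(
            rng.uniform(1, 9, (n, 3)), columns=["a", "b", "c"],
            index=[f"s{i}" for i in range(n)],
        )
        params = fit_normalization(frame, ["a", "b", "c"])
        z = params.transform(frame)
        candidates, design = expand_candidates(z)
        y = 1.0 - 2.0 * z["a"].to_numpy() ** 2 + 0.5 * np.log(z["c"].to_numpy() + 1e-6)
        model = fos_fit(design, candidates, y, 3)
        return frame, params, model, y

    def test_constant_only_model_predicts_its_coefficient(self):
        model = FOSModel([CandidateBasis("constant")], np.array([7.0]), np.array([1.0]))
        frame = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        params = NormalizationParams({"x": (1.0, 3.0)})
        assert predict(model, frame, params).tolist() == [7.0, 7.0, 7.0]

    def test_exact_fit_reproduces_training_targets(self):
        frame, params, model, y = self._exact_model()
        np.testing.assert_allclose(predict(model, frame, params), y, atol=1e-8)

    def test_row_permutation_permutes_predictions(self):
        frame, params, model, _ = self._exact_model()
        perm = np.random.default_rng(7).permutation(len(frame))
        base = predict(model, frame, params)
        shuffled = predict(model, frame.iloc[perm], params)
        np.testing.assert_allclose(shuffled, base[perm])

    def test_missing_metric_is_a_contract_error(self):
        frame, params, model, _ = self._exact_model()
        with pytest.raises(KeyError):
            predict(model, frame.drop(columns=[model.metrics[0]]), params)

    def test_model_json_round_trip(self):
        _, _, model, _ = self._exact_model()
        again = FOSModel.from_json(model.to_json())
        assert [c.label for c in again.selected] == [c.label for c in model.selected]
        np.testing.assert_allclose(again.coefficients, model.coefficients)
        payload = json.loads(model.to_json())
        assert set(payload) == {"target", "terms", "train_mse_path"}
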