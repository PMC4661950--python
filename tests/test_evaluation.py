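import numpy as np
import pandas as pd
import pytest

from fosbio.evaluation import (
    clip_to_range,
    compare_r,
    compare_r_from_predictions,
    compute_r,
    cross_validate,
    pearson_r,
)
from fosbio.features_io import BiomarkerTable, TargetSpec, fit_normalization
from fosbio.basis import expand_candidates


FIM_TOTAL = TargetSpec("FIM-Total-2w", 18, 126)
FIM_MOTOR = TargetSpec("FIM-Motor-2w", 13, 91)


class TestRValue:
    def test_perfect_prediction_scores_one(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert compute_r(y, y) == pytest.approx(1.0)

    def test_perfect_anticorrelation_clamps_to_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert compute_r(y, -y) == 0.0
        assert pearson_r(y, -y) == pytest.approx(-1.0)

    def test_constant_prediction_scores_zero_by_convention(self):
        y = np.array([1.0, 2.0, 3.0])
        assert compute_r(y, np.full(3, 5.0)) == 0.0

    def test_length_mismatch_is_a_contract_error(self):
        with pytest.raises(ValueError):
            compute_r([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_invariant_under_common_affine_rescaling(self, rng):
        y = rng.standard_normal(50)
        pred = y + rng.standard_normal(50)
        assert compute_r(3.0 * y - 7.0, 3.0 * pred - 7.0) == pytest.approx(
            compute_r(y, pred)
        )


class TestClipping:
    @pytest.mark.parametrize(
        "value,spec,expected",
        [
            (130.0, FIM_TOTAL, 126.0),
            (10.0, FIM_MOTOR, 13.0),
            (100.0, FIM_TOTAL, 100.0),
            (5.0, FIM_TOTAL, 18.0),
        ],
    )
    def test_out_of_range_scores_snap_to_the_scale_limits(self, value, spec, expected):
        assert clip_to_range(value, spec) == expected

    def test_clipping_never_worsens_error_against_in_range_actuals(self, rng):
        actual = rng.uniform(18, 126, 200)
        pred = actual + rng.normal(0, 40, 200)
        clipped = clip_to_range(pred, FIM_TOTAL)
        assert (np.abs(clipped - actual) <= np.abs(pred - actual) + 1e-12).all()


def _table_from_frame(frame):
    return BiomarkerTable(
        data=frame, group_map={c: "G" for c in frame.columns},
        dataset_unions={"G-set": ("G",)},
    )


def _noise_free_setup(n=60, seed=11):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        rng.uniform(0, 10, (n, 6)), columns=[f"g{i}" for i in range(6)],
        index=[f"s{i}" for i in range(n)],
    )
    table = _table_from_frame(frame)
    params = fit_normalization(table, list(frame.columns))
    z = params.transform(frame)
    # two log terms: distinctive enough for exact greedy identification in
    # every fold, and the noise-free target stays inside the valid range so
    # prediction clipping is a no-op
    y = (
        100.0
        + 4.0 * np.log(z["g1"].to_numpy() + 1e-6)
        + 2.5 * np.log(z["g4"].to_numpy() + 1e-6)
    )
    return table, list(frame.columns), TargetSpec("FIM-Total-2w", 18, 126, y)


class TestCrossValidate:
    def test_noise_free_two_term_target_saturates_at_order_three(self):
        table, cols, spec = _noise_free_setup()
        cv = cross_validate(table, cols, spec, max_order=5, k=5, seed=1)
        assert np.allclose(cv.mean_r[2:], 1.0, atol=1e-9)
        assert cv.chosen_order == 3
        assert cv.overall_r == pytest.approx(1.0)

    def test_folds_partition_subjects(self):
        table, cols, spec = _noise_free_setup()
        cv = cross_validate(table, cols, spec, max_order=3, k=5, seed=2)
        counts = np.bincount(cv.fold_assignments, minlength=5)
        assert counts.sum() == table.n_subjects
        assert (counts > 0).all()

    def test_same_seed_reproduces_the_result_exactly(self):
        table, cols, spec = _noise_free_setup()
        a = cross_validate(table, cols, spec, max_order=4, k=5, seed=3)
        b = cross_validate(table, cols, spec, max_order=4, k=5, seed=3)
        np.testing.assert_array_equal(a.per_order_r, b.per_order_r)
        assert a.chosen_order == b.chosen_order

    def test_more_orders_never_lower_the_best_mean_r(self):
        table, cols, spec = _noise_free_setup(seed=12)
        rng = np.random.default_rng(0)
        noisy = spec.with_values(spec.values + rng.normal(0, 5, table.n_subjects))
        short = cross_validate(table, cols, noisy, max_order=4, k=5, seed=4)
        long = cross_validate(table, cols, noisy, max_order=9, k=5, seed=4)
        assert long.mean_r.max() >= short.mean_r.max() - 1e-12

    def test_train_fold_scope_shields_training_from_test_outliers(self):
        table, cols, spec = _noise_free_setup(seed=13)
        cv_ref = cross_validate(table, cols, spec, max_order=3, k=5, seed=5,
                                norm_scope="train_fold")
        # corrupt one subject's metrics with an extreme outlier
        frame = table.data.copy()
        victim = 4
        frame.iloc[victim, :] = 1e6
        cv_out = cross_validate(_table_from_frame(frame), cols, spec, max_order=3,
                                k=5, seed=5, norm_scope="train_fold")
        fold = cv_ref.fold_assignments[victim]
        mates = (cv_ref.fold_assignments == fold) & (np.arange(len(frame)) != victim)
        # fold-mates' held-out predictions depend only on the (unchanged) training fold
        np.testing.assert_allclose(
            cv_out.pooled_predictions[mates, :], cv_ref.pooled_predictions[mates, :]
        )

    def test_fewer_subjects_than_folds_rejected(self):
        table, cols, spec = _noise_free_setup(n=8)
        with pytest.raises(ValueError):
            cross_validate(table, cols, spec, k=10)


class TestCompareR:
    def test_equal_r_values_give_p_one(self):
        assert compare_r(0.5, 0.5, 85, "independent") == pytest.approx(1.0)
        assert compare_r(0.5, 0.5, 85, "dependent-overlapping", r12=0.3) == pytest.approx(1.0)

    def test_large_independent_gap_is_significant(self):
        assert compare_r(0.9, 0.1, 100, "independent") < 0.001

    def test_independent_matches_monte_carlo_type_i_rate(self, rng):
        # under H0 (equal true correlation), p < 0.05 should occur ~5% of the time
        hits = 0
        sims = 400
        for _ in range(sims):
            x1 = rng.standard_normal(60)
            y1 = 0.5 * x1 + rng.standard_normal(60)
            x2 = rng.standard_normal(60)
            y2 = 0.5 * x2 + rng.standard_normal(60)
            p = compare_r(abs(pearson_r(x1, y1)), abs(pearson_r(x2, y2)), 60, "independent")
            hits += p < 0.05
        assert 0.02 <= hits / sims <= 0.10

    def test_dependent_with_zero_interprediction_r_nears_independent_form(self):
        p_dep = compare_r(0.10, 0.02, 200, "dependent-overlapping", r12=0.0)
        p_ind = compare_r(0.10, 0.02, 200, "independent")
        assert p_dep == pytest.approx(p_ind, rel=0.02)

    def test_contract_violations(self):
        with pytest.raises(ValueError):
            compare_r(1.0, 0.5, 100, "independent")
        with pytest.raises(ValueError):
            compare_r(0.5, 0.4, 5, "independent")
        with pytest.raises(ValueError):
            compare_r(0.5, 0.4, 100, "dependent-overlapping")  # r12 missing

    def test_prediction_level_helper_stamps_method(self, rng):
        y = rng.standard_normal(80)
        res = compare_r_from_predictions(y, y + rng.normal(0, 1, 80), y + rng.normal(0, 1, 80))
        assert res["method"] == "steiger-dependent-z"
        assert 0.0 <= res["p"] <= 1.0
        assert res["n"] == 80
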