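import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from klsnet import (
    PatientRecord,
    PredictionResult,
    loocv_predict,
    permutation_test,
    permutation_test_loocv,
    summarize_weights,
    train_svr,
)
from klsnet.atlas import aal90_lookup
from klsnet.survival_model import svr_objective


class TestTrainSVR:
    def test_recovers_slope_in_least_squares_limit(self, rng):
        x = rng.normal(size=(100, 1))
        y = 2.5 * x[:, 0]
        model = train_svr(x, y, C=1e6, eps=0.0)
        assert model.weights.iloc[0] == pytest.approx(2.5, rel=0.01)

    def test_zero_outcome_gives_zero_weights(self, rng):
        x = rng.normal(size=(30, 4))
        model = train_svr(x, np.zeros(30))
        np.testing.assert_allclose(model.weights.to_numpy(), 0.0, atol=1e-8)

    def test_returned_weights_minimize_objective(self, rng):
        x = rng.normal(size=(40, 3))
        y = x @ np.array([1.0, -2.0, 0.5]) + rng.normal(0, 0.5, 40)
        model = train_svr(x, y, C=1.0, eps=0.1)
        w = model.weights.to_numpy()
        obj = svr_objective(w, x, y, 1.0, 0.1)
        assert obj <= svr_objective(np.zeros(3), x, y, 1.0, 0.1)
        for _ in range(50):
            delta = rng.normal(0, 0.05, 3)
            assert obj <= svr_objective(w + delta, x, y, 1.0, 0.1) + 1e-8

    def test_matches_independent_convex_solver(self, rng):
        x = rng.normal(size=(25, 2))
        y = x @ np.array([1.5, -1.0]) + rng.normal(0, 0.3, 25)
        model = train_svr(x, y, C=2.0, eps=0.1)
        res = minimize(
            svr_objective, np.zeros(2), args=(x, y, 2.0, 0.1), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
        )
        np.testing.assert_allclose(model.weights.to_numpy(), res.x, atol=1e-3)

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError):
            train_svr(np.array([[np.nan], [1.0]]), np.array([0.0, 1.0]))


def make_cohort(factory, **kw):
    cohort = factory(**kw)
    return cohort.patient_records(), cohort.controls_table()


class TestLOOCV:
    def test_one_prediction_per_patient(self, direct_cohort_factory):
        patients, controls = make_cohort(
            direct_cohort_factory, seed=1, n_patients=12, n_controls=10,
            planted=[(1, 2, 2.0)], betas={(1, 2): 30.0},
        )
        res = loocv_predict(patients, controls, select_on="raw")
        assert len(res.predicted) == len(res.observed) == 12
        assert len(res.fold_weights) == 12

    def test_noiseless_linear_outcome_recovered(self, direct_cohort_factory):
        patients, controls = make_cohort(
            direct_cohort_factory, seed=11, n_patients=60, n_controls=40, n_regions=10,
            planted=[(1, 2, 2.0), (3, 4, 2.0), (5, 6, 2.0), (7, 8, 2.0), (9, 10, 2.0)],
            betas={(1, 2): 40, (3, 4): -30, (5, 6): 25, (7, 8): 35, (9, 10): -20},
            survival_noise_sd=0.0,
        )
        res = loocv_predict(patients, controls)
        assert res.pearson_r >= 0.95

    def test_permuted_labels_give_null_correlation(self, direct_cohort_factory):
        cohort = direct_cohort_factory(
            seed=5, n_patients=30, n_controls=20, n_regions=8,
            planted=[(1, 2, 1.5), (3, 4, 1.5)],
        )
        patients = cohort.patient_records()
        controls = cohort.controls_table()
        y = np.array([p.overall_survival for p in patients])
        rs = []
        for seed in range(20):
            perm = np.random.default_rng(seed).permutation(len(y))
            shuffled = [
                PatientRecord(p.subject_id, p.connection_features, p.age, p.sex, y[perm[i]])
                for i, p in enumerate(patients)
            ]
            rs.append(loocv_predict(shuffled, controls, select_on="raw").pearson_r)
        assert abs(np.mean(rs)) <= 0.15

    def test_loocv_tracks_target_population_correlation(self, direct_cohort_factory):
        # population r pinned to 0.5 analytically; LOOCV estimate lands nearby
        rs = []
        for seed in range(20):
            patients, controls = make_cohort(
                direct_cohort_factory, seed=seed, n_patients=60, n_controls=40, n_regions=8,
                planted=[(1, 2, 1.5), (3, 4, 1.5), (5, 6, 1.5)],
                betas={(1, 2): 40, (3, 4): -30, (5, 6): 25},
                outcome_target_r=0.5,
            )
            rs.append(loocv_predict(patients, controls).pearson_r)
        assert 0.3 <= np.mean(rs) <= 0.6

    def test_no_leakage_from_held_out_outcome(self, direct_cohort_factory):
        patients, controls = make_cohort(
            direct_cohort_factory, seed=2, n_patients=10, n_controls=8,
            planted=[(1, 2, 2.0)], betas={(1, 2): 30.0},
        )
        res_a = loocv_predict(patients, controls, select_on="raw")
        perturbed = list(patients)
        k = 4
        perturbed[k] = PatientRecord(
            patients[k].subject_id, patients[k].connection_features,
            patients[k].age, patients[k].sex, patients[k].overall_survival + 25.0,
        )
        res_b = loocv_predict(perturbed, controls, select_on="raw")
        pd.testing.assert_series_equal(res_a.fold_weights[k], res_b.fold_weights[k])

    def test_empty_selection_falls_back_to_mean(self, direct_cohort_factory):
        # no planted effects + FDR selection -> (nearly) no features chosen
        patients, controls = make_cohort(
            direct_cohort_factory, seed=3, n_patients=10, n_controls=8, n_regions=6
        )
        res = loocv_predict(patients, controls, select_on="fdr")
        assert len(res.predicted) == 10
        assert all(np.isfinite(res.predicted))

    def test_fixed_selection_mode(self, direct_cohort_factory):
        patients, controls = make_cohort(
            direct_cohort_factory, seed=4, n_patients=15, n_controls=12,
            planted=[(1, 2, 2.5)], betas={(1, 2): 30.0},
        )
        res = loocv_predict(patients, controls, selection="fixed", select_on="raw")
        assert len({tuple(w.index) for w in res.fold_weights}) == 1

    def test_too_few_patients_rejected(self, direct_cohort_factory):
        patients, controls = make_cohort(
            direct_cohort_factory, seed=6, n_patients=10, n_controls=8
        )
        with pytest.raises(ValueError):
            loocv_predict(patients[:2], controls)


def synthetic_result(predicted, observed):
    n = len(predicted)
    predicted = np.asarray(predicted, float)
    observed = np.asarray(observed, float)
    r = float(np.corrcoef(predicted, observed)[0, 1])
    return PredictionResult(
        subject_ids=[f"p{k}" for k in range(n)],
        predicted=predicted,
        observed=observed,
        observed_raw=observed,
        pearson_r=r,
    )


class TestPermutationTest:
    def test_anticorrelated_result_gives_p_one(self):
        x = np.linspace(1, 10, 8)
        res = synthetic_result(x, -x)  # every permutation r >= -1 = observed
        assert permutation_test(res, n_perm=200, seed=0) == pytest.approx(1.0)

    def test_perfectly_predictive_result_add_one_convention(self):
        x = np.linspace(1, 20, 10)
        res = synthetic_result(x, x)  # only the identity ordering reaches r = 1
        p = permutation_test(res, n_perm=9999, seed=1)
        assert p == pytest.approx(1e-4)

    def test_coupled_cohort_significant(self, direct_cohort_factory):
        patients, controls = make_cohort(
            direct_cohort_factory, seed=8, n_patients=40, n_controls=30, n_regions=8,
            planted=[(1, 2, 2.0), (3, 4, 2.0)],
            betas={(1, 2): 40.0, (3, 4): -35.0}, survival_noise_sd=2.0,
        )
        res = loocv_predict(patients, controls)
        assert permutation_test(res, n_perm=999, seed=0) <= 0.01

    def test_full_rerun_mode_agrees_on_strong_signal(self, direct_cohort_factory):
        patients, controls = make_cohort(
            direct_cohort_factory, seed=9, n_patients=20, n_controls=15, n_regions=6,
            planted=[(1, 2, 2.5)], betas={(1, 2): 40.0}, survival_noise_sd=2.0,
        )
        p = permutation_test_loocv(
            patients, controls, n_perm=39, seed=0, select_on="raw"
        )
        assert p <= 0.05


class TestWeightSummaries:
    def test_within_lobe_connections_sum_absolutely(self):
        _, _, lobe_map = aal90_lookup()
        # two temporal-temporal connections (region ids 89, 85, 81 are temporal)
        weights = pd.Series({"85-89": -13.70, "81-87": 15.04})
        lobes = summarize_weights(weights, lobe_map)
        assert lobes["temporal"] == pytest.approx(28.74)

    def test_cross_lobe_connection_counts_for_both(self):
        lobes = summarize_weights(
            pd.Series({"1-2": 3.0}), {1: "frontal", 2: "temporal"}
        )
        assert lobes == {"frontal": 3.0, "temporal": 3.0}

    def test_zero_weights_give_zero_totals(self):
        lobes = summarize_weights(pd.Series({"1-2": 0.0}), {1: "a", 2: "a"})
        assert lobes == {"a": 0.0}

    def test_unmapped_region_rejected(self):
        with pytest.raises(KeyError):
            summarize_weights(pd.Series({"1-99": 1.0}), {1: "a"})

    def test_loocv_weights_aggregate(self, direct_cohort_factory):
        cohort = direct_cohort_factory(
            seed=10, n_patients=20, n_controls=15, n_regions=6,
            planted=[(1, 2, 2.5)], betas={(1, 2): 30.0},
        )
        res = loocv_predict(cohort.patient_records(), cohort.controls_table(), select_on="raw")
        lobe_map = {rid: "left" if rid <= 3 else "right" for rid in range(1, 7)}
        lobes = summarize_weights(res.mean_weights, lobe_map)
        assert all(v >= 0 for v in lobes.values())
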