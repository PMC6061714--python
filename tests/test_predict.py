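"""PCR/PLS calibration, overlap exclusion, design-level prediction."""

import numpy as np
import pandas as pd
import pytest

import rtshift as rt


@pytest.fixture(scope="module")
def X_default(ds_default):
    return ds_default.retention.values


@pytest.fixture(scope="module")
def X_clean(ds_clean):
    return ds_clean.retention.values


class TestExcludeOverlapping:
    def test_zero_window_excludes_only_target(self, X_default):
        target = X_default.columns[0]
        cal = rt.exclude_overlapping(X_default, target, rt_window=0.0)
        assert target not in cal
        assert len(cal) == X_default.shape[1] - 1

    def test_forced_coelution_is_excluded(self, X_default):
        X = X_default.copy()
        a, b = X.columns[3], X.columns[50]
        X.iloc[7, X.columns.get_loc(b)] = X.iloc[7, X.columns.get_loc(a)] + 0.05
        cal = rt.exclude_overlapping(X, a, rt_window=0.2)
        assert b not in cal

    def test_exclusion_is_symmetric(self, X_default):
        window = 0.2
        for target in X_default.columns[::13]:
            for other in X_default.columns[::17]:
                if other == target:
                    continue
                a = other in rt.exclude_overlapping(X_default, target, window)
                b = target in rt.exclude_overlapping(X_default, other, window)
                assert a == b

    def test_only_elution_neighbours_are_excluded(self, X_default):
        # an excluded calibrant must elute close to the target on average:
        # the shift amplitudes bound how far apart co-eluters can sit
        target = X_default.columns[40]
        cal = set(rt.exclude_overlapping(X_default, target, rt_window=0.2))
        excluded = [c for c in X_default.columns if c != target and c not in cal]
        mean_rt = X_default.mean(axis=0)
        assert all(abs(mean_rt[c] - mean_rt[target]) < 2.5 for c in excluded)

    def test_missing_target_rejected(self, X_default):
        with pytest.raises(ValueError, match="not in retention"):
            rt.exclude_overlapping(X_default, "nope")


class TestFitPcr:
    def test_noiseless_design_data_predicts_exactly(self, X_clean):
        target = X_clean.columns[10]
        cal = rt.exclude_overlapping(X_clean, target, rt_window=0.0)
        model = rt.fit_pcr(X_clean, target, cal, n_components=5, cv=False)
        assert model.rrv_auto < 1e-8

    def test_residual_decreases_with_components(self, X_default):
        target = X_default.columns[20]
        cal = rt.exclude_overlapping(X_default, target)
        rrv = [
            rt.fit_pcr(X_default, target, cal, n_components=k, cv=False).rrv_auto
            for k in range(1, 8)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(rrv, rrv[1:]))

    def test_one_component_on_rank_two_data_leaves_residual(self, rng):
        T = rng.normal(size=(20, 2))
        P = rng.normal(size=(6, 2))
        X = pd.DataFrame(T @ P.T, columns=[f"c{i}" for i in range(6)])
        m1 = rt.fit_pcr(X, "c0", [f"c{i}" for i in range(1, 6)], 1, cv=False)
        m2 = rt.fit_pcr(X, "c0", [f"c{i}" for i in range(1, 6)], 2, cv=False)
        assert m2.rrv_auto < 1e-8 < m1.rrv_auto

    def test_cv_residual_not_better_than_auto(self, X_default):
        rrv_auto, rrv_cv = [], []
        for target in X_default.columns[::9]:
            cal = rt.exclude_overlapping(X_default, target)
            m = rt.fit_pcr(X_default, target, cal, n_components=6)
            rrv_auto.append(m.rrv_auto)
            rrv_cv.append(m.rrv_cv)
        # optimism inequality, in expectation over compounds
        assert np.mean(rrv_cv) >= np.mean(rrv_auto)

    def test_target_among_calibrants_rejected(self, X_default):
        c = X_default.columns[0]
        with pytest.raises(ValueError):
            rt.fit_pcr(X_default, c, [c], 1)

    def test_too_many_components_rejected(self, X_clean):
        target = X_clean.columns[0]
        cal = rt.exclude_overlapping(X_clean, target, rt_window=0.0)
        with pytest.raises(ValueError, match="rank"):
            rt.fit_pcr(X_clean, target, cal, n_components=20, cv=False)


class TestFitPls:
    def test_noiseless_design_data_predicts_exactly(self, X_clean):
        target = X_clean.columns[10]
        cal = rt.exclude_overlapping(X_clean, target, rt_window=0.0)
        model = rt.fit_pls(X_clean, target, cal, n_components=5, cv=False)
        assert model.rrv_auto < 1e-8

    def test_zero_components_rejected(self, X_default):
        target = X_default.columns[0]
        with pytest.raises(ValueError):
            rt.fit_pls(X_default, target, [X_default.columns[1]], 0)

    def test_pls_and_pcr_practically_the_same(self, X_default):
        # cross-validated residual variances agree on the absolute scale
        # (both are within 1% of the compound's retention variance) for the
        # overwhelming majority of compounds
        gaps = []
        for target in X_default.columns[::4]:
            cal = rt.exclude_overlapping(X_default, target)
            a = rt.fit_pcr(X_default, target, cal, n_components=6).rrv_cv
            b = rt.fit_pls(X_default, target, cal, n_components=6).rrv_cv
            gaps.append(abs(a - b))
        assert np.mean(np.array(gaps) < 0.01) >= 0.9


@pytest.fixture(scope="module")
def levels_default(X_default, design):
    return rt.predict_design_levels(X_default, design)


class TestPredictDesignLevels:
    def test_noiseless_strong_terms_calibrate_exactly(self, X_clean, design):
        res = rt.predict_design_levels(X_clean, design, cv=False)
        for term in ("pH", "temperature", "pH^2"):
            assert res.rmsec.loc[term, 5] < 1e-6

    def test_rmsec_non_increasing_in_components(self, levels_default):
        arr = levels_default.rmsec.to_numpy()
        assert np.all(np.diff(arr, axis=1) <= 1e-10)

    def test_null_terms_stay_unpredictable(self, spec, design):
        truth = rt.default_ground_truth(
            spec, seed=8,
            coefficient_sd={"temperature^2": 0.0, "pH*temperature": 0.0},
        )
        ds = rt.simulate_retention(design, truth, seed=8)
        res = rt.predict_design_levels(ds.retention.values, design)
        col_sd = design.frame[["temperature^2", "pH*temperature"]].std(ddof=0)
        for term in ("temperature^2", "pH*temperature"):
            assert (res.rmsecv.loc[term] >= 0.8 * col_sd[term]).all()

    def test_center_replicates_predicted_at_coded_zero(self, levels_default, design):
        k = 6
        preds = levels_default.cv_predictions[k].loc[design.is_replicate]
        for term in preds.columns:
            tol = 3 * levels_default.rmsecv.loc[term, k]
            assert np.abs(preds[term]).max() <= tol

    def test_best_component_count_plausible(self, levels_default, design):
        k = levels_default.best_n_components()
        assert 4 <= k <= len(design.frame) - 1

    def test_out_of_range_components_rejected(self, X_default, design):
        with pytest.raises(ValueError):
            rt.predict_design_levels(X_default, design, component_range=[0, 1])


class TestResidualVarianceComparison:
    def test_clean_data_all_methods_near_zero(self, X_clean, design):
        tab = rt.residual_variance_comparison(
            X_clean, design, n_components=5, include_cv=False
        )
        assert tab["mlr_auto"].max() < 1e-10
        assert tab["pcr_auto"].max() < 1e-10

    def test_latent_factor_favours_pcr(self, X_default, design):
        tab = rt.residual_variance_comparison(
            X_default, design, n_components=6, include_cv=False
        )
        assert tab["pcr_auto"].median() < tab["mlr_auto"].median()
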