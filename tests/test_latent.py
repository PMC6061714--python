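"""PCA, the scores<->design conversion bridge, and ASCA."""

import numpy as np
import pandas as pd
import pytest

import rtshift as rt
from rtshift.latent import LatentDecomposition


def _mlr(ds, design):
    return rt.fit_mlr(ds.retention.values, design)


class TestFitPca:
    def test_rank_one_matrix_fully_explained(self, rng):
        X = pd.DataFrame(np.outer(rng.normal(size=8), rng.normal(size=5)))
        pca = rt.fit_pca(X, n_components=1, center=False)
        assert np.abs(pca.residual.to_numpy()).max() < 1e-10
        assert pca.explained_variance.iloc[0] == pytest.approx(1.0)

    def test_loadings_orthonormal_scores_orthogonal(self, ds_default):
        pca = rt.fit_pca(ds_default.retention.values, n_components=6)
        P = pca.loadings.to_numpy()
        np.testing.assert_allclose(P.T @ P, np.eye(6), atol=1e-10)
        TtT = pca.scores.to_numpy().T @ pca.scores.to_numpy()
        off = TtT - np.diag(np.diag(TtT))
        assert np.abs(off).max() < 1e-8

    def test_reconstruction_identity(self, ds_default):
        X = ds_default.retention.values
        pca = rt.fit_pca(X, n_components=4)
        np.testing.assert_allclose(pca.reconstruct().to_numpy(), X.to_numpy(), atol=1e-10)

    def test_explained_variance_against_eigendecomposition(self, rng):
        X = pd.DataFrame(rng.normal(size=(3, 2)))
        pca = rt.fit_pca(X, n_components=2)
        Xc = X - X.mean(axis=0)
        evals = np.sort(np.linalg.eigh(Xc.T @ Xc)[0])[::-1]
        np.testing.assert_allclose(
            pca.explained_variance.to_numpy(), evals / evals.sum(), atol=1e-12
        )

    def test_sign_convention_largest_loading_positive(self, ds_default):
        pca = rt.fit_pca(ds_default.retention.values, n_components=6)
        P = pca.loadings.to_numpy()
        for k in range(P.shape[1]):
            assert P[np.argmax(np.abs(P[:, k])), k] > 0

    def test_explained_variance_monotone_and_bounded(self, ds_default):
        pca = rt.fit_pca(ds_default.retention.values, n_components=8)
        ev = pca.explained_variance.to_numpy()
        assert np.all(np.diff(ev) <= 1e-15)
        assert ev.sum() <= 1.0 + 1e-12

    def test_matches_sklearn_pca_variances(self, ds_default):
        # independent implementation cross-check
        from sklearn.decomposition import PCA

        X = ds_default.retention.values.to_numpy()
        ours = rt.fit_pca(ds_default.retention.values, n_components=6)
        ref = PCA(n_components=6).fit(X)
        np.testing.assert_allclose(
            ours.explained_variance.to_numpy(),
            ref.explained_variance_ratio_,
            rtol=1e-8,
        )

    def test_component_count_out_of_range(self, ds_default):
        with pytest.raises(ValueError):
            rt.fit_pca(ds_default.retention.values, n_components=0)
        with pytest.raises(ValueError):
            rt.fit_pca(ds_default.retention.values, n_components=31)


class TestFitConversion:
    def test_scores_equal_to_design_give_identity(self, design):
        D_ni = design.frame.drop(columns="intercept")
        T = D_ni - D_ni.mean(axis=0)
        conv = rt.fit_conversion(T, design)
        np.testing.assert_allclose(conv.matrix.to_numpy(), np.eye(5), atol=1e-10)
        assert np.abs(conv.residual.to_numpy()).max() < 1e-10

    def test_scores_spanning_design_space_fit_perfectly(self, design):
        D_ni = design.frame.drop(columns="intercept").to_numpy()
        Dc = D_ni - D_ni.mean(axis=0)
        Q, _ = np.linalg.qr(Dc)
        conv = rt.fit_conversion(pd.DataFrame(Q, index=design.run_labels), design)
        assert np.abs(conv.residual.to_numpy()).max() < 1e-10
        np.testing.assert_allclose(conv.fit_quality.to_numpy(), 1.0, atol=1e-12)

    def test_scores_orthogonal_to_design_give_zero_map(self, design, rng):
        D_ni = design.frame.drop(columns="intercept").to_numpy()
        Dc = D_ni - D_ni.mean(axis=0)
        T = rng.normal(size=(len(Dc), 3))
        T -= Dc @ np.linalg.lstsq(Dc, T, rcond=None)[0]  # project out design
        T -= T.mean(axis=0)
        conv = rt.fit_conversion(pd.DataFrame(T, index=design.run_labels), design)
        assert np.abs(conv.matrix.to_numpy()).max() < 1e-8

    def test_degenerate_score_column_rejected(self, design):
        T = pd.DataFrame(
            {"PC1": np.arange(30.0), "PC2": np.zeros(30)}, index=design.run_labels
        )
        with pytest.raises(ValueError, match="degenerate"):
            rt.fit_conversion(T, design)


class TestCoefficientsFromLoadings:
    def test_pca_route_reproduces_mlr_on_clean_data(self, design, ds_clean):
        mlr = _mlr(ds_clean, design)
        pca = rt.fit_pca(ds_clean.retention.values, n_components=5)
        conv = rt.fit_conversion(pca.scores, design)
        b = rt.coefficients_from_loadings(conv, pca, design)
        scale = np.abs(mlr.values.to_numpy()).max()
        assert np.abs(b.values.to_numpy() - mlr.values.to_numpy()).max() < 1e-8 * scale

    def test_identity_conversion_returns_loadings(self, design, ds_clean):
        pca = rt.fit_pca(ds_clean.retention.values, n_components=5)
        conv = rt.fit_conversion(pca.scores, design)
        conv.matrix.iloc[:, :] = np.eye(5)
        b = rt.coefficients_from_loadings(conv, pca, design)
        np.testing.assert_allclose(
            b.values.drop(index="intercept").to_numpy(),
            pca.loadings.to_numpy().T,
            atol=1e-10,
        )

    def test_invariant_under_joint_orthogonal_rotation(self, design, ds_default, rng):
        # rotating T and P together cancels in the conversion algebra
        pca = rt.fit_pca(ds_default.retention.values, n_components=5)
        conv = rt.fit_conversion(pca.scores, design)
        b_ref = rt.coefficients_from_loadings(conv, pca, design)
        R = np.linalg.qr(rng.normal(size=(5, 5)))[0]
        rot = LatentDecomposition(
            scores=pd.DataFrame(
                pca.scores.to_numpy() @ R, index=pca.scores.index,
                columns=pca.scores.columns,
            ),
            loadings=pd.DataFrame(
                pca.loadings.to_numpy() @ R, index=pca.loadings.index,
                columns=pca.loadings.columns,
            ),
            residual=pca.residual,
            explained_variance=pca.explained_variance,
            centering=pca.centering,
            singular_values=pca.singular_values,
        )
        conv_rot = rt.fit_conversion(rot.scores, design)
        b_rot = rt.coefficients_from_loadings(conv_rot, rot, design)
        np.testing.assert_allclose(
            b_rot.values.to_numpy(), b_ref.values.to_numpy(), atol=1e-8
        )

    def test_too_few_components_rejected(self, design, ds_default):
        pca = rt.fit_pca(ds_default.retention.values, n_components=3)
        conv = rt.fit_conversion(pca.scores, design)
        with pytest.raises(ValueError, match="singular"):
            rt.coefficients_from_loadings(conv, pca, design)

    def test_latent_contamination_skews_small_terms(self, spec, design):
        # with a strong uncontrolled factor the PCA route diverges from MLR
        # on the small terms, beyond the clean-data discrepancy
        clean = rt.default_ground_truth(spec, noise_sd=0.0, n_latent=0, seed=3)
        strong = rt.default_ground_truth(
            spec, noise_sd=0.0, n_latent=1, latent_score_sd=0.2, seed=3
        )

        def small_term_gap(truth):
            ds = rt.simulate_retention(design, truth, seed=3)
            mlr = _mlr(ds, design)
            pca = rt.fit_pca(ds.retention.values, n_components=5)
            conv = rt.fit_conversion(pca.scores, design)
            b = rt.coefficients_from_loadings(conv, pca, design)
            gap = (b.values - mlr.values).abs()
            return gap.loc[["temperature^2", "pH*temperature"]].to_numpy().max()

        assert small_term_gap(strong) > 100 * max(small_term_gap(clean), 1e-12)


class TestAsca:
    def test_partition_reconstructs_grand_centered_matrix(self, design, ds_default):
        X = ds_default.retention.values
        asca = rt.fit_asca(X, design)
        grand = X.loc[~design.is_replicate].mean(axis=0)
        np.testing.assert_allclose(
            asca.reconstruct().to_numpy(), (X - grand).to_numpy(), atol=1e-10
        )

    def test_null_factor_effect_is_zero(self, spec, design):
        # zero out everything temperature-related: its effect matrix vanishes
        truth = rt.default_ground_truth(
            spec, noise_sd=0.0, n_latent=0, seed=4,
            coefficient_sd={"temperature": 0.0, "temperature^2": 0.0,
                            "pH*temperature": 0.0},
        )
        ds = rt.simulate_retention(design, truth, seed=4)
        asca = rt.fit_asca(ds.retention.values, design)
        assert np.linalg.norm(asca.effects["temperature"].to_numpy()) < 1e-10

    def test_effect_matrices_orthogonal_on_pure_factorial(self, spec):
        pure = rt.DesignSpec(factors=spec.factors, center_replicates=0)
        dm = rt.build_design(pure)
        truth = rt.default_ground_truth(pure, noise_sd=0.0, n_latent=0, seed=5)
        ds = rt.simulate_retention(dm, truth, seed=5)
        asca = rt.fit_asca(ds.retention.values, dm)
        cross = np.trace(
            asca.effects["pH"].to_numpy().T @ asca.effects["temperature"].to_numpy()
        )
        assert abs(cross) < 1e-10

    def test_asca_route_matches_mlr_on_clean_data(self, design, ds_clean):
        mlr = _mlr(ds_clean, design)
        asca = rt.fit_asca(ds_clean.retention.values, design)
        b = rt.asca_coefficients(asca, design)
        assert np.abs(b.values.to_numpy() - mlr.values.to_numpy()).max() < 1e-6

    def test_large_terms_agree_under_latent_contamination(self, spec, design):
        truth = rt.default_ground_truth(spec, seed=6)
        ds = rt.simulate_retention(design, truth, seed=6)
        mlr = _mlr(ds, design)
        asca = rt.fit_asca(ds.retention.values, design)
        b = rt.asca_coefficients(asca, design)
        for term in ("pH", "temperature", "pH^2"):
            true_mag = truth.coefficients.loc[term].abs()
            strong = true_mag > 5 * truth.noise_sd
            if strong.sum() < 3:
                continue
            r = np.corrcoef(
                b.values.loc[term, strong], mlr.values.loc[term, strong]
            )[0, 1]
            assert r > 0.99

    def test_unbalanced_core_rejected_unless_forced(self, spec, design, ds_default):
        X = ds_default.retention.values.iloc[1:]  # drop one factorial run
        sub = rt.DesignMatrix(
            frame=design.frame.iloc[1:],
            coded=design.coded.iloc[1:],
            is_replicate=design.is_replicate[1:],
            spec=spec,
        )
        with pytest.raises(ValueError, match="unbalanced"):
            rt.fit_asca(X, sub)
        asca = rt.fit_asca(X, sub, force=True)  # type-I style means still exact
        grand = X.loc[~sub.is_replicate].mean(axis=0)
        np.testing.assert_allclose(
            asca.reconstruct().to_numpy(), (X - grand).to_numpy(), atol=1e-10
        )
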