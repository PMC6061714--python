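"""End-to-end workflows: simulate a study, analyze it, or run recovery MC.

Each stage writes plain CSV tables plus a JSON metadata sidecar carrying
the seed and configuration hash, so a run is reproducible byte-for-byte
from its config.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .data import RetentionMatrix
from .design import build_design
from .latent import (
    asca_coefficients,
    coefficients_from_loadings,
    fit_asca,
    fit_conversion,
    fit_pca,
)
from .peaks import classify_runs, filter_monoisotopic
from .predict import predict_design_levels, residual_variance_comparison
from .regression import coefficient_ci, fit_mlr, replicate_ci
from .simulate import (
    GroundTruth,
    SyntheticDataset,
    default_ground_truth,
    generate_peak_lists,
    simulate_retention,
)

__all__ = ["make_dataset", "simulate_to_dir", "analyze", "analyze_to_dir", "recover"]

log = logging.getLogger("rtshift")


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            if exc[0] is None:
                log.info("%s finished in %.2f s", stage, time.perf_counter() - self.t0)

    return _Timer()


def make_dataset(config: RunConfig, seed: int | None = None) -> SyntheticDataset:
    """Build design + ground truth and realize one synthetic study."""
    seed = config.seed if seed is None else seed
    truth = default_ground_truth(
        config.design,
        n_compounds=config.n_compounds,
        n_latent=config.n_latent,
        noise_sd=config.noise_sd,
        latent_score_sd=config.latent_score_sd,
        n_positive_temperature=config.n_positive_temperature,
        seed=seed,
    )
    dataset = simulate_retention(config.design, truth, seed=seed + 1)
    if config.simulate_peaks:
        generate_peak_lists(dataset, seed=seed + 2)
    return dataset


def _write_meta(outdir: Path, config: RunConfig, seed: int, stage: str) -> None:
    meta = {"stage": stage, "seed": seed, "config_sha256": config.digest()}
    (outdir / f"{stage}_meta.json").write_text(json.dumps(meta, indent=1))


def simulate_to_dir(
    config: RunConfig, outdir: str | Path, seed: int | None = None
) -> SyntheticDataset:
    """Write design, retention matrix, peak lists and truth to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    with _timed("simulate"):
        dataset = make_dataset(config, seed=seed)
        dataset.design.to_csv(outdir / "design.csv")
        dataset.retention.to_csv(outdir / "retention.csv")
        pd.DataFrame(
            {
                "mz": dataset.truth.compound_mz,
                "charge": dataset.truth.compound_charge,
                "base_rt": dataset.truth.base_rts,
            }
        ).to_csv(outdir / "compounds.csv", index_label="compound")
        if dataset.peaks is not None:
            dataset.peaks.to_csv(outdir / "peaks.csv", index=False)
        dataset.truth.to_json(outdir / "truth.json")
        _write_meta(outdir, config, seed, "simulate")
    log.info("seed=%d  runs=%d  compounds=%d", seed, *dataset.retention.shape)
    return dataset


def load_dataset_dir(config: RunConfig, outdir: str | Path) -> tuple:
    """Load retention matrix, design and optional peaks written by simulate."""
    outdir = Path(outdir)
    design = build_design(config.design)
    retention = RetentionMatrix.from_csv(outdir / "retention.csv")
    if list(retention.values.index) != design.run_labels:
        raise ValueError("retention.csv run labels do not match the design")
    peaks = None
    peaks_path = outdir / "peaks.csv"
    if peaks_path.exists():
        peaks = pd.read_csv(peaks_path)
    return retention, design, peaks


def analyze(
    retention: RetentionMatrix | pd.DataFrame,
    design,
    config: RunConfig,
    peaks: pd.DataFrame | None = None,
) -> dict:
    """Run filtering -> MLR+CI -> PCA -> conversion -> ASCA -> PCR -> levels.

    Returns a dict of result tables (all DataFrames/Series) keyed by stage.
    """
    results: dict = {}

    if peaks is not None:
        with _timed("peak filtering"):
            classified = classify_runs(
                peaks,
                mz_tolerance=config.mz_tolerance,
                rt_tolerance=config.rt_tolerance,
            )
            mono = filter_monoisotopic(classified)
            results["peaks_classified"] = classified
            results["peaks_monoisotopic"] = mono
    else:
        log.info("no peak lists provided; filtering stage skipped")

    X = retention.values if isinstance(retention, RetentionMatrix) else retention

    with _timed("MLR"):
        mlr = fit_mlr(X, design)
        rep = X.loc[design.is_replicate]
        n_rep = int(design.is_replicate.sum())
        if n_rep >= 2:
            rt_ci = replicate_ci(rep, level=config.confidence_level)
            coef_ci = coefficient_ci(
                design, rep.std(axis=0, ddof=1), n_rep, level=config.confidence_level
            )
        else:
            rt_ci, coef_ci = None, None
            log.info("fewer than 2 replicates: confidence intervals skipped")
        results["coefficients_mlr"] = mlr.values
        results["rt_ci_halfwidth"] = rt_ci
        results["coefficient_ci_halfwidth"] = coef_ci

    with _timed("PCA + conversion"):
        full = fit_pca(X)
        sv = full.singular_values
        # effective rank: components carrying real variance, not SVD dust
        rank = int((sv > 1e-8 * sv[0]).sum())
        k = min(config.n_components, rank)
        if k < config.n_components:
            log.info(
                "effective rank %d < requested %d components; using %d",
                rank,
                config.n_components,
                k,
            )
        pca = fit_pca(X, n_components=k)
        conv = fit_conversion(pca.scores, design)
        b_pca = coefficients_from_loadings(conv, pca, design)
        results["pca_scores"] = pca.scores
        results["pca_loadings"] = pca.loadings
        results["explained_variance"] = pca.explained_variance
        results["conversion"] = conv.matrix
        results["conversion_r2"] = conv.fit_quality
        results["coefficients_pca"] = b_pca.values

    with _timed("ASCA"):
        asca = fit_asca(X, design)
        b_asca = asca_coefficients(asca, design)
        results["asca_effect_ss"] = asca.effect_ss
        results["coefficients_asca"] = b_asca.values
        scatter = pd.concat(
            {
                "mlr": mlr.values.stack(),
                "asca": b_asca.values.stack(),
            },
            axis=1,
        )
        scatter.index.names = ["term", "compound"]
        results["asca_vs_mlr"] = scatter.reset_index()

    with _timed("PCR residual comparison"):
        results["residual_variance"] = residual_variance_comparison(
            X,
            design,
            n_components=k,
            rt_window=config.overlap_window,
        )

    with _timed("design-level prediction"):
        levels = predict_design_levels(
            X, design, max_components=config.max_level_components
        )
        results["level_rmsec"] = levels.rmsec
        results["level_rmsecv"] = levels.rmsecv
        results["level_explained_variance"] = levels.explained_variance
        results["best_n_components"] = levels.best_n_components()

    return results


_TABLE_FILES = {
    "coefficients_mlr": "coefficients_mlr.csv",
    "rt_ci_halfwidth": "rt_ci_halfwidth.csv",
    "coefficient_ci_halfwidth": "coefficient_ci_halfwidth.csv",
    "pca_scores": "pca_scores.csv",
    "pca_loadings": "pca_loadings.csv",
    "explained_variance": "explained_variance.csv",
    "conversion": "conversion.csv",
    "conversion_r2": "conversion_r2.csv",
    "coefficients_pca": "coefficients_pca.csv",
    "coefficients_asca": "coefficients_asca.csv",
    "asca_effect_ss": "asca_effect_ss.csv",
    "asca_vs_mlr": "asca_vs_mlr.csv",
    "residual_variance": "residual_variance.csv",
    "level_rmsec": "level_rmsec.csv",
    "level_rmsecv": "level_rmsecv.csv",
    "level_explained_variance": "level_explained_variance.csv",
    "peaks_monoisotopic": "peaks_monoisotopic.csv",
}


def analyze_to_dir(config: RunConfig, datadir: str | Path, outdir: str | Path) -> dict:
    """Load a simulated dataset directory, analyze it, write report CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    retention, design, peaks = load_dataset_dir(config, datadir)
    results = analyze(retention, design, config, peaks=peaks)
    for key, fname in _TABLE_FILES.items():
        table = results.get(key)
        if table is None:
            continue
        if isinstance(table, pd.Series):
            table = table.to_frame(key)
        index = key not in ("asca_vs_mlr", "peaks_monoisotopic")
        table.to_csv(outdir / fname, index=index)
    _write_meta(outdir, config, config.seed, "analyze")
    (outdir / "summary.json").write_text(
        json.dumps(
            {
                "best_n_components": results["best_n_components"],
                "explained_variance_total": float(
                    results["explained_variance"].sum()
                ),
            },
            indent=1,
        )
    )
    return results


def recover(config: RunConfig, n_repeats: int, seed: int | None = None) -> dict:
    """Monte-Carlo simulate+fit loop: coefficient bias, RMSE and CI coverage.

    The ground truth is drawn once from the base seed; each repeat redraws
    latent scores and noise.  Coverage counts true coefficients inside the
    replicate-propagated confidence intervals.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    seed = config.seed if seed is None else seed
    truth = default_ground_truth(
        config.design,
        n_compounds=config.n_compounds,
        n_latent=config.n_latent,
        noise_sd=config.noise_sd,
        latent_score_sd=config.latent_score_sd,
        n_positive_temperature=config.n_positive_temperature,
        seed=seed,
    )
    design = build_design(config.design)
    B_true = truth.coefficients.to_numpy()
    n_rep = int(design.is_replicate.sum())

    errors = np.zeros((n_repeats,) + B_true.shape)
    covered = np.zeros(B_true.shape)
    cov_repeats = 0
    with _timed(f"recovery ({n_repeats} repeats)"):
        for r in range(n_repeats):
            ds = simulate_retention(design, truth, seed=seed + 1 + r)
            fit = fit_mlr(ds.retention.values, design)
            errors[r] = fit.values.to_numpy() - B_true
            if n_rep >= 2:
                rep = ds.retention.values.loc[design.is_replicate]
                hw = coefficient_ci(
                    design,
                    rep.std(axis=0, ddof=1),
                    n_rep,
                    level=config.confidence_level,
                ).to_numpy()
                covered += (np.abs(errors[r]) <= hw).astype(float)
                cov_repeats += 1

    terms = list(design.term_labels)
    compounds = truth.compounds
    bias = pd.DataFrame(errors.mean(axis=0), index=terms, columns=compounds)
    rmse = pd.DataFrame(
        np.sqrt((errors**2).mean(axis=0)), index=terms, columns=compounds
    )
    coverage = (
        pd.DataFrame(covered / cov_repeats, index=terms, columns=compounds)
        if cov_repeats
        else None
    )
    return {
        "bias": bias,
        "rmse": rmse,
        "coverage": coverage,
        "bias_per_term": bias.mean(axis=1),
        "coverage_overall": float(coverage.to_numpy().mean()) if cov_repeats else None,
        "n_repeats": n_repeats,
        "seed": seed,
    }
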