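"""Retention-time cross-prediction (PCR/PLS) and design-level prediction.

The diagnostic question: can one compound's retention time be predicted
from the retention times of the *other* compounds better than from the
experimental design itself?  If yes, the shifts carry shared structure —
including uncontrolled sources the design does not encode — which is the
premise of pattern-based peak alignment.

Per-compound calibration uses principal component regression: principal
components of the calibrant block (all other compounds, minus any compound
that ever co-elutes with the target within a retention-time window, so the
model cannot lean on trivially overlapping peaks) are regressed against
the target's retention-time vector.  A NIPALS PLS1 variant is provided for
parity checks.  Cross-validation is leave-one-run-out.

Design-level prediction reverses the direction: each design-term column is
regressed on the PCA scores of the retention matrix, with RMSEC / RMSECV
surfaces over component counts used to pick the model size.  Terms whose
true coefficients sit below the noise produce flat, sd-level RMSECV
curves — those effects simply are not encoded in the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .data import as_frame
from .design import DesignMatrix, INTERCEPT_LABEL
from .regression import fit_mlr, relative_residual_variance

__all__ = [
    "PcrModel",
    "LevelPredictionResult",
    "exclude_overlapping",
    "fit_pcr",
    "fit_pls",
    "predict_design_levels",
    "residual_variance_comparison",
]

#: default co-elution exclusion window, minutes
DEFAULT_RT_WINDOW = 0.2


@dataclass
class PcrModel:
    """Per-compound calibration model and its fit metrics."""

    target_compound: str
    calibrant_compounds: list[str]
    n_components: int
    method: str  # "pcr" | "pls"
    regression_vector: pd.Series  # per calibrant
    intercept: float
    fitted: pd.Series  # auto-prediction per run
    cv_predictions: pd.Series | None
    rrv_auto: float  # relative residual variance, auto-prediction
    rrv_cv: float | None  # same, leave-one-run-out


def exclude_overlapping(X, target: str, rt_window: float = DEFAULT_RT_WINDOW) -> list[str]:
    """Calibrants for ``target``: drop any compound that ever co-elutes.

    A compound is excluded iff ``|rt_compound - rt_target| < rt_window`` in
    at least one run; the target itself is always excluded.  The returned
    list preserves the matrix's column order, so it is deterministic.
    """
    Xf = as_frame(X)
    if target not in Xf.columns:
        raise ValueError(f"target compound {target!r} not in retention matrix")
    if rt_window < 0:
        raise ValueError("rt_window must be >= 0")
    diff = (Xf.sub(Xf[target], axis=0)).abs()
    overlaps = (diff < rt_window).any(axis=0)
    return [c for c in Xf.columns if c != target and not overlaps[c]]


def _svd_scores(block: np.ndarray):
    mx = block.mean(axis=0)
    u, s, vt = np.linalg.svd(block - mx, full_matrices=False)
    return mx, u, s, vt


def _check_components(k: int, n_runs: int, n_calibrants: int, s: np.ndarray) -> None:
    if k < 1:
        raise ValueError("n_components must be >= 1")
    if k > min(n_runs - 1, n_calibrants):
        raise ValueError(
            f"n_components={k} exceeds min(runs-1, calibrants)="
            f"{min(n_runs - 1, n_calibrants)}"
        )
    if s[k - 1] <= max(len(s), 1) * np.finfo(float).eps * s[0]:
        raise ValueError(f"n_components={k} exceeds the rank of the calibrant block")


def fit_pcr(
    X,
    target: str,
    calibrants: Sequence[str],
    n_components: int = 6,
    cv: bool = True,
) -> PcrModel:
    """Regress the target's retention times on calibrant-block PC scores.

    Both sides are mean-centered; the intercept is restored at prediction.
    When ``cv`` is set, leave-one-run-out predictions and their relative
    residual variance are attached.
    """
    Xf = as_frame(X)
    calibrants = list(calibrants)
    if not calibrants:
        raise ValueError("calibrant list is empty")
    if target in calibrants:
        raise ValueError("target must not be among the calibrants")
    y = Xf[target].to_numpy(dtype=float)
    block = Xf[calibrants].to_numpy(dtype=float)
    n = len(y)

    mx, u, s, vt = _svd_scores(block)
    _check_components(n_components, n, len(calibrants), s)
    T = u[:, :n_components] * s[:n_components]
    my = y.mean()
    q, *_ = np.linalg.lstsq(T, y - my, rcond=None)
    fitted = my + T @ q
    beta = vt[:n_components].T @ q
    intercept = my - mx @ beta

    cv_pred = None
    rrv_cv = None
    if cv:
        cv_pred = np.empty(n)
        for i in range(n):
            tr = np.ones(n, dtype=bool)
            tr[i] = False
            mx_t, u_t, s_t, vt_t = _svd_scores(block[tr])
            T_t = u_t[:, :n_components] * s_t[:n_components]
            q_t, *_ = np.linalg.lstsq(T_t, y[tr] - y[tr].mean(), rcond=None)
            t_new = (block[i] - mx_t) @ vt_t[:n_components].T
            cv_pred[i] = y[tr].mean() + t_new @ q_t
        rrv_cv = float(((y - cv_pred) ** 2).sum() / ((y - my) ** 2).sum())
        cv_pred = pd.Series(cv_pred, index=Xf.index)

    rrv_auto = float(((y - fitted) ** 2).sum() / ((y - my) ** 2).sum())
    return PcrModel(
        target_compound=target,
        calibrant_compounds=calibrants,
        n_components=n_components,
        method="pcr",
        regression_vector=pd.Series(beta, index=calibrants),
        intercept=float(intercept),
        fitted=pd.Series(fitted, index=Xf.index),
        cv_predictions=cv_pred,
        rrv_auto=rrv_auto,
        rrv_cv=rrv_cv,
    )


def fit_pls(
    X,
    target: str,
    calibrants: Sequence[str],
    n_components: int = 6,
    cv: bool = True,
) -> PcrModel:
    """PLS1 (NIPALS) analogue of :func:`fit_pcr`, same metric surface."""
    Xf = as_frame(X)
    calibrants = list(calibrants)
    if not calibrants:
        raise ValueError("calibrant list is empty")
    if target in calibrants:
        raise ValueError("target must not be among the calibrants")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    y = Xf[target].to_numpy(dtype=float)
    block = Xf[calibrants].to_numpy(dtype=float)
    n = len(y)
    if n_components > min(n - 1, len(calibrants)):
        raise ValueError("n_components exceeds min(runs-1, calibrants)")

    model = PLSRegression(n_components=n_components, scale=False)
    model.fit(block, y)
    fitted = model.predict(block).ravel()
    my = y.mean()

    cv_pred = None
    rrv_cv = None
    if cv:
        cv_pred = np.empty(n)
        for i in range(n):
            tr = np.ones(n, dtype=bool)
            tr[i] = False
            m = PLSRegression(n_components=n_components, scale=False)
            m.fit(block[tr], y[tr])
            cv_pred[i] = m.predict(block[i][None, :]).ravel()[0]
        rrv_cv = float(((y - cv_pred) ** 2).sum() / ((y - my) ** 2).sum())
        cv_pred = pd.Series(cv_pred, index=Xf.index)

    beta = np.asarray(model.coef_).reshape(-1)
    return PcrModel(
        target_compound=target,
        calibrant_compounds=calibrants,
        n_components=n_components,
        method="pls",
        regression_vector=pd.Series(beta, index=calibrants),
        intercept=float(my - block.mean(axis=0) @ beta),
        fitted=pd.Series(fitted, index=Xf.index),
        cv_predictions=cv_pred,
        rrv_auto=float(((y - fitted) ** 2).sum() / ((y - my) ** 2).sum()),
        rrv_cv=rrv_cv,
    )


@dataclass
class LevelPredictionResult:
    """RMSEC / RMSECV surfaces for predicting design terms from scores."""

    rmsec: pd.DataFrame  # terms x component counts
    rmsecv: pd.DataFrame | None
    explained_variance: pd.DataFrame  # auto-prediction R^2, terms x counts
    cv_predictions: dict[int, pd.DataFrame] | None  # per count: runs x terms

    @property
    def component_counts(self) -> list[int]:
        return list(self.rmsec.columns)

    def best_n_components(self) -> int:
        """Component count minimizing the mean RMSECV across terms."""
        if self.rmsecv is None:
            raise ValueError("cross-validation was not run")
        return int(self.rmsecv.mean(axis=0).idxmin())


def predict_design_levels(
    X,
    design: DesignMatrix,
    component_range: Sequence[int] | None = None,
    cv: bool = True,
    max_components: int = 10,
) -> LevelPredictionResult:
    """Regress each non-intercept design column on retention PCA scores.

    For every component count ``k`` in ``component_range`` the RMSEC (and,
    with ``cv``, leave-one-run-out RMSECV) of predicting each design term
    from the first ``k`` principal components of the centered retention
    matrix is reported, together with the auto-prediction explained
    variance.  RMSEC is non-increasing in ``k`` by construction.
    """
    Xf = as_frame(X)
    arr = Xf.to_numpy(dtype=float)
    n = arr.shape[0]
    if len(design.frame) != n:
        raise ValueError("X and design have different run counts")
    D_ni = design.frame[[c for c in design.term_labels if c != INTERCEPT_LABEL]]
    terms = list(D_ni.columns)
    Dv = D_ni.to_numpy(dtype=float)

    mx, u, s, vt = _svd_scores(arr)
    rank = int((s > max(arr.shape) * np.finfo(float).eps * s[0]).sum())
    if component_range is None:
        component_range = range(1, min(max_components, rank) + 1)
    ks = sorted(int(k) for k in component_range)
    if ks[0] < 1 or ks[-1] > rank:
        raise ValueError(f"component_range must lie within [1, rank={rank}]")
    kmax = ks[-1]

    # auto-prediction: scores are orthogonal, so residual SS is cumulative
    T = u[:, :kmax] * s[:kmax]
    dm = Dv.mean(axis=0)
    Dc = Dv - dm
    proj = T.T @ Dc  # kmax x terms
    contrib = proj**2 / (s[:kmax] ** 2)[:, None]
    ss0 = (Dc**2).sum(axis=0)
    ss_path = ss0[None, :] - np.cumsum(contrib, axis=0)  # kmax x terms
    ss_path = np.maximum(ss_path, 0.0)
    rmsec = pd.DataFrame(
        {k: np.sqrt(ss_path[k - 1] / n) for k in ks}, index=terms
    )
    expl = pd.DataFrame(
        {k: 1.0 - ss_path[k - 1] / ss0 for k in ks}, index=terms
    )

    rmsecv = None
    cv_predictions = None
    if cv:
        preds = {k: np.empty((n, len(terms))) for k in ks}
        for i in range(n):
            tr = np.ones(n, dtype=bool)
            tr[i] = False
            mx_t, u_t, s_t, vt_t = _svd_scores(arr[tr])
            T_t = u_t[:, :kmax] * s_t[:kmax]
            dm_t = Dv[tr].mean(axis=0)
            proj_t = T_t.T @ (Dv[tr] - dm_t)  # kmax x terms
            coef = proj_t / (s_t[:kmax] ** 2)[:, None]
            t_new = (arr[i] - mx_t) @ vt_t[:kmax].T  # kmax
            inc = t_new[:, None] * coef  # contribution of each component
            cum = dm_t[None, :] + np.cumsum(inc, axis=0)  # kmax x terms
            for k in ks:
                preds[k][i] = cum[k - 1]
        rmsecv = pd.DataFrame(
            {
                k: np.sqrt(((Dv - preds[k]) ** 2).mean(axis=0))
                for k in ks
            },
            index=terms,
        )
        cv_predictions = {
            k: pd.DataFrame(preds[k], index=Xf.index, columns=terms) for k in ks
        }
    return LevelPredictionResult(
        rmsec=rmsec,
        rmsecv=rmsecv,
        explained_variance=expl,
        cv_predictions=cv_predictions,
    )


def residual_variance_comparison(
    X,
    design: DesignMatrix,
    n_components: int = 6,
    rt_window: float = DEFAULT_RT_WINDOW,
    include_cv: bool = True,
) -> pd.DataFrame:
    """Per-compound table: MLR auto vs PCR auto (and PCR CV) residual variance.

    All three columns are relative residual variances (residual SS over
    centered total SS of the compound's retention vector); the MLR model is
    the factorial design fit, the PCR models use overlap-excluded
    calibrant blocks with ``n_components`` components.
    """
    Xf = as_frame(X)
    mlr = fit_mlr(Xf, design)
    rrv_mlr = relative_residual_variance(Xf, Xf - mlr.residuals)
    rows = {}
    for compound in Xf.columns:
        calibrants = exclude_overlapping(Xf, compound, rt_window=rt_window)
        model = fit_pcr(
            Xf, compound, calibrants, n_components=n_components, cv=include_cv
        )
        rows[compound] = {
            "mlr_auto": rrv_mlr[compound],
            "pcr_auto": model.rrv_auto,
            "pcr_cv": model.rrv_cv if include_cv else np.nan,
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[list(Xf.columns)]
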