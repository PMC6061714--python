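"""Design-of-experiments coefficients by multiple linear regression.

The response matrix ``X`` (runs x compounds, retention times in minutes)
is regressed on the expanded design matrix ``D``:

    X = D B,    B_hat = pinv(D) X = (D' D)^-1 D' X

computed through an SVD-based pseudo-inverse (singular values below
``max(dim) * eps * s_max`` are truncated), which stays stable when the raw
quadratic columns are nearly collinear with the intercept.

Uncertainty comes from the center-point replicates (pure experimental
error, independent of model adequacy): per compound, a t-interval on the
replicate retention times, and optionally the same pure-error sd
propagated to each coefficient through its design leverage
``sqrt([(D'D)^-1]_jj)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import as_frame
from .design import DesignMatrix

__all__ = [
    "CoefficientSet",
    "fit_mlr",
    "replicate_ci",
    "coefficient_ci",
    "relative_residual_variance",
]


@dataclass
class CoefficientSet:
    """Terms x compounds coefficient table with provenance and optional CIs.

    ``values`` holds minutes per coded unit (the intercept row is in
    minutes); ``method`` is one of ``"mlr"``, ``"pca"`` or ``"asca"``.
    """

    values: pd.DataFrame
    method: str
    residuals: pd.DataFrame | None = None
    ci_halfwidth: pd.DataFrame | None = None
    confidence_level: float | None = None

    def __post_init__(self) -> None:
        if self.ci_halfwidth is not None and (self.ci_halfwidth < 0).any().any():
            raise ValueError("CI halfwidths must be non-negative")

    @property
    def term_labels(self) -> list[str]:
        return list(self.values.index)

    @property
    def compounds(self) -> list[str]:
        return list(self.values.columns)


def _check_rank(D: np.ndarray, term_labels: list[str]) -> None:
    u, s, vt = np.linalg.svd(D, full_matrices=False)
    cutoff = max(D.shape) * np.finfo(float).eps * s[0]
    rank = int((s > cutoff).sum())
    if rank < D.shape[1]:
        null = vt[rank:]
        weight = np.abs(null).max(axis=0)
        involved = [
            t for t, w in zip(term_labels, weight) if w > 0.1 * weight.max()
        ]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {D.shape[1]}); "
            f"collinear term(s): {involved}"
        )


def fit_mlr(X, design: DesignMatrix) -> CoefficientSet:
    """Least-squares DoE coefficients, ``B_hat = pinv(D) X``.

    Raises on a rank-deficient design (naming the collinear columns) or on
    a run-count mismatch.  Residuals ``X - D B_hat`` are attached.
    """
    Xf = as_frame(X)
    D = design.values
    if Xf.shape[0] != D.shape[0]:
        raise ValueError(
            f"run count mismatch: X has {Xf.shape[0]} rows, design has {D.shape[0]}"
        )
    _check_rank(D, design.term_labels)
    B = np.linalg.pinv(D) @ Xf.to_numpy(dtype=float)
    values = pd.DataFrame(B, index=design.term_labels, columns=Xf.columns)
    residuals = Xf - pd.DataFrame(
        D @ B, index=Xf.index, columns=Xf.columns
    )
    return CoefficientSet(values=values, method="mlr", residuals=residuals)


def replicate_ci(replicate_rts, level: float = 0.95) -> pd.Series:
    """Pure-error t-interval halfwidth per compound from replicate runs.

    ``halfwidth = t(1 - (1-level)/2, n-1) * sd / sqrt(n)`` with ``n``
    replicate rows (``n >= 2``); the sample sd uses ``n - 1`` degrees of
    freedom.
    """
    rep = as_frame(replicate_rts)
    n = rep.shape[0]
    if n < 2:
        raise ValueError("at least 2 replicate runs are required")
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    t = stats.t.ppf(1 - (1 - level) / 2, df=n - 1)
    sd = rep.std(axis=0, ddof=1)
    return t * sd / np.sqrt(n)


def coefficient_ci(
    design: DesignMatrix, pure_sd: pd.Series, n_replicates: int, level: float = 0.95
) -> pd.DataFrame:
    """Propagate the replicate pure-error sd to each coefficient.

    ``halfwidth[j, c] = t(level, n-1) * sd_c * sqrt([(D'D)^-1]_jj)``.
    Because replicate rows share one design row, the pure-error sd is
    independent of the coefficient estimates and the interval is exact
    under i.i.d. run-to-run noise.
    """
    if n_replicates < 2:
        raise ValueError("at least 2 replicates are required")
    D = design.values
    g = np.diag(np.linalg.pinv(D.T @ D))
    t = stats.t.ppf(1 - (1 - level) / 2, df=n_replicates - 1)
    hw = t * np.sqrt(g)[:, None] * pure_sd.to_numpy()[None, :]
    return pd.DataFrame(hw, index=design.term_labels, columns=pure_sd.index)


def relative_residual_variance(X, X_hat, centered: bool = True) -> pd.Series:
    """Per-compound residual sum of squares over the (centered) total SS.

    0 for a perfect prediction; 1 when the prediction is no better than the
    compound's mean retention time.  Raises on a zero-variance compound.
    """
    Xf, Hf = as_frame(X), as_frame(X_hat)
    if Xf.shape != Hf.shape:
        raise ValueError(f"shape mismatch: {Xf.shape} vs {Hf.shape}")
    resid = Xf.to_numpy(dtype=float) - Hf.to_numpy(dtype=float)
    obs = Xf.to_numpy(dtype=float)
    denom = obs - obs.mean(axis=0) if centered else obs
    ss_tot = (denom**2).sum(axis=0)
    if np.any(ss_tot == 0):
        bad = [c for c, s in zip(Xf.columns, ss_tot) if s == 0]
        raise ValueError(f"zero-variance compound column(s): {bad}")
    return pd.Series((resid**2).sum(axis=0) / ss_tot, index=Xf.columns)
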