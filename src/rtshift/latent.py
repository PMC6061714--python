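"""PCA of retention data, the scores <-> design bridge, and ASCA.

The central algebraic idea: a retention matrix generated by a factorial
design has low-rank structure, so its PCA scores ``T`` play the role of
the design matrix ``D`` and its loadings ``P`` the role of the DoE
coefficients ``B``.  A least-squares *conversion factor* links the two
bases:

    D = T C + E_C,        C_hat = (T'T)^-1 T' D

and substituting ``D = T C_hat`` into ``X = D B`` gives ``P' ~ C_hat B``,
so the design coefficients can be recovered from the loadings alone:

    B_pca = (C_hat' C_hat)^-1 C_hat' P'

With at least as many components as the design rank and no uncontrolled
structure, this reproduces MLR exactly; when latent (uncontrolled) factors
contaminate the data, the PCA route and MLR diverge for the small terms —
which is precisely what makes the comparison diagnostic.

``X`` is column-mean-centered before PCA (otherwise PC1 would only encode
mean elution times); consequently the intercept column of ``D`` is dropped
from the conversion regression and the intercept is reconstructed from the
centering offsets.

ASCA (ANOVA-simultaneous component analysis) partitions the grand-centered
matrix into per-factor effect matrices (level means broadcast to member
runs) plus a residual, then decomposes each part by PCA.  Level and grand
means are computed on the balanced factorial core; center-point replicate
rows receive the level-0 effect, and the residual is defined as the exact
remainder, so the partition always reconstructs the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import as_frame
from .design import DesignMatrix, INTERCEPT_LABEL
from .regression import CoefficientSet

__all__ = [
    "LatentDecomposition",
    "ConversionFit",
    "AscaResult",
    "fit_pca",
    "fit_conversion",
    "coefficients_from_loadings",
    "fit_asca",
    "asca_coefficients",
]


@dataclass
class LatentDecomposition:
    """Scores/loadings decomposition ``X = centering + T P' + E``."""

    scores: pd.DataFrame  # runs x components
    loadings: pd.DataFrame  # compounds x components
    residual: pd.DataFrame  # runs x compounds
    explained_variance: pd.Series  # fraction of total (centered) variance
    centering: pd.Series  # per-compound offsets (zeros when uncentered)
    singular_values: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def reconstruct(self) -> pd.DataFrame:
        rec = self.scores.to_numpy() @ self.loadings.to_numpy().T
        rec = rec + self.residual.to_numpy() + self.centering.to_numpy()[None, :]
        return pd.DataFrame(
            rec, index=self.scores.index, columns=self.loadings.index
        )


def fit_pca(X, n_components: int | None = None, center: bool = True) -> LatentDecomposition:
    """SVD-based PCA with a reproducible sign convention.

    Components are ordered by decreasing variance; each component's sign is
    fixed so that its largest-magnitude loading entry is positive.
    ``explained_variance`` is the fraction of the total (centered) sum of
    squares carried by each retained component.
    """
    Xf = as_frame(X)
    arr = Xf.to_numpy(dtype=float)
    n_runs, n_comp_max = arr.shape[0], min(arr.shape)
    if n_components is None:
        n_components = n_comp_max
    if not 1 <= n_components <= n_comp_max:
        raise ValueError(
            f"n_components must be in [1, {n_comp_max}], got {n_components}"
        )
    mu = arr.mean(axis=0) if center else np.zeros(arr.shape[1])
    Xc = arr - mu
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|loading| entry positive per component
    for k in range(len(s)):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    total = float((s**2).sum())
    k = n_components
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T
    resid = Xc - scores @ loadings.T
    comp_labels = [f"PC{i + 1}" for i in range(k)]
    frac = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return LatentDecomposition(
        scores=pd.DataFrame(scores, index=Xf.index, columns=comp_labels),
        loadings=pd.DataFrame(loadings, index=Xf.columns, columns=comp_labels),
        residual=pd.DataFrame(resid, index=Xf.index, columns=Xf.columns),
        explained_variance=pd.Series(frac, index=comp_labels),
        centering=pd.Series(mu, index=Xf.columns),
        singular_values=s[:k].copy(),
    )


@dataclass
class ConversionFit:
    """Least-squares map from PCA scores to the (centered) design columns."""

    matrix: pd.DataFrame  # components x terms (C_hat)
    residual: pd.DataFrame  # runs x terms
    fit_quality: pd.Series  # per-term R^2
    design_means: pd.Series  # non-intercept column means used for centering

    @property
    def term_labels(self) -> list[str]:
        return list(self.matrix.columns)


def _nonintercept(design: DesignMatrix) -> pd.DataFrame:
    cols = [c for c in design.term_labels if c != INTERCEPT_LABEL]
    return design.frame[cols]


def fit_conversion(
    T, design: DesignMatrix, center_mask: np.ndarray | None = None
) -> ConversionFit:
    """Fit ``C_hat = pinv(T) D`` on the centered non-intercept design columns.

    ``center_mask`` selects the rows whose means center the design columns
    (default: all rows, matching whole-matrix PCA centering; ASCA passes
    the factorial core).  Raises if any score column has zero variance.
    """
    Tf = T if isinstance(T, pd.DataFrame) else pd.DataFrame(np.asarray(T, float))
    D_ni = _nonintercept(design)
    if Tf.shape[0] != D_ni.shape[0]:
        raise ValueError(
            f"row mismatch: scores {Tf.shape[0]} vs design {D_ni.shape[0]}"
        )
    Tarr = Tf.to_numpy(dtype=float)
    if np.any(Tarr.std(axis=0) == 0):
        bad = [c for c, s in zip(Tf.columns, Tarr.std(axis=0)) if s == 0]
        raise ValueError(f"degenerate (zero-variance) score component(s): {bad}")
    mask = np.ones(len(D_ni), dtype=bool) if center_mask is None else center_mask
    means = D_ni.iloc[mask].mean(axis=0)
    Dc = D_ni.to_numpy(dtype=float) - means.to_numpy()[None, :]
    C, *_ = np.linalg.lstsq(Tarr, Dc, rcond=None)
    resid = Dc - Tarr @ C
    ss_tot = (Dc**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - (resid**2).sum(axis=0) / ss_tot
    return ConversionFit(
        matrix=pd.DataFrame(C, index=Tf.columns, columns=D_ni.columns),
        residual=pd.DataFrame(resid, index=Tf.index, columns=D_ni.columns),
        fit_quality=pd.Series(r2, index=D_ni.columns),
        design_means=means,
    )


def coefficients_from_loadings(
    conv: ConversionFit,
    decomposition: LatentDecomposition,
    design: DesignMatrix,
) -> CoefficientSet:
    """Recover DoE coefficients from loadings: ``B = pinv(C_hat) P'``.

    The intercept row is reconstructed from the PCA centering offsets so
    the result is term-for-term comparable with MLR.  Raises when
    ``C_hat' C_hat`` is singular (fewer effective components than terms).
    """
    C = conv.matrix.to_numpy(dtype=float)
    P = decomposition.loadings
    if C.shape[0] != P.shape[1]:
        raise ValueError(
            f"component mismatch: conversion has {C.shape[0]}, loadings {P.shape[1]}"
        )
    s = np.linalg.svd(C, compute_uv=False)
    if C.shape[0] < C.shape[1] or s[-1] <= max(C.shape) * np.finfo(float).eps * s[0]:
        raise ValueError(
            "C_hat'C_hat is singular: more design terms than effective "
            "components; increase n_components"
        )
    B_ni, *_ = np.linalg.lstsq(C, P.to_numpy(dtype=float).T, rcond=None)
    B_ni = pd.DataFrame(B_ni, index=conv.term_labels, columns=P.index)
    intercept = decomposition.centering - conv.design_means @ B_ni
    values = pd.concat([intercept.to_frame(INTERCEPT_LABEL).T, B_ni])
    values = values.reindex([t for t in design.term_labels])
    return CoefficientSet(values=values, method="pca")


@dataclass
class AscaResult:
    """Exact additive partition of the grand-centered retention matrix."""

    effects: dict[str, pd.DataFrame]  # per-factor runs x compounds
    residual: pd.DataFrame
    grand_mean: pd.Series
    decompositions: dict[str, LatentDecomposition]  # per effect + "residual"
    effect_ss: pd.Series  # sum of squares per effect, residual and total
    factorial_mask: np.ndarray

    def reconstruct(self) -> pd.DataFrame:
        total = self.residual.copy()
        for eff in self.effects.values():
            total = total + eff
        return total


def fit_asca(
    X,
    design: DesignMatrix,
    factors: list[str] | None = None,
    n_components: int | None = None,
    n_residual_components: int | None = None,
    force: bool = False,
) -> AscaResult:
    """Partition ``X`` into per-factor level-mean effect matrices + residual.

    Grand and level means are computed over the balanced factorial core
    (non-replicate rows); replicate rows are centered with the same grand
    mean and receive their level's effect, and the residual is the exact
    remainder.  With center replicates present the overall design is
    unbalanced; this type-I-style treatment keeps the partition exact and a
    truly null factor's effect matrix exactly zero.  Each effect matrix and
    the residual are decomposed by (uncentered) PCA.

    Raises when the factorial core itself is unbalanced, unless ``force``.
    """
    Xf = as_frame(X)
    if len(Xf) != len(design.frame):
        raise ValueError("X and design have different run counts")
    factors = list(factors or design.spec.factor_names)
    core = ~design.is_replicate
    coded = design.coded

    for f in factors:
        counts = coded.loc[core, f].value_counts()
        if counts.nunique() > 1 and not force:
            raise ValueError(
                f"unbalanced level counts for factor {f!r}: "
                f"{counts.to_dict()}; pass force=True for type-I style means"
            )

    arr = Xf.to_numpy(dtype=float)
    grand = arr[core].mean(axis=0)
    Xg = arr - grand

    effects: dict[str, pd.DataFrame] = {}
    for f in factors:
        levels = coded[f].to_numpy()
        eff = np.zeros_like(arr)
        for lev in np.unique(levels[core]):
            sel_core = core & (levels == lev)
            mean_rows = Xg[sel_core].mean(axis=0)
            eff[levels == lev] = mean_rows
        effects[f] = pd.DataFrame(eff, index=Xf.index, columns=Xf.columns)

    resid = Xg - sum(e.to_numpy() for e in effects.values())
    residual = pd.DataFrame(resid, index=Xf.index, columns=Xf.columns)

    decompositions: dict[str, LatentDecomposition] = {}
    ss = {}
    for f in factors:
        k = n_components
        if k is None:
            n_levels = coded.loc[core, f].nunique()
            k = min(n_levels - 1, arr.shape[0], arr.shape[1])
        decompositions[f] = fit_pca(effects[f], n_components=k, center=False)
        ss[f] = float((effects[f].to_numpy() ** 2).sum())
    kr = n_residual_components
    if kr is None:
        kr = min(4, arr.shape[0], arr.shape[1])
    decompositions["residual"] = fit_pca(residual, n_components=kr, center=False)
    ss["residual"] = float((resid**2).sum())
    ss["total"] = float((Xg**2).sum())

    return AscaResult(
        effects=effects,
        residual=residual,
        grand_mean=pd.Series(grand, index=Xf.columns),
        decompositions=decompositions,
        effect_ss=pd.Series(ss),
        factorial_mask=core.copy(),
    )


def _trimmed(decomp: LatentDecomposition, sv_floor: float):
    keep = decomp.singular_values > sv_floor
    return (
        decomp.scores.to_numpy()[:, keep],
        decomp.loadings.to_numpy()[:, keep],
    )


def asca_coefficients(
    asca: AscaResult,
    design: DesignMatrix,
    include_residual: bool = True,
) -> CoefficientSet:
    """DoE coefficients from ASCA loadings via the conversion-factor bridge.

    Per-effect scores and loadings (and, by default, the residual's, which
    carry the interaction structure a main-effects partition leaves out)
    are concatenated and passed through the same ``C_hat`` machinery as the
    plain PCA route; the output is aligned term-for-term with MLR.
    """
    keys = [k for k in asca.decompositions if k != "residual"]
    if include_residual:
        keys.append("residual")
    sv_max = max(
        (d.singular_values.max(initial=0.0) for d in asca.decompositions.values()),
    )
    floor = 1e-9 * sv_max
    score_blocks, loading_blocks, labels = [], [], []
    for key in keys:
        t, p = _trimmed(asca.decompositions[key], floor)
        score_blocks.append(t)
        loading_blocks.append(p)
        labels += [f"{key}:PC{i + 1}" for i in range(t.shape[1])]
    T = pd.DataFrame(
        np.hstack(score_blocks), index=asca.residual.index, columns=labels
    )
    P = np.hstack(loading_blocks)

    conv = fit_conversion(T, design, center_mask=asca.factorial_mask)
    decomp = LatentDecomposition(
        scores=T,
        loadings=pd.DataFrame(P, index=asca.residual.columns, columns=labels),
        residual=asca.residual * 0.0,
        explained_variance=pd.Series(np.nan, index=labels),
        centering=asca.grand_mean,
        singular_values=np.full(len(labels), np.nan),
    )
    out = coefficients_from_loadings(conv, decomp, design)
    out.method = "asca"
    return out
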