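"""Synthetic retention data with known ground truth.

The generator emulates an LC-MS study of a tryptic peptide digest run under
a two-factor five-level factorial design (mobile-phase pH and column
temperature): each of ~98 monoisotopic species gets compound-specific
polynomial shift coefficients, one or more latent *uncontrolled* factors
add low-rank run-to-run structure that the design does not explain, and
i.i.d. Gaussian measurement noise is added on top:

    X = D @ B_true + S_latent @ L_latent + noise

Default effect structure (per coded unit, minutes):

* linear temperature coefficients are negative for all but 10 of the 98
  compounds (higher temperature elutes peptides earlier, with a small
  minority behaving oppositely);
* linear and quadratic pH coefficients take either sign;
* quadratic temperature and pH x temperature interaction coefficients are
  drawn well below the measurement noise, i.e. practically insignificant.

Ground truth (coefficients, latent loadings, peak species flags) is
recorded so recovery can be tested exactly.  A companion generator turns
the retention matrix into per-run peak lists, optionally decorating each
monoisotopic peak with isotopologue peaks at 1.00335/z Th spacing and
cation-adduct peaks, co-eluting at the same retention time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import RetentionMatrix
from .design import DesignMatrix, DesignSpec, build_design

__all__ = [
    "GroundTruth",
    "SyntheticDataset",
    "PeakSimConfig",
    "default_ground_truth",
    "simulate_retention",
    "generate_peak_lists",
    "ISOTOPE_SPACING",
    "ADDUCT_DELTAS",
]

#: m/z spacing between consecutive isotopologues of a singly charged ion (Th).
ISOTOPE_SPACING = 1.00335

#: m/z shift of common cation adducts relative to [M+H]+, singly charged (Th).
ADDUCT_DELTAS: dict[str, float] = {
    "[M+Na]+": 21.98194,
    "[M+NH4]+": 17.02655,
    "[M+K]+": 37.95588,
}


@dataclass
class GroundTruth:
    """True generative parameters behind a synthetic retention matrix."""

    coefficients: pd.DataFrame  # terms x compounds, minutes per coded unit
    latent_loadings: pd.DataFrame  # latent factors x compounds
    latent_score_sd: np.ndarray  # per latent factor, minutes
    noise_sd: float
    base_rts: pd.Series  # per-compound mean RT, minutes
    compound_mz: pd.Series
    compound_charge: pd.Series
    seed: int

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if (self.base_rts <= 0).any():
            raise ValueError("base retention times must be strictly positive")
        if not self.base_rts.is_monotonic_increasing:
            raise ValueError("compounds must be sorted by base retention time")
        self.latent_score_sd = np.atleast_1d(
            np.asarray(self.latent_score_sd, dtype=float)
        )
        if len(self.latent_score_sd) != len(self.latent_loadings):
            raise ValueError("one score sd per latent factor required")

    @property
    def compounds(self) -> list[str]:
        return list(self.coefficients.columns)

    @property
    def n_latent(self) -> int:
        return len(self.latent_loadings)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "noise_sd": self.noise_sd,
            "latent_score_sd": self.latent_score_sd.tolist(),
            "coefficients": self.coefficients.to_dict(orient="split"),
            "latent_loadings": self.latent_loadings.to_dict(orient="split"),
            "base_rts": self.base_rts.to_dict(),
            "compound_mz": self.compound_mz.to_dict(),
            "compound_charge": {k: int(v) for k, v in self.compound_charge.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class SyntheticDataset:
    """Design, retention matrix, generating truth and optional peak lists."""

    design: DesignMatrix
    retention: RetentionMatrix
    truth: GroundTruth
    peaks: pd.DataFrame | None = None
    latent_scores: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        n_runs, n_compounds = self.retention.shape
        if n_runs != len(self.design.frame):
            raise ValueError("retention rows do not match design runs")
        if n_compounds != len(self.truth.compounds):
            raise ValueError("retention columns do not match truth compounds")


def _temperature_like(rng, n, sd, n_positive):
    """Mostly negative linear coefficients with a fixed positive minority."""
    mag = np.abs(rng.normal(0.18, sd, size=n)) + 0.02
    sign = -np.ones(n)
    pos = rng.choice(n, size=min(n_positive, n), replace=False)
    sign[pos] = 1.0
    return mag * sign


def _assign_mz(
    rng: np.random.Generator,
    n: int,
    charges: np.ndarray,
    mz_range: tuple[float, float],
    adduct_deltas: Sequence[float],
    min_separation: float = 0.012,
    max_iter: int = 200,
) -> np.ndarray:
    """Draw compound m/z values whose isotope/adduct ladders do not collide.

    Any two peaks from *different* compounds are kept at least
    ``min_separation`` Th apart once isotope (+1, +2) and adduct shifts are
    applied, so that classification on the synthetic lists is exact rather
    than tolerance-lucky.
    """
    mz = rng.uniform(*mz_range, size=n)
    offsets = [
        np.array(
            [0.0, ISOTOPE_SPACING / z, 2 * ISOTOPE_SPACING / z]
            + [d / z for d in adduct_deltas]
        )
        for z in charges
    ]
    for _ in range(max_iter):
        ladders = [mz[i] + offsets[i] for i in range(n)]
        all_mz = np.concatenate(ladders)
        owner = np.concatenate([np.full(len(ladders[i]), i) for i in range(n)])
        order = np.argsort(all_mz)
        bad: set[int] = set()
        sorted_mz, sorted_owner = all_mz[order], owner[order]
        close = np.flatnonzero(np.diff(sorted_mz) < min_separation)
        for i in close:
            if sorted_owner[i] != sorted_owner[i + 1]:
                bad.add(int(max(sorted_owner[i], sorted_owner[i + 1])))
        if not bad:
            return mz
        idx = np.array(sorted(bad))
        mz[idx] = rng.uniform(*mz_range, size=len(idx))
    raise RuntimeError("could not place compound m/z values without collisions")


def default_ground_truth(
    spec: DesignSpec,
    n_compounds: int = 98,
    n_latent: int = 1,
    noise_sd: float = 0.03,
    latent_score_sd: float | Sequence[float] = 0.03,
    n_positive_temperature: int = 10,
    rt_range: tuple[float, float] = (2.0, 38.0),
    mz_range: tuple[float, float] = (400.0, 1400.0),
    seed: int = 0,
    coefficient_sd: Mapping[str, float] | None = None,
) -> GroundTruth:
    """Draw a ground truth emulating the peptide retention-shift study.

    The first factor is treated as pH-like (mixed-sign linear and quadratic
    effects), the second as temperature-like (mostly negative linear,
    negligible quadratic); interactions are small and positive.  Override
    any per-term scale through ``coefficient_sd`` (keyed by term label).
    """
    rng = np.random.default_rng(seed)
    compounds = [f"C{i + 1:03d}" for i in range(n_compounds)]
    base = np.sort(rng.uniform(*rt_range, size=n_compounds))
    base_rts = pd.Series(base, index=compounds, name="base_rt")

    names = spec.factor_names
    overrides = dict(coefficient_sd or {})
    coef = {}
    for term in spec.model_terms:
        label = term.label
        if term.kind == "intercept":
            coef[label] = base.copy()
            continue
        if label in overrides:
            coef[label] = rng.normal(0.0, overrides[label], size=n_compounds)
            continue
        role = "pH" if not term.factors or names.index(term.factors[0]) == 0 else "T"
        if term.kind == "linear":
            if role == "T":
                coef[label] = _temperature_like(
                    rng, n_compounds, 0.06, n_positive_temperature
                )
            else:
                coef[label] = rng.normal(0.0, 0.15, size=n_compounds)
        elif term.kind == "quadratic":
            sd = 0.05 if role == "pH" else 0.005
            coef[label] = rng.normal(0.0, sd, size=n_compounds)
        else:  # interaction: small, positive on average
            coef[label] = np.abs(rng.normal(0.0, 0.004, size=n_compounds))
    coefficients = pd.DataFrame(coef, index=compounds).T
    coefficients = coefficients.loc[list(spec.term_labels)]

    loadings = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(n_latent, n_compounds)),
        index=[f"L{i + 1}" for i in range(n_latent)],
        columns=compounds,
    )
    score_sd = np.full(n_latent, latent_score_sd, dtype=float) if np.isscalar(
        latent_score_sd
    ) else np.asarray(latent_score_sd, dtype=float)

    charge = rng.choice([1, 2], size=n_compounds, p=[0.35, 0.65])
    mz = _assign_mz(rng, n_compounds, charge, mz_range, list(ADDUCT_DELTAS.values()))

    return GroundTruth(
        coefficients=coefficients,
        latent_loadings=loadings,
        latent_score_sd=score_sd,
        noise_sd=noise_sd,
        base_rts=base_rts,
        compound_mz=pd.Series(mz, index=compounds, name="mz"),
        compound_charge=pd.Series(charge, index=compounds, name="charge"),
        seed=seed,
    )


def simulate_retention(
    spec: DesignSpec | DesignMatrix,
    truth: GroundTruth,
    seed: int | None = None,
) -> SyntheticDataset:
    """Realize ``X = D B_true + S L + noise`` for one seeded experiment.

    ``seed`` defaults to ``truth.seed``; the same seed reproduces the
    dataset exactly.
    """
    design = spec if isinstance(spec, DesignMatrix) else build_design(spec)
    if list(design.term_labels) != list(truth.coefficients.index):
        raise ValueError(
            "design terms and ground-truth coefficient terms differ: "
            f"{list(design.term_labels)} vs {list(truth.coefficients.index)}"
        )
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    D = design.values
    B = truth.coefficients.to_numpy()
    X = D @ B

    n_runs = D.shape[0]
    scores = None
    if truth.n_latent:
        S = rng.normal(0.0, 1.0, size=(n_runs, truth.n_latent)) * truth.latent_score_sd
        X = X + S @ truth.latent_loadings.to_numpy()
        scores = pd.DataFrame(
            S, index=design.run_labels, columns=list(truth.latent_loadings.index)
        )
    if truth.noise_sd > 0:
        X = X + rng.normal(0.0, truth.noise_sd, size=X.shape)

    retention = RetentionMatrix(
        values=pd.DataFrame(
            X, index=design.run_labels, columns=truth.compounds
        ),
        compound_mz=truth.compound_mz,
    )
    return SyntheticDataset(
        design=design, retention=retention, truth=truth, latent_scores=scores
    )


@dataclass(frozen=True)
class PeakSimConfig:
    """Controls decoration of monoisotopic peaks with isotopes and adducts."""

    n_isotopes: int = 2
    isotope_fractions: tuple[float, ...] = (0.55, 0.22)
    adducts: tuple[str, ...] = ("[M+Na]+", "[M+NH4]+")
    adduct_fraction: float = 0.30  # intensity relative to the base peak
    adduct_prob: float = 0.5  # probability a compound shows each adduct
    mz_jitter_sd: float = 0.0005  # Th
    rt_jitter_sd: float = 0.005  # minutes
    log10_intensity_mean: float = 6.0
    log10_intensity_sd: float = 0.4

    def __post_init__(self) -> None:
        if self.n_isotopes > len(self.isotope_fractions):
            raise ValueError("need one intensity fraction per isotope peak")
        for name in self.adducts:
            if name not in ADDUCT_DELTAS:
                raise ValueError(f"unknown adduct {name!r}")


def generate_peak_lists(
    dataset: SyntheticDataset,
    config: PeakSimConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Emit per-run peak lists (long table with a ``run`` column).

    Each compound contributes its monoisotopic peak at the simulated
    retention time, optionally followed by isotopologues at
    ``k * 1.00335 / z`` and adduct peaks at ``delta / z``, co-eluting with
    small m/z and RT jitter.  Ground-truth ``species`` and ``compound``
    columns are recorded for recovery tests.  The result is also stored on
    ``dataset.peaks``.
    """
    if dataset.retention.compound_mz is None:
        raise ValueError("dataset has no compound m/z values")
    config = config or PeakSimConfig()
    rng = np.random.default_rng(dataset.truth.seed + 1 if seed is None else seed)

    compounds = dataset.retention.compound_labels
    mz = dataset.retention.compound_mz.to_numpy()
    charge = dataset.truth.compound_charge.to_numpy()
    n = len(compounds)

    base_intensity = 10 ** rng.normal(
        config.log10_intensity_mean, config.log10_intensity_sd, size=n
    )
    has_adduct = {
        name: rng.random(n) < config.adduct_prob for name in config.adducts
    }

    records = []
    rt = dataset.retention.values.to_numpy()
    for r, run in enumerate(dataset.retention.run_labels):
        for c in range(n):
            z = int(charge[c])
            entries = [(mz[c], base_intensity[c], "monoisotopic")]
            for k in range(1, config.n_isotopes + 1):
                entries.append(
                    (
                        mz[c] + k * ISOTOPE_SPACING / z,
                        base_intensity[c] * config.isotope_fractions[k - 1],
                        "isotope",
                    )
                )
            for name in config.adducts:
                if has_adduct[name][c]:
                    entries.append(
                        (
                            mz[c] + ADDUCT_DELTAS[name] / z,
                            base_intensity[c] * config.adduct_fraction,
                            "adduct",
                        )
                    )
            for peak_mz, inten, species in entries:
                records.append(
                    (
                        run,
                        compounds[c],
                        peak_mz + rng.normal(0.0, config.mz_jitter_sd),
                        rt[r, c] + rng.normal(0.0, config.rt_jitter_sd),
                        inten * np.exp(rng.normal(0.0, 0.05)),
                        z,
                        species,
                    )
                )
    peaks = pd.DataFrame(
        records,
        columns=["run", "compound", "mz", "rt", "intensity", "charge", "species"],
    )
    dataset.peaks = peaks
    return peaks
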