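"""Isotope/adduct detection: reduce peak lists to monoisotopic species.

Before any shift modelling, LC-MS peak lists are collapsed so that each
analyte is represented once: isotopologue peaks (spaced ``1.00335 / z`` Th
above a more intense co-eluting peak) and cation adducts (e.g. [M+Na]+ at
+21.98194 Th relative to [M+H]+ for ``z = 1``) are flagged and removed,
keeping only monoisotopic species.

Classification is a deterministic greedy pass in decreasing intensity
order: the most intense unflagged peak claims its co-eluting isotope and
adduct partners, which settles ambiguous chains (A isotope-of B isotope-of
C) in favour of the most intense parent.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .simulate import ADDUCT_DELTAS, ISOTOPE_SPACING

__all__ = ["classify_peaks", "filter_monoisotopic", "classify_runs"]

MONOISOTOPIC = "monoisotopic"
ISOTOPE = "isotope"
ADDUCT = "adduct"

#: default m/z tolerance, Th (matches typical orbitrap tracking tolerance)
DEFAULT_MZ_TOLERANCE = 0.005
#: default co-elution tolerance, minutes
DEFAULT_RT_TOLERANCE = 0.1


def _require_columns(peaks: pd.DataFrame, cols: Iterable[str]) -> None:
    missing = [c for c in cols if c not in peaks.columns]
    if missing:
        raise ValueError(f"peak list missing column(s) {missing}")


def classify_peaks(
    peaks: pd.DataFrame,
    mz_tolerance: float = DEFAULT_MZ_TOLERANCE,
    rt_tolerance: float = DEFAULT_RT_TOLERANCE,
    adduct_deltas: Mapping[str, float] | None = None,
    max_isotopes: int = 2,
    charge_candidates: tuple[int, ...] = (1, 2, 3),
) -> pd.DataFrame:
    """Flag each peak of one run as monoisotopic, isotope or adduct.

    A peak is an *isotope* if a more intense unflagged peak sits at
    ``mz - k * 1.00335 / z`` (``k = 1 .. max_isotopes``) within both
    tolerances; an *adduct* if an unflagged peak sits at
    ``mz - delta / z`` for any adduct table entry.  ``z`` is taken from the
    ``charge`` column when present, otherwise every candidate charge is
    tried.  Flags are mutually exclusive; everything unclaimed is
    monoisotopic.

    Returns a copy with a ``flag`` column; input order is preserved.
    """
    if mz_tolerance <= 0 or rt_tolerance <= 0:
        raise ValueError("tolerances must be positive")
    if peaks.empty:
        out = peaks.copy()
        out["flag"] = pd.Series(dtype=object)
        return out
    _require_columns(peaks, ["mz", "rt", "intensity"])
    if (peaks["mz"] <= 0).any():
        raise ValueError("m/z values must be positive")
    if (peaks["intensity"] < 0).any():
        raise ValueError("intensities must be non-negative")
    adducts = dict(ADDUCT_DELTAS if adduct_deltas is None else adduct_deltas)

    mz = peaks["mz"].to_numpy(dtype=float)
    rt = peaks["rt"].to_numpy(dtype=float)
    intensity = peaks["intensity"].to_numpy(dtype=float)
    if "charge" in peaks.columns:
        charge = pd.to_numeric(peaks["charge"], errors="coerce").to_numpy()
    else:
        charge = np.full(len(peaks), np.nan)

    n = len(peaks)
    flags = np.array([MONOISOTOPIC] * n, dtype=object)
    claimed = np.zeros(n, dtype=bool)
    # stable ordering: intensity desc, then m/z asc for ties
    order = np.lexsort((mz, -intensity))

    def candidates(i: int) -> tuple[int, ...]:
        z = charge[i]
        if np.isfinite(z) and z > 0:
            return (int(z),)
        return charge_candidates

    for i in order:
        if claimed[i]:
            continue
        coelute = np.abs(rt - rt[i]) <= rt_tolerance
        for z in candidates(i):
            # isotopologue children: heavier, strictly less intense
            for k in range(1, max_isotopes + 1):
                target = mz[i] + k * ISOTOPE_SPACING / z
                hits = np.flatnonzero(
                    coelute
                    & ~claimed
                    & (np.abs(mz - target) <= mz_tolerance)
                    & (intensity < intensity[i])
                )
                hits = hits[hits != i]
                if "charge" in peaks.columns:
                    zc = charge[hits]
                    hits = hits[~np.isfinite(zc) | (zc == z)]
                if len(hits):
                    j = hits[np.argmin(np.abs(mz[hits] - target))]
                    flags[j] = ISOTOPE
                    claimed[j] = True
            # adduct children
            for delta in adducts.values():
                target = mz[i] + delta / z
                hits = np.flatnonzero(
                    coelute & ~claimed & (np.abs(mz - target) <= mz_tolerance)
                )
                hits = hits[hits != i]
                if len(hits):
                    j = hits[np.argmin(np.abs(mz[hits] - target))]
                    flags[j] = ADDUCT
                    claimed[j] = True

    out = peaks.copy()
    out["flag"] = flags
    return out


def classify_runs(peaks: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Apply :func:`classify_peaks` independently within each ``run`` group."""
    _require_columns(peaks, ["run"])
    parts = [
        classify_peaks(group, **kwargs) for _, group in peaks.groupby("run", sort=False)
    ]
    return pd.concat(parts).loc[peaks.index]


def filter_monoisotopic(peaks: pd.DataFrame) -> pd.DataFrame:
    """Keep only monoisotopic records of a classified list, order preserved."""
    if "flag" not in peaks.columns:
        raise ValueError("peak list is unclassified: run classify_peaks first")
    return peaks[peaks["flag"] == MONOISOTOPIC].copy()
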