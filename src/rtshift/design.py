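"""Full factorial designs on a coded scale with a real-unit mapping.

A design is described by a list of factors, each with a physical *center*
value, a *step* (the physical increment corresponding to one coded unit),
and a set of integer coded levels (default ``-2 .. +2``, the five-level
grid used for chromatographic pH/temperature studies).  The design matrix
``D`` expands every run's coded levels into model-term columns — intercept,
linear, quadratic and pairwise-interaction terms — so that a response
matrix ``X`` (runs x compounds) can be regressed on ``D``.

Coded quadratic columns are raw squares of the coded levels, not orthogonal
polynomials: the pseudo-inverse used downstream tolerates the resulting
non-orthogonality and the coefficients stay directly interpretable as
minutes per coded unit (or per coded unit squared).

Run order is deterministic: the Cartesian product of coded levels is
enumerated with the first declared factor as the outermost loop, and
center-point replicates are appended last, flagged via
:attr:`DesignMatrix.is_replicate`.  Replicates are kept as distinct rows
because they carry the pure-error information used for confidence
intervals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FactorSpec",
    "Term",
    "DesignSpec",
    "DesignMatrix",
    "build_design",
    "coded_to_real",
    "expand_terms",
]

INTERCEPT_LABEL = "intercept"


class DesignError(ValueError):
    """Invalid factor, term or design specification."""


@dataclass(frozen=True)
class FactorSpec:
    """One controlled factor of the design.

    Parameters
    ----------
    name:
        Factor identifier, e.g. ``"pH"`` or ``"temperature"``.
    center:
        Physical value at coded level 0 (pH units, degrees Celsius, ...).
    step:
        Physical increment per coded unit; must be positive.
    coded_levels:
        Strictly increasing integer levels; default five-level grid.
    """

    name: str
    center: float
    step: float
    coded_levels: tuple[int, ...] = (-2, -1, 0, 1, 2)

    def __post_init__(self) -> None:
        if not self.name:
            raise DesignError("factor name must be non-empty")
        if not self.step > 0:
            raise DesignError(f"factor {self.name!r}: step must be > 0")
        levels = tuple(int(v) for v in self.coded_levels)
        if len(levels) < 2:
            raise DesignError(f"factor {self.name!r}: need at least two coded levels")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise DesignError(
                f"factor {self.name!r}: coded levels must be strictly increasing"
            )
        object.__setattr__(self, "coded_levels", levels)

    def to_real(self, coded: int) -> float:
        """Map a coded level to its physical value, ``center + coded * step``."""
        if coded not in self.coded_levels:
            raise DesignError(
                f"coded level {coded} not among declared levels "
                f"{self.coded_levels} of factor {self.name!r}"
            )
        return self.center + coded * self.step


def coded_to_real(coded: int, factor: FactorSpec) -> float:
    """Functional alias for :meth:`FactorSpec.to_real`."""
    return factor.to_real(coded)


@dataclass(frozen=True)
class Term:
    """A model term: intercept, linear, quadratic or pairwise interaction."""

    kind: str  # "intercept" | "linear" | "quadratic" | "interaction"
    factors: tuple[str, ...] = ()

    _KINDS = ("intercept", "linear", "quadratic", "interaction")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise DesignError(f"unknown term kind {self.kind!r}")
        n_expected = {"intercept": 0, "linear": 1, "quadratic": 1, "interaction": 2}
        if len(self.factors) != n_expected[self.kind]:
            raise DesignError(
                f"term kind {self.kind!r} takes {n_expected[self.kind]} factor(s)"
            )
        object.__setattr__(self, "factors", tuple(self.factors))

    @property
    def label(self) -> str:
        if self.kind == "intercept":
            return INTERCEPT_LABEL
        if self.kind == "linear":
            return self.factors[0]
        if self.kind == "quadratic":
            return f"{self.factors[0]}^2"
        return f"{self.factors[0]}*{self.factors[1]}"

    @classmethod
    def parse(cls, label: str, factor_names: Sequence[str]) -> "Term":
        """Parse a term label (``intercept``, ``pH``, ``pH^2``, ``pH*T``)."""
        label = label.strip()
        if label in ("1", INTERCEPT_LABEL):
            return cls("intercept")
        if "*" in label:
            a, b = (s.strip() for s in label.split("*", 1))
            for name in (a, b):
                if name not in factor_names:
                    raise DesignError(f"interaction references unknown factor {name!r}")
            return cls("interaction", (a, b))
        if label.endswith("^2"):
            name = label[:-2].strip()
            if name not in factor_names:
                raise DesignError(f"quadratic term references unknown factor {name!r}")
            return cls("quadratic", (name,))
        if label not in factor_names:
            raise DesignError(f"linear term references unknown factor {label!r}")
        return cls("linear", (label,))

    def evaluate(self, coded: Mapping[str, float]) -> float:
        if self.kind == "intercept":
            return 1.0
        if self.kind == "linear":
            return float(coded[self.factors[0]])
        if self.kind == "quadratic":
            return float(coded[self.factors[0]]) ** 2
        return float(coded[self.factors[0]]) * float(coded[self.factors[1]])


def default_model_terms(factors: Sequence[FactorSpec]) -> tuple[Term, ...]:
    """Intercept, each linear, each quadratic, then each pairwise interaction."""
    terms: list[Term] = [Term("intercept")]
    terms += [Term("linear", (f.name,)) for f in factors]
    terms += [Term("quadratic", (f.name,)) for f in factors]
    terms += [
        Term("interaction", (a.name, b.name))
        for a, b in itertools.combinations(factors, 2)
    ]
    return tuple(terms)


@dataclass(frozen=True)
class DesignSpec:
    """Factors, replicate count and model terms of a full factorial design."""

    factors: tuple[FactorSpec, ...]
    center_replicates: int = 0
    model_terms: tuple[Term, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        factors = tuple(self.factors)
        if not factors:
            raise DesignError("design needs at least one factor")
        names = [f.name for f in factors]
        if len(set(names)) != len(names):
            raise DesignError("duplicate factor names")
        if self.center_replicates < 0:
            raise DesignError("center_replicates must be >= 0")
        if self.center_replicates > 0 and any(0 not in f.coded_levels for f in factors):
            raise DesignError(
                "center replicates requested but some factor lacks coded level 0"
            )
        terms = self.model_terms
        if terms is None:
            terms = default_model_terms(factors)
        terms = tuple(terms)
        labels = [t.label for t in terms]
        if len(set(labels)) != len(labels):
            raise DesignError("duplicate model terms")
        if not terms or terms[0].kind != "intercept":
            raise DesignError("model terms must start with the intercept")
        for t in terms:
            for name in t.factors:
                if name not in names:
                    raise DesignError(
                        f"term {t.label!r} references factor {name!r} absent "
                        f"from the design"
                    )
        object.__setattr__(self, "factors", factors)
        object.__setattr__(self, "model_terms", terms)

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    @property
    def term_labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.model_terms)

    @property
    def n_runs(self) -> int:
        n = 1
        for f in self.factors:
            n *= len(f.coded_levels)
        return n + self.center_replicates

    @classmethod
    def two_factor_default(cls, center_replicates: int = 5) -> "DesignSpec":
        """The five-level pH x column-temperature design.

        pH spans 3.25–4.25 (center 3.75, step 0.25) and column temperature
        35–45 degC (center 40, step 2.5); 25 factorial runs plus the
        requested number of center-point replicates.
        """
        factors = (
            FactorSpec("pH", center=3.75, step=0.25),
            FactorSpec("temperature", center=40.0, step=2.5),
        )
        return cls(factors=factors, center_replicates=center_replicates)

    # -- config I/O ---------------------------------------------------------

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "DesignSpec":
        try:
            raw_factors = cfg["factors"]
        except KeyError as exc:
            raise DesignError("design config missing 'factors'") from exc
        factors = tuple(
            FactorSpec(
                name=f["name"],
                center=float(f["center"]),
                step=float(f["step"]),
                coded_levels=tuple(f.get("coded_levels", (-2, -1, 0, 1, 2))),
            )
            for f in raw_factors
        )
        names = [f.name for f in factors]
        terms = cfg.get("model_terms")
        parsed = (
            tuple(Term.parse(label, names) for label in terms) if terms else None
        )
        return cls(
            factors=factors,
            center_replicates=int(cfg.get("center_replicates", 0)),
            model_terms=parsed,
        )

    def to_dict(self) -> dict:
        return {
            "factors": [
                {
                    "name": f.name,
                    "center": f.center,
                    "step": f.step,
                    "coded_levels": list(f.coded_levels),
                }
                for f in self.factors
            ],
            "center_replicates": self.center_replicates,
            "model_terms": list(self.term_labels),
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DesignSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class DesignMatrix:
    """Expanded design: term columns per run, plus the coded levels.

    Attributes
    ----------
    frame:
        runs x terms table on the coded scale (intercept column all ones).
    coded:
        runs x factors table of raw coded levels.
    is_replicate:
        Boolean flag per run, True for appended center replicates.
    spec:
        The originating :class:`DesignSpec`.
    """

    frame: pd.DataFrame
    coded: pd.DataFrame
    is_replicate: np.ndarray
    spec: DesignSpec

    @property
    def run_labels(self) -> list[str]:
        return list(self.frame.index)

    @property
    def term_labels(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    def real_values(self) -> pd.DataFrame:
        """Physical factor settings per run (Table-style view of the design)."""
        out = {}
        for f in self.spec.factors:
            out[f.name] = [f.to_real(int(c)) for c in self.coded[f.name]]
        return pd.DataFrame(out, index=self.frame.index)

    def to_csv(self, path: str | Path) -> None:
        df = self.frame.copy()
        df.insert(len(df.columns), "is_replicate", self.is_replicate.astype(int))
        df.to_csv(path, index_label="run")


def expand_terms(
    coded_row: Mapping[str, float], model_terms: Iterable[Term]
) -> list[float]:
    """Evaluate every model term at one run's coded levels.

    For the default two-factor spec this yields
    ``[1, p, t, p^2, t^2, p*t]``.
    """
    return [t.evaluate(coded_row) for t in model_terms]


def build_design(spec: DesignSpec) -> DesignMatrix:
    """Enumerate the full factorial and expand it into model-term columns.

    Rows are the Cartesian product of coded levels (first factor outermost),
    followed by ``center_replicates`` rows at all-zero coded levels.
    """
    names = spec.factor_names
    grids = [f.coded_levels for f in spec.factors]
    rows = list(itertools.product(*grids))
    n_factorial = len(rows)
    rows += [tuple(0 for _ in names)] * spec.center_replicates

    coded = pd.DataFrame(rows, columns=list(names), dtype=float)
    width = max(2, len(str(len(rows))))
    labels = [f"run{i + 1:0{width}d}" for i in range(n_factorial)] + [
        f"center{i + 1:02d}" for i in range(spec.center_replicates)
    ]
    coded.index = labels

    values = np.array(
        [expand_terms(dict(zip(names, row)), spec.model_terms) for row in rows],
        dtype=float,
    )
    frame = pd.DataFrame(values, index=labels, columns=list(spec.term_labels))
    is_replicate = np.array(
        [False] * n_factorial + [True] * spec.center_replicates, dtype=bool
    )
    return DesignMatrix(frame=frame, coded=coded, is_replicate=is_replicate, spec=spec)
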