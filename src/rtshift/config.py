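"""Run configuration: one YAML document drives simulate/analyze/recover."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .design import DesignSpec

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Validated parameters for the full pipeline.

    Defaults reproduce the reference study layout: a 25-run five-level
    two-factor factorial with 5 center replicates, 98 monoisotopic
    compounds, one latent uncontrolled factor, and six principal
    components in the latent models.
    """

    design: DesignSpec = field(
        default_factory=lambda: DesignSpec.two_factor_default(center_replicates=5)
    )
    n_compounds: int = 98
    n_latent: int = 1
    noise_sd: float = 0.03
    latent_score_sd: float = 0.03
    n_positive_temperature: int = 10
    simulate_peaks: bool = True
    mz_tolerance: float = 0.005
    rt_tolerance: float = 0.1
    overlap_window: float = 0.2
    n_components: int = 6
    max_level_components: int = 10
    confidence_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 2:
            raise ValueError("n_compounds must be >= 2")
        if self.n_latent < 0:
            raise ValueError("n_latent must be >= 0")
        if self.noise_sd < 0 or self.latent_score_sd < 0:
            raise ValueError("noise and latent scales must be >= 0")
        if self.mz_tolerance <= 0 or self.rt_tolerance <= 0:
            raise ValueError("tolerances must be positive")
        if self.overlap_window < 0:
            raise ValueError("overlap_window must be >= 0")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if not 0 < self.confidence_level < 1:
            raise ValueError("confidence_level must be in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["design"] = self.design.to_dict()
        return d

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        cfg = dict(cfg)
        if "design" in cfg and cfg["design"] is not None:
            cfg["design"] = DesignSpec.from_dict(cfg["design"])
        else:
            cfg.pop("design", None)
        unknown = set(cfg) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**cfg)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def digest(self) -> str:
        """Stable hash of the full configuration, recorded in every output."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
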