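"""Run configuration (YAML) shared by the CLI and the pipeline drivers."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .exceptions import ConfigurationError
from .kinetics import MOLAR_MASS

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Pipeline settings with the assay's defaults.

    ``dilution_rate`` is the chemostat loss rate D (day^-1) at which R* is
    evaluated; ``alpha`` the level of the zero-growth gate; ``top_k`` the
    number of highest interval rates averaged per well.
    """

    dilution_rate: float = 0.2
    alpha: float = 0.05
    top_k: int = 5
    fdr_method: str = "fdr_bh"
    weighting: str = "none"  # or "inverse_variance"
    aggregate: str = "per_well"  # or "per_treatment"
    subtract_control_baseline: bool = False
    molar_mass: dict[str, float] = field(default_factory=lambda: dict(MOLAR_MASS))
    gradient: list[float] | None = None  # override the nutrient default

    def __post_init__(self) -> None:
        if self.dilution_rate <= 0:
            raise ConfigurationError("dilution_rate must be positive")
        if not (0 < self.alpha < 1):
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.top_k < 1:
            raise ConfigurationError("top_k must be >= 1")
        for el in ("C", "N", "P"):
            if self.molar_mass.get(el, 0) <= 0:
                raise ConfigurationError(f"molar_mass.{el} must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run configuration; missing keys fall back to defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = RunConfig.__dataclass_fields__.keys()
    unknown = set(raw) - set(known)
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    if "molar_mass" in raw:
        mm = dict(MOLAR_MASS)
        mm.update(raw["molar_mass"])
        raw["molar_mass"] = mm
    return RunConfig(**raw)
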