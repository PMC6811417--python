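"""Run configuration: one YAML file, every CLI flag can override a key."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .params import ModelParameters, default_parameter_file, read_parameters
from .regimen import Regimen, regimen_from_phases, standard_regimens

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs; seed is mandatory for reproducibility."""

    seed: int
    parameter_file: Path = field(default_factory=default_parameter_file)
    output_dir: Path = Path("bdqsim-out")
    n_per_race: int = 2000  # virtual subjects per race for regimen comparisons
    n_rep: int = 500  # VPC replicates
    cmax_resolution_h: float = 0.25  # peak-search grid within dosing days
    trough_resolution_h: float = 24.0  # trough-trajectory output grid
    regimen_specs: dict = field(default_factory=dict)  # name -> phase list

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_per_race < 2 or self.n_rep < 1:
            raise ValueError("n_per_race must be >= 2 and n_rep >= 1")
        if self.cmax_resolution_h <= 0 or self.trough_resolution_h <= 0:
            raise ValueError("grid resolutions must be positive")
        object.__setattr__(self, "parameter_file", Path(self.parameter_file))
        object.__setattr__(self, "output_dir", Path(self.output_dir))
        if not self.parameter_file.exists():
            raise FileNotFoundError(f"parameter file not found: {self.parameter_file}")

    def load_parameters(self) -> ModelParameters:
        return read_parameters(self.parameter_file)

    def regimens(self) -> dict[str, Regimen]:
        """Standard four regimens, plus/overridden by any configured specs."""
        regs = standard_regimens()
        for name, spec in self.regimen_specs.items():
            regs[name] = regimen_from_phases(name, spec["phases"],
                                             duration_days=spec.get("duration_days"))
        return regs


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file plus keyword overrides.

    ``overrides`` with value ``None`` are ignored, so CLI flags can be passed
    straight through.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(RunConfig.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    if "seed" not in data:
        raise ValueError("config must provide a seed (file key 'seed' or --seed)")
    return RunConfig(**data)
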