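"""Fixed-effect and variance parameters of the population-PK model.

The model is parameterised the way oral population-PK models conventionally
are: apparent clearances and volumes (i.e. scaled by the reference
bioavailability), a relative bioavailable fraction ``F`` with reference value
1, and a fraction ``FR`` of the absorbed dose entering the fast absorption
pathway.  Parameters are shipped in a flat key-value text file so that the
math core stays data-driven and auditable; :func:`read_parameters` /
:func:`write_parameters` round-trip that format.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

__all__ = [
    "ThetaSet",
    "OmegaSet",
    "ResidualError",
    "ModelParameters",
    "read_parameters",
    "write_parameters",
    "default_parameter_file",
    "load_default_parameters",
    "parameter_file_hash",
]

#: name of the parameter file bundled with the package
DEFAULT_PARAMETER_RESOURCE = "bedaquiline_popkk.txt"


@dataclass(frozen=True)
class ThetaSet:
    """Typical (fixed-effect) parameter values of the structural model."""

    apparent_clearance_typical: float  # L/h
    central_volume_typical: float  # L
    peripheral_volumes: tuple[float, float, float]  # L
    intercompartmental_clearances: tuple[float, float, float]  # L/h
    absorption_rate_path1: float  # 1/h
    absorption_rate_path2: float  # 1/h
    absorption_lag_path1: float  # h
    absorption_lag_path2: float  # h
    bioavailable_fraction_typical: float  # relative, reference 1
    fraction_to_path1_typical: float  # in [0, 1]

    def __post_init__(self) -> None:
        positive = {
            "apparent_clearance_typical": self.apparent_clearance_typical,
            "central_volume_typical": self.central_volume_typical,
            "absorption_rate_path1": self.absorption_rate_path1,
            "absorption_rate_path2": self.absorption_rate_path2,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if len(self.peripheral_volumes) != 3 or len(self.intercompartmental_clearances) != 3:
            raise ValueError("expected exactly 3 peripheral compartments")
        if any(v <= 0 for v in self.peripheral_volumes):
            raise ValueError("peripheral volumes must be strictly positive")
        if any(q < 0 for q in self.intercompartmental_clearances):
            raise ValueError("intercompartmental clearances must be nonnegative")
        if self.absorption_lag_path1 < 0 or self.absorption_lag_path2 < 0:
            raise ValueError("absorption lags must be nonnegative")
        if not 0 < self.bioavailable_fraction_typical <= 1.6:
            raise ValueError("bioavailable_fraction_typical must lie in (0, 1.6]")
        if not 0 <= self.fraction_to_path1_typical <= 1:
            raise ValueError("fraction_to_path1_typical must lie in [0, 1]")


@dataclass(frozen=True)
class OmegaSet:
    """Between-subject variance terms (log scale; logit scale for FR)."""

    variance_clearance: float = 0.0
    variance_volume: float = 0.0
    variance_bioavailability: float = 0.0
    variance_path_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "variance_clearance",
            "variance_volume",
            "variance_bioavailability",
            "variance_path_fraction",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @classmethod
    def zero(cls) -> "OmegaSet":
        return cls()


@dataclass(frozen=True)
class ResidualError:
    """Residual unexplained variability applied to observed concentrations.

    ``conc_obs = conc * (1 + eps_prop) + eps_add`` with independent zero-mean
    normal deviates; negative results are truncated at zero.
    """

    proportional_cv: float = 0.30
    additive_sd: float = 0.0  # ug/mL

    def __post_init__(self) -> None:
        if self.proportional_cv < 0 or self.additive_sd < 0:
            raise ValueError("residual error magnitudes must be nonnegative")


@dataclass(frozen=True)
class ModelParameters:
    """Bundle of everything the parameter file defines."""

    theta: ThetaSet
    omega: OmegaSet
    residual: ResidualError = field(default_factory=ResidualError)


_KEYMAP = {
    "cl_typical": ("theta", "apparent_clearance_typical"),
    "vc_typical": ("theta", "central_volume_typical"),
    "ka_path1": ("theta", "absorption_rate_path1"),
    "ka_path2": ("theta", "absorption_rate_path2"),
    "lag_path1": ("theta", "absorption_lag_path1"),
    "lag_path2": ("theta", "absorption_lag_path2"),
    "f_typical": ("theta", "bioavailable_fraction_typical"),
    "fr_path1_typical": ("theta", "fraction_to_path1_typical"),
    "omega2_cl": ("omega", "variance_clearance"),
    "omega2_vc": ("omega", "variance_volume"),
    "omega2_f": ("omega", "variance_bioavailability"),
    "omega2_fr": ("omega", "variance_path_fraction"),
    "sigma_prop": ("residual", "proportional_cv"),
    "sigma_add": ("residual", "additive_sd"),
}


def read_parameters(path: str | Path) -> ModelParameters:
    """Parse a flat key-value parameter file into a :class:`ModelParameters`.

    Lines are ``key value [unit] [# comment]``; blank lines and lines starting
    with ``#`` are ignored.  Peripheral compartments use keys ``vp1..vp3`` and
    ``q1..q3``.
    """
    values: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'key value', got {raw!r}")
        key = parts[0]
        try:
            values[key] = float(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric value {parts[1]!r}") from exc

    missing = [k for k in list(_KEYMAP) + ["vp1", "vp2", "vp3", "q1", "q2", "q3"] if k not in values]
    if missing:
        raise ValueError(f"parameter file {path} is missing keys: {', '.join(missing)}")

    kw: dict[str, dict[str, object]] = {"theta": {}, "omega": {}, "residual": {}}
    for key, (group, attr) in _KEYMAP.items():
        kw[group][attr] = values[key]
    kw["theta"]["peripheral_volumes"] = (values["vp1"], values["vp2"], values["vp3"])
    kw["theta"]["intercompartmental_clearances"] = (values["q1"], values["q2"], values["q3"])
    return ModelParameters(
        theta=ThetaSet(**kw["theta"]),
        omega=OmegaSet(**kw["omega"]),
        residual=ResidualError(**kw["residual"]),
    )


def write_parameters(params: ModelParameters, path: str | Path) -> None:
    """Write ``params`` in the flat key-value dialect read by :func:`read_parameters`."""
    th, om, re_ = params.theta, params.omega, params.residual
    rows = [
        ("cl_typical", th.apparent_clearance_typical, "L/h"),
        ("vc_typical", th.central_volume_typical, "L"),
        ("vp1", th.peripheral_volumes[0], "L"),
        ("vp2", th.peripheral_volumes[1], "L"),
        ("vp3", th.peripheral_volumes[2], "L"),
        ("q1", th.intercompartmental_clearances[0], "L/h"),
        ("q2", th.intercompartmental_clearances[1], "L/h"),
        ("q3", th.intercompartmental_clearances[2], "L/h"),
        ("ka_path1", th.absorption_rate_path1, "1/h"),
        ("ka_path2", th.absorption_rate_path2, "1/h"),
        ("lag_path1", th.absorption_lag_path1, "h"),
        ("lag_path2", th.absorption_lag_path2, "h"),
        ("f_typical", th.bioavailable_fraction_typical, "-"),
        ("fr_path1_typical", th.fraction_to_path1_typical, "-"),
        ("omega2_cl", om.variance_clearance, "-"),
        ("omega2_vc", om.variance_volume, "-"),
        ("omega2_f", om.variance_bioavailability, "-"),
        ("omega2_fr", om.variance_path_fraction, "-"),
        ("sigma_prop", re_.proportional_cv, "-"),
        ("sigma_add", re_.additive_sd, "ug/mL"),
    ]
    lines = ["# bdqsim parameter file"]
    lines += [f"{k:<20}{v:<12g}{u}" for k, v, u in rows]
    Path(path).write_text("\n".join(lines) + "\n")


def default_parameter_file() -> Path:
    """Path of the bedaquiline parameter file bundled with the package."""
    return Path(str(resources.files("bdqsim.data") / DEFAULT_PARAMETER_RESOURCE))


def load_default_parameters() -> ModelParameters:
    return read_parameters(default_parameter_file())


def parameter_file_hash(path: str | Path | None = None) -> str:
    """Short SHA-256 of the parameter file, for provenance headers."""
    p = Path(path) if path is not None else default_parameter_file()
    return hashlib.sha256(p.read_bytes()).hexdigest()[:12]


def with_zero_omega(params: ModelParameters) -> ModelParameters:
    """Convenience: same thetas, no between-subject variability."""
    return replace(params, omega=OmegaSet.zero())
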