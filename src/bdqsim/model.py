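"""Structural PK model: covariate effects, BSV sampling, rate matrix.

The disposition system is a 4-compartment mammillary model (central + 3
peripheral) with first-order elimination from the central compartment, fed by
two parallel first-order oral absorption pathways, each with its own rate
constant and lag time.  Covariate effects are multiplicative on the typical
values:

* clearance x 1.375 for healthy subjects or DS-TB patients (vs MDR-TB),
* clearance x 1.52 for black (vs nonblack) race,
* central volume x 0.843 for female (vs male) subjects,
* bioavailability x 1.51 for healthy subjects or DS-TB patients (vs MDR-TB).

Between-subject variability is log-normal on clearance, central volume and
bioavailability, and logit-normal on the fast-pathway fraction so the
realised fraction stays in [0, 1].
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

from .params import OmegaSet, ThetaSet

__all__ = [
    "Race",
    "Sex",
    "PatientType",
    "CovariateSet",
    "IndividualParameters",
    "typical_parameters",
    "sample_individual",
    "sample_individuals",
    "build_rate_matrix",
    "N_COMPARTMENTS",
    "DEPOT1",
    "DEPOT2",
    "CENTRAL",
    "CL_RACE_BLACK",
    "CL_DS_OR_HEALTHY",
    "VC_FEMALE",
    "F_DS_OR_HEALTHY",
]

# Covariate multipliers as reported for the published model.
CL_DS_OR_HEALTHY = 1.375  # clearance, healthy/DS-TB vs MDR-TB
CL_RACE_BLACK = 1.52  # clearance, black vs nonblack
VC_FEMALE = 0.843  # central volume, female vs male
F_DS_OR_HEALTHY = 1.51  # bioavailability, healthy/DS-TB vs MDR-TB

# Compartment indexing used throughout the package.
DEPOT1, DEPOT2, CENTRAL = 0, 1, 2
N_COMPARTMENTS = 6  # 2 depots + central + 3 peripheral


class Race(str, enum.Enum):
    BLACK = "black"
    NONBLACK = "nonblack"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class PatientType(str, enum.Enum):
    MDR_TB = "MDR_TB"
    DS_TB = "DS_TB"
    HEALTHY = "healthy"


@dataclass(frozen=True)
class CovariateSet:
    """Subject-level covariates entering the model."""

    race: Race
    sex: Sex
    patient_type: PatientType

    def __post_init__(self) -> None:
        # accept plain strings, reject anything outside the enums
        object.__setattr__(self, "race", Race(self.race))
        object.__setattr__(self, "sex", Sex(self.sex))
        object.__setattr__(self, "patient_type", PatientType(self.patient_type))


@dataclass(frozen=True)
class IndividualParameters:
    """Realised parameters for one subject (covariates + random effects)."""

    clearance: float  # L/h
    central_volume: float  # L
    peripheral_volumes: tuple[float, float, float]
    intercompartmental_clearances: tuple[float, float, float]
    absorption_rate_path1: float
    absorption_rate_path2: float
    absorption_lag_path1: float
    absorption_lag_path2: float
    bioavailable_fraction: float
    fraction_to_path1: float

    def __post_init__(self) -> None:
        if self.clearance <= 0 or self.central_volume <= 0:
            raise ValueError("clearance and central volume must be positive")
        if self.bioavailable_fraction <= 0:
            raise ValueError("bioavailable fraction must be positive")
        if not 0 <= self.fraction_to_path1 <= 1:
            raise ValueError("fraction_to_path1 must lie in [0, 1]")


def typical_parameters(theta: ThetaSet, cov: CovariateSet) -> IndividualParameters:
    """Covariate-adjusted typical values (all random effects at zero).

    Multipliers compose multiplicatively, so the order of application is
    irrelevant.  The patient-type effects on clearance and bioavailability are
    applied jointly (their impact on CL/F is largely offsetting and the model
    does not support using one without the other).
    """
    cov = CovariateSet(cov.race, cov.sex, cov.patient_type)  # revalidate enums
    cl = theta.apparent_clearance_typical
    vc = theta.central_volume_typical
    f = theta.bioavailable_fraction_typical
    if cov.patient_type in (PatientType.DS_TB, PatientType.HEALTHY):
        cl *= CL_DS_OR_HEALTHY
        f *= F_DS_OR_HEALTHY
    if cov.race is Race.BLACK:
        cl *= CL_RACE_BLACK
    if cov.sex is Sex.FEMALE:
        vc *= VC_FEMALE
    return IndividualParameters(
        clearance=cl,
        central_volume=vc,
        peripheral_volumes=tuple(theta.peripheral_volumes),
        intercompartmental_clearances=tuple(theta.intercompartmental_clearances),
        absorption_rate_path1=theta.absorption_rate_path1,
        absorption_rate_path2=theta.absorption_rate_path2,
        absorption_lag_path1=theta.absorption_lag_path1,
        absorption_lag_path2=theta.absorption_lag_path2,
        bioavailable_fraction=f,
        fraction_to_path1=theta.fraction_to_path1_typical,
    )


def _draw_etas(omega: OmegaSet, rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    return {
        "cl": rng.normal(0.0, np.sqrt(omega.variance_clearance), n),
        "vc": rng.normal(0.0, np.sqrt(omega.variance_volume), n),
        "f": rng.normal(0.0, np.sqrt(omega.variance_bioavailability), n),
        "fr": rng.normal(0.0, np.sqrt(omega.variance_path_fraction), n),
    }


def _apply_etas(typ: IndividualParameters, etas: dict[str, np.ndarray], i: int) -> IndividualParameters:
    fr0 = typ.fraction_to_path1
    if 0.0 < fr0 < 1.0:
        fr = float(expit(logit(fr0) + etas["fr"][i]))
    else:  # degenerate typical fraction: logit undefined, keep it fixed
        fr = fr0
    return replace(
        typ,
        clearance=typ.clearance * float(np.exp(etas["cl"][i])),
        central_volume=typ.central_volume * float(np.exp(etas["vc"][i])),
        bioavailable_fraction=typ.bioavailable_fraction * float(np.exp(etas["f"][i])),
        fraction_to_path1=fr,
    )


def sample_individual(
    typ: IndividualParameters,
    omega: OmegaSet,
    rng: np.random.Generator | int,
) -> IndividualParameters:
    """Draw one realisation of the between-subject random effects.

    CL, VC and F are perturbed by exponentiated zero-mean normal deviates with
    the stated variances; the path-1 fraction by a logit-scale deviate.
    Deterministic given the seed / generator state.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return _apply_etas(typ, _draw_etas(omega, rng, 1), 0)


def sample_individuals(
    typicals: Sequence[IndividualParameters],
    omega: OmegaSet,
    rng: np.random.Generator | int,
) -> list[IndividualParameters]:
    """Vector version of :func:`sample_individual` (one eta vector per subject)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    etas = _draw_etas(omega, rng, len(typicals))
    return [_apply_etas(typ, etas, i) for i, typ in enumerate(typicals)]


def build_rate_matrix(ind: IndividualParameters) -> np.ndarray:
    """First-order rate-constant matrix of the full linear system.

    Compartment order: [depot path 1, depot path 2, central, peripheral 1..3].
    Off-diagonal entries are nonnegative transfer rates; each column sums to
    minus the elimination rate out of that compartment (zero everywhere except
    the central column, which loses CL/VC to elimination).  dy/dt = A @ y.
    """
    cl, vc = ind.clearance, ind.central_volume
    if vc <= 0 or any(v <= 0 for v in ind.peripheral_volumes):
        raise ValueError("volumes must be strictly positive")
    A = np.zeros((N_COMPARTMENTS, N_COMPARTMENTS))
    A[DEPOT1, DEPOT1] = -ind.absorption_rate_path1
    A[DEPOT2, DEPOT2] = -ind.absorption_rate_path2
    A[CENTRAL, DEPOT1] = ind.absorption_rate_path1
    A[CENTRAL, DEPOT2] = ind.absorption_rate_path2
    qs = ind.intercompartmental_clearances
    vs = ind.peripheral_volumes
    A[CENTRAL, CENTRAL] = -(cl + sum(qs)) / vc
    for i, (q, v) in enumerate(zip(qs, vs)):
        p = CENTRAL + 1 + i
        A[p, CENTRAL] = q / vc
        A[CENTRAL, p] = q / v
        A[p, p] = -q / v
    return A
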