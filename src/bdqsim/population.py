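"""Virtual populations and synthetic observed datasets.

Emulates the covariate structure of the NC-005 trial used for model
qualification: three arms (labeled regimen in DS-TB, 200 mg QD in DS-TB, and
200 mg QD in MDR-TB; n = 59/59/60), predominantly black (83 % overall) and
male.  Body weight, age and albumin are generated as population descriptors
for dataset realism only — they are not covariates of this model.

Synthetic "observed" concentrations are model predictions with residual
error applied, sampled at a documented nominal schedule: trough visits over
the study plus 24-h post-dose profiles on days 14 and 56 in a 15-subject
per-arm substudy.  The schedule is a stand-in design, not a reconstruction
of the trial's actual records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    CovariateSet,
    IndividualParameters,
    PatientType,
    Race,
    Sex,
    sample_individuals,
    typical_parameters,
)
from .params import ModelParameters, ResidualError
from .regimen import HOURS_PER_DAY, Regimen, labeled_regimen, qd_regimen
from .simulate import simulate_batch

__all__ = [
    "ArmSpec",
    "PopulationSpec",
    "VirtualSubject",
    "ObservationDesign",
    "generate_population",
    "generate_observed",
    "apply_residual_error",
    "nc005_population_spec",
    "nc005_regimens",
    "nc005_observation_design",
]


@dataclass(frozen=True)
class ArmSpec:
    """One trial arm: name, size, patient type and the regimen it receives."""

    name: str
    n: int
    patient_type: PatientType
    regimen_name: str
    fraction_black: float | None = None  # overrides the population-level fraction

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("arm size must be >= 1")
        if self.fraction_black is not None and not 0 <= self.fraction_black <= 1:
            raise ValueError("fraction_black must lie in [0, 1]")


@dataclass(frozen=True)
class PopulationSpec:
    """Arms plus marginal covariate fractions for a virtual trial population."""

    arms: tuple[ArmSpec, ...]
    fraction_black: float = 0.83
    fraction_male: float = 0.65

    def __post_init__(self) -> None:
        if not self.arms:
            raise ValueError("need at least one arm")
        for frac in (self.fraction_black, self.fraction_male):
            if not 0 <= frac <= 1:
                raise ValueError("covariate fractions must lie in [0, 1]")

    @property
    def n_total(self) -> int:
        return sum(arm.n for arm in self.arms)


@dataclass(frozen=True)
class VirtualSubject:
    """One simulated subject: identity, covariates and realised parameters."""

    subject_id: str
    arm: str
    covariates: CovariateSet
    parameters: IndividualParameters
    descriptors: dict = field(default_factory=dict)  # weight/age/albumin etc.


@dataclass(frozen=True)
class ObservationDesign:
    """Nominal sampling schedule for synthetic observed data."""

    trough_days: tuple[int, ...] = (7, 14, 28, 42, 56, 70)
    profile_days: tuple[int, ...] = (14, 56)
    profile_times_h: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0)
    n_profile_per_arm: int = 15
    horizon_days: float = 70.0  # simulation horizon; all sampling must fall inside


def nc005_population_spec() -> PopulationSpec:
    """The NC-005-like three-arm population (n = 59/59/60, 83 % black)."""
    return PopulationSpec(
        arms=(
            ArmSpec("B(loading)PaZ", 59, PatientType.DS_TB, "labeled_56d", fraction_black=46 / 59),
            ArmSpec("B(200mg)PaZ", 59, PatientType.DS_TB, "qd200_56d", fraction_black=48 / 59),
            ArmSpec("B(200mg)PaMZ", 60, PatientType.MDR_TB, "qd200_56d", fraction_black=53 / 60),
        ),
        fraction_black=147 / 178,
        fraction_male=0.65,
    )


def nc005_regimens() -> dict[str, Regimen]:
    """The 56-day dosing schedules of the NC-005 arms."""
    return {
        "labeled_56d": labeled_regimen().truncated(56, name="400 mg QD x 14 d, 200 mg TIW (56 d)"),
        "qd200_56d": qd_regimen(200.0, 56, name="200 mg QD (56 d)"),
    }


def nc005_observation_design() -> ObservationDesign:
    return ObservationDesign()


_DESCRIPTOR_MEDIANS = {"weight_kg": 53.0, "age_yr": 32.0, "albumin_g_dl": 3.5}


def generate_population(
    spec: PopulationSpec,
    params: ModelParameters,
    seed: int | np.random.Generator,
) -> list[VirtualSubject]:
    """Sample a virtual population: covariates, random effects, descriptors.

    Arm sizes are respected exactly; race and sex are Bernoulli draws at the
    spec fractions (per-arm black fraction if given).  Deterministic given the
    seed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    subjects: list[VirtualSubject] = []
    for arm in spec.arms:
        frac_black = arm.fraction_black if arm.fraction_black is not None else spec.fraction_black
        races = np.where(rng.random(arm.n) < frac_black, Race.BLACK.value, Race.NONBLACK.value)
        sexes = np.where(rng.random(arm.n) < spec.fraction_male, Sex.MALE.value, Sex.FEMALE.value)
        covs = [CovariateSet(r, s, arm.patient_type) for r, s in zip(races, sexes)]
        typicals = [typical_parameters(params.theta, c) for c in covs]
        inds = sample_individuals(typicals, params.omega, rng)
        # descriptors: log-normal around NC-005-like medians; not model inputs
        desc = {
            k: med * np.exp(rng.normal(0.0, 0.15, arm.n))
            for k, med in _DESCRIPTOR_MEDIANS.items()
        }
        for i, (cov, ind) in enumerate(zip(covs, inds)):
            subjects.append(VirtualSubject(
                subject_id=f"{arm.name}-{i + 1:03d}",
                arm=arm.name,
                covariates=cov,
                parameters=ind,
                descriptors={k: float(v[i]) for k, v in desc.items()},
            ))
    return subjects


def apply_residual_error(
    conc: np.ndarray,
    residual: ResidualError,
    rng: np.random.Generator,
) -> np.ndarray:
    """Proportional + additive normal residual error, truncated at zero."""
    conc = np.asarray(conc, dtype=float)
    out = conc * (1.0 + rng.normal(0.0, residual.proportional_cv, conc.shape))
    if residual.additive_sd > 0:
        out = out + rng.normal(0.0, residual.additive_sd, conc.shape)
    return np.clip(out, 0.0, None)


def generate_observed(
    population: Sequence[VirtualSubject],
    design: ObservationDesign,
    regimens: Mapping[str, Regimen],
    arm_regimen: Mapping[str, str],
    residual: ResidualError,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Synthetic observed dataset (long format) for a virtual population.

    Troughs are sampled at ``day * 24`` h (pre-dose; follow-up visits past the
    end of dosing are simply post-treatment samples); the profile substudy
    takes the first ``n_profile_per_arm`` subjects of each arm.  Returns a
    tidy frame with columns subject_id, arm, race, sex, patient_type, time_h,
    conc, record_type — the dialect accepted by :class:`bdqsim.vpc.ObservedDataset`.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    frames = []
    for arm_name in dict.fromkeys(s.arm for s in population):
        members = [s for s in population if s.arm == arm_name]
        reg = regimens[arm_regimen[arm_name]]
        horizon = design.horizon_days * HOURS_PER_DAY
        trough_times = [d * HOURS_PER_DAY for d in design.trough_days]
        profile_times = [d * HOURS_PER_DAY + t for d in design.profile_days
                         for t in design.profile_times_h]
        for t in trough_times + profile_times:
            if t > horizon + 1e-9:
                raise ValueError(
                    f"observation at t={t:g} h lies beyond the simulation horizon "
                    f"({design.horizon_days:g} days)")
        horizon = max(horizon, reg.duration)
        all_times = np.array(sorted(set(trough_times + profile_times)))
        res = simulate_batch([s.parameters for s in members], reg,
                             conc_times=all_times, t_end=float(horizon))
        col = {round(float(t), 9): j for j, t in enumerate(all_times)}
        for i, subj in enumerate(members):
            rows_t = [(t, "trough") for t in trough_times]
            if i < design.n_profile_per_arm:
                rows_t += [(t, "profile") for t in profile_times]
            times = np.array([t for t, _ in rows_t])
            kinds = [k for _, k in rows_t]
            pred = np.array([res.conc[i, col[round(float(t), 9)]] for t in times])
            obs = apply_residual_error(np.clip(pred, 0.0, None), residual, rng)
            frames.append(pd.DataFrame({
                "subject_id": subj.subject_id,
                "arm": subj.arm,
                "race": subj.covariates.race.value,
                "sex": subj.covariates.sex.value,
                "patient_type": subj.covariates.patient_type.value,
                "time_h": times,
                "conc": obs,
                "record_type": kinds,
            }))
    return pd.concat(frames, ignore_index=True)
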