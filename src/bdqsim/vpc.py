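"""Visual predictive check (VPC) for model qualification.

The observed design (subjects, covariates, nominal sampling times) is
re-simulated many times (default 500 replicates) with fresh between-subject
random effects and residual error.  Within each time bin the observed
percentiles are compared to the 90 % confidence interval of the same
percentile computed across replicates.  Troughs use the 5th/50th/95th
percentiles; the small-n 24-h profile substudy uses the 10th/50th/90th
(an 80 % prediction interval).

Data generated by the model itself should fall inside the bands nearly
everywhere (calibration); data from a grossly mis-specified model should
fail directionally — both properties are exercised in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .model import CovariateSet, sample_individuals, typical_parameters
from .params import ModelParameters, ResidualError
from .population import apply_residual_error
from .regimen import Regimen
from .simulate import simulate_batch

__all__ = [
    "ObservedDataset",
    "VPCResult",
    "simulate_replicates",
    "percentile_bands",
    "vpc_report",
    "DEFAULT_LEVELS",
]

REQUIRED_COLUMNS = ("subject_id", "arm", "race", "sex", "patient_type",
                    "time_h", "conc", "record_type")

#: percentile levels per record type: troughs (many subjects) vs profiles (n=15)
DEFAULT_LEVELS: dict[str, tuple[float, float, float]] = {
    "trough": (5.0, 50.0, 95.0),
    "profile": (10.0, 50.0, 90.0),
}
ALLOWED_LEVELS = {(5.0, 50.0, 95.0), (10.0, 50.0, 90.0)}


class ObservedDataset:
    """Observed (or synthetic-observed) concentration records, long format."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"observed dataset is missing columns: {', '.join(missing)}")
        if len(df) == 0:
            raise ValueError("observed dataset is empty")
        if (df["conc"] < 0).any():
            raise ValueError("observed concentrations must be nonnegative")
        arms_per_subject = df.groupby("subject_id")["arm"].nunique()
        if (arms_per_subject > 1).any():
            bad = arms_per_subject[arms_per_subject > 1].index.tolist()
            raise ValueError(f"subjects assigned to multiple arms: {bad}")
        unknown = set(df["record_type"]) - set(DEFAULT_LEVELS)
        if unknown:
            raise ValueError(f"unknown record types: {sorted(unknown)}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def arms(self) -> list[str]:
        return list(dict.fromkeys(self.df["arm"]))


@dataclass
class VPCResult:
    """Percentile bands with observed values and inside/outside flags."""

    bands: pd.DataFrame  # arm, record_type, time_h, level, observed, ci_lo, ci_hi, inside
    n_rep: int

    @property
    def fraction_inside(self) -> float:
        return float(self.bands["inside"].mean())

    def __post_init__(self) -> None:
        if (self.bands["ci_lo"] > self.bands["ci_hi"]).any():
            raise ValueError("confidence bands must satisfy ci_lo <= ci_hi")


def simulate_replicates(
    obs: ObservedDataset,
    params: ModelParameters,
    regimens: Mapping[str, Regimen],
    arm_regimen: Mapping[str, str],
    n_rep: int = 500,
    seed: int | np.random.Generator = 0,
    *,
    include_residual: bool = True,
) -> np.ndarray:
    """Re-simulate the observed design ``n_rep`` times.

    Each replicate draws fresh between-subject random effects for every
    subject while keeping covariates, regimen and nominal sampling times
    fixed.  Returns an array of shape ``(n_rep, len(obs))`` aligned with the
    rows of ``obs.df``.  Deterministic given the seed.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    df = obs.df
    sims = np.empty((n_rep, len(df)))
    for arm in obs.arms:
        rows = df.index[df["arm"] == arm]
        sub = df.loc[rows]
        subjects = sub.drop_duplicates("subject_id")
        for col in ("race", "sex", "patient_type"):
            if subjects[col].isna().any():
                raise ValueError(f"missing covariate {col!r} in arm {arm!r}")
        covs = [CovariateSet(r.race, r.sex, r.patient_type) for r in subjects.itertuples()]
        typicals = [typical_parameters(params.theta, c) for c in covs]
        reg = regimens[arm_regimen[arm]]
        times = np.array(sorted(sub["time_h"].unique()))
        t_end = max(float(times.max()), reg.duration)
        col_of = {round(float(t), 9): j for j, t in enumerate(times)}
        sid_of = {sid: i for i, sid in enumerate(subjects["subject_id"])}
        row_subj = sub["subject_id"].map(sid_of).to_numpy()
        row_time = np.array([col_of[round(float(t), 9)] for t in sub["time_h"]])
        # one batch of n_subjects * n_rep individuals, replicate-major
        batch = sample_individuals(typicals * n_rep, params.omega, rng)
        res = simulate_batch(batch, reg, conc_times=times, t_end=t_end)
        conc = res.conc.reshape(n_rep, len(typicals), len(times))
        vals = conc[:, row_subj, row_time]
        if include_residual:
            vals = apply_residual_error(np.clip(vals, 0.0, None), params.residual, rng)
        sims[:, rows] = vals
    return sims


def percentile_bands(
    obs: ObservedDataset,
    sims: np.ndarray,
    levels: Mapping[str, tuple[float, float, float]] | None = None,
    ci_level: float = 90.0,
) -> pd.DataFrame:
    """Observed percentiles and simulated percentile CIs per time bin.

    Bins are (arm, record type, nominal time); within a bin the observed
    percentiles at the record type's levels are compared against the
    ``ci_level`` % interval of the same percentile across replicates.
    """
    levels = dict(DEFAULT_LEVELS if levels is None else levels)
    for kind, lv in levels.items():
        if tuple(float(x) for x in lv) not in ALLOWED_LEVELS:
            raise ValueError(f"unsupported percentile levels {lv} for {kind!r}")
    sims = np.asarray(sims)
    if sims.ndim != 2 or sims.shape[1] != len(obs):
        raise ValueError("sims must have shape (n_rep, n_observations)")
    alpha = (100.0 - ci_level) / 2.0
    records = []
    for (arm, kind, t), idx in obs.df.groupby(["arm", "record_type", "time_h"]).groups.items():
        idx = np.asarray(idx)
        if idx.size == 0:
            raise ValueError("empty time bin")
        lv = levels[kind]
        obs_pct = np.percentile(obs.df.loc[idx, "conc"], lv)
        sim_pct = np.percentile(sims[:, idx], lv, axis=1)  # (n_levels, n_rep)
        ci_lo = np.percentile(sim_pct, alpha, axis=1)
        ci_hi = np.percentile(sim_pct, 100.0 - alpha, axis=1)
        for k, level in enumerate(lv):
            inside = bool(ci_lo[k] <= obs_pct[k] <= ci_hi[k])
            position = "inside" if inside else ("below" if obs_pct[k] < ci_lo[k] else "above")
            records.append({
                "arm": arm, "record_type": kind, "time_h": float(t),
                "level": float(level), "observed": float(obs_pct[k]),
                "ci_lo": float(ci_lo[k]), "ci_hi": float(ci_hi[k]),
                "inside": inside, "position": position, "n_obs": int(idx.size),
            })
    return pd.DataFrame.from_records(records).sort_values(
        ["arm", "record_type", "time_h", "level"]).reset_index(drop=True)


def vpc_report(
    obs: ObservedDataset,
    sims: np.ndarray,
    levels: Mapping[str, tuple[float, float, float]] | None = None,
    ci_level: float = 90.0,
    csv_path=None,
    plot_path=None,
) -> VPCResult:
    """Full VPC: bands, inside/outside flags, optional CSV and band plot."""
    bands = percentile_bands(obs, sims, levels=levels, ci_level=ci_level)
    result = VPCResult(bands=bands, n_rep=int(np.asarray(sims).shape[0]))
    if csv_path is not None:
        bands.to_csv(csv_path, index=False)
    if plot_path is not None:
        plot_vpc(result, plot_path)
    return result


def plot_vpc(result: VPCResult, path) -> None:
    """Band plot: observed percentile points over shaded simulated CIs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bands = result.bands
    arms = list(dict.fromkeys(bands["arm"]))
    kinds = list(dict.fromkeys(bands["record_type"]))
    fig, axes = plt.subplots(len(kinds), len(arms),
                             figsize=(4.0 * len(arms), 3.0 * len(kinds)),
                             squeeze=False)
    for i, kind in enumerate(kinds):
        for j, arm in enumerate(arms):
            ax = axes[i][j]
            sel = bands[(bands["arm"] == arm) & (bands["record_type"] == kind)]
            for level, grp in sel.groupby("level"):
                grp = grp.sort_values("time_h")
                ax.fill_between(grp["time_h"], grp["ci_lo"], grp["ci_hi"], alpha=0.25)
                ax.plot(grp["time_h"], grp["observed"], "o-", ms=3,
                        label=f"P{level:g}")
            ax.set_title(f"{arm} ({kind})", fontsize=9)
            ax.set_xlabel("time (h)")
            ax.set_ylabel("conc (ug/mL)")
            if i == 0 and j == 0:
                ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
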