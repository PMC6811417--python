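"""Readers and writers for the pipeline's file formats.

Three dialects:

* NONMEM-style dataset CSV — columns ``ID, TIME, DV, EVID, MDV, AMT`` plus
  numeric covariate codes (``RACE`` 1=black/2=nonblack, ``SEX`` 1=male/
  2=female, ``TYPE`` 1=MDR-TB/2=DS-TB/3=healthy, ``RECTYPE`` 1=trough/
  2=profile) and a plain-text ``ARM`` column.  Dose records have ``EVID=1``
  and ``AMT`` set; observations have ``EVID=0, MDV=0`` and ``DV`` set.
* tidy observed CSV — the long format used internally
  (subject_id, arm, race, sex, patient_type, time_h, conc, record_type).
* profile CSV — long format (subject_id, time_h, conc_ug_ml).

Summary tables are written with a provenance header (tool version, seed,
parameter-file hash) and values rounded to 3 significant figures.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .regimen import Regimen
from .simulate import ConcentrationProfile
from .vpc import ObservedDataset

__all__ = [
    "read_tidy_observed",
    "read_nonmem_dataset",
    "write_nonmem_dataset",
    "write_profiles_csv",
    "write_summary_csv",
    "round_sig",
    "provenance_header",
]

RACE_CODES = {"black": 1, "nonblack": 2}
SEX_CODES = {"male": 1, "female": 2}
TYPE_CODES = {"MDR_TB": 1, "DS_TB": 2, "healthy": 3}
RECTYPE_CODES = {"trough": 1, "profile": 2}

_REV = {name: {v: k for k, v in codes.items()}
        for name, codes in (("RACE", RACE_CODES), ("SEX", SEX_CODES),
                            ("TYPE", TYPE_CODES), ("RECTYPE", RECTYPE_CODES))}


def round_sig(x: float, digits: int = 3) -> float:
    """Round to ``digits`` significant figures (tabulation convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))


def provenance_header(seed: int | None, param_hash: str | None, extra: Mapping | None = None) -> str:
    from . import __version__
    lines = [f"# bdqsim {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if param_hash is not None:
        lines.append(f"# parameter_file_sha256: {param_hash}")
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def read_tidy_observed(path: str | Path) -> ObservedDataset:
    """Read the tidy long-format observed-concentration dialect."""
    df = pd.read_csv(path, comment="#")
    return ObservedDataset(df)


def write_nonmem_dataset(
    obs: ObservedDataset | pd.DataFrame,
    regimens: Mapping[str, Regimen],
    arm_regimen: Mapping[str, str],
    path: str | Path,
    header: str | None = None,
) -> None:
    """Write observations plus per-subject dose records as a NONMEM-style CSV."""
    df = obs.df if isinstance(obs, ObservedDataset) else ObservedDataset(obs).df
    ids = {sid: i + 1 for i, sid in enumerate(dict.fromkeys(df["subject_id"]))}
    rows = []
    for sid, sub in df.groupby("subject_id", sort=False):
        first = sub.iloc[0]
        base = {
            "ID": ids[sid],
            "ARM": first["arm"],
            "RACE": RACE_CODES[str(first["race"])],
            "SEX": SEX_CODES[str(first["sex"])],
            "TYPE": TYPE_CODES[str(first["patient_type"])],
        }
        for ev in regimens[arm_regimen[first["arm"]]].events:
            rows.append({**base, "TIME": ev.time, "DV": ".", "EVID": 1, "MDV": 1,
                         "AMT": ev.amount, "RECTYPE": 0})
        for r in sub.itertuples():
            rows.append({**base, "TIME": r.time_h, "DV": r.conc, "EVID": 0, "MDV": 0,
                         "AMT": ".", "RECTYPE": RECTYPE_CODES[str(r.record_type)]})
    out = pd.DataFrame(rows, columns=["ID", "TIME", "DV", "EVID", "MDV", "AMT",
                                      "RACE", "SEX", "TYPE", "RECTYPE", "ARM"])
    out = out.sort_values(["ID", "TIME", "EVID"], kind="stable")
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        out.to_csv(fh, index=False)


def read_nonmem_dataset(path: str | Path) -> ObservedDataset:
    """Read a NONMEM-style dataset back into an :class:`ObservedDataset`.

    Only observation records (``EVID == 0``) are kept; dosing is reconstructed
    from the regimen configuration, not from the file.  Parse problems are
    reported with the offending column or row.
    """
    df = pd.read_csv(path, comment="#")
    for col in ("ID", "TIME", "DV", "EVID", "MDV"):
        if col not in df.columns:
            raise ValueError(f"NONMEM dataset {path} is missing required column {col!r}")
    obs = df[df["EVID"] == 0].copy()
    if len(obs) == 0:
        raise ValueError(f"NONMEM dataset {path} contains no observation records")
    try:
        conc = pd.to_numeric(obs["DV"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric DV among observation rows of {path}: {exc}") from exc
    out = pd.DataFrame({
        "subject_id": obs["ID"].astype(int).astype(str),
        "arm": obs["ARM"] if "ARM" in obs else "arm1",
        "time_h": pd.to_numeric(obs["TIME"]),
        "conc": conc,
    })
    for col, name in (("RACE", "race"), ("SEX", "sex"), ("TYPE", "patient_type"),
                      ("RECTYPE", "record_type")):
        if col not in obs.columns:
            raise ValueError(f"NONMEM dataset {path} is missing covariate column {col!r}")
        codes = pd.to_numeric(obs[col]).astype(int)
        bad = set(codes) - set(_REV[col])
        if bad:
            raise ValueError(f"column {col!r} of {path} has unknown codes {sorted(bad)}")
        out[name] = codes.map(_REV[col])
    return ObservedDataset(out[["subject_id", "arm", "race", "sex", "patient_type",
                                "time_h", "conc", "record_type"]])


def write_profiles_csv(profiles: Iterable[ConcentrationProfile], path: str | Path,
                       header: str | None = None) -> None:
    """Long-format profile export: subject_id, time_h, conc_ug_ml."""
    frames = []
    for i, p in enumerate(profiles):
        frames.append(pd.DataFrame({
            "subject_id": p.subject_id if p.subject_id is not None else str(i + 1),
            "time_h": p.times,
            "conc_ug_ml": p.concentrations,
        }))
    if not frames:
        raise ValueError("no profiles to write")
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        pd.concat(frames, ignore_index=True).to_csv(fh, index=False)


def write_summary_csv(summary: pd.DataFrame, path: str | Path,
                      header: str | None = None, sig: int = 3) -> None:
    """Exposure-summary table with all numbers at 3 significant figures."""
    out = summary.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: round_sig(v, sig) if pd.notna(v) else v)
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        out.to_csv(fh, index=False)
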