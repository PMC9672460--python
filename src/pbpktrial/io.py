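"""Shared file I/O: tidy concentration tables, result tables, run manifests.

All tabular interchange is header-carrying delimited text (CSV).  Times are
hours, concentrations ng/ml, doses mg, volumes L.  Below-LLOQ cells are
written as the token ``BLQ``.  Writes are atomic (temp file in the target
directory, then rename).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .nca import ConcentrationTimeProfile, NCAResult
from .params import DoseRegimen

BLQ_TOKEN = "BLQ"

CONC_TABLE_COLUMNS = [
    "subject_id",
    "cohort_id",
    "dose_mg",
    "occasion",
    "time_h",
    "conc_ng_ml",
    "lloq_ng_ml",
    "infusion_h",
    "tau_h",
    "n_doses",
    "active",
]


class SchemaError(ValueError):
    pass


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write ``text`` to ``path`` via a temp file + rename in the same dir."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_concentration_table(profiles: list[ConcentrationTimeProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        for t, c in zip(p.times, p.concentrations):
            rows.append(
                {
                    "subject_id": p.subject_id,
                    "cohort_id": p.cohort_id,
                    "dose_mg": p.dose_mg,
                    "occasion": p.occasion,
                    "time_h": t,
                    "conc_ng_ml": BLQ_TOKEN if c is None else repr(float(c)),
                    "lloq_ng_ml": p.lloq,
                    "infusion_h": p.regimen.infusion_duration,
                    "tau_h": "" if p.regimen.dosing_interval_tau is None else p.regimen.dosing_interval_tau,
                    "n_doses": p.regimen.n_doses,
                    "active": int(p.active),
                }
            )
    df = pd.DataFrame(rows, columns=CONC_TABLE_COLUMNS)
    atomic_write_text(path, df.to_csv(index=False))


def read_concentration_table(path: str | Path) -> list[ConcentrationTimeProfile]:
    """Parse a tidy concentration table into validated profiles.

    Raises :class:`SchemaError` naming the offending column on header
    mismatch; profile invariant violations (e.g. non-monotone times) raise
    with the subject id in the message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"conc_ng_ml": str})
    required = ["subject_id", "cohort_id", "dose_mg", "time_h", "conc_ng_ml", "lloq_ng_ml"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    if "occasion" not in df.columns:
        df["occasion"] = "single"
    if "infusion_h" not in df.columns:
        df["infusion_h"] = 1.0
    if "tau_h" not in df.columns:
        df["tau_h"] = float("nan")
    if "n_doses" not in df.columns:
        df["n_doses"] = 1
    if "active" not in df.columns:
        df["active"] = 1

    profiles = []
    keys = ["subject_id", "cohort_id", "occasion"]
    for (sid, cid, occ), grp in df.groupby(keys, sort=False):
        grp = grp.reset_index(drop=True)
        conc: list[Optional[float]] = []
        for raw in grp["conc_ng_ml"]:
            token = str(raw).strip()
            if token.upper() in (BLQ_TOKEN, "BLOQ", "<LLOQ", "NA", "NAN", ""):
                conc.append(None)
            else:
                conc.append(float(token))
        tau = grp["tau_h"].iloc[0]
        tau = None if pd.isna(tau) or tau == "" else float(tau)
        regimen = DoseRegimen(
            dose_amount=float(grp["dose_mg"].iloc[0]),
            infusion_duration=float(grp["infusion_h"].iloc[0]),
            dosing_interval_tau=tau,
            n_doses=int(grp["n_doses"].iloc[0]),
        )
        profiles.append(
            ConcentrationTimeProfile(
                subject_id=str(sid),
                cohort_id=str(cid),
                dose_mg=float(grp["dose_mg"].iloc[0]),
                regimen=regimen,
                occasion=str(occ),
                times=[float(t) for t in grp["time_h"]],
                concentrations=conc,
                lloq=float(grp["lloq_ng_ml"].iloc[0]),
                active=bool(int(grp["active"].iloc[0])),
            )
        )
    return profiles


def nca_results_to_frame(results: list[NCAResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])


def write_nca_results(results: list[NCAResult], path: str | Path) -> None:
    atomic_write_text(path, nca_results_to_frame(results).to_csv(index=False))


def write_simulation_result(sim, path: str | Path) -> None:
    """Simulation trajectories as delimited text: time, plasma concentration,
    per-tissue sub-compartment amounts, cumulative eliminated amount."""
    data = {"time_h": sim.times, "plasma_ng_per_ml": sim.plasma_concentration}
    for j, name in enumerate(sim.tissue_names):
        data[f"{name}_vascular_ng"] = sim.vascular_amounts[:, j]
        data[f"{name}_extravascular_ng"] = sim.extravascular_amounts[:, j]
    data["venous_ng"] = sim.venous_amount
    data["arterial_ng"] = sim.arterial_amount
    data["eliminated_ng"] = sim.eliminated_amount
    atomic_write_text(path, pd.DataFrame(data).to_csv(index=False))


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


class RunManifest(BaseModel):
    """Reproducibility record accompanying every pipeline output."""

    tool_version: str = __version__
    seeds: dict[str, int] = Field(default_factory=dict)
    input_digests: dict[str, str] = Field(default_factory=dict)
    config_snapshot: dict = Field(default_factory=dict)
    outputs: list[str] = Field(default_factory=list)
    timestamp: str = Field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def write(self, path: str | Path) -> None:
        atomic_write_text(path, self.model_dump_json(indent=2))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls.model_validate(json.loads(Path(path).read_text()))
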