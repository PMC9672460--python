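"""End-to-end pipeline: synthetic trial -> NCA -> dose proportionality.

The pipeline is configured with a small validated structure, writes every
stage output as delimited text under one output directory, and accompanies
them with a :class:`pbpktrial.io.RunManifest`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field

from . import io as pio
from .doseprop import DoseExposureRecord, fit_power_model
from .nca import LambdaZError, nca_multiple, nca_single
from .params import PBPKParameterSet, load_default_parameters
from .population import default_variability
from .synth import default_design, generate_trial

KNOWN_STAGES = ("synth", "nca", "doseprop")


class DosePropConfig(BaseModel):
    theta_low: float = 0.8
    theta_high: float = 1.25
    ci_level: float = 0.90
    min_dose: float = 20.0  # excludes the sentinel low-dose cohort
    parameters: list[str] = Field(default_factory=lambda: ["cmax", "auc_last"])


class SynthConfig(BaseModel):
    residual_cv: float = 0.10


class PipelineConfig(BaseModel):
    seed: int
    out_dir: str
    stages: list[str] = Field(default_factory=lambda: list(KNOWN_STAGES))
    params_file: Optional[str] = None
    input_table: Optional[str] = None  # replaces the synth stage
    synth: SynthConfig = Field(default_factory=SynthConfig)
    doseprop: DosePropConfig = Field(default_factory=DosePropConfig)

    def model_post_init(self, _ctx) -> None:
        for s in self.stages:
            if s not in KNOWN_STAGES:
                raise ValueError(f"unknown stage {s!r}; known: {KNOWN_STAGES}")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def verdict_block(results) -> str:
    lines = ["Dose-proportionality assessment (power model)"]
    for r in results:
        lines += [
            f"  parameter      : {r.parameter_name}",
            f"  beta (slope)   : {r.beta:.4f}",
            f"  {int(r.ci_level*100)}% CI         : {r.beta_ci90[0]:.4f} - {r.beta_ci90[1]:.4f}",
            f"  acceptance     : {r.acceptance_range[0]:.4f} - {r.acceptance_range[1]:.4f}"
            f" (R = {r.dose_ratio_R:g})",
            f"  verdict        : {r.verdict} (deviation: {r.deviation_direction})",
            "",
        ]
    return "\n".join(lines)


def pipeline_run(config: PipelineConfig | dict) -> tuple[dict[str, Path], pio.RunManifest]:
    """Run the configured stages in dependency order.

    Returns the mapping of stage output names to written paths plus the run
    manifest (also written to ``manifest.json``).  Any stage failure aborts
    downstream stages and is re-raised as :class:`StageError`.
    """
    if isinstance(config, dict):
        config = PipelineConfig.model_validate(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    manifest = pio.RunManifest(
        seeds={"master": config.seed},
        config_snapshot=config.model_dump(),
    )

    if config.params_file:
        params = PBPKParameterSet.from_json(Path(config.params_file).read_text())
        manifest.input_digests[config.params_file] = pio.sha256_of(config.params_file)
    else:
        params = load_default_parameters()

    profiles = None
    if config.input_table:
        try:
            profiles = pio.read_concentration_table(config.input_table)
        except Exception as exc:
            raise StageError("read_input", exc) from exc
        manifest.input_digests[config.input_table] = pio.sha256_of(config.input_table)
    elif "synth" in config.stages:
        try:
            profiles = generate_trial(
                default_design(),
                params,
                default_variability(),
                residual_cv=config.synth.residual_cv,
                seed=config.seed,
                rtol=1e-6,
            )
            path = out_dir / "concentrations.csv"
            pio.write_concentration_table(profiles, path)
            outputs["concentrations"] = path
        except StageError:
            raise
        except Exception as exc:
            raise StageError("synth", exc) from exc

    nca_results = None
    if "nca" in config.stages:
        if profiles is None:
            raise StageError("nca", ValueError("no input profiles (run synth or set input_table)"))
        try:
            nca_results = []
            for p in profiles:
                if not p.active:
                    continue
                try:
                    res = nca_multiple(p) if p.occasion == "day6" else nca_single(p)
                except (LambdaZError, ValueError):
                    continue
                nca_results.append(res)
            path = out_dir / "nca.csv"
            pio.write_nca_results(nca_results, path)
            outputs["nca"] = path
        except Exception as exc:
            raise StageError("nca", exc) from exc

    if "doseprop" in config.stages:
        if nca_results is None:
            raise StageError("doseprop", ValueError("doseprop requires the nca stage"))
        try:
            cfg = config.doseprop
            dp_results = []
            for pname in cfg.parameters:
                records = [
                    DoseExposureRecord(
                        subject_id=r.subject_id,
                        dose=r.dose_mg,
                        parameter_name=pname,
                        value=getattr(r, pname),
                    )
                    for r in nca_results
                    if r.occasion == "single"
                    and r.dose_mg >= cfg.min_dose
                    and getattr(r, pname) is not None
                ]
                dp_results.append(
                    fit_power_model(
                        records,
                        ci_level=cfg.ci_level,
                        theta_low=cfg.theta_low,
                        theta_high=cfg.theta_high,
                    )
                )
            path = out_dir / "doseprop.csv"
            pio.atomic_write_text(
                path,
                pd.DataFrame([dataclasses.asdict(r) for r in dp_results]).to_csv(index=False),
            )
            outputs["doseprop"] = path
            vpath = out_dir / "doseprop_verdict.txt"
            pio.atomic_write_text(vpath, verdict_block(dp_results))
            outputs["doseprop_verdict"] = vpath
        except StageError:
            raise
        except Exception as exc:
            raise StageError("doseprop", exc) from exc

    manifest.outputs = [str(p) for p in outputs.values()]
    mpath = out_dir / "manifest.json"
    manifest.write(mpath)
    outputs["manifest"] = mpath
    return outputs, manifest
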