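"""Domain parameter types for the whole-body PBPK model.

All quantities use a fixed unit convention: time in hours, volumes in
litres, flows in L/h, doses in mg, concentrations in ng/ml, amounts in ng.
Transporter ``vmax`` is in ng/h and ``km`` in ng/ml.
"""

from __future__ import annotations

import json
import math
from importlib import resources
from typing import Optional

from pydantic import BaseModel, Field, model_validator

#: The fourteen tissue compartments of the whole-body model.  Lung is in
#: series with the blood pools (it receives total cardiac output); all other
#: tissues are perfused in parallel from arterial blood.
TISSUE_NAMES = (
    "lung",
    "heart",
    "brain",
    "adipose",
    "muscle",
    "skin",
    "bone",
    "gut",
    "spleen",
    "liver",
    "kidney",
    "reproductive",
    "rest_of_body",
    "red_marrow",
)

FLOW_BALANCE_RTOL = 1e-6


class CompoundProperties(BaseModel):
    """Physicochemical and binding properties of the simulated compound."""

    name: str
    molecular_weight: float = Field(gt=0, description="g/mol")
    fraction_unbound_plasma: float = Field(gt=0, le=1)
    blood_to_plasma_ratio: float = Field(gt=0)
    acid_pKa: Optional[float] = None
    logP: Optional[float] = None

    @property
    def fraction_unbound_blood(self) -> float:
        """fu_b = fu_p / blood:plasma ratio; drives permeability/transport."""
        return self.fraction_unbound_plasma / self.blood_to_plasma_ratio


class TissueSpec(BaseModel):
    """One tissue compartment: volume, perfusion, partitioning, permeability."""

    tissue_name: str
    volume: float = Field(gt=0, description="L")
    blood_flow: float = Field(ge=0, description="L/h")
    kp: float = Field(gt=0, description="tissue:plasma partition coefficient")
    pstc: float = Field(ge=0, description="permeability-surface area product, L/h")
    vascular_fraction: float = Field(default=0.05, gt=0, lt=1)

    @model_validator(mode="after")
    def _known_tissue(self) -> "TissueSpec":
        if self.tissue_name not in TISSUE_NAMES:
            raise ValueError(
                f"unknown tissue {self.tissue_name!r}; expected one of {TISSUE_NAMES}"
            )
        return self

    @property
    def vascular_volume(self) -> float:
        return self.volume * self.vascular_fraction

    @property
    def extravascular_volume(self) -> float:
        return self.volume * (1.0 - self.vascular_fraction)


class TransporterKinetics(BaseModel):
    """Michaelis-Menten kinetics of a hepatic transporter."""

    transporter_name: str
    vmax: float = Field(ge=0, description="ng/h")
    km: float = Field(gt=0, description="ng/ml")
    direction: str

    @model_validator(mode="after")
    def _direction_matches(self) -> "TransporterKinetics":
        if self.transporter_name not in ("OATP1B1", "P-gp"):
            raise ValueError(f"unknown transporter {self.transporter_name!r}")
        if self.direction not in ("uptake", "efflux"):
            raise ValueError(f"direction must be uptake or efflux, got {self.direction!r}")
        expected = {"OATP1B1": "uptake", "P-gp": "efflux"}[self.transporter_name]
        if self.direction != expected:
            raise ValueError(
                f"{self.transporter_name} must have direction {expected!r}"
            )
        return self


class DoseRegimen(BaseModel):
    """Zero-order intravenous infusion schedule."""

    dose_amount: float = Field(gt=0, description="mg")
    infusion_duration: float = Field(gt=0, description="h")
    dosing_interval_tau: Optional[float] = Field(default=None, gt=0, description="h")
    n_doses: int = Field(default=1, ge=1)

    @model_validator(mode="after")
    def _tau_consistent(self) -> "DoseRegimen":
        if self.n_doses > 1:
            if self.dosing_interval_tau is None:
                raise ValueError("dosing_interval_tau required when n_doses > 1")
            if self.dosing_interval_tau < self.infusion_duration:
                raise ValueError("dosing_interval_tau must be >= infusion_duration")
        return self

    def dose_start_times(self) -> list[float]:
        if self.n_doses == 1:
            return [0.0]
        tau = self.dosing_interval_tau
        return [k * tau for k in range(self.n_doses)]

    @property
    def infusion_rate_ng_per_h(self) -> float:
        """Zero-order input rate during each infusion window (ng/h)."""
        return self.dose_amount * 1e6 / self.infusion_duration

    @property
    def total_duration(self) -> float:
        return self.dose_start_times()[-1] + self.infusion_duration


class PBPKParameterSet(BaseModel):
    """Complete parameterization of the whole-body simulator."""

    compound: CompoundProperties
    tissues: list[TissueSpec]
    transporters: list[TransporterKinetics] = Field(default_factory=list)
    cardiac_output: float = Field(gt=0, description="L/h")
    venous_volume: float = Field(gt=0, description="L")
    arterial_volume: float = Field(gt=0, description="L")
    systemic_linear_clearance: float = Field(default=0.0, ge=0, description="L/h")

    @model_validator(mode="after")
    def _topology(self) -> "PBPKParameterSet":
        names = [t.tissue_name for t in self.tissues]
        if len(set(names)) != len(names):
            raise ValueError("duplicate tissue names")
        if "liver" not in names:
            raise ValueError("parameter set must contain a liver tissue")
        if "lung" not in names:
            raise ValueError("parameter set must contain a lung tissue")
        lung = self.tissue("lung")
        if not math.isclose(
            lung.blood_flow, self.cardiac_output, rel_tol=FLOW_BALANCE_RTOL
        ):
            raise ValueError(
                "lung blood flow must equal cardiac output "
                f"({lung.blood_flow} vs {self.cardiac_output})"
            )
        parallel = sum(
            t.blood_flow for t in self.tissues if t.tissue_name != "lung"
        )
        if not math.isclose(parallel, self.cardiac_output, rel_tol=FLOW_BALANCE_RTOL):
            raise ValueError(
                "sum of non-lung tissue flows must equal cardiac output "
                f"({parallel} vs {self.cardiac_output}); venous return unbalanced"
            )
        uptakes = [t for t in self.transporters if t.direction == "uptake"]
        effluxes = [t for t in self.transporters if t.direction == "efflux"]
        if len(uptakes) > 1 or len(effluxes) > 1:
            raise ValueError("at most one uptake and one efflux transporter supported")
        return self

    def tissue(self, name: str) -> TissueSpec:
        for t in self.tissues:
            if t.tissue_name == name:
                return t
        raise KeyError(name)

    def transporter(self, direction: str) -> Optional[TransporterKinetics]:
        for t in self.transporters:
            if t.direction == direction:
                return t
        return None

    @property
    def total_volume(self) -> float:
        return (
            self.venous_volume
            + self.arterial_volume
            + sum(t.volume for t in self.tissues)
        )

    def to_json(self, **kwargs) -> str:
        return self.model_dump_json(indent=2, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "PBPKParameterSet":
        return cls.model_validate(json.loads(text))


class VariabilitySpec(BaseModel):
    """Lognormal inter-individual variability on one parameter path.

    ``parameter_path`` addresses a positive scalar of the parameter set with
    a dotted grammar: ``cardiac_output``, ``systemic_linear_clearance``,
    ``tissues.<name>.<field>``, ``transporters.<direction>.<field>``.  The
    tissue/transporter segment accepts ``*`` to hit every element.  Scaling
    ``cardiac_output`` scales every tissue blood flow by the same factor so
    the venous-return balance invariant is preserved.
    """

    parameter_path: str
    distribution: str = "lognormal"
    cv: float = Field(ge=0)

    @model_validator(mode="after")
    def _dist(self) -> "VariabilitySpec":
        if self.distribution != "lognormal":
            raise ValueError("only lognormal variability is supported")
        return self


def load_default_parameters() -> PBPKParameterSet:
    """Packaged parameter set for a 70-kg adult given the default compound.

    Tissue volumes and perfusion fractions follow standard reference-human
    compilations (Brown et al. 1997; ICRP 89).  Partition coefficients,
    permeability products and transporter kinetics are repository
    calibrations against published single-ascending-dose exposure summaries;
    they are not vendor or literature values.
    """
    text = (
        resources.files("pbpktrial.data")
        .joinpath("default_params.json")
        .read_text()
    )
    return PBPKParameterSet.from_json(text)
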