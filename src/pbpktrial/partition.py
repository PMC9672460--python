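"""Tissue:plasma partition coefficients.

Two routes are provided: a tissue-composition calculation for monoprotic
acids (extracellular/intracellular water, neutral lipid, neutral
phospholipid and an albumin-type binding term, with Henderson-Hasselbalch
ionization correction), and a direct exposure-ratio estimate from measured
tissue distribution data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .params import CompoundProperties

# Plasma neutral-lipid and neutral-phospholipid volume fractions used in the
# protein-binding correction term (standard composition-method constants).
PLASMA_F_NEUTRAL_LIPID = 0.0023
PLASMA_F_NEUTRAL_PHOSPHOLIPID = 0.0013
PLASMA_PH = 7.4


class TissueComposition(BaseModel):
    """Fractional composition and binding capacity of one tissue."""

    tissue_name: str
    f_extracellular_water: float = Field(ge=0, le=1)
    f_intracellular_water: float = Field(ge=0, le=1)
    f_neutral_lipid: float = Field(ge=0, le=1)
    f_neutral_phospholipid: float = Field(ge=0, le=1)
    albumin_ratio_or_acidic_phospholipid: float = Field(ge=0)
    intracellular_pH: float = Field(ge=6, le=8)

    @model_validator(mode="after")
    def _fractions_sum(self) -> "TissueComposition":
        total = (
            self.f_extracellular_water
            + self.f_intracellular_water
            + self.f_neutral_lipid
            + self.f_neutral_phospholipid
        )
        if total > 1.0 + 1e-9:
            raise ValueError(f"water+lipid fractions sum to {total:.3f} > 1")
        return self


class TissueDistributionRecord(BaseModel):
    """Matched tissue and plasma exposures (AUC or matched-time levels)."""

    tissue_name: str
    tissue_exposure: float = Field(gt=0)
    plasma_exposure: float = Field(gt=0)
    metric: str = "auc_ratio"  # or "single_timepoint_ratio"


@dataclass
class KpEstimate:
    tissue_name: str
    kp: float
    method: str


class MissingPKaError(ValueError):
    """Raised when the composition method is asked for a compound without pKa."""


def kp_rodgers_rowland_acid(
    compound: CompoundProperties,
    comp: TissueComposition,
    plasma_pH: float = PLASMA_PH,
) -> float:
    """Tissue:plasma Kp for a monoprotic acid from tissue composition.

    Computes the unbound partition coefficient as the sum of an
    extracellular-water term, an ionization-corrected intracellular-water
    term, a neutral-lipid/phospholipid term (neutral species only), and a
    protein-binding term scaled by the tissue:plasma binder ratio, then
    multiplies by plasma unbound fraction to return the total Kp.
    """
    if compound.acid_pKa is None:
        raise MissingPKaError(
            "compound has no acid_pKa; use kp_from_distribution or supply kp directly"
        )
    pka = compound.acid_pKa
    fu = compound.fraction_unbound_plasma
    p = 10.0 ** compound.logP if compound.logP is not None else 0.0

    ion_plasma = 1.0 + 10.0 ** (plasma_pH - pka)
    ion_cell = 1.0 + 10.0 ** (comp.intracellular_pH - pka)

    water_term = comp.f_extracellular_water + comp.f_intracellular_water * (
        ion_cell / ion_plasma
    )
    lipid_term = (
        p * comp.f_neutral_lipid + (0.3 * p + 0.7) * comp.f_neutral_phospholipid
    ) / ion_plasma
    plasma_lipid_term = (
        p * PLASMA_F_NEUTRAL_LIPID + (0.3 * p + 0.7) * PLASMA_F_NEUTRAL_PHOSPHOLIPID
    ) / ion_plasma
    # Binding capacity inferred from fu; floored at zero so Kp stays positive
    # for weakly bound compounds where the plasma-lipid correction dominates.
    binding_term = max(1.0 / fu - 1.0 - plasma_lipid_term, 0.0) * (
        comp.albumin_ratio_or_acidic_phospholipid
    )
    kpu = water_term + lipid_term + binding_term
    return kpu * fu


def kp_from_distribution(rec: TissueDistributionRecord) -> float:
    """Kp as the ratio of tissue exposure to plasma exposure."""
    if rec.plasma_exposure <= 0:
        raise ValueError("plasma exposure must be positive")
    return rec.tissue_exposure / rec.plasma_exposure


def load_tissue_compositions() -> dict[str, TissueComposition]:
    """Packaged tissue-composition constants (surrogate reference values).

    Values approximate published human/rat composition compilations for the
    composition-based Kp method; see the data file header for provenance.
    """
    path = resources.files("pbpktrial.data").joinpath("tissue_composition.csv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, comment="#")
    out = {}
    for row in df.to_dict(orient="records"):
        comp = TissueComposition(
            tissue_name=row["tissue_name"],
            f_extracellular_water=row["f_extracellular_water"],
            f_intracellular_water=row["f_intracellular_water"],
            f_neutral_lipid=row["f_neutral_lipid"],
            f_neutral_phospholipid=row["f_neutral_phospholipid"],
            albumin_ratio_or_acidic_phospholipid=row["albumin_ratio"],
            intracellular_pH=row["intracellular_pH"],
        )
        out[comp.tissue_name] = comp
    return out


def estimate_kp_table(
    compound: CompoundProperties,
    distribution_records: Optional[list[TissueDistributionRecord]] = None,
    plasma_pH: float = PLASMA_PH,
) -> list[KpEstimate]:
    """Kp for all packaged tissues: measured ratios where available,
    composition-based values elsewhere."""
    measured = {r.tissue_name: r for r in (distribution_records or [])}
    estimates = []
    for name, comp in load_tissue_compositions().items():
        if name in measured:
            rec = measured[name]
            estimates.append(KpEstimate(name, kp_from_distribution(rec), rec.metric))
        else:
            estimates.append(
                KpEstimate(name, kp_rodgers_rowland_acid(compound, comp, plasma_pH), "composition")
            )
    return estimates
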