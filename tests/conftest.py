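import numpy as np
import pytest

from pbpktrial.params import (
    CompoundProperties,
    DoseRegimen,
    PBPKParameterSet,
    TissueSpec,
    TransporterKinetics,
    load_default_parameters,
)

VOLUMES = {
    "lung": 0.5, "heart": 0.33, "brain": 1.45, "adipose": 14.0,
    "muscle": 29.0, "skin": 3.4, "bone": 10.0, "gut": 1.65,
    "spleen": 0.19, "liver": 1.8, "kidney": 0.31, "reproductive": 0.05,
    "rest_of_body": 3.0, "red_marrow": 1.4,
}
FLOW_FRACTIONS = {
    "brain": 0.12, "heart": 0.04, "kidney": 0.17, "muscle": 0.13,
    "adipose": 0.05, "skin": 0.05, "gut": 0.10, "spleen": 0.02,
    "liver": 0.25, "bone": 0.04, "red_marrow": 0.02,
    "reproductive": 0.0025, "rest_of_body": 0.0075,
}


def build_params(
    kp=1.0,
    pstc=5.0,
    fu=1.0,
    bp=1.0,
    cl_sys=0.0,
    vmax_uptake=0.0,
    vmax_efflux=None,
    km=1000.0,
    cardiac_output=390.0,
    venous_volume=3.5,
    arterial_volume=1.8,
    pKa=3.0,
    logP=1.0,
):
    """Parameter-set factory: scalar kp/pstc applied to all tissues, or
    dicts keyed by tissue name for per-tissue overrides."""
    kp_map = kp if isinstance(kp, dict) else {n: kp for n in VOLUMES}
    ps_map = pstc if isinstance(pstc, dict) else {n: pstc for n in VOLUMES}
    tissues = [
        TissueSpec(
            tissue_name=n,
            volume=VOLUMES[n],
            blood_flow=cardiac_output if n == "lung" else FLOW_FRACTIONS[n] * cardiac_output,
            kp=kp_map[n],
            pstc=ps_map[n],
        )
        for n in VOLUMES
    ]
    transporters = []
    if vmax_uptake > 0:
        if vmax_efflux is None:
            vmax_efflux = 2.0 * vmax_uptake
        transporters = [
            TransporterKinetics(
                transporter_name="OATP1B1", vmax=vmax_uptake, km=km, direction="uptake"
            ),
            TransporterKinetics(
                transporter_name="P-gp", vmax=vmax_efflux, km=km, direction="efflux"
            ),
        ]
    return PBPKParameterSet(
        compound=CompoundProperties(
            name="test-acid",
            molecular_weight=494.45,
            fraction_unbound_plasma=fu,
            blood_to_plasma_ratio=bp,
            acid_pKa=pKa,
            logP=logP,
        ),
        tissues=tissues,
        transporters=transporters,
        cardiac_output=cardiac_output,
        venous_volume=venous_volume,
        arterial_volume=arterial_volume,
        systemic_linear_clearance=cl_sys,
    )


@pytest.fixture(scope="session")
def default_params():
    return load_default_parameters()


@pytest.fixture(scope="session")
def onecomp_params():
    """Near well-stirred linear configuration: huge permeability, kp=1,
    no binding, linear venous clearance 30 L/h."""
    return build_params(kp=1.0, pstc=1e5, fu=1.0, bp=1.0, cl_sys=30.0)


@pytest.fixture
def infusion_80mg():
    return DoseRegimen(dose_amount=80.0, infusion_duration=1.0)


def one_compartment_infusion_conc(t, dose_mg, infusion_h, cl, v):
    """Closed-form plasma concentration (ng/ml) for a one-compartment model
    under a zero-order infusion; independent oracle for the simulator."""
    t = np.asarray(t, dtype=float)
    r0 = dose_mg * 1e6 / infusion_h  # ng/h
    k = cl / v
    css = r0 / cl  # ng/L
    c = np.where(
        t <= infusion_h,
        css * (1.0 - np.exp(-k * t)),
        css * (1.0 - np.exp(-k * infusion_h)) * np.exp(-k * (t - infusion_h)),
    )
    return c / 1e3  # ng/ml
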