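import math

import numpy as np
import pytest

from pbpktrial.nca import (
    ConcentrationTimeProfile,
    LambdaZError,
    compute_auc,
    estimate_lambda_z,
    nca_multiple,
    nca_single,
)
from pbpktrial.params import DoseRegimen
from pbpktrial.synth import load_single_dose_summary

from conftest import one_compartment_infusion_conc

SINGLE = DoseRegimen(dose_amount=80.0, infusion_duration=1.0)
Q12H = DoseRegimen(
    dose_amount=60.0, infusion_duration=1.0, dosing_interval_tau=12.0, n_doses=11
)


def make_profile(times, concs, dose=80.0, regimen=SINGLE, occasion="single", lloq=1.0):
    return ConcentrationTimeProfile(
        subject_id="s1",
        cohort_id="c1",
        dose_mg=dose,
        regimen=regimen,
        occasion=occasion,
        times=list(times),
        concentrations=list(concs),
        lloq=lloq,
    )


def onecomp_profile(cl=30.0, v=100.0, dose=80.0, infusion_h=1.0, times=None):
    """Analytic one-compartment infusion profile — independent of the
    PBPK simulator."""
    if times is None:
        # the default single-dose sampling schedule
        times = [0.25, 0.5, 0.75, 1.0, 1.0833, 1.1667, 1.5, 1.75,
                 2.0, 2.5, 3.0, 4.0, 5.0, 7.0, 9.0, 11.0, 13.0]
    conc = one_compartment_infusion_conc(np.asarray(times), dose, infusion_h, cl, v)
    return make_profile(times, [float(c) for c in conc], dose=dose)


class TestComputeAUC:
    def test_constant_profile_linear(self):
        prof = make_profile([0.0, 1.0, 2.0], [100.0, 100.0, 100.0])
        assert compute_auc(prof, 2.0, "linear") == pytest.approx(200.0)

    def test_dense_monoexponential_matches_integral(self):
        t = np.arange(0.0, 10.0 + 1e-9, 0.01)
        c = 1000.0 * np.exp(-0.5 * t)
        prof = make_profile(t, c)
        analytic = (1000.0 / 0.5) * (1.0 - math.exp(-5.0))
        assert compute_auc(prof, 10.0, "linear") == pytest.approx(analytic, rel=5e-3)
        assert compute_auc(prof, 10.0, "linear_up_log_down") == pytest.approx(
            analytic, rel=5e-3
        )

    def test_log_trapezoid_closed_form(self):
        prof = make_profile([1.0, 2.0], [100.0, 50.0])
        expected = 100.0 * (1.0 - 0.5) / math.log(2.0)
        # interval AUC from 1 to 2 h; profile starts at its first sample
        assert compute_auc(prof, 2.0, "linear_up_log_down") == pytest.approx(
            expected, rel=1e-12
        )

    def test_additive_over_adjacent_intervals(self):
        t = [0.0, 0.5, 1.0, 2.0, 4.0, 8.0]
        c = [0.0, 80.0, 100.0, 60.0, 25.0, 5.0]
        prof = make_profile(t, c)
        full = compute_auc(prof, 8.0)
        split = compute_auc(prof, 2.0) + (full - compute_auc(prof, 2.0))
        assert split == pytest.approx(full, rel=1e-12)
        # cut mid-interval: pieces must re-assemble
        a = compute_auc(prof, 3.0)
        assert compute_auc(prof, 2.0) < a < full

    def test_monotone_in_t_end(self):
        t = [0.0, 1.0, 2.0, 4.0, 8.0, 12.0]
        c = [0.0, 100.0, 60.0, 25.0, 5.0, 1.5]
        prof = make_profile(t, c)
        values = [compute_auc(prof, te) for te in (2.0, 4.0, 8.0, 12.0, 20.0)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_leading_blq_counts_as_zero(self):
        prof = make_profile([0.0, 0.5, 1.0], [None, 50.0, 100.0])
        # 0-0.5 h triangle from zero + 0.5-1.0 h trapezoid
        assert compute_auc(prof, 1.0, "linear") == pytest.approx(
            0.5 * 50.0 * 0.5 + 0.5 * (50 + 100) * 0.5
        )

    def test_t_end_too_early(self):
        prof = make_profile([0.0, 1.0, 2.0], [10.0, 20.0, 5.0])
        with pytest.raises(ValueError):
            compute_auc(prof, 0.5)


class TestLambdaZ:
    def test_exact_monoexponential(self):
        lam = 0.3466
        t = [4.0, 6.0, 8.0, 10.0, 12.0]
        c = [1000.0 * math.exp(-lam * ti) for ti in t]
        prof = make_profile([0.5, 1.0, *t], [500.0, 900.0, *c])
        fit = estimate_lambda_z(prof)
        assert fit.lambda_z == pytest.approx(lam, rel=1e-6)
        assert fit.t_half == pytest.approx(2.0, rel=1e-3)
        assert fit.n_points == 5

    def test_biphasic_recovers_slow_phase(self):
        # fast + slow phases; >=3 samples purely in the slow phase
        t = np.array([0.5, 1.0, 1.5, 2.0, 3.0, 6.0, 8.0, 10.0, 12.0, 14.0])
        c = 800.0 * np.exp(-1.8 * t) + 200.0 * np.exp(-0.25 * t)
        prof = make_profile(t, c)
        fit = estimate_lambda_z(prof)
        assert fit.lambda_z == pytest.approx(0.25, rel=0.02)

    def test_flat_tail_flagged(self):
        flat = make_profile([0.5, 2.0, 4.0, 6.0], [100.0, 30.0, 30.0, 30.0])
        with pytest.raises(LambdaZError):
            estimate_lambda_z(flat)

    def test_too_few_points(self):
        prof = make_profile([0.5, 1.0, 2.0], [100.0, 80.0, 60.0])
        with pytest.raises(LambdaZError):
            estimate_lambda_z(prof)


class TestSingleDoseNCA:
    def test_recovery_from_onecomp_truth(self):
        prof = onecomp_profile(cl=30.0, v=100.0, dose=80.0)
        res = nca_single(prof)
        assert res.cl == pytest.approx(30.0, rel=0.05)
        assert res.vd == pytest.approx(100.0, rel=0.08)
        assert res.t_half == pytest.approx(math.log(2.0) / 0.3, rel=0.05)
        assert res.auc_inf >= res.auc_last > 0
        assert res.extrapolated_fraction < 0.2

    def test_invariants(self):
        res = nca_single(onecomp_profile())
        assert res.t_half == pytest.approx(math.log(2.0) / res.lambda_z)
        assert res.cl == pytest.approx(res.dose_mg * 1e6 / res.auc_inf / 1e3)
        assert res.vd == pytest.approx(res.cl / res.lambda_z)

    def test_fold_range_of_packaged_summary(self):
        # ratio of mean Cmax at the dose-range extremes ~ 23.9-fold
        df = load_single_dose_summary()
        cmax = df[df.parameter_name == "cmax"].set_index("dose_mg")["mean"]
        assert round(cmax[300] / cmax[20], 1) == 23.9

    def test_zero_profile_rejected(self):
        prof = make_profile([0.0, 1.0, 2.0, 3.0], [None, None, None, None])
        with pytest.raises(ValueError):
            nca_single(prof)

    def test_scale_equivariance(self):
        base = onecomp_profile()
        res0 = nca_single(base)
        c = 3.7
        scaled = make_profile(
            base.times, [v * c for v in base.concentrations], dose=base.dose_mg
        )
        res1 = nca_single(scaled)
        assert res1.cmax == pytest.approx(res0.cmax * c, rel=1e-9)
        assert res1.auc_last == pytest.approx(res0.auc_last * c, rel=1e-9)
        assert res1.auc_inf == pytest.approx(res0.auc_inf * c, rel=1e-9)
        assert res1.t_half == pytest.approx(res0.t_half, rel=1e-9)
        assert res1.cl == pytest.approx(res0.cl / c, rel=1e-9)
        assert res1.vd == pytest.approx(res0.vd / c, rel=1e-9)

    def test_lambda_z_failure_gives_reason(self):
        prof = make_profile([0.5, 1.0, 2.0, 4.0, 6.0], [100.0, 30.0, 30.0, 30.0, 40.0])
        res = nca_single(prof)
        assert res.failure_reason is not None
        assert res.auc_inf is None and res.cl is None and res.vd is None
        assert res.auc_last > 0


class TestMultipleDoseNCA:
    def test_accumulation_index_identity(self):
        # lambda_z = ln2/3 and tau = 12 -> AI = 1/(1-2^-4) = 16/15
        lam = math.log(2.0) / 3.0
        t = [0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 12.0]
        c = [None, *(1000.0 * math.exp(-lam * ti) for ti in t[1:])]
        prof = make_profile(t, c, dose=60.0, regimen=Q12H, occasion="day6")
        res = nca_multiple(prof)
        assert res.accumulation_index == pytest.approx(16.0 / 15.0, rel=1e-6)

    def test_fluctuation_formula(self):
        t = [0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0]
        lam = 0.35
        c = [40.0, 150.0, 200.0, *(200.0 * math.exp(-lam * (ti - 1.0)) for ti in t[3:])]
        prof = make_profile(t, c, dose=60.0, regimen=Q12H, occasion="day6")
        res = nca_multiple(prof)
        assert res.cmax == pytest.approx(200.0)
        assert res.cmin == pytest.approx(min(v for v in c if v is not None))
        assert res.fluctuation_pct == pytest.approx(
            (res.cmax - res.cmin) / res.cavg * 100.0
        )
        assert res.cavg == pytest.approx(res.auc_tau / 12.0)
        assert res.accumulation_index >= 1.0

    def test_worked_fluctuation_example(self):
        # cmax 200, cmin 40, cavg 80 -> fluctuation 200%
        assert (200.0 - 40.0) / 80.0 * 100.0 == pytest.approx(200.0)

    def test_missing_tau_rejected(self):
        prof = make_profile(
            [0.0, 1.0, 2.0, 4.0, 6.0], [10.0, 100.0, 60.0, 20.0, 8.0], occasion="day6"
        )
        with pytest.raises(ValueError, match="tau"):
            nca_multiple(prof)

    def test_auc_tau_extrapolated_when_sampling_stops_early(self):
        # samples to 10 h, tau 12 h: AUC_tau adds the lambda_z tail
        lam = 0.3
        t = [0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0]
        c = [300.0, 600.0, 1000.0, *(1000.0 * math.exp(-lam * (ti - 1.0)) for ti in t[3:])]
        prof = make_profile(t, c, dose=60.0, regimen=Q12H, occasion="day6")
        res = nca_multiple(prof)
        auc_10 = compute_auc(prof, 10.0)
        assert res.auc_tau > auc_10
        tail = 1000.0 * math.exp(-lam * 9.0) / lam * (1 - math.exp(-lam * 2.0))
        assert res.auc_tau == pytest.approx(auc_10 + tail, rel=0.02)


class TestProfileValidation:
    def test_non_monotone_times_name_subject(self):
        with pytest.raises(ValueError, match="s1"):
            make_profile([0.0, 2.0, 1.0], [1.0, 2.0, 3.0])

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            make_profile([0.0, 1.0], [1.0, -2.0])
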