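"""Blood Phe fluxes, meal-driven simulation, scans and inversion."""

import numpy as np
import pytest

from pkusim import (
    BloodParams,
    InvalidInputError,
    MealSchedule,
    diet_reduction_scan,
    elimination_attribution,
    fasting_equilibrium,
    fasting_phe,
    gut_to_plasma_factor,
    pah_rate,
    renal_rate,
    required_consumption_for_lowering,
    simulate_blood,
    trans_rate,
)


class TestFluxes:
    def test_pah_zero_activity(self, blood_params):
        for phe in (0.0, 0.5, 1.18, 5.0):
            assert pah_rate(phe, blood_params, f_pah=0.0) == 0.0

    def test_pah_healthy_at_low_phe(self, blood_params):
        # direct evaluation of the substrate-activation form at 0.065 mmol/L
        assert pah_rate(0.065, blood_params, f_pah=1.0) == pytest.approx(
            0.012157, abs=1e-5
        )

    def test_pah_saturates_at_vmax(self, blood_params):
        assert pah_rate(1e6, blood_params, f_pah=1.0) == pytest.approx(0.9, rel=1e-4)

    def test_trans_examples(self, blood_params):
        assert trans_rate(1.18, blood_params) == pytest.approx(0.029153, abs=1e-5)
        assert trans_rate(blood_params.km_trans, blood_params) == pytest.approx(0.0315)
        assert trans_rate(0.0, blood_params) == 0.0

    def test_renal_linear(self, blood_params):
        assert renal_rate(1.18, blood_params) == pytest.approx(3.3607e-4, abs=1e-7)
        assert renal_rate(2.36, blood_params) == pytest.approx(
            2 * renal_rate(1.18, blood_params), rel=1e-12
        )

    def test_gut_to_plasma_factor(self, blood_params):
        assert gut_to_plasma_factor(blood_params) == pytest.approx(1.7297e-4, abs=1e-7)
        heavier = BloodParams(weight=140.0)
        assert gut_to_plasma_factor(heavier) == pytest.approx(
            gut_to_plasma_factor(blood_params) / 2, rel=1e-12
        )

    def test_rejects_negative_phe(self, blood_params):
        with pytest.raises(InvalidInputError):
            pah_rate(-0.1, blood_params)


class TestSimulation:
    def test_gut_bolus_exponential_decay(self, blood_params):
        """A single bolus decays as exp(-ka*t): closed-form check to 1e-9."""
        sched = MealSchedule(daily_phe_g=1.0, meal_times_hr=(0.0,), per_meal_fraction=(1.0,))
        res = simulate_blood(1, sched, blood_params, phe0=1.18, rtol=1e-12, atol=1e-14)
        expected = 1000.0 * np.exp(-blood_params.ka_gut * res.t_hr)
        assert np.max(np.abs(res.gut - expected)) < 1e-9 * 1000.0

    def test_bolus_cumulative_plasma_delivery(self, blood_params):
        """1000 mg absorbed completely delivers 0.1730 mmol/L of plasma input
        (integral of the absorption flux)."""
        res = simulate_blood(
            3,
            MealSchedule(daily_phe_g=1.0, meal_times_hr=(0.0,), per_meal_fraction=(1.0,)),
            blood_params,
            phe0=1.18,
        )
        mask = res.t_hr <= 24.0  # only the first bolus in this window
        delivered = np.trapezoid(
            blood_params.ka_gut * res.gut[mask] * gut_to_plasma_factor(blood_params),
            res.t_hr[mask],
        )
        # the bolus is not fully absorbed by 24 h: e^(-ka*24) remains
        expected = 1000.0 * 1.7297e-4 * (1.0 - np.exp(-blood_params.ka_gut * 24.0))
        assert delivered == pytest.approx(expected, rel=1e-3)

    def test_no_meals_approaches_fasting_equilibrium(self, blood_params):
        eq = fasting_equilibrium(blood_params, f_pah=0.0)
        res = simulate_blood(
            60, MealSchedule(daily_phe_g=0.0), blood_params, f_pah=0.0, phe0=1.18
        )
        assert res.phe[-1] == pytest.approx(eq, rel=1e-3)

    def test_full_removal_equals_zero_diet(self, blood_params):
        a = simulate_blood(
            10, MealSchedule(daily_phe_g=2.5, removal_fraction=1.0), blood_params
        )
        b = simulate_blood(10, MealSchedule(daily_phe_g=0.0), blood_params)
        assert np.allclose(a.phe, b.phe, atol=1e-12)

    def test_periodic_steady_state(self, blood_params):
        """Consecutive end-of-day fasting values differ < 0.1% once settled."""
        res = simulate_blood(60, MealSchedule(), blood_params)
        phe_d59 = np.interp(59 * 24.0, res.t_hr, res.phe)
        phe_d60 = np.interp(60 * 24.0, res.t_hr, res.phe)
        assert abs(phe_d60 - phe_d59) / phe_d59 < 1e-3

    def test_daily_flux_balance_at_steady_state(self, blood_params):
        """Input (meals x F_gp + 24 V_npd) balances integrated elimination
        over the final day within 0.5%."""
        res = simulate_blood(90, MealSchedule(), blood_params)
        mask = res.t_hr >= res.t_hr[-1] - 24.0
        t, phe = res.t_hr[mask], res.phe[mask]
        gut = res.gut[mask]
        elim = np.trapezoid(
            pah_rate(phe, res.params) + trans_rate(phe, res.params) + renal_rate(phe, res.params),
            t,
        )
        absorbed = np.trapezoid(
            res.params.ka_gut * gut * gut_to_plasma_factor(res.params), t
        )
        inputs = absorbed + 24.0 * res.params.v_npd
        assert elim == pytest.approx(inputs, rel=5e-3)

    def test_fasting_readout_of_constant_trajectory(self, blood_params):
        res = simulate_blood(
            2, MealSchedule(daily_phe_g=0.0), blood_params, phe0=fasting_equilibrium(blood_params)
        )
        assert fasting_phe(res) == pytest.approx(res.phe[-1] * 1000.0, rel=1e-6)

    def test_fasting_monotone_in_f_pah(self, blood_params):
        values = [
            fasting_phe(simulate_blood(40, MealSchedule(), blood_params, f_pah=f))
            for f in (0.0, 0.02, 0.5)
        ]
        assert values[0] > values[1] > values[2]


class TestScansAndInversion:
    def test_zero_reduction_zero_lowering(self, blood_params):
        table = diet_reduction_scan([0.0], days=30, params=blood_params)
        assert table["pct_lowering"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_lowering_monotone_in_reduction(self, blood_params):
        table = diet_reduction_scan([0.1, 0.3, 0.5], days=40, params=blood_params)
        assert np.all(np.diff(table["pct_lowering"]) > 0)

    def test_inversion_round_trip(self, blood_params):
        """Removing the returned mg/day reproduces the target lowering."""
        target = 15.0
        mg = required_consumption_for_lowering(target, days=40, params=blood_params)
        sched = MealSchedule(removal_mg_per_meal=mg / 3.0)
        baseline = fasting_phe(simulate_blood(40, MealSchedule(), blood_params))
        achieved = 100.0 * (
            1.0 - fasting_phe(simulate_blood(40, sched, blood_params)) / baseline
        )
        assert achieved == pytest.approx(target, abs=0.5)

    def test_inversion_zero_target(self, blood_params):
        assert required_consumption_for_lowering(0.0, params=blood_params) == 0.0

    def test_inversion_unreachable_target(self, blood_params):
        with pytest.raises(InvalidInputError):
            required_consumption_for_lowering(95.0, days=30, params=blood_params)

    def test_attribution_sums_to_one_and_pah_zero(self, blood_params):
        res = simulate_blood(30, MealSchedule(), blood_params, f_pah=0.0)
        frac = elimination_attribution(res)
        assert sum(frac.values()) == pytest.approx(1.0, abs=1e-9)
        assert frac["pah"] == 0.0
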