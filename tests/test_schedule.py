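"""Schedule construction, protocol builders, and discrete events."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import alcotwin as at
from alcotwin.model import AUX_INDEX, STATE_INDEX, initial_state
from alcotwin.schedule import ETHANOL_DENSITY_G_PER_L, ProtocolOptions


class TestDoseToVolume:
    @pytest.mark.parametrize("dose, weight, vv, expected", [
        (0.51, 106.6, 0.13, 0.530),
        (1.0, 106.6, 0.40, 0.338),
        (0.0, 80.0, 0.05, 0.0),
    ])
    def test_examples(self, dose, weight, vv, expected):
        assert at.dose_to_volume(dose, weight, vv) == pytest.approx(expected, abs=5e-4)

    def test_zero_strength_rejected(self):
        with pytest.raises(ValueError):
            at.dose_to_volume(0.5, 80.0, 0.0)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0.01, 2.0), st.floats(40, 150), st.floats(0.01, 1.0))
    def test_dose_volume_roundtrip(self, dose, weight, vv):
        vol = at.dose_to_volume(dose, weight, vv)
        back = vol * vv * ETHANOL_DENSITY_G_PER_L / weight
        assert back == pytest.approx(dose, rel=1e-9)


class TestDualDrinkProtocol:
    def test_first_drink_is_four_ten_minute_blocks(self):
        sched = at.build_dual_drink_protocol(70.0, "vodka", 0.51)
        beer = [d for d in sched.drinks if "beer" in d.label]
        assert len(beer) == 4
        assert [d.start for d in beer] == [0.0, 15.0, 30.0, 45.0]
        assert all(d.duration == 10.0 for d in beer)
        total_dose = sum(d.ethanol_mass_mg for d in beer) / 1000.0 / 70.0
        assert total_dose == pytest.approx(0.51, rel=1e-9)

    @pytest.mark.parametrize("beverage, dose, duration", [
        ("vodka", 0.25, 15.0),
        ("whiskey", 0.85, 30.0),
        ("beer", 0.51, 30.0),
        ("wine", 0.85, 30.0),
    ])
    def test_second_drink_duration_by_dose(self, beverage, dose, duration):
        sched = at.build_dual_drink_protocol(70.0, beverage, dose)
        second = [d for d in sched.drinks if "second" in d.label][0]
        assert second.duration == duration

    def test_high_vodka_window_shifted_and_shortened(self):
        sched = at.build_dual_drink_protocol(70.0, "vodka", 0.85)
        second = [d for d in sched.drinks if "second" in d.label][0]
        assert second.start == 70.0 and second.duration == 20.0

    def test_spirit_dilution_doubles_volume_halves_strength(self):
        diluted = at.build_dual_drink_protocol(70.0, "vodka", 0.51)
        neat = at.build_dual_drink_protocol(
            70.0, "vodka", 0.51, ProtocolOptions(dilute_spirits=False))
        d, n = ([x for x in s.drinks if "second" in x.label][0]
                for s in (diluted, neat))
        assert d.volume == pytest.approx(2 * n.volume)
        assert d.vv_fraction == pytest.approx(n.vv_fraction / 2)
        assert d.ethanol_mass_mg == pytest.approx(n.ethanol_mass_mg)

    def test_meals_at_session_start_and_180(self):
        sched = at.build_dual_drink_protocol(70.0, "beer", 0.25)
        assert [(m.time, m.kcal) for m in sched.meals] == [(0.0, 300.0),
                                                           (180.0, 500.0)]

    def test_unknown_beverage_rejected(self):
        with pytest.raises(ValueError):
            at.build_dual_drink_protocol(70.0, "mead", 0.51)
        with pytest.raises(ValueError):
            at.build_dual_drink_protocol(70.0, "beer", 0.3)

    def test_builders_always_validate(self):
        for bev in ("vodka", "whiskey", "beer", "wine"):
            for dose in (0.25, 0.51, 0.85):
                at.build_dual_drink_protocol(80.0, bev, dose).validate()


class TestWangProtocol:
    def test_fixed_drink_and_meal(self):
        sched = at.build_wang_protocol(70.0)
        (drink,) = sched.drinks
        assert drink.volume == 0.119
        assert drink.vv_fraction == 0.40
        assert drink.kcal_per_L == 0.0
        assert drink.duration == 30.0
        (meal,) = sched.meals
        assert meal.kcal == 500.0 and meal.duration == 30.0

    def test_volume_independent_of_weight(self):
        assert (at.build_wang_protocol(50.0).drinks[0].volume
                == at.build_wang_protocol(120.0).drinks[0].volume)


class TestScheduleInvariants:
    def test_overlapping_drinks_rejected(self):
        a = at.DrinkEvent(start=0, duration=20, volume=0.2, vv_fraction=0.05)
        b = at.DrinkEvent(start=10, duration=20, volume=0.2, vv_fraction=0.05)
        with pytest.raises(ValueError, match="overlap"):
            at.InputSchedule(drinks=(a, b))

    def test_nonincreasing_urinations_rejected(self):
        with pytest.raises(ValueError, match="urination"):
            at.InputSchedule(urinations=(at.UrinationEvent(60),
                                         at.UrinationEvent(60)))

    def test_events_outside_horizon_rejected(self):
        with pytest.raises(ValueError, match="horizon"):
            at.InputSchedule(meals=(at.MealEvent(time=800, kcal=100),),
                             horizon=720)

    def test_total_ethanol_mass(self):
        sched = at.build_dual_drink_protocol(70.0, "wine", 0.51)
        expected = sum(d.volume * d.vv_fraction * ETHANOL_DENSITY_G_PER_L * 1000
                       for d in sched.drinks)
        assert sched.total_ethanol_mg == pytest.approx(expected)
        assert sched.total_ethanol_mg == pytest.approx((0.51 + 0.51) * 70.0 * 1000,
                                                       rel=1e-9)

    def test_dict_roundtrip(self):
        sched = at.build_dual_drink_protocol(70.0, "vodka", 0.85)
        back = at.InputSchedule.from_dict(sched.to_dict())
        assert back == sched


class TestDiscreteEvents:
    def test_new_drink_resets_liquid_kcal(self, params, male):
        y = initial_state(male, params)
        y[STATE_INDEX["Kcal_remain"]] = 120.0
        y2 = at.apply_new_drink(y)
        assert y2[STATE_INDEX["Kcal_Liquid"]] == 120.0
        changed = STATE_INDEX["Kcal_Liquid"]
        assert np.array_equal(np.delete(y2, changed), np.delete(y, changed))
        assert np.array_equal(at.apply_new_drink(y2), y2)  # idempotent

    def test_urination_scales_masses_to_residual(self, params, male):
        y = initial_state(male, params)
        y[STATE_INDEX["UrineVolume"]] = 5.0
        y[STATE_INDEX["UrineMassEtOH"]] = 100.0
        y[STATE_INDEX["UrineMassEtG"]] = 10.0
        y2 = at.apply_urination(y)
        assert y2[STATE_INDEX["UrineVolume"]] == 0.05
        assert y2[STATE_INDEX["UrineMassEtOH"]] == pytest.approx(1.0)
        assert y2[STATE_INDEX["UrineMassEtG"]] == pytest.approx(0.1)

    def test_urination_preserves_urine_concentrations(self, params, male):
        y = initial_state(male, params)
        y[STATE_INDEX["UrineVolume"]] = 2.5
        for name, mass in (("UrineMassEtOH", 80.0), ("UrineMassEtG", 3.0),
                           ("UrineMassEtS", 1.0)):
            y[STATE_INDEX[name]] = mass
        y2 = at.apply_urination(y)
        for name in ("UrineMassEtOH", "UrineMassEtG", "UrineMassEtS"):
            before = y[STATE_INDEX[name]] / y[STATE_INDEX["UrineVolume"]]
            after = y2[STATE_INDEX[name]] / y2[STATE_INDEX["UrineVolume"]]
            assert after == pytest.approx(before, rel=1e-12), name

    def test_urination_at_residual_is_noop(self, params, male):
        y = initial_state(male, params)
        assert np.array_equal(at.apply_urination(y), y)

    def test_below_residual_warns_and_noops(self, params, male):
        y = initial_state(male, params)
        y[STATE_INDEX["UrineVolume"]] = 0.01
        with pytest.warns(UserWarning, match="residual"):
            y2 = at.apply_urination(y)
        assert np.array_equal(y2, y)

    def test_voided_mass_tracked_for_audit(self, params, male):
        y = initial_state(male, params, with_aux=True)
        y[STATE_INDEX["UrineVolume"]] = 1.0
        y[STATE_INDEX["UrineMassEtOH"]] = 50.0
        y2 = at.apply_urination(y)
        assert y2[AUX_INDEX["cum_voided"]] == pytest.approx(50.0 * (1 - 0.05))
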