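"""Intake schedules: drinks, meals, urinations, and the named study protocols.

A schedule is an ordered set of events on a simulation horizon.  Drinks are
delivered uniformly over their duration (volume/duration L/min); meals feed
the solid-calorie sub-model uniformly over their duration; urinations empty
the bladder down to its 0.05 dL residual.

Two families of study protocols are built here:

* the dual-drink challenge — a first drink of beer (0.51 g/kg) consumed in
  four 10-minute blocks with 5-minute sampling gaps over one hour, followed
  by a second drink of whiskey/vodka/beer/wine at a low (0.25), medium
  (0.51) or high (0.85) g/kg dose over 15 min (low) or 30 min (medium/high);
  meals of 300 kcal at session start and 500 kcal at 180 min;
* the single-spirits validation protocol — 0.119 L of 40 v/v% zero-calorie
  spirits over 30 min paired with a 500 kcal meal over the same window.

Protocol options mirror the documented study-handling assumptions: hard
spirits may be diluted with an equal volume of non-alcoholic beverage
(doubling volume, halving strength), and the high-dose vodka window starts
10 min late with a 20-minute duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .model import STATE_INDEX, AUX_INDEX, URINE_VOLUME_0

ETHANOL_DENSITY_G_PER_L = 789.0

# default beverage strengths (v/v fraction) and liquid calories (kcal/L)
BEVERAGES: dict[str, dict[str, float]] = {
    "beer":    {"vv_fraction": 0.05, "kcal_per_L": 440.0},
    "wine":    {"vv_fraction": 0.13, "kcal_per_L": 830.0},
    "vodka":   {"vv_fraction": 0.40, "kcal_per_L": 0.0},
    "whiskey": {"vv_fraction": 0.40, "kcal_per_L": 0.0},
}
SPIRITS = ("vodka", "whiskey")

__all__ = [
    "DrinkEvent", "MealEvent", "UrinationEvent", "InputSchedule",
    "ProtocolOptions", "dose_to_volume", "build_dual_drink_protocol",
    "build_wang_protocol", "build_fig5_protocol", "build_single_drink_protocol",
    "apply_new_drink", "apply_urination",
]


@dataclass(frozen=True)
class DrinkEvent:
    start: float          # min
    duration: float       # min
    volume: float         # L
    vv_fraction: float    # ethanol volume fraction
    kcal_per_L: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("drink duration must be positive")
        if not 0 <= self.vv_fraction <= 1:
            raise ValueError("vv_fraction must lie in [0, 1]")
        if self.volume < 0:
            raise ValueError("drink volume must be non-negative")

    @property
    def end(self) -> float:
        return self.start + self.duration

    @property
    def ethanol_mass_mg(self) -> float:
        return self.volume * self.vv_fraction * ETHANOL_DENSITY_G_PER_L * 1000.0

    @property
    def vol_per_min(self) -> float:
        return self.volume / self.duration

    @property
    def etoh_conc_mg_per_L(self) -> float:
        return self.vv_fraction * ETHANOL_DENSITY_G_PER_L * 1000.0


@dataclass(frozen=True)
class MealEvent:
    time: float            # min
    kcal: float
    duration: float = 1.0  # min, delivery window of the solid calories

    def __post_init__(self) -> None:
        if self.kcal < 0:
            raise ValueError("meal kcal must be non-negative")
        if not self.duration > 0:
            raise ValueError("meal duration must be positive")

    @property
    def end(self) -> float:
        return self.time + self.duration


@dataclass(frozen=True)
class UrinationEvent:
    time: float  # min


@dataclass(frozen=True)
class InputSchedule:
    drinks: tuple[DrinkEvent, ...] = ()
    meals: tuple[MealEvent, ...] = ()
    urinations: tuple[UrinationEvent, ...] = ()
    horizon: float = 720.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "drinks", tuple(sorted(self.drinks, key=lambda d: d.start)))
        object.__setattr__(self, "meals", tuple(sorted(self.meals, key=lambda m: m.time)))
        object.__setattr__(self, "urinations", tuple(sorted(self.urinations, key=lambda u: u.time)))
        self.validate()

    def validate(self) -> None:
        for a, b in zip(self.drinks, self.drinks[1:]):
            if b.start < a.end - 1e-9:
                raise ValueError(f"drinks overlap: {a} and {b}")
        times = [u.time for u in self.urinations]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("urination times must be strictly increasing")
        for t in ([d.start for d in self.drinks] + [d.end for d in self.drinks]
                  + [m.time for m in self.meals] + times):
            if not 0 <= t <= self.horizon + 1e-9:
                raise ValueError(
                    f"event time {t} outside the horizon [0, {self.horizon}]")

    @property
    def total_ethanol_mg(self) -> float:
        return sum(d.ethanol_mass_mg for d in self.drinks)

    @property
    def last_drink_end(self) -> float:
        return max((d.end for d in self.drinks), default=0.0)

    def to_dict(self) -> dict:
        return {
            "horizon": self.horizon,
            "drinks": [{"start": d.start, "duration": d.duration, "volume": d.volume,
                        "EtOHConc": d.vv_fraction, "kcalLiquidPerVol": d.kcal_per_L,
                        "label": d.label} for d in self.drinks],
            "meals": [{"time": m.time, "MealKcal": m.kcal, "duration": m.duration}
                      for m in self.meals],
            "urinate": [u.time for u in self.urinations],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InputSchedule":
        return cls(
            drinks=tuple(DrinkEvent(start=x["start"], duration=x["duration"],
                                    volume=x["volume"], vv_fraction=x["EtOHConc"],
                                    kcal_per_L=x.get("kcalLiquidPerVol", 0.0),
                                    label=x.get("label", ""))
                         for x in d.get("drinks", [])),
            meals=tuple(MealEvent(time=x["time"], kcal=x["MealKcal"],
                                  duration=x.get("duration", 1.0))
                        for x in d.get("meals", [])),
            urinations=tuple(UrinationEvent(t) for t in d.get("urinate", [])),
            horizon=float(d.get("horizon", 720.0)),
        )


def dose_to_volume(dose_g_per_kg: float, weight_kg: float, vv_fraction: float) -> float:
    """Beverage volume (L) delivering a g/kg ethanol dose at a given strength."""
    if vv_fraction <= 0 or vv_fraction > 1:
        raise ValueError("vv_fraction must lie in (0, 1]")
    if dose_g_per_kg < 0:
        raise ValueError("dose must be non-negative")
    return dose_g_per_kg * weight_kg / (ETHANOL_DENSITY_G_PER_L * vv_fraction)


@dataclass(frozen=True)
class ProtocolOptions:
    """Assumption switches for the dual-drink study protocols."""

    dilute_spirits: bool = True        # equal-volume non-alcoholic co-consumption
    shift_high_vodka: bool = True      # high-dose vodka: +10 min start, 20 min window
    second_drink_start: float = 60.0   # min
    urination_interval: float | None = 60.0  # min; None = no scheduled voids
    horizon: float = 720.0


_SECOND_DRINK_DURATION = {0.25: 15.0, 0.51: 30.0, 0.85: 30.0}


def _first_drink_blocks(weight: float, dose: float = 0.51) -> list[DrinkEvent]:
    """First drink: beer, four 10-min blocks with 5-min sampling gaps over 60 min."""
    bev = BEVERAGES["beer"]
    total = dose_to_volume(dose, weight, bev["vv_fraction"])
    return [DrinkEvent(start=15.0 * i, duration=10.0, volume=total / 4.0,
                       vv_fraction=bev["vv_fraction"], kcal_per_L=bev["kcal_per_L"],
                       label=f"beer block {i + 1}")
            for i in range(4)]


def _spirits_drink(beverage: str, start: float, duration: float, volume: float,
                   dilute: bool, label: str) -> DrinkEvent:
    bev = BEVERAGES[beverage]
    vv, vol = bev["vv_fraction"], volume
    if dilute and beverage in SPIRITS:
        vv, vol = vv / 2.0, vol * 2.0
    return DrinkEvent(start=start, duration=duration, volume=vol, vv_fraction=vv,
                      kcal_per_L=bev["kcal_per_L"], label=label)


def build_dual_drink_protocol(weight: float, second_type: str, second_dose: float,
                              options: ProtocolOptions | None = None) -> InputSchedule:
    """Dual-drink challenge: beer first drink plus a dose-graded second drink."""
    if second_type not in BEVERAGES:
        raise ValueError(f"unknown beverage {second_type!r}; choose from {sorted(BEVERAGES)}")
    if second_dose not in _SECOND_DRINK_DURATION:
        raise ValueError(f"second dose must be one of {sorted(_SECOND_DRINK_DURATION)} g/kg")
    opt = options or ProtocolOptions()

    drinks = _first_drink_blocks(weight)
    start = opt.second_drink_start
    duration = _SECOND_DRINK_DURATION[second_dose]
    if opt.shift_high_vodka and second_type == "vodka" and second_dose == 0.85:
        start, duration = start + 10.0, 20.0
    volume = dose_to_volume(second_dose, weight, BEVERAGES[second_type]["vv_fraction"])
    if second_type in SPIRITS:
        drinks.append(_spirits_drink(second_type, start, duration, volume,
                                     opt.dilute_spirits, f"{second_type} second drink"))
    else:
        bev = BEVERAGES[second_type]
        drinks.append(DrinkEvent(start=start, duration=duration, volume=volume,
                                 vv_fraction=bev["vv_fraction"],
                                 kcal_per_L=bev["kcal_per_L"],
                                 label=f"{second_type} second drink"))
    meals = (MealEvent(time=0.0, kcal=300.0), MealEvent(time=180.0, kcal=500.0))
    urinations = _regular_urinations(opt.urination_interval, opt.horizon)
    return InputSchedule(drinks=tuple(drinks), meals=meals,
                         urinations=urinations, horizon=opt.horizon)


def _regular_urinations(interval: float | None, horizon: float) -> tuple[UrinationEvent, ...]:
    if interval is None:
        return ()
    times = np.arange(interval, horizon, interval)
    return tuple(UrinationEvent(float(t)) for t in times)


def build_wang_protocol(weight: float, horizon: float = 720.0,
                        urination_interval: float | None = None) -> InputSchedule:
    """Validation protocol: 0.119 L of 40 v/v% zero-kcal spirits + 500 kcal meal, 30 min."""
    drink = DrinkEvent(start=0.0, duration=30.0, volume=0.119, vv_fraction=0.40,
                       kcal_per_L=0.0, label="spirits")
    meal = MealEvent(time=0.0, kcal=500.0, duration=30.0)
    return InputSchedule(drinks=(drink,), meals=(meal,),
                         urinations=_regular_urinations(urination_interval, horizon),
                         horizon=horizon)


def build_single_drink_protocol(weight: float, dose_g_per_kg: float,
                                vv_fraction: float = 0.40, duration: float = 30.0,
                                start: float = 0.0, kcal_per_L: float = 0.0,
                                meals: tuple[MealEvent, ...] = (),
                                urination_interval: float | None = 60.0,
                                horizon: float = 720.0) -> InputSchedule:
    """A single drink of a given g/kg dose and strength; generic building block."""
    volume = dose_to_volume(dose_g_per_kg, weight, vv_fraction)
    drink = DrinkEvent(start=start, duration=duration, volume=volume,
                       vv_fraction=vv_fraction, kcal_per_L=kcal_per_L, label="drink")
    return InputSchedule(drinks=(drink,), meals=meals,
                         urinations=_regular_urinations(urination_interval, horizon),
                         horizon=horizon)


def build_fig5_protocol(weight: float, sex: str, scenario: str = "claim",
                        urination_interval: float | None = 60.0,
                        horizon: float = 720.0) -> InputSchedule:
    """The two forensic showcase scenarios for the male/female subjects.

    ``claim``: 0.85 g/kg of 13 v/v% wine in four 10-min blocks over 60 min,
    then 0.51 g/kg of 20 v/v% vodka over 30 min.  ``alternative``: a single
    1.0 g/kg drink of 40 v/v% vodka.  Meals of 300/500/500 kcal at
    90/180/540 min (male) or 30/180/540 min (female).
    """
    meal_times = (90.0, 180.0, 540.0) if sex == "male" else (30.0, 180.0, 540.0)
    meals = tuple(MealEvent(time=t, kcal=k)
                  for t, k in zip(meal_times, (300.0, 500.0, 500.0)))
    urinations = _regular_urinations(urination_interval, horizon)
    if scenario == "claim":
        wine_total = dose_to_volume(0.85, weight, 0.13)
        drinks = [DrinkEvent(start=15.0 * i, duration=10.0, volume=wine_total / 4.0,
                             vv_fraction=0.13, kcal_per_L=BEVERAGES["wine"]["kcal_per_L"],
                             label=f"wine block {i + 1}") for i in range(4)]
        drinks.append(DrinkEvent(start=60.0, duration=30.0,
                                 volume=dose_to_volume(0.51, weight, 0.20),
                                 vv_fraction=0.20, kcal_per_L=0.0, label="vodka"))
    elif scenario == "alternative":
        drinks = [DrinkEvent(start=0.0, duration=30.0,
                             volume=dose_to_volume(1.0, weight, 0.40),
                             vv_fraction=0.40, kcal_per_L=0.0, label="vodka single")]
    else:
        raise ValueError("scenario must be 'claim' or 'alternative'")
    return InputSchedule(drinks=tuple(drinks), meals=meals,
                         urinations=urinations, horizon=horizon)


def apply_new_drink(state: np.ndarray) -> np.ndarray:
    """Drink-start event: the active liquid-calorie load resets to what remains."""
    out = np.array(state, dtype=float)
    out[STATE_INDEX["Kcal_Liquid"]] = out[STATE_INDEX["Kcal_remain"]]
    return out


def apply_urination(state: np.ndarray) -> np.ndarray:
    """Urination event: bladder empties to its 0.05 dL residual.

    All urine masses are scaled by residual/current volume, so urine
    concentrations (UAC, urinary EtG/EtS) are continuous across the event.
    States below the residual volume trigger a warning and are left alone.
    """
    out = np.array(state, dtype=float)
    i_vol = STATE_INDEX["UrineVolume"]
    u_vol = out[i_vol]
    if u_vol < URINE_VOLUME_0:
        warnings.warn(f"urination requested at bladder volume {u_vol:.3g} dL "
                      f"< residual {URINE_VOLUME_0}; ignored", stacklevel=2)
        return out
    frac = URINE_VOLUME_0 / u_vol
    voided_etoh = out[STATE_INDEX["UrineMassEtOH"]] * (1.0 - frac)
    for name in ("UrineMassEtOH", "UrineMassEtG", "UrineMassEtS"):
        out[STATE_INDEX[name]] *= frac
    out[i_vol] = URINE_VOLUME_0
    if out.shape[0] >= AUX_INDEX["cum_voided"] + 1:  # audit block present
        out[AUX_INDEX["cum_voided"]] += voided_etoh
    return out
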