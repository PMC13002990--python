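"""Anthropometrics, kinetic parameters, and derived physiological volumes.

The twin is personalised entirely through four anthropometric inputs
(sex, weight, height, age).  From these it derives the distribution
volumes that the kinetics run on:

* blood volume from a cubic-in-height polynomial (per-sex coefficients),
  split 15 % central / 85 % peripheral;
* total body water (TBW) from a linear age/height/weight form with height
  in centimetres, scaled by 1/0.84;
* liver volume from a linear weight formula.

Internally all body-water/blood/bladder volumes are carried in decilitres
(concentrations are mg/dL), stomach volume in litres, time in minutes.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "PARAM_INDEX",
    "DEFAULT_PARAM_TABLE",
    "Anthropometrics",
    "DerivedVolumes",
    "ParameterSet",
    "derive_volumes",
]


class InvalidAnthropometricsError(ValueError):
    """Raised when anthropometric inputs produce non-physical volumes."""


@dataclass(frozen=True)
class Anthropometrics:
    """Subject description: sex ('male'/'female'), weight kg, height m, age years."""

    sex: str
    weight: float
    height: float
    age: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not self.weight > 0:
            raise ValueError(f"weight must be positive, got {self.weight}")
        if not 1.0 <= self.height <= 2.5:
            raise ValueError(f"height must be in [1.0, 2.5] m, got {self.height}")
        if not 0 < self.age < 120:
            raise ValueError(f"age must be in (0, 120) years, got {self.age}")

    def to_dict(self) -> dict:
        return {"sex": self.sex, "weight": self.weight,
                "height": self.height, "age": self.age}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Anthropometrics":
        return cls(sex=d["sex"], weight=float(d["weight"]),
                   height=float(d["height"]), age=float(d["age"]))


# name -> (estimate, lower bound, upper bound); full printed precision
DEFAULT_PARAM_TABLE: dict[str, tuple[float, float, float]] = {
    "VmaxGastric":             (0.10028847533601028, 1e-5, 1e5),
    "KmGastric":               (0.8115471295053232, 2.766e1, 1.844e3),
    "k_kcalscaling":           (0.026009077044725923, 1e-5, 1e5),
    "km_kcal":                 (7219.025648168511, 1e-5, 1e5),
    "n_kcal":                  (2.9350431505014307, 1e-1, 4e0),
    "k_poolIn":                (0.049215056963481905, 1e-5, 1e5),
    "k_poolOut":               (0.00011026963373147828, 1e-7, 1e5),
    "VmaxADHSto":              (383.0316652068957, 1e-5, 1e5),
    "KmADHSto":                (1750.8565753331234, 2.766e2, 1.844e3),
    "k_EtOHuptake":            (0.05085931578651339, 1e-5, 1e5),
    "k_equalize":              (3.364285096106452, 1e-5, 1e5),
    "k_equalize_liver":        (0.5664934932515018, 1e-5, 1e5),
    "VmaxADH":                 (17.490115599723829, 1e-5, 1e5),
    "VmaxCYP2E1":              (0.7715882956131286, 1e-5, 1e5),
    "KmADH":                   (12.13180346563429, 9.22e-1, 9.22e0),
    "KmCYP2E1":                (45.98540429542478, 3.688e1, 4.61e1),
    "k_food_clearance":        (0.1350242774593947, 1e-5, 1e5),
    "k_acetate":               (1.1650870599405063, 1e-5, 1e5),
    "k_blood_plasma_ratio":    (0.6871729866586396, 1e-1, 1e0),
    "k_urine_water":           (5.961711956546037, 1e-5, 1e5),
    "k_basal_vasopressin":     (0.3849587409310818, 1e-5, 1e5),
    "k_vasopressin_BAC":       (74740.43401768291, 1e-5, 1e5),
    "k_clearance_vasopressin": (0.0006626630440471179, 1e-5, 1e5),
    "k_kidney_permability":    (2.5215624280668018e-05, 1e-5, 1e5),
    "VmaxEtG":                 (0.6461457040480787, 1e-5, 1e5),
    "KmEtG":                   (29854.322456892394, 1e-5, 1e5),
    "VmaxEtS":                 (0.011876595138349037, 1e-5, 1e5),
    "KmEtS":                   (414.40740948670106, 1e-5, 1e5),
    "k_EtG_urine":             (0.0024879684263205454, 1e-5, 1e5),
    "k_EtS_urine":             (0.014152433882270748, 1e-5, 1e5),
    "k_PEth":                  (0.13959486810293995, 1e-7, 1e3),
    "k_PEth_clearance":        (0.001460712263112933, 1e-7, 1e3),
    "k_PEth_bind":             (0.07805739912357477, 1e-7, 1e3),
    "k_PEth_release":          (0.002851044320061577, 1e-7, 1e3),
}

PARAM_NAMES: tuple[str, ...] = tuple(DEFAULT_PARAM_TABLE)
PARAM_INDEX: dict[str, int] = {n: i for i, n in enumerate(PARAM_NAMES)}


@dataclass
class ParameterSet:
    """The 34 named kinetic parameters with their estimation bounds.

    Values default to the fitted estimates; bounds are the search box used
    during estimation.  A printed estimate lying outside its own bounds is
    reported as a warning, not an error (two of the published Michaelis
    constants do).
    """

    values: dict[str, float] = field(
        default_factory=lambda: {n: v for n, (v, _, _) in DEFAULT_PARAM_TABLE.items()})
    lower: dict[str, float] = field(
        default_factory=lambda: {n: lo for n, (_, lo, _) in DEFAULT_PARAM_TABLE.items()})
    upper: dict[str, float] = field(
        default_factory=lambda: {n: hi for n, (_, _, hi) in DEFAULT_PARAM_TABLE.items()})

    def __post_init__(self) -> None:
        missing = set(PARAM_NAMES) - set(self.values)
        if missing:
            raise ValueError(f"missing parameters: {sorted(missing)}")
        unknown = set(self.values) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        for n in PARAM_NAMES:
            if not self.values[n] > 0:
                raise ValueError(f"parameter {n} must be positive, got {self.values[n]}")
            if not self.lower[n] < self.upper[n]:
                raise ValueError(f"bounds for {n} must satisfy lower < upper")
            if not self.lower[n] <= self.values[n] <= self.upper[n]:
                warnings.warn(
                    f"parameter {n}={self.values[n]:g} lies outside its bounds "
                    f"[{self.lower[n]:g}, {self.upper[n]:g}]", stacklevel=2)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def replace(self, **updates: float) -> "ParameterSet":
        """Return a copy with the given parameter values replaced."""
        vals = dict(self.values)
        for k, v in updates.items():
            if k not in PARAM_INDEX:
                raise KeyError(k)
            vals[k] = float(v)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return ParameterSet(values=vals, lower=dict(self.lower), upper=dict(self.upper))

    def without_elimination(self) -> "ParameterSet":
        """Copy with every ethanol elimination / metabolite synthesis Vmax set ~0.

        Used by the mass-conservation audit: with these channels closed the
        only ethanol sinks left are transport between compartments and the
        bladder, so total ethanol mass must be conserved.
        """
        eps = 0.0  # exact zero; Michaelis-Menten terms remain well-defined
        return self.replace(VmaxADHSto=np.nextafter(eps, 1), VmaxADH=np.nextafter(eps, 1),
                            VmaxCYP2E1=np.nextafter(eps, 1), VmaxEtG=np.nextafter(eps, 1),
                            VmaxEtS=np.nextafter(eps, 1))

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "ParameterSet":
        arr = np.asarray(list(arr), dtype=float)
        if arr.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} values, got {arr.shape}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return cls(values=dict(zip(PARAM_NAMES, arr.tolist())))

    def bounds_array(self) -> np.ndarray:
        return np.array([[self.lower[n], self.upper[n]] for n in PARAM_NAMES])

    def to_json(self, path) -> None:
        payload = {n: {"value": self.values[n], "lower_bound": self.lower[n],
                       "upper_bound": self.upper[n]} for n in PARAM_NAMES}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ParameterSet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(values={n: float(payload[n]["value"]) for n in payload},
                   lower={n: float(payload[n]["lower_bound"]) for n in payload},
                   upper={n: float(payload[n]["upper_bound"]) for n in payload})


CENTRAL_FRACTION = 0.15  # share of blood volume in the central (breath-facing) pool
WATSON_SCALE = 0.84      # TBW = linear form / 0.84


@dataclass(frozen=True)
class DerivedVolumes:
    """Distribution volumes in dL derived from anthropometrics."""

    V_blood: float
    V_blood_central: float
    V_blood_peripheral: float
    V_plasma_peripheral: float
    TBW: float
    V_liver: float
    central_fraction: float = CENTRAL_FRACTION
    watson_scale: float = WATSON_SCALE

    @property
    def V_blood_L(self) -> float:
        return self.V_blood / 10.0

    @property
    def TBW_L(self) -> float:
        return self.TBW / 10.0


def blood_volume_L(anthro: Anthropometrics) -> float:
    """Blood volume (L): per-sex cubic polynomial in height (m) and weight (kg)."""
    h, w = anthro.height, anthro.weight
    if anthro.sex == "male":
        return 0.3669 * h ** 3 + 0.03219 * w + 0.6041
    return 0.3561 * h ** 3 + 0.03308 * w + 0.1833


def total_body_water_L(anthro: Anthropometrics) -> float:
    """TBW (L): per-sex linear form (height in cm) divided by 0.84."""
    h_cm, w, a = anthro.height * 100.0, anthro.weight, anthro.age
    if anthro.sex == "male":
        raw = 2.447 - 0.09516 * a + 0.1074 * h_cm + 0.3362 * w
    else:
        raw = -2.097 + 0.1069 * h_cm + 0.2466 * w
    return raw / WATSON_SCALE


def liver_volume_dL(anthro: Anthropometrics) -> float:
    """Liver volume (dL) from the linear weight formula."""
    return (18.51 * anthro.weight + 191.8) / 100.0


def derive_volumes(anthro: Anthropometrics, params: ParameterSet) -> DerivedVolumes:
    """Derive all distribution volumes (dL) for a subject.

    Raises InvalidAnthropometricsError if any derived volume is non-positive
    or if TBW does not exceed blood + liver volume (the tissue compartment
    would then have negative volume).
    """
    vb = blood_volume_L(anthro) * 10.0
    tbw = total_body_water_L(anthro) * 10.0
    vliver = liver_volume_dL(anthro)
    vc = CENTRAL_FRACTION * vb
    vbp = (1.0 - CENTRAL_FRACTION) * vb
    vpp = params["k_blood_plasma_ratio"] * vbp
    vols = DerivedVolumes(V_blood=vb, V_blood_central=vc, V_blood_peripheral=vbp,
                          V_plasma_peripheral=vpp, TBW=tbw, V_liver=vliver)
    if min(vb, tbw, vliver, vc, vbp, vpp) <= 0 or not math.isfinite(vb + tbw):
        raise InvalidAnthropometricsError(
            f"non-positive derived volume for {anthro}")
    if tbw <= vb + vliver:
        raise InvalidAnthropometricsError(
            f"TBW ({tbw:.1f} dL) must exceed blood + liver volume for {anthro}")
    return vols
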