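"""State equations of the ethanol digital twin.

Compartments: stomach (volume, liquid/solid calories, dissolved ethanol and a
mucosal ethanol pool), intestines (ethanol mass awaiting uptake), central and
peripheral blood, tissue, liver (where ethanol is oxidised by ADH/CYP2E1 and
conjugated to EtG/EtS), and the bladder (ethanol, EtG, EtS masses plus urine
volume).  Diuresis is driven by a vasopressin state whose production is
suppressed by blood alcohol.

Units: time min; stomach volume L; all other volumes dL; masses mg;
concentrations mg/dL; PEth in µmol/L (uncalibrated minimal sub-model).

The right-hand side operates on a flat state vector.  Alongside the 26
physiological states it integrates 8 auxiliary cumulative-flux states
(ingested ethanol, the five elimination channels, net tissue influx, voided
urine mass) used by the mass-balance audit; they feed back into nothing.

Sub-models carried over from the earlier ethanol/PEth twin (stomach ethanol
pool, stomach ADH, solid-meal calories, acetate, PEth binding) are not
printed in full anywhere; they are implemented here as the documented
minimal forms collected in the ``legacy`` section below so they can be
swapped out against a released reference implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import Anthropometrics, DerivedVolumes, ParameterSet, PARAM_INDEX, derive_volumes

try:  # jit the hot RHS when numba is available; fall back to pure python
    from numba import njit as _njit

    def _maybe_jit(fn):
        return _njit(cache=True, fastmath=False)(fn)
except ImportError:  # pragma: no cover
    def _maybe_jit(fn):
        return fn

__all__ = [
    "STATE_NAMES", "STATE_INDEX", "AUX_NAMES", "N_STATES", "N_AUX",
    "OBSERVABLE_NAMES", "ObservableVector", "kcal_effect",
    "gastric_emptying_rate", "rhs", "observables", "observables_from_states",
    "initial_state",
]

STATE_NAMES: tuple[str, ...] = (
    "Vol_Stomach", "Kcal_Liquid", "Kcal_remain", "MaxKcal_Solid", "Kcal_Solid",
    "EtOH_Pool", "ConcEtOH_Stomach", "MassEtOH_Intestines",
    "BloodConcCentral", "BloodConcPeripheral", "TissueConc", "LiverConc",
    "LiverEtG", "PeripheralEtG", "LiverEtS", "PeripheralEtS",
    "Plasma_Acetate", "TissueExtraWater", "Vasopressin",
    "UrineMassEtOH", "UrineVolume", "UrineMassEtG", "UrineMassEtS",
    "PEth", "PEth_Bound", "timeElapsed",
)
STATE_INDEX: dict[str, int] = {n: i for i, n in enumerate(STATE_NAMES)}
N_STATES = len(STATE_NAMES)

AUX_NAMES: tuple[str, ...] = (
    "cum_ingested", "cum_elim_stomach_adh", "cum_elim_adh", "cum_elim_cyp2e1",
    "cum_elim_etg", "cum_elim_ets", "cum_tissue_mass", "cum_voided",
)
AUX_INDEX: dict[str, int] = {n: N_STATES + i for i, n in enumerate(AUX_NAMES)}
N_AUX = len(AUX_NAMES)

VOL_STOMACH_0 = 1.0e-3   # residual stomach volume, L
URINE_VOLUME_0 = 0.05    # residual bladder volume after voiding, dL
BRAC_SLOPE = 0.840       # breath/blood linear map, g/210L per g/dL
BRAC_INTERCEPT = 0.00367
ACETATE_MM_PER_MGDL = 1.0 / 10.2
ACETATE_CLEARANCE = 0.1  # /min, fixed constant of the minimal acetate form

OBSERVABLE_NAMES: tuple[str, ...] = (
    "yGastricVolume", "yEtOH", "yBrAC_g210L", "yBrAC_gdL", "yAcetate",
    "yPEth", "yUAC", "yEtG", "yEtS",
)

# unpack parameter indices once for the jitted kernel
_PI = PARAM_INDEX
_IP_VMAX_GASTRIC = _PI["VmaxGastric"]; _IP_KM_GASTRIC = _PI["KmGastric"]
_IP_KCALSCALING = _PI["k_kcalscaling"]; _IP_N_KCAL = _PI["n_kcal"]
_IP_POOL_IN = _PI["k_poolIn"]; _IP_POOL_OUT = _PI["k_poolOut"]
_IP_VMAX_ADH_STO = _PI["VmaxADHSto"]; _IP_KM_ADH_STO = _PI["KmADHSto"]
_IP_UPTAKE = _PI["k_EtOHuptake"]; _IP_EQUALIZE = _PI["k_equalize"]
_IP_EQUALIZE_LIVER = _PI["k_equalize_liver"]
_IP_VMAX_ADH = _PI["VmaxADH"]; _IP_VMAX_CYP = _PI["VmaxCYP2E1"]
_IP_KM_ADH = _PI["KmADH"]; _IP_KM_CYP = _PI["KmCYP2E1"]
_IP_FOOD_CLEAR = _PI["k_food_clearance"]; _IP_ACETATE = _PI["k_acetate"]
_IP_URINE_WATER = _PI["k_urine_water"]
_IP_BASAL_VASO = _PI["k_basal_vasopressin"]; _IP_VASO_BAC = _PI["k_vasopressin_BAC"]
_IP_CLEAR_VASO = _PI["k_clearance_vasopressin"]
_IP_KIDNEY = _PI["k_kidney_permability"]
_IP_VMAX_ETG = _PI["VmaxEtG"]; _IP_KM_ETG = _PI["KmEtG"]
_IP_VMAX_ETS = _PI["VmaxEtS"]; _IP_KM_ETS = _PI["KmEtS"]
_IP_ETG_URINE = _PI["k_EtG_urine"]; _IP_ETS_URINE = _PI["k_EtS_urine"]
_IP_PETH = _PI["k_PEth"]; _IP_PETH_CLEAR = _PI["k_PEth_clearance"]
_IP_PETH_BIND = _PI["k_PEth_bind"]; _IP_PETH_RELEASE = _PI["k_PEth_release"]


def kcal_effect(kcal_liquid: float, params: ParameterSet) -> float:
    """Caloric inhibition of gastric emptying, in (0, 1].

    A Hill function of the scaled liquid-calorie load
    ``x = Kcal_Liquid / k_kcalscaling`` with exponent ``n_kcal`` and
    half-saturation at ``x = KmGastric``; zero calories give 1.
    """
    if kcal_liquid < 0:
        raise ValueError(f"Kcal_Liquid must be >= 0, got {kcal_liquid}")
    if kcal_liquid == 0:
        return 1.0
    x = kcal_liquid / params["k_kcalscaling"]
    n = params["n_kcal"]
    kmn = params["KmGastric"] ** n
    # algebraically 1 - x^n/(x^n + Km^n); this form avoids cancellation
    return kmn / (x ** n + kmn)


def gastric_emptying_rate(vol_stomach: float, kcal_liquid: float,
                          params: ParameterSet) -> float:
    """Stomach-to-intestine liquid flow (L/min).

    Michaelis-Menten in the volume above the residual (clipped at zero),
    multiplied by the caloric inhibition factor.
    """
    vol_change = max(vol_stomach - VOL_STOMACH_0, 0.0)
    mm = vol_change / (vol_change + params["KmGastric"])
    return params["VmaxGastric"] * mm * kcal_effect(kcal_liquid, params)


def _rhs_kernel(t, y, p, u, vols, consts):
    """Flat RHS over the 26 model states + 8 cumulative audit states.

    u = (volDrinkPerTime [L/min], EtOHConc [mg/L], kcalLiquidPerVol [kcal/L],
         meal_kcal_rate [kcal/min]) — piecewise constant over a segment.
    vols = (V_blood, V_central, V_blood_peripheral, V_plasma_peripheral,
            TBW, V_liver) in dL.
    consts = (food_upregulation_factor, vol_stomach_residual)
    """
    dy = np.zeros(34)

    vol_sto = y[0]; kcal_liq = y[1]; kcal_rem = y[2]
    kcal_solid = y[4]; pool = y[5]; conc_sto = y[6]; m_int = y[7]
    cc = y[8]; cp = y[9]; ct = y[10]; cl = y[11]
    l_etg = y[12]; p_etg = y[13]; l_ets = y[14]; p_ets = y[15]
    acetate = y[16]; tew = y[17]; vaso = y[18]
    um_etoh = y[19]; u_vol = y[20]
    peth = y[23]; peth_b = y[24]

    u_voldrink = u[0]; u_etohconc = u[1]; u_kcalpervol = u[2]; u_meal = u[3]

    v_blood = vols[0]; v_c = vols[1]; v_bp = vols[2]
    v_pp = vols[3]; tbw = vols[4]; v_liver = vols[5]

    # --- gastric emptying -------------------------------------------------
    vol_change = vol_sto - consts[1]
    if vol_change < 0.0:
        vol_change = 0.0
    if kcal_liq > 0.0:
        x = kcal_liq / p[_IP_KCALSCALING]
        kmn = p[_IP_KM_GASTRIC] ** p[_IP_N_KCAL]
        keff = kmn / (x ** p[_IP_N_KCAL] + kmn)
    else:
        keff = 1.0
    rvol_emptying = p[_IP_VMAX_GASTRIC] * vol_change / (vol_change + p[_IP_KM_GASTRIC]) * keff

    dy[0] = u_voldrink - rvol_emptying
    dy[1] = u_voldrink * u_kcalpervol
    dy[2] = u_voldrink * u_kcalpervol - rvol_emptying * kcal_rem / vol_sto

    # --- legacy: solid-meal calories --------------------------------------
    dy[3] = u_meal                                   # MaxKcal_Solid bookkeeping
    dy[4] = u_meal - p[_IP_FOOD_CLEAR] * kcal_solid  # Kcal_Solid

    food_factor = consts[0] if kcal_solid > 0.0 else 1.0

    # --- legacy: stomach ethanol (dissolved + mucosal pool + stomach ADH) --
    r_drink = u_voldrink * u_etohconc                       # mg/min in
    r_empty_etoh = rvol_emptying * 10.0 * conc_sto          # mg/min to intestines
    r_adh_sto = p[_IP_VMAX_ADH_STO] * conc_sto / (conc_sto + p[_IP_KM_ADH_STO])
    m_sto_dl = 10.0 * vol_sto                               # stomach volume in dL
    r_pool_in = p[_IP_POOL_IN] * conc_sto * m_sto_dl
    r_pool_out = p[_IP_POOL_OUT] * pool
    dy[5] = r_pool_in - r_pool_out
    dy[6] = ((r_drink - r_empty_etoh - r_adh_sto - r_pool_in + r_pool_out) / m_sto_dl
             - conc_sto * dy[0] / vol_sto)

    # --- intestinal uptake -------------------------------------------------
    r_uptake = p[_IP_UPTAKE] * m_int
    dy[7] = r_empty_etoh - r_uptake

    # --- circulation: central / peripheral blood ---------------------------
    r_circ = p[_IP_EQUALIZE] * (cc - cp)
    dy[8] = r_uptake / v_c - r_circ

    r_tissue_per = cp - ct
    r_liver = p[_IP_EQUALIZE_LIVER] * (cp - cl)
    r_tissueurine = tew / vaso * p[_IP_URINE_WATER]
    r_urine = r_tissueurine * (cp * v_bp) / v_pp + 0.01 * cp
    uac = um_etoh / u_vol
    r_urinereturn = (p[_IP_KIDNEY] * vaso * (uac - cp * v_bp / v_pp) * u_vol)
    dy[9] = (r_circ * (v_c / v_bp) - r_tissue_per - r_liver
             + (-r_urine + r_urinereturn) / v_bp)

    # --- liver: oxidation and conjugation ----------------------------------
    mm_adh = cl / (cl + p[_IP_KM_ADH])
    mm_cyp = cl / (cl + p[_IP_KM_CYP])
    r_elim = (p[_IP_VMAX_ADH] * mm_adh + p[_IP_VMAX_CYP] * mm_cyp) * food_factor
    r_etg = p[_IP_VMAX_ETG] * cl / (cl + p[_IP_KM_ETG])
    r_ets = p[_IP_VMAX_ETS] * cl / (cl + p[_IP_KM_ETS])
    dy[11] = r_liver * v_bp / v_liver - r_elim - r_etg - r_ets

    # --- EtG / EtS ---------------------------------------------------------
    r_etg_lp = l_etg - p_etg
    r_ets_lp = l_ets - p_ets
    r_etg_urine = p[_IP_ETG_URINE] * p_etg
    r_ets_urine = p[_IP_ETS_URINE] * p_ets
    dy[12] = r_etg - r_etg_lp
    dy[13] = r_etg_lp * v_liver / v_bp - r_etg_urine
    dy[14] = r_ets - r_ets_lp
    dy[15] = r_ets_lp * v_liver / v_bp - r_ets_urine

    # --- legacy: plasma acetate -------------------------------------------
    dy[16] = p[_IP_ACETATE] * r_elim * v_liver / v_pp - ACETATE_CLEARANCE * acetate

    # --- tissue and vasopressin -------------------------------------------
    v_tissue = tbw - v_blood - v_liver + tew
    dy[10] = r_tissue_per * v_bp / v_tissue
    dy[17] = rvol_emptying * 10.0 - r_tissueurine
    r_vaso_in = p[_IP_BASAL_VASO] / (1.0 + p[_IP_VASO_BAC] * cp)
    dy[18] = r_vaso_in - vaso * p[_IP_CLEAR_VASO]

    # --- bladder -----------------------------------------------------------
    dy[19] = r_urine - r_urinereturn
    dy[20] = 0.01 + r_tissueurine
    dy[21] = r_etg_urine * v_bp
    dy[22] = r_ets_urine * v_bp

    # --- legacy: PEth ------------------------------------------------------
    dy[23] = (p[_IP_PETH] * cp - p[_IP_PETH_CLEAR] * peth
              - p[_IP_PETH_BIND] * peth + p[_IP_PETH_RELEASE] * peth_b)
    dy[24] = p[_IP_PETH_BIND] * peth - p[_IP_PETH_RELEASE] * peth_b

    dy[25] = 1.0  # timeElapsed

    # --- cumulative-flux audit states --------------------------------------
    dy[26] = r_drink
    dy[27] = r_adh_sto
    dy[28] = p[_IP_VMAX_ADH] * mm_adh * food_factor * v_liver
    dy[29] = p[_IP_VMAX_CYP] * mm_cyp * food_factor * v_liver
    dy[30] = r_etg * v_liver
    dy[31] = r_ets * v_liver
    dy[32] = r_tissue_per * v_bp
    dy[33] = 0.0  # voided mass advances only at urination events
    return dy


rhs_kernel = _maybe_jit(_rhs_kernel)


def _vols_array(volumes: DerivedVolumes) -> np.ndarray:
    return np.array([volumes.V_blood, volumes.V_blood_central,
                     volumes.V_blood_peripheral, volumes.V_plasma_peripheral,
                     volumes.TBW, volumes.V_liver])


def rhs(t: float, state: np.ndarray, inputs: np.ndarray,
        volumes: DerivedVolumes, params: ParameterSet,
        food_upregulation: float = 1.0) -> np.ndarray:
    """Time derivative of the full state vector (convenience wrapper).

    ``state`` may be length 26 (physiological states only) or 34 (with audit
    states); the returned derivative matches the input length.
    """
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise FloatingPointError("non-finite model state passed to rhs")
    short = state.shape[0] == N_STATES
    y = np.concatenate([state, np.zeros(N_AUX)]) if short else state
    dy = rhs_kernel(t, y, params.as_array(), np.asarray(inputs, dtype=float),
                    _vols_array(volumes),
                    np.array([food_upregulation, VOL_STOMACH_0]))
    return dy[:N_STATES] if short else dy


def initial_state(anthro: Anthropometrics, params: ParameterSet,
                  with_aux: bool = False) -> np.ndarray:
    """Fasted, alcohol-free initial condition.

    Residual stomach volume 0.001 L, residual bladder volume 0.05 dL,
    vasopressin at its drug-free steady state (basal production / clearance),
    everything else zero.
    """
    n = N_STATES + N_AUX if with_aux else N_STATES
    y0 = np.zeros(n)
    y0[STATE_INDEX["Vol_Stomach"]] = VOL_STOMACH_0
    y0[STATE_INDEX["UrineVolume"]] = URINE_VOLUME_0
    y0[STATE_INDEX["Vasopressin"]] = (
        params["k_basal_vasopressin"] / params["k_clearance_vasopressin"])
    return y0


@dataclass(frozen=True)
class ObservableVector:
    """The measurable outputs mapped from one model state."""

    yGastricVolume: float  # L
    yEtOH: float           # BAC, mg/dL
    yBrAC_g210L: float     # g/210 L breath
    yBrAC_gdL: float       # g/dL
    yAcetate: float        # mM
    yPEth: float           # µmol/L
    yUAC: float            # mg/dL
    yEtG: float            # mg/dL
    yEtS: float            # mg/dL

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in OBSERVABLE_NAMES}


def observables(state: np.ndarray, volumes: DerivedVolumes) -> ObservableVector:
    """Map one state vector to the observable outputs.

    BAC is the peripheral blood concentration; BrAC is an affine map of the
    central concentration; UAC is bladder ethanol mass over urine volume.
    """
    s = np.asarray(state, dtype=float)
    u_vol = s[STATE_INDEX["UrineVolume"]]
    if u_vol <= 0:
        raise ZeroDivisionError("urine volume must be positive to evaluate UAC")
    cc = s[STATE_INDEX["BloodConcCentral"]]
    return ObservableVector(
        yGastricVolume=s[STATE_INDEX["Vol_Stomach"]],
        yEtOH=s[STATE_INDEX["BloodConcPeripheral"]],
        yBrAC_g210L=BRAC_SLOPE * (cc / 1000.0) + BRAC_INTERCEPT,
        yBrAC_gdL=cc / 1000.0,
        yAcetate=s[STATE_INDEX["Plasma_Acetate"]] * ACETATE_MM_PER_MGDL,
        yPEth=s[STATE_INDEX["PEth"]],
        yUAC=s[STATE_INDEX["UrineMassEtOH"]] / u_vol,
        yEtG=s[STATE_INDEX["PeripheralEtG"]],
        yEtS=s[STATE_INDEX["PeripheralEtS"]],
    )


def observables_from_states(states: np.ndarray,
                            volumes: DerivedVolumes) -> dict[str, np.ndarray]:
    """Vectorised observable map over an (n_times, n_states) array."""
    s = np.atleast_2d(np.asarray(states, dtype=float))
    u_vol = s[:, STATE_INDEX["UrineVolume"]]
    if np.any(u_vol <= 0):
        raise ZeroDivisionError("urine volume must be positive to evaluate UAC")
    cc = s[:, STATE_INDEX["BloodConcCentral"]]
    return {
        "yGastricVolume": s[:, STATE_INDEX["Vol_Stomach"]],
        "yEtOH": s[:, STATE_INDEX["BloodConcPeripheral"]],
        "yBrAC_g210L": BRAC_SLOPE * (cc / 1000.0) + BRAC_INTERCEPT,
        "yBrAC_gdL": cc / 1000.0,
        "yAcetate": s[:, STATE_INDEX["Plasma_Acetate"]] * ACETATE_MM_PER_MGDL,
        "yPEth": s[:, STATE_INDEX["PEth"]],
        "yUAC": s[:, STATE_INDEX["UrineMassEtOH"]] / u_vol,
        "yEtG": s[:, STATE_INDEX["PeripheralEtG"]],
        "yEtS": s[:, STATE_INDEX["PeripheralEtS"]],
    }
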