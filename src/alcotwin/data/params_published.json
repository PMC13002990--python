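{
 "VmaxGastric": {
  "value": 0.10028847533601028,
  "lower_bound": 1e-05,
  "upper_bound": 100000.0
 },
 "KmGastric": {
  "value": 0.8115471295053232,
  "lower_bound": 27.66,
  "upper_bound": 1844.0
 },
 "k_kcalscaling": {
  "value": 0.026009077044725923,
  "lower_bound": 1e-05,
  "upper_bound": 100000.0
 },
 "km_kcal": {
  "value": 7219.025648168511,
  "lower_bound": 1e-05,
  "upper_bound": 100000.0
 },
 "n_kcal": {
  "value": 2.9350431505014307,
  "lower_bound": 0.1,
  "upper_bound": 4.0
 },
 "k_poolIn": {
  "value": 0.049215056963481905,
  "lower_bound": 1e-05,
  "upper_bound": 100000.0
 },
 "k_poolOut": {
  "value": 0.00011026963373147828,
  "lower_bound": 1e-07,
  "upper_bound": 100000.0
 },
 "VmaxADHSto": {
  "value": 383.0316652068957,
  "lower_bound": 1e-05,
  "upper_bound": 100000.0
 },
 "KmADHSto": {
  "value": 1750.8565753331234,
  "lower_bound": 276.6,
  "upper_bound": 1844.0
 },
 "k_EtOHuptake": {
  "value": 0.05085931578651339,
  "lower_bound": 1e-05,
  "upper_bound": 100000.0
 },
 "k_equalize": {
  "value": 3.364285096106452,
  "lower_bound": 1e-05,
  "upper_bound": 100000.0
 },
 "k_equalize_liver": {
  "value": 0.5664934932515018,
  "lower_bound": 1e-05,
  "upper_bound": 100000.0
 },
 "VmaxADH": {
  "value": 17.49011559972383,
  "lower_bound": 1e-05,
  "upper_bound": 100000.0
 },
 "VmaxCYP2E1": {
  "value": 0.7715882956131286,
  "lower_bound": 1e-05,
  "upper_bound": 100000.0
 },
 "KmADH": {
  "value": 12.13180346563429,
  "lower_bound": 0.922,
  "upper_bound": 9.22
 },
 "KmCYP2E1": {
  "value": 45.98540429542478,
  "lower_bound": 36.88,
  "upper_bound": 46.1
 },
 "k_food_clearance": {
  "value": 0.1350242774593947,
  "lower_bound": 1e-05,
  "upper_bound": 100000.0
 },
 "k_acetate": {
  "value": 1.1650870599405063,
  "lower_bound": 1e-05,
  "upper_bound": 100000.0
 },
 "k_blood_plasma_ratio": {
  "value": 0.6871729866586396,
  "lower_bound": 0.1,
  "upper_bound": 1.0
 },
 "k_urine_water": {
  "value": 5.961711956546037,
  "lower_bound": 1e-05,
  "upper_bound": 100000.0
 },
 "k_basal_vasopressin": {
  "value": 0.3849587409310818,
  "lower_bound": 1e-05,
  "upper_bound": 100000.0
 },
 "k_vasopressin_BAC": {
  "value": 74740.43401768291,
  "lower_bound": 1e-05,
  "upper_bound": 100000.0
 },
 "k_clearance_vasopressin": {
  "value": 0.0006626630440471179,
  "lower_bound": 1e-05,
  "upper_bound": 100000.0
 },
 "k_kidney_permability": {
  "value": 2.5215624280668018e-05,
  "lower_bound": 1e-05,
  "upper_bound": 100000.0
 },
 "VmaxEtG": {
  "value": 0.6461457040480787,
  "lower_bound": 1e-05,
  "upper_bound": 100000.0
 },
 "KmEtG": {
  "value": 29854.322456892394,
  "lower_bound": 1e-05,
  "upper_bound": 100000.0
 },
 "VmaxEtS": {
  "value": 0.011876595138349037,
  "lower_bound": 1e-05,
  "upper_bound": 100000.0
 },
 "KmEtS": {
  "value": 414.40740948670106,
  "lower_bound": 1e-05,
  "upper_bound": 100000.0
 },
 "k_EtG_urine": {
  "value": 0.0024879684263205454,
  "lower_bound": 1e-05,
  "upper_bound": 100000.0
 },
 "k_EtS_urine": {
  "value": 0.014152433882270748,
  "lower_bound": 1e-05,
  "upper_bound": 100000.0
 },
 "k_PEth": {
  "value": 0.13959486810293995,
  "lower_bound": 1e-07,
  "upper_bound": 1000.0
 },
 "k_PEth_clearance": {
  "value": 0.001460712263112933,
  "lower_bound": 1e-07,
  "upper_bound": 1000.0
 },
 "k_PEth_bind": {
  "value": 0.07805739912357477,
  "lower_bound": 1e-07,
  "upper_bound": 1000.0
 },
 "k_PEth_release": {
  "value": 0.002851044320061577,
  "lower_bound": 1e-07,
  "upper_bound": 1000.0
 }
}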