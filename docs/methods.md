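# Methods

## Model structure and units

The twin is a 26-state ODE system integrated in minutes.  Units are fixed
throughout: stomach volume in L; every other volume (blood, plasma, liver,
tissue water, bladder) in dL; ethanol and metabolite masses in mg;
concentrations in mg/dL; PEth in µmol/L.  The ×10 and /100 factors in the
volume formulas are L→dL conversions.

Personalisation enters only through four anthropometric inputs.  Blood
volume (L) is a per-sex cubic polynomial in height with a linear weight
term (male `0.3669·h³ + 0.03219·w + 0.6041`, female
`0.3561·h³ + 0.03308·w + 0.1833`); total body water (L) is the per-sex
linear form in age/height(cm)/weight divided by 0.84 (the scale maps the
classical lean-mass estimate onto the ethanol distribution volume used
here; its value is adopted as given, without a separate physiological
derivation); liver volume (dL) is `(18.51·w + 191.8)/100`.  The blood pool
splits 15 % central (breath-facing) / 85 % peripheral, and the peripheral
plasma fraction is the parameter `k_blood_plasma_ratio`.  For the two
reference subjects these formulas give 6.4 L blood / 66.2 L TBW (male,
106.6 kg) and 4.0 L / 37.4 L (female, 62.7 kg).

Gastric emptying is Michaelis–Menten in the stomach volume above its
1 mL residual (clipped at zero, which keeps the Michaelis term in its
domain and the volume above the residual), multiplied by a Hill-type
caloric inhibition `kcal_effect = Km^n / (x^n + Km^n)` with
`x = Kcal_Liquid/k_kcalscaling`, `n = n_kcal` and `Km = KmGastric`.  The
form is evaluated as written here rather than as `1 − x^n/(x^n+Km^n)`,
which loses all precision for large caloric loads.  At each drink start
the active caloric load `Kcal_Liquid` is reset to the calories still in
the stomach (`Kcal_remain`), which tracks inflow minus emptying.

One consequence of the fitted constants deserves emphasis: with
`KmGastric ≈ 0.81` and `k_kcalscaling ≈ 0.026`, the half-inhibition point
sits at ~0.02 kcal of liquid calories, so any caloric drink (beer, wine)
essentially freezes gastric emptying for the rest of the session, and the
simulated exposure from such drinks is minimal.  Zero-calorie beverages
(diluted spirits) are unaffected.  All internal calibration experiments in
this package therefore use the zero-calorie single-spirits protocol, where
the kinetics are informative; conclusions about caloric-drink scenarios
inherit this behaviour of the published parameter set.

The blood/liver/tissue/bladder couplings are linear exchanges
(`k_equalize`, `k_equalize_liver`, unit-rate tissue diffusion); hepatic
elimination is the sum of two Michaelis–Menten terms (ADH and CYP2E1) and
two conjugation channels (EtG, EtS) with first-order liver→blood transfer
and first-order urinary elimination.  Urine is carried as mass plus
volume; baseline urine production is 0.01 dL/min plus a diuresis term
`TissueExtraWater/Vasopressin · k_urine_water`, with vasopressin produced
at `k_basal/(1 + k_vasopressin_BAC·BAC)` and cleared first-order (its
alcohol-free steady state, `k_basal/k_clearance ≈ 580.9` model units, is
the initial value).  A urination event rescales all urine masses by
`0.05 dL / volume`, preserving concentrations exactly.

One printed-form ambiguity was resolved in favour of mass balance: the
urine-exchange term in the peripheral-blood equation is applied as a
division by the peripheral blood volume (concentration units), which makes
the blood→bladder flux exactly the negative of the bladder's mass gain.
The companion `0.01·BAC` baseline filtration term is kept as given.

### Carried-over minimal sub-models

Five sub-models are inherited from the earlier ethanol/PEth twin and are
not fully specified here; they are implemented as minimal, unit-consistent
forms, isolated in the `legacy` section of `model.py` so they can be
swapped against a reference implementation:

- **Stomach ethanol pool** — first-order exchange between dissolved
  stomach ethanol (mass form, `k_poolIn` on the dissolved mass,
  `k_poolOut` on the pool).
- **Stomach ADH** — Michaelis–Menten in the stomach ethanol concentration,
  `VmaxADHSto` interpreted as mg/min.
- **Solid meal calories** — meals feed `Kcal_Solid` uniformly over their
  duration with first-order clearance `k_food_clearance`;
  `MaxKcal_Solid` records the cumulative intake.  `km_kcal` from the
  parameter table belongs to this inherited machinery and is carried in
  the set but not referenced by the present kinetics.
- **Acetate** — production proportional to hepatic elimination
  (`k_acetate`, scaled into peripheral plasma) with a fixed first-order
  clearance of 0.1/min; reported in mM via the 1/10.2 mg/dL→mM factor.
- **PEth** — formation `k_PEth·BAC`, clearance `k_PEth_clearance`, and
  reversible binding (`k_PEth_bind`/`k_PEth_release`).  The absolute PEth
  scale is not calibrated here.

Food-present upregulation of hepatic elimination is exposed as a
multiplicative hook gated by `Kcal_Solid > 0` and defaults to 1 (off): no
kinetic form for it is published, so the package provides the switch
without inventing the kinetics.

The parameter table ships at full printed precision.  Two published
Michaelis constants (`KmGastric`, `KmADH`) lie outside their own search
bounds; validation warns rather than rejects, since the values are the
published estimates.

## Simulation

All events (drink block starts/ends, meal windows, urinations) are known
in advance, so the ODE is integrated segment-wise between event boundaries
(LSODA, rtol 1e-8 / atol 1e-10 by default) with hard restarts; drink-start
and urination updates are applied at the left edge of a segment, and the
stored state at an event time is the post-event value.  The output grid
defaults to 1-min spacing.  Eight auxiliary cumulative-flux states
(ingested mass, the five elimination channels, net tissue influx, voided
mass) are integrated alongside the physiology; the **mass audit** checks
`ingested = held + eliminated + voided` and closes to ~1e-8 relative on a
full dual-drink run (the tissue pool is audited by its cumulative influx
because its physical volume varies with the extra-water state).

## Estimation, χ² test, uncertainty

The cost is the SEM-weighted residual sum over studies, observables and
time points; a simulation failure yields an infinite cost with a
diagnostic rather than an exception, so global optimizers treat the point
as infeasible.  Degrees of freedom equal the number of data points (not
data minus parameters), matching the rejection test the cost is compared
against: the model is rejected only when the cost strictly exceeds the χ²
quantile at α = 0.05.

Search runs in log10 parameter space inside the published bounds (values
span ten decades), using scipy's differential evolution (default) or dual
annealing, always seeded.  Differential evolution's relative-tolerance
stop is disabled (it fires spuriously when the whole population sits high
on a plateau); the iteration budget is the stopping rule.  A `warm` init
option seeds the population around the starting vector (SD 0.5 decades)
for refit-from-a-credible-start workflows; the global Latin-hypercube init
remains the default.

Profile-style bounds relax the constraint `V(θ) ≤ T` into an L1 penalty
`|p̂| + |p̂₀|·(1 + V − T)` added to the objective when the constraint is
violated, and minimise `±p̂ + penalty` with the same seeded global
optimizer.  Because the feasible set is a neighbourhood of the feasible
start, the population is seeded around it, and the best feasible point
evaluated anywhere during the search is the one reported; accepted
constraint overshoot at a reported bound is 0.1 % of T.  On closed-form
toys this machinery reproduces the exact `V = T` crossings (quadratic
cost) and the analytic profile envelope of a weighted straight-line fit.

Prediction bands per time point are solved independently (the per-point
problems share nothing, so parallel and sequential evaluation agree).  For
multi-marker scenario work a cheaper **ensemble envelope** is provided:
seeded log-normal draws (SD 0.15 decades) around the best fit, filtered by
`V ≤ T`, with the band the pointwise min/max of accepted trajectories.  It
under-covers relative to per-point optimization but shares its semantics
and always contains the best-fit curve.

## Synthetic cohorts and what they do (not) show

The generator emulates the dual-drink study measurement protocol: blood
markers every 15 min, urine every 30 min, n subjects, additive Gaussian
noise, and SEM = SD/√n.  Defaults are stated assumptions, not literature
values: measurement SD is 5 % of each marker's simulated peak, and
optional inter-subject scatter is log-normal with 15 % CV on
`k_EtOHuptake`, `VmaxADH`, `VmaxEtG`, `VmaxEtS` (enzymatic variability is
the plausible driver of between-subject EtG/EtS spread; the true
magnitudes are unknown and these are placeholders).  Two SEM modes exist:
`sample` (the estimator a real study reports) and `known` (true σ/√n).
The recovery harness uses `known` so that the cost at the generating
parameters is exactly χ²(df), which is what its calibration check asserts
(mean cost/df ≈ 1 over replicates).

Because the data are generated by the model itself, passing recovery and
calibration checks demonstrates internal consistency and identifiability
under the stated designs — not fidelity to real cohorts, which contain
model error, non-Gaussian noise, censoring at assay detection limits and
reporting idiosyncrasies the generator does not emulate.  Detection-limit
truncation is available as a filter (EtS kept for t > 30 min, EtG for
t > 75 min, configurable per observable).

Calibration problem sizes were chosen to keep the full pipeline
desk-scale: recovery uses 20 seeded replicates of an ~84-point
single-spirits design with a 15-iteration warm-start optimizer; χ²
calibration uses 50 replicates of a 50-point design.

## Scenario discrimination

Two candidate schedules are compared through their per-marker uncertainty
bands on a common grid; the **deviation intervals** are the runs of grid
points, after the end of the last drink, where the (optionally
margin-expanded) bands are disjoint.  No standard quantitative threshold
for "distinguishable" exists, so strict band non-overlap is this package's
operationalisation, and reports say so; the margin parameter adds
conservatism (it can only shrink intervals).  The plausibility report
widens the band by 2·SEM of each sample before flagging it, so a sample is
called inconsistent only when its measurement uncertainty cannot bridge
the gap; the verdict is `consistent` when every marker keeps ≥ 95 % of its
samples inside, `indeterminate` with no samples.

Population sweeps reconstruct weight as BMI·height² over a full-factorial
grid (default ranges: age 20–80 y, BMI 18–32 kg/m², heights 1.5–1.8 m
female / 1.6–1.95 m male), with a seeded Latin-hypercube alternative.

## Known limitations

- The caloric-inhibition constant makes caloric-drink simulations nearly
  exposure-free under the published parameters (see above); treat such
  scenarios with caution.
- The five legacy sub-models are stated minimal forms; their constants'
  unit interpretations (notably `VmaxADHSto` and the PEth scale) are
  choices, not derivations.
- Ensemble bands under-cover; use per-point penalized optimization when a
  single marker's band is the quantity of interest.
- Band-based verdicts are not likelihood ratios and quantify no evidence
  strength; they are screening aids, not court-ready statistics.
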