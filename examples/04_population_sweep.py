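"""Population sensitivity: the same drink across body compositions.

A factorial grid of virtual subjects (age 20-80 y, BMI 18-32 kg/m²,
heights 1.5-1.8 m female / 1.6-1.95 m male) receives the identical
fixed-volume spirits challenge.  Total body water (TBW) — the effective
distribution volume of ethanol — orders the exposure: less body water,
higher peak blood alcohol.
"""

import warnings

import numpy as np

warnings.filterwarnings("ignore", message="parameter Km")
import alcotwin as at

params = at.ParameterSet()
schedule = at.build_wang_protocol(70.0)  # fixed 0.119 L drink for everyone
spec = at.PopulationSpec(grid_size=3, seed=0)

sweep = at.population_sweep(spec, schedule, params,
                            t_grid=np.arange(0.0, 361.0, 5.0),
                            options=at.SimOptions(rtol=1e-6, atol=1e-9))
print(f"{len(sweep)} virtual subjects\n")
print(f"{'sex':>7} {'age':>4} {'kg':>6} {'TBW (L)':>8} {'peak BAC':>9}")
for anthro, tbw, traj in sweep[:: max(len(sweep) // 9, 1)]:
    peak = traj.observables['yEtOH'].max()
    print(f"{anthro.sex:>7} {anthro.age:4.0f} {anthro.weight:6.1f} "
          f"{tbw:8.1f} {peak:9.2f}")

tbws = np.array([r[1] for r in sweep])
peaks = np.array([r[2].observables["yEtOH"].max() for r in sweep])
r = np.corrcoef(tbws, peaks)[0, 1]
print(f"\ncorrelation(TBW, peak BAC) = {r:.2f}")
print("The same drink hits smaller bodies (less TBW) harder — the model's")
print("behaviour is preserved across the population, shifted by body water.")
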