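horizon: 720.0
drinks:
- start: 0.0
  duration: 10.0
  volume: 0.2262357414448669
  EtOHConc: 0.05
  kcalLiquidPerVol: 440.0
  label: beer block 1
- start: 15.0
  duration: 10.0
  volume: 0.2262357414448669
  EtOHConc: 0.05
  kcalLiquidPerVol: 440.0
  label: beer block 2
- start: 30.0
  duration: 10.0
  volume: 0.2262357414448669
  EtOHConc: 0.05
  kcalLiquidPerVol: 440.0
  label: beer block 3
- start: 45.0
  duration: 10.0
  volume: 0.2262357414448669
  EtOHConc: 0.05
  kcalLiquidPerVol: 440.0
  label: beer block 4
- start: 60.0
  duration: 30.0
  volume: 0.2262357414448669
  EtOHConc: 0.2
  kcalLiquidPerVol: 0.0
  label: vodka second drink
meals:
- time: 0.0
  MealKcal: 300.0
  duration: 1.0
- time: 180.0
  MealKcal: 500.0
  duration: 1.0
urinate:
- 60.0
- 120.0
- 180.0
- 240.0
- 300.0
- 360.0
- 420.0
- 480.0
- 540.0
- 600.0
- 660.0
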