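horizon: 720.0
drinks:
- start: 0.0
  duration: 30.0
  volume: 0.119
  EtOHConc: 0.4
  kcalLiquidPerVol: 0.0
  label: spirits
meals:
- time: 0.0
  MealKcal: 500.0
  duration: 30.0
urinate: []
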