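{
 "sex": "male",
 "weight": 106.6,
 "height": 1.86,
 "age": 28
}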