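{
 "sex": "female",
 "weight": 62.7,
 "height": 1.69,
 "age": 22
}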