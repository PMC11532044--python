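name: hoaf30
rates:
  hydrogenated_oil_and_animal_fats: 0.30
pass_through: 1.0
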