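# Water-filled rubber ball (experimental validation case).
shell:
  R_mm: 25
  h_mm: 4
  rho: 1200
  nu: 0.45
  E_MPa: 4.8
filling:
  label: water
pressure:
  value: 13.7
  unit: kPa
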