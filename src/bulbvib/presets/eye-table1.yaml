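# Human eye baseline: corneoscleral shell with rigidity-derived moduli,
# vitreous-humor filling, physiological IOP.
shell:
  R_mm: 11.2
  h_mm: 0.5
  rho: 1077
  nu: 0.5
  rigidity_per_ul: 0.021
filling:
  label: vitreous
pressure:
  value: 15
  unit: mmHg
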