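## Conformational selection + binding + induced fit (HG3.17-style ligand binding)
## Rates in molar/second units unless a units key says otherwise.
name: cs_if_binding
species: [I, A, L, AL, ALs]
reactions:
  - "I -> A : k_ia"
  - "A -> I : k_ai"
  - "A + L -> AL : k_on"
  - "AL -> A + L : k_off"
  - "AL -> ALs : k_if"
  - "ALs -> AL : k_ir"
rate_constants:
  k_ia: 9.5e-4
  k_ai: 5.0e-5
  k_on: {value: 1.0, units: 1/uM/s}
  k_off: 4.4
  k_if: 0.5
  k_ir: 1.5
observables:
  bound:
    coeffs: {AL: 1.0, ALs: 1.0}
    baseline: 0.0
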