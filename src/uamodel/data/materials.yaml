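# Dielectric data for Hamaker-constant evaluation. For dielectrics,
# frequency is the dominant UV absorption frequency (Hz); for conductors it
# is the plasma frequency and the static dielectric constant is irrelevant
# (the zero-frequency difference factor is taken as 1).
materials:
  water:
    kind: dielectric
    dielectric: 78.4
    refractive_index: 1.333
    frequency: 3.0e15
  amino_acid:
    # generic side-chain analogue phase: protein-like optical response
    kind: dielectric
    dielectric: 4.0
    refractive_index: 1.50
    frequency: 3.0e15
  polystyrene:
    kind: dielectric
    dielectric: 2.55
    refractive_index: 1.557
    frequency: 3.0e15
  silver:
    kind: conducting
    dielectric: null
    refractive_index: 1.0
    frequency: 2.18e15   # plasma frequency, h*nu_p ~ 9.0 eV
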