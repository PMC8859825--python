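# Coarse-grained bead registry: one bead per residue / fragment, named in the
# CHARMM residue convention. charge in elementary charges at pH 7; radius is
# the effective bead radius in nm (from standard residue volumes via
# R = (3V/4pi)^(1/3)); material_id keys the dielectric database. Glycine has
# no side chain and binds through the alanine surface potential (pmf_name).
beads:
  ALA:    {charge: 0,  radius: 0.276}
  ARG:    {charge: 1,  radius: 0.347}
  ASN:    {charge: 0,  radius: 0.301}
  ASP:    {charge: -1, radius: 0.298}
  ASPP:   {charge: 0,  radius: 0.298}   # protonated aspartate
  CYS:    {charge: 0,  radius: 0.296}
  GLN:    {charge: 0,  radius: 0.326}
  GLU:    {charge: -1, radius: 0.321}
  GLUP:   {charge: 0,  radius: 0.321}   # protonated glutamate
  GLY:    {charge: 0,  radius: 0.243, pmf_name: ALA}
  HSD:    {charge: 0,  radius: 0.333}   # His, N-delta protonated
  HSE:    {charge: 0,  radius: 0.333}   # His, N-epsilon protonated
  HSP:    {charge: 1,  radius: 0.333}   # His, doubly protonated
  ILE:    {charge: 0,  radius: 0.343}
  LEU:    {charge: 0,  radius: 0.343}
  LYS:    {charge: 1,  radius: 0.344}
  LSN:    {charge: 0,  radius: 0.344}   # neutral lysine
  MET:    {charge: 0,  radius: 0.340}
  PHE:    {charge: 0,  radius: 0.358}
  PRO:    {charge: 0,  radius: 0.300}
  SER:    {charge: 0,  radius: 0.277}
  THR:    {charge: 0,  radius: 0.303}
  TRP:    {charge: 0,  radius: 0.380}
  TYR:    {charge: 0,  radius: 0.360}
  VAL:    {charge: 0,  radius: 0.323}
  # carbohydrate fragments (glycan residues)
  BGALNA: {charge: 0,  radius: 0.377}   # N-acetyl-beta-galactosamine
  BGLCNA: {charge: 0,  radius: 0.377}   # N-acetyl-beta-glucosamine
  BGLC:   {charge: 0,  radius: 0.330}
  BMAN:   {charge: 0,  radius: 0.330}
  AFUC:   {charge: 0,  radius: 0.318}
  BXYL:   {charge: 0,  radius: 0.305}
  # lipid head-group fragment
  DMP:    {charge: -1, radius: 0.306}   # dimethyl phosphate
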