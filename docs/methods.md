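# Methods

## Model and assumptions

The package computes the physisorption energy of a rigid protein on a
homogeneous nanoparticle (sphere or flat slab) in an implicit aqueous
medium. The protein is coarse-grained to one bead per residue; the bead is
placed at the centroid of the side-chain heavy atoms because the short-range
potentials describe *side-chain analogues* — the residue with its backbone
replaced by hydrogen — so backbone atoms carry no interaction terms. Glycine
has no side chain: its bead sits on Cα and borrows the alanine surface
potential. Protonation states are taken verbatim from residue names in the
prepared PDB (pH-7 convention: HSD is the default histidine tautomer, HSP is
the +1 form, ASPP/GLUP are neutral acids); there is no titration model, no
hydrogen placement, and no structural relaxation.

Key assumptions and their consequences:

- **Rigid body.** Conformational change on adsorption is ignored; the model
  is appropriate for proteins with small structural change on binding and
  will overestimate affinities when unfolding dominates.
- **Pairwise additivity.** The total energy is a sum of independent
  bead–surface terms; cooperative solvent effects are only included to the
  extent they are baked into the single-residue PMFs.
- **Implicit solvent and linearized electrostatics.** Ion correlations,
  image charges and pH shifts at the interface are not modeled.

## Energy terms

For a bead at surface separation h (SSD, NP surface to bead centre):

- **h < r_c**: tabulated PMF (PCHIP interpolation through the nodes; beyond
  the last node up to r_c the last value; below the first node a linear
  extrapolation with the slope at h_min, capped at +50 kT so Boltzmann
  integrals over overlapping states stay finite), plus a *core correction* =
  (dispersion with the full particle body) − (dispersion with a slab of the
  MD parametrization thickness, default 1.1 nm) at the same gap, plus
  electrostatics. Tables are zero-referenced so the mean over the last
  0.1 nm before r_c is 0; the branch-continuity test holds the residual jump
  at r_c below 0.25 kT.
- **h ≥ r_c**: Hamaker core dispersion (two-sphere closed form with centre
  separation R_NP + R_bead + h, or sphere–half-space for slabs), plus
  electrostatics U = z e φ_s e^{−κh} · R_NP/(R_NP + h).

Hamaker constants A_132 come from Lifshitz theory. For two dielectric phases
across a dielectric solvent the standard two-term approximation is used:
(3/4)kT Δ13(0)Δ23(0) plus the refractive-index dispersion term, with a
geometric-mean combination of unlike absorption frequencies. When the
particle material conducts (silver, plasma frequency hν_p ≈ 9 eV), no
two-term closed form exists, so the dispersion term is computed by numerical
quadrature of the Ninham–Parsegian single-oscillator spectral integral with
ε(iν) = 1 + (ν_p/ν)²; the implementation reproduces the textbook
metal–vacuum–metal limit A = 3hν_p/(16√2) to 0.1%. Whether h in the
dispersion term is measured to the bead centre or surface is a genuine
convention choice; the surface-gap convention (centre separation includes
the bead radius) is adopted so the term stays finite at all sampled h.

## Orientation and distance sampling

Orientations are parametrized by R_z(φ)·R_y(θ) applied about the protein
COM, sampled on a regular grid (default 5°×5°) with solid-angle weights
∝ sin θ in both averages — the unbiased measure on the orientation sphere.
For each orientation, U(z) is sampled from the first steric contact (all
beads at h ≥ the smallest tabulated separation) outward in 0.01 nm steps
until the total energy decays below 10⁻³ kT; the per-orientation energy is
the Boltzmann-weighted mean of the PCHIP interpolant of that profile with
measure dz (slab) or z²dz (sphere), evaluated by trapezoidal quadrature on a
uniformly doubled grid to a relative tolerance of 10⁻⁴. The z interval is
[first contact, decay distance] because separations below steric contact are
unphysical under the rigid model; the interval length is recorded per
orientation. The 0.01 nm z-step was chosen so that the engine agrees with a
direct one-bead Boltzmann integral to better than 10⁻³ kT, and halving the
orientation grid spacing changes E_ads^B by < 2% on the test fixtures.

E_ads^A is the weighted arithmetic mean of the orientation map; E_ads^B uses
canonical weights P_kl ∝ w_kl e^{−E_kl/kT} (computed with a max-shift to
avoid overflow), so E_ads^B ≤ E_ads^A always. Facet-resolved energies are
combined as a weighted arithmetic mean, equal weights by default. Internal
energies are in kT at the medium temperature (default 300 K); conversion to
kJ/mol at I/O boundaries uses the fixed constant kT(300 K) = 2.494 kJ/mol.

The lowest-energy pose is the orientation-grid node with the deepest
z-profile minimum (ties broken deterministically by ascending θ then φ
index), refined by bounded 1-D minimization in z; contacts are residues
within 0.5 nm of the surface.

## Descriptors

Immersion enthalpy ΔH_imm = (H_slab+liquid − H_slab − H_liquid)/A in
kJ/(mol nm²); when time series are supplied, means carry block-average
standard errors (block doubling until the estimate changes < 5% across two
doublings). The hydrophobicity descriptor is
log P^NM = (ΔH_imm,water − ΔH_imm,octanol)/(RT ln 10) at T = 298.15 K,
positive for lipophilic surfaces. This form reproduces the published silver
(110) and (111) facet values from their printed enthalpies to better than
1% (14.42 vs 14.49 and 18.11 vs 18.13). For Ag(100) the same enthalpies
give 1.80, not the published 6.04; this inconsistency in the source data
could not be resolved from the printed values, so the (100) entry is
retained in the packaged table for completeness but excluded from validation.

PMF summaries report the interpolated global minimum E_min and
ΔF_ads = −kT ln[(1/L)∫ e^{−F(h)/kT} dh] over the sampled range L — a
flat-bulk-referenced bound-state weighting; other binding-constant
conventions (e.g. with an explicit bound-state cutoff) would shift absolute
values but not rankings. Pearson correlations use the t-transform two-sided
p-value; rankings are ascending in energy with lexicographic deterministic
tie-breaks and optional position-agreement/Kendall-τ statistics against a
reference ordering.

## Synthetic data

The atomistic PMF parametrization set for silver is an external dataset and
is not redistributed; tests and demonstrations use a synthetic generator
that emulates the documented shape of those profiles: a steep repulsive wall
(decay length 0.012 nm), Gaussian adsorption minima at the hydration-layer
positions 0.2 and 0.47 nm (width 0.05 nm), an optional barrier between them,
optional seeded noise, and a smooth taper to exactly zero at
r_c = 1.0–1.2 nm. Default well depths (−4, −2 kT) sit in the middle of the
single-residue range for silver facets (roughly −1 to −10 kT). The generator
is deterministic for a fixed seed and recovers its own parameters (well
depth to 0.01 kT).

What the synthetic tables do *not* emulate: facet- and residue-specific well
structure, charged-residue asymmetries, and the absolute energy scale of the
real parametrization. Passing tests therefore demonstrate the correctness of
the machinery (interpolation, integration, averaging, pose extraction) and
its physical invariants — not the accuracy of absolute adsorption energies
for real proteins on silver, which requires the external PMF set. The
benchmark correlation and ranking checks run on the published per-protein
energy table shipped with the package.

## Numerical choices and degenerate inputs

- Extrapolation wall cap +50 kT (far above any sampled barrier).
- Overlapping beads (h ≤ 0) contribute the capped wall energy rather than
  raising, so orientation scans never abort mid-grid.
- Zero ionic strength returns κ = 0 with an "unscreened" warning flag.
- Matched Lifshitz media give A = 0 exactly; a conducting solvent is
  rejected.
- Quadrature: profile averaging refines to rel. 10⁻⁴; the Lifshitz spectral
  integral uses an adaptive tangent-substitution quadrature.
- Determinism: no randomness anywhere in the engine; generators and reports
  are seeded and byte-stable.

## Known limitations

Rigid protein (no unfolding or side-chain repacking), no image-charge /
polarization corrections, no pH response, no coated or capped particles, no
cylinder geometry, no multi-protein competition or corona kinetics. The
absolute energy scale of E_ads^B is known to be large compared to measured
ΔG_ads — the canonical average includes all optimized side-chain
arrangements, many of which are unreachable in a real constrained protein —
so E_ads values should be used as relative descriptors (rankings,
correlations), not as binding free energies.
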