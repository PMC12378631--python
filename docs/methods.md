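# Methods

## Scope and model

`contactsar` implements a contact-occupancy → PLS structure–activity
analysis for protein–ligand MD trajectories. The statistical model is
PLS1: the response y is pIC50 = −log₁₀(IC50 in mol L⁻¹); the predictors
are per-contact occupancy percentages, one column per collapsed contact
definition, one row per ligand (replicates averaged by default). The
model assumes the potency differences across a congeneric series are
(partly) linear in how persistently each binding-site contact is formed;
it makes no claim about interaction energetics, only about covariance
between contact persistence and potency.

## Contact definitions

**Candidate enumeration.** A ligand-heavy/protein-heavy atom pair is a
candidate if its distance is ≤ 4.0 Å in at least one sampled frame.
Sampling is every frame by default; a coarser stride is available (and
recorded in provenance) for very long trajectories, but occupancy is
always computed over all frames of the trajectory.

**Filtering.** Hydrogen-bond capability is element-based: both atoms in
{N, O, S}. No donor/acceptor geometry or angle criteria are applied —
the fingerprint deliberately counts *potential* hydrogen bonds at
heavy-atom resolution. π-stacking candidates are ring-pairs (annotated
ligand rings × PHE/TYR/HIS/TRP side-chain templates) whose centroid
distance dips to 6.0 Å or below; this is a permissive superset, since the
final statistic is governed by the per-type occupancy cutoff.

**Equivalent-atom collapsing.** Distances to the two oxygens of a ligand
carboxylate are replaced by one distance to the carboxyl carbon;
distances to NE/NH1/NH2 of one arginine are replaced by one distance to
its CZ. When both rules hit the same pair the result is a single
salt-bridge contact C_COOH↔CZ — never two half-collapsed contacts. The
collapse keeps a surjective audit map from every filtered atom pair to
its collapsed contact. Residue-side carboxylates (ASP/GLU, C-termini)
are annotated but not collapsed; contacts to them remain atom-to-atom
unless the ligand side collapses (matching the convention that the
ligand's carboxylate is the group of interest).

**Cutoffs.** Default per-type occupancy cutoffs: hydrogen bond 3.5 Å
(heavy-atom), collapsed carboxylate/guanidinium and salt bridge 5.0 Å
(representative–representative distances are systematically longer than
the underlying O⋯N distances), ring-centroid π-stack 5.5 Å. These are
conventional geometric criteria, exposed in the configuration and logged
in every run report. A distance exactly equal to a cutoff counts as
in-contact (≤); the tie rule is fixed and documented in the run report.

## Occupancy and aggregation

Occupancy is 100 × (#frames at/below cutoff)/(#frames). Replicates are
averaged per ligand by default ("mean" policy); a "concat" policy that
keeps each replicate as a row is available for sensitivity analysis. A
contact never enumerated for a ligand was never within the candidate
cutoff, so its occupancy is filled as 0% rather than treated as missing.
Smoothed trend summaries use a centred rolling mean with truncated
windows at the edges; the fluctuation band is ±1 rolling *population*
standard deviation (ddof = 0, so a window of one frame has zero band).
Window default: 51 frames.

## PLS

PLS1 is fitted by NIPALS, implemented in the package so the fit is fully
inspectable: X columns are mean-centred and by default scaled by their
sample standard deviation (ddof = 1, matching common chemometrics
autoscaling); zero-variance columns get scale 1 and receive exactly zero
weight. Components extract unit-norm weight vectors w ∝ Xᵀy on the
deflated block; scores are mutually orthogonal; coefficients are
β = W(PᵀW)⁻¹q, reported on both the standardized and the raw scale.
With as many components as the centred predictor rank, the fit equals
OLS; the test suite verifies agreement with an independent reference
implementation to 10⁻⁸. The default component count is min(2, n−1); the
choice is logged, not asserted as canonical. With fewer than six ligands
the run report carries an explicit small-sample warning — the model is
then severely underdetermined and coefficient magnitudes (though often
not their signs) are fragile.

The response is whatever affinity the ligand table provides as
`ic50_nM`; the run report records that pIC50 was derived from that
column, so a user substituting e.g. a Ki-derived value can see the choice
in the log.

## Synthetic-complex generator

The generator emulates the study design the analysis is meant for:
several ligands × 3 replicates per ligand, each replicate a trajectory of
a ligand bound in a pocket, with a nominal simulated length of 500 ns per
replicate (1.5 µs per ligand) carried as metadata. Defaults: 8 ligands,
3 replicates, 2000 frames per replicate — sized so the full pipeline runs
in seconds; a 4-ligand preset mirrors the small published series and
demonstrates the small-sample warning.

Geometry is schematic: a ligand with a carboxylate, an amide-nitrogen
surrogate and a hexagonal ring, plus one arginine per salt-bridge
program, a tyrosine ring per π program, and static control residues (a
glutamate hydrogen bond pinned at 100% occupancy, an arginine facing the
amide nitrogen and a serine hydroxyl facing the carboxylate, exercising
the guanidinium-only and carboxylate-only collapse rules at constant
occupancy). Only inter-group distances carry information; nothing is
physical. Each programmed contact follows a two-state Markov chain with
stationary bound probability equal to its target occupancy and total
switching rate 0.5 per frame (fast-switching, so realized occupancy
concentrates tightly: sd ≈ √(π(1−π)·3/n)). In the bound state the
governing distance sits at d_on plus clipped axial noise (sd 0.1 Å,
clipped at ±0.3 Å), in the unbound state at d_off; spec validation
enforces a separation margin between both distances and the cutoff that
covers the worst-case axial noise plus the (4σ-clipped, sd 0.02 Å)
per-atom jitter, so occupancy equals the bound-state fraction exactly.
Potencies are pIC50ᵢ = intercept + Σⱼ βⱼ·occupancyᵢⱼ + ε,
ε ~ N(0, 0.2²), with planted β = −1.5 for the ARG929-like salt bridge and
+1.5 for the ARG439-like one; target occupancies form a crossed two-level
design (0.1/0.2 vs 0.8/0.9) so the two planted columns are nearly
orthogonal. All randomness derives from the spec seed via per-(ligand,
replicate) substreams; identical specs yield byte-identical files.

What passing tests on this generator do **not** show about real data:
real contacts are not two-state, occupancies are correlated across
contacts and far from a designed layout, trajectories have autocorrelated
collective motions, and real series are tiny (n = 4 in the motivating
study) with unknown noise — sign recovery at n = 8 with a planted
near-orthogonal design is a best-case validation of the machinery, not a
statement about statistical power on real series.

## File formats and numerics

Topologies and trajectories are fixed-column PDB (multi-model
MODEL/ENDMDL for trajectories), parsed via biotite with a validation
layer that reports per-model atom-count mismatches by model number;
writing uses an in-repo formatter with 3-decimal coordinates so
write→read round-trips are exact at PDB precision. Coordinates are
Cartesian Å with no periodic-boundary handling (inputs are assumed
binding-site-centred post-processed trajectories). Residue numbers are
preserved verbatim so crystal-structure labels (ARG929, ARG439, TYR961)
round-trip. Ligand detection defaults to HETATM records excluding
solvent/ions, overridable by residue name.

Monoisotopic masses use a curated table (¹H 1.00782503, ¹²C 12 exactly,
¹⁴N 14.00307401, ¹⁶O 15.99491462, ³²S 31.97207069, plus P and halogens);
[M+H]⁺ "calcd" values are reproduced by summing neutral-atom masses of
the protonated formula, electron mass ignored, matching standard
organic-chemistry practice. Fold ratios round half away from zero, the
conventional reading of "n-fold higher".

## Problem sizes used in validation

Enumeration is cross-checked against an exhaustive all-pairs scan on 100
random 10–30-atom pockets; Markov occupancy recovery uses 10⁵ frames at
five stationary targets (tolerance ±1 percentage point); PLS is compared
with the reference implementation on 50 random small matrices; sign
recovery runs the full in-memory analysis chain on 20 independently
seeded datasets at the default size; bit-level determinism of `run-all`
is checked on a reduced 4-ligand × 2-replicate × 300-frame dataset, since
bit-stability does not depend on size.

## Known limitations

- No hydrogen-bond angles, cation–π, halogen bonds, hydrophobic contacts
  or water-mediated bridges; the fingerprint is a heavy-atom distance
  fingerprint by design.
- No cross-validated component selection, VIP scores or permutation
  tests; with the intended series sizes these would be decorative.
- DCD/XTC trajectories are out of scope for the core; the supported,
  bit-tested dialect is multi-model PDB.
- The generator's pocket supports at most two programs per contact type
  (directions are allocated on fixed axes to guarantee non-interference).
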