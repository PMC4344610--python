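# Methods

This note documents the models and numerical choices behind glyconf: what
is computed, under which assumptions, with which defaults, and what the
synthetic-data generator does and does not emulate.

## Torsion definitions and conventions

A glycosidic linkage between a glycosylating residue (anomeric carbon C1)
and an aglycon carbon Cx is parameterized by

    φ = H1–C1–O–Cx        ψ = C1–O–Cx–Hx

the proton-based convention used in NMR work because both torsions are
then directly connected to measurable trans-glycosidic ³J(C–H) couplings.
Angles are degrees at every API boundary, in (−180°, +180°], with the
IUPAC sign convention (cis = 0°, positive by the right-hand rule about
the central bond, verified against MDAnalysis and biotite). ±180° are the
same point on the circle and are treated as equal wherever angles are
compared; all angular distances are circular, because the "inverted"
conformer region straddles the boundary. Dihedrals are computed with the
standard double-cross-product/atan2 formula; near-collinear triples
(cross-product norm < 1e−10) raise a degenerate-geometry error rather
than returning an ill-conditioned value. A documented consequence of the
convention: the torsion is invariant under reversal of the atom order,
τ(A,B,C,D) = τ(D,C,B,A), and flips sign under improper (mirror)
transformations only.

## Karplus couplings

J(θ) = A·cos²θ + B·cosθ + C. Coefficients are configuration data, not
constants: named sets live in a YAML table and callers may register
alternates. The shipped default `tvaroska1989` (A = 5.7, B = −0.6,
C = 0.5 Hz) is the standard parameterization for C–O–C–H coupling
pathways in glycosides.

The ensemble prediction is the uniform (optionally weighted) snapshot
average ⟨J(θ)⟩. Averaging J rather than θ is essential: for a bimodal
torsion distribution J(⟨θ⟩) can be off by far more than the experimental
error, and the test suite contains a discriminating case where the two
differ by > 0.2 Hz. Uniform weights are the default because constant-
temperature trajectories sample the equilibrium distribution directly; no
additional Boltzmann re-weighting of snapshots is applied.

Experiment comparison pairs rows by (compound, linkage, torsion kind),
computes absolute deviations and flags rows within a tolerance that
defaults to 0.5 Hz — the uncertainty of J-HMBC-measured ³J(C–H). The
headline statistic is the mean absolute deviation (MAD), reported
unrounded and conventionally quoted at 2 decimals (1 decimal for coupling
values, matching how such tables are printed). The packaged coupling
table for FCS-fragment compounds 1–5 gives MAD = 0.34 Hz for the
continuum-solvation predictions (14 pairs, within experimental error),
0.84 Hz in vacuo and 0.29 Hz for explicit water.

## Relative NOEs

The isolated two-spin approximation is used: cross-relaxation between a
proton pair scales as ⟨r⁻⁶⟩ over the ensemble, so

    NOE(pair) / NOE(ref) = ⟨r_pair⁻⁶⟩ / ⟨r_ref⁻⁶⟩

with the reference pair (H1 of the glycosylating residue to the linkage
proton Hx) normalized to exactly 1. No relaxation matrix, spin diffusion
or mixing-time dependence is modelled; the approximation is appropriate
in the linear regime of the NOE build-up, which should be verified
experimentally for the mixing time used. Observed absence of a cross-peak
is encoded as literal intensity 0. `flag_incompatible_noes` reports pairs
predicted at or above a threshold but observed absent (and the converse);
the threshold defaults to 0.05, the largest predicted relative intensity
still treated as consistent with absence, and is configurable. Distances
are Å; intensities dimensionless. An equilibration-discard option exists
for coordinate ensembles but defaults to 0, since supplied trajectories
are normally production-only.

## Conformer states and populations

States are *declared* circular regions, not discovered clusters — this
matches how linkage conformers are named in practice and keeps
classification deterministic. A state has a (φ, ψ) center and a
per-coordinate circular acceptance radius (default 35°). A snapshot is
assigned to the nearest containing state by combined circular distance
√(Δφ² + Δψ²); exact ties go to the earlier-declared state; snapshots
outside every region are "unassigned". The default taxonomy is
I = (30°, +40°), II = (30°, 0°), III = (30°, 180°): with a 35° radius the
I and II boxes meet at ψ = 20°, where the nearest-center rule gives an
unambiguous midpoint boundary. "−0°" center notation in source data is
read as 0°. Populations are exact counts/fractions with an explicit
unassigned bucket.

## Conformational maps

`scan` performs rigid (single-point) dihedral driving of a user-supplied
energy function E(φ, ψ) on a uniform grid covering [−180°, 180°) once per
step (default 10°, 1296 points). No relaxation of other degrees of
freedom is attempted — the result is deliberately a rough estimate of the
potential-energy surface; pluggable energy functions let users substitute
anything better. The function must be deterministic and 360°-periodic
(spot-checked at the grid edges). Energies are shifted so the global
minimum is exactly 0; only relative energies are meaningful. Minima are
grid-local under strict 8-neighbour comparison with periodic wrapping, no
sub-grid interpolation, reported within a 5 kcal/mol window by default.
Boltzmann fractions use R = 0.0019872 kcal/(mol·K) at 298 K by default.
Two toy potentials ship for testing: a single well at (30°, 40°) and a
two-well potential (exo-anomeric-like cosine on φ, double-well cosine on
ψ) with analytic minima at (30°, 40°) and (30°, −140°), ΔE = 3 kcal/mol.

## Ensembles and I/O

Coordinate ensembles are read from multi-frame XYZ and multi-MODEL PDB
through MDAnalysis; torsion tables (CSV: frame, phi_deg, psi_deg) are a
first-class input so the coupling/conformer pipeline runs without any
coordinates. NOE prediction requires coordinates and raises a capability
error on torsion-only input. Native binary trajectory formats (DCD/XTC/
TRR) and engine-specific archives are intentionally out of scope: users
export to the universal text formats, keeping the analysis layer
engine-agnostic. Atom ids come from the XYZ name column or PDB atom
name (+ residue id when names repeat). Because trajectory readers
silently drop a truncated trailing frame, a structural pre-check turns
truncation into an explicit parse error naming the frame.
`SimulationPlan` does the sampling bookkeeping: a 20,000 ps run sampled
every 2 ps yields 10,000 snapshots; an equilibration prefix (default 0)
is subtracted before the division.

## Synthetic ensembles

The generator emulates the statistical structure the analysis assumes:
i.i.d. draws from a mixture of localized states, each a wrapped-Gaussian
component on the torus. Wrapped Gaussians were chosen over von Mises
because at the spreads of interest (≤ ~35°) the two are practically
indistinguishable and the Gaussian is trivially invertible in tests.
Defaults: spread 8° in both φ and ψ — the exo-anomeric effect pins φ
tightly, and ψ clusters 40° apart are well resolved in conformational
scatter plots, which requires σ well under half the separation. All
randomness flows through one explicit seed.

What the generator does **not** emulate: temporal correlation (frames are
i.i.d., real MD is autocorrelated), intra-ring flexibility (frames are
rigid idealized fragments), anharmonic/skewed basin shapes, and any
energetics. Passing tests therefore demonstrate the correctness of the
averaging, classification and normalization machinery — not the realism
of any force field or solvent model.

Presets encode qualitative population patterns seen across solvent
treatments of Fuc(1→3)GlcA-like linkages: `fuc_gla_sasa_like`
(I/II/III = 0.75/0.20/0.05, a trace of the inverted conformer, as
continuum-solvation models tend to retain), `fuc_gla_water_like`
(0.80/0.20/0.00 — the inverted conformer disappears) and `fuc_fuc_like`
(0.80/0.20, two states only, rotation being more hindered). These weights
are synthetic choices consistent with the qualitative descriptions, not
measured populations, and are labelled as such in the API docs.

## Idealized fragment geometry

`build_fragment` converts (φ, ψ) into Cartesian coordinates of a minimal
five-atom linkage fragment (H1, C1, O, Cx, Hx) plus extra sites placed by
fixed internal coordinates: pseudo ring carbons C(x−1)/C(x+1) attached to
Cx at ψ ∓ 120°, each carrying one proton. Bond lengths C–H 1.09 Å,
C–O 1.43 Å, C–C 1.53 Å; tetrahedral angles at carbon, 117° at the
glycosidic oxygen. The proton torsions are chosen so the H1⋯H(x+1)
contact is short (≈1.8 Å) only in the inverted ψ ≈ 180° state and long
(≈4.4 Å) in states I/II — reproducing the qualitative NOE signature by
which inverted conformers betray themselves — while H1⋯H(x−1) stays
moderate in all states. Only relative quantities (torsions, distance
ratios) are consumed downstream, so the idealization is harmless there;
absolute distances from these fragments should not be quoted.

## Numerical choices and degenerate inputs

- Round trips: build_fragment → torsion extraction is the identity to
  ≤ 1e−6° over a full 36×36 grid (measured ~1e−14°).
- Oracle checks: the dihedral agrees with an independent axis-projection
  construction to ≤ 1e−9°; ⟨r⁻⁶⟩ agrees with a naive per-frame loop to
  1e−12 relative.
- Empty ensembles, zero interproton distances, non-finite angles,
  negative weights, steps not dividing 360°, orphaned comparison rows and
  missing atoms all raise typed errors naming the offending entity.
- Output CSVs use fixed 4-decimal float formatting and a comment header
  with the package version and a config hash, making re-runs
  byte-identical for identical inputs and seed.

## Problem sizes

Stochastic validations use n = 10,000 frames (matching the sampling plan
above) with fixed seeds and 3-standard-error / binomial 3σ bounds;
end-to-end NOE scenario checks use 2,000-frame coordinate ensembles,
ample for intensity contrasts of the size involved (0.27 vs 0.02). The
acceptance script regenerates everything in a few seconds.

## Known limitations

- The two-spin NOE model ignores spin diffusion; quantitative NOE work at
  long mixing times needs a relaxation-matrix treatment.
- Declared-region classification does not discover unexpected conformers;
  inspect the φ/ψ scatter (the time-series CSV) before trusting an
  "unassigned" fraction of zero.
- The rigid grid scan has no geometry relaxation, so barrier heights are
  upper bounds and map details are qualitative.
- The fragment builder is not a sugar-ring builder: no ring pucker, no
  exocyclic rotamers, no force-field energies.
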