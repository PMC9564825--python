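# Methods

This note records the model behind the synthetic generator, the estimators
implemented in `mtlattice.geometry`/`annotate`, the numerical conventions,
and known limitations. Units are ångström (Å) and degrees unless stated;
reported periodicities are in nm (1 nm = 10 Å).

## 1. Synthetic lattice model

### Geometry

A singlet microtubule is modelled as `n_pf` protofilaments of αβ-tubulin
dimers on a cylinder:

- protofilament *i* sits at azimuth φ_i = s·2πi/n_pf (handedness sign
  s = −1 by default, giving a left-handed 3-start lateral helix when viewed
  with +z up) at radius `radius` (default 105 Å);
- each dimer has rise `dimer_rise` (default 80 Å = 8 nm); the monomer
  length is `dimer_rise/2` (40 Å);
- successive protofilaments are shifted axially by the 3-start stagger
  δ = `n_starts`·monomer_len/n_pf (9.2308 Å at 13 pf). If
  n_pf·δ is not an integer multiple of the monomer length the closure
  mismatch is redistributed and a warning is emitted;
- the lattice closes with exactly one heterotypic (A-lattice) seam. The
  generator builds the geometric seam between positions n_pf−1 and 0 and
  rotates protofilament labels so the seam falls at interface
  `seam_index` (default n_pf−1).

Doublets add an incomplete B-tubule: a 10-protofilament arc of the same
lattice centred at (2r+10, 0) relative to the A-tubule axis, labelled
B01–B10. This is a geometric stand-in for the real junction (no junction
protein chemistry is modelled); its purpose is to exercise open-arc
annotation and per-protofilament span selection.

### Pseudo-atom dimers

Each monomer is a deterministic Gaussian ellipsoid point cloud
(σ = 9 × 6.5 × monomer_len/3.2, default 80 atoms/monomer), exactly centred
and rotated so its longest principal axis is exactly longitudinal. α and β
monomers carry marker residue names `TBA`/`TBB`; annotation does not rely on
these (it also classifies by residue multiplicity and size) but the tests
use them as ground truth. Chain ids encode tubule/pf/role/axial index
(`S01a00`); the annotator is tested with these labels hidden as well.

### MIP decoration

`decorate_mips` places rod-shaped pseudo-protein copies in one of two modes:

- `lateral_interface` (default): one copy per decorated lateral interface
  per axial period, anchored at the lumen-ward midpoint of the two flanking
  dimer mass centres, with its axis tilted `tilt` (default 51.5°) out of the
  local lattice plane (least-squares plane of the two flanking dimers).
  Default span is `all_non_seam`; an explicit request to decorate the seam
  raises. With the default period of one dimer rise this yields 12 copies
  per 8-nm repeat on a 13-pf tubule, arranged as a left-handed,
  seam-interrupted spiral.
- `longitudinal_filament`: one continuous rod per protofilament groove.

Copy placement is computed in a local frame derived from the lattice, so the
lattice screw symmetry maps copies onto each other exactly: pairwise RMSD
between undecorated copies is ~1e-13 Å, giving a true zero baseline for the
conformational-spread estimator. Decoration periods must be integer
multiples of the monomer length.

### What the generator does *not* emulate

- Atomic chemistry: pseudo-atoms are all carbon-like spheres; no side
  chains, secondary structure or junction proteins.
- Realistic packing density. The clouds are far sparser than real protein,
  so Shrake–Rupley burial between a MIP rod and tubulin is ≈ 0 Å² on
  synthetic data. Interface-area code is therefore validated on analytic
  constructions (single sphere, two-sphere cap) and against biotite, not on
  the generator; on synthetic data MIP↔α association falls back from
  "largest buried area" to nearest mass-centre distance (ties broken by
  lower pf index, then lower axial index).
- B-tubule junction geometry beyond an open arc.

## 2. Estimators

### Tubule axis

PCA of chain mass centres is **biased** on a 3-start lattice: the stagger
correlates azimuth with z, tilting the leading principal component by ~7.7°
at default geometry (enough to break copy counting entirely). The axis is
therefore refined as the normalised, sign-aligned mean of nearest-neighbour
mass-centre steps: each monomer's nearest neighbour is its longitudinal
neighbour (40 Å) rather than a lateral one (~51 Å), so the mean step is
purely longitudinal. Exact on synthetic data; on real models this assumes
rise < lateral spacing, which holds for microtubules.

### Protofilament clustering and seam

Chains are clustered by azimuthal gaps (with `n_pf` as an optional hint;
otherwise a threshold of half the largest gap). Per lateral interface, each
monomer's nearest monomer on the neighbouring protofilament is found; a
contact is counted only if the axial offset is below 0.75× the median
longitudinal monomer spacing (gating out pf-end monomers without a true
lateral partner). The seam is the unique interface with heterotypic fraction
> 0.5; zero or multiple candidates raise an error listing all fractions.
Open arcs return no seam. Unlabeled closed tubules are renumbered
seam-anchored: pf 0 immediately follows the seam in the rising-stagger
direction, so the seam is interface n_pf−1.

### Spiral statistics

MIP copies are grouped into axial **columns** by single-linkage clustering
of their axis-perpendicular projections (cutoff 6 Å). Periodicity is the
median of per-column consecutive z-spacings (error if no column has ≥ 2
copies — "periodicity undefined"). Copies-per-repeat counts copies whose z
falls in one half-open window of length one period centred mid-lattice.
Handedness takes azimuth-adjacent column pairs, computes the signed Δz of
nearest copies over the signed Δφ, and reports the sign of the median slope
(`none` if median |Δz| < 0.5 Å). Tilt is 90° minus the angle between the
copy's largest principal component and the local lattice-plane normal,
folded to [0°, 90°].

### Superposition and spread

Kabsch superposition via SVD with the det = +1 correction; rotation angle
arccos((tr R − 1)/2). Note the arccos is sqrt-sensitive near identity:
machine epsilon in the trace appears as ~1e-6 degree, which is the floor for
"zero" angles. Conformational spread superposes the α-tubulin associated
with each copy, applies that transform to the copy, and reports pairwise
RMSD over atoms paired by residue number and atom name.

### SASA

Shrake–Rupley with 960 Fibonacci-sphere points per atom, probe 1.4 Å, vdW
radii C 1.70 / N 1.55 / O 1.52 / S 1.80 / P 1.80 / H 1.20 (unknown elements
use 1.70 with a warning). Validated to 1 % against 4π(r+p)² for a lone atom
and 2 % against the spherical-cap closed form A = 2πRh, h = R − d/2 for two
equal spheres; cross-checked against biotite within 2 %.

### Orientation tables

RELION ZYZ convention, R = R_z(rot)·R_y(tilt)·R_z(psi), angles in degrees
wrapped to (−180°, 180°], tilt in [0°, 180°]. Worked example:
rot = tilt = psi = 90° gives

```
R = [[-1 0 0]
     [ 0 0 1]
     [ 0 1 0]]   (columns: images of x, y, z)
```

Inverse extraction: tilt = arccos R[2,2]; rot = atan2(R[1,2], R[0,2]);
psi = atan2(R[2,1], −R[2,0]); at tilt = 0 or 180° (gimbal) rot is set to 0
and the full in-plane rotation assigned to psi. Register corrections
compose as M′ = M·R_axis(Δφ) with origin′ = origin + Δs·(M·axis); angle
columns are rewritten at 1e-6 degree precision, non-orientation columns are
preserved verbatim.

## 3. Problem sizes and tolerances

- Default validation lattice: 13 pf × 6 repeats × 160 atoms/dimer
  (~25 000 tubulin atoms, 72 MIP copies); full fit with areas and RMSD ≈ 6 s
  on one CPU. Parameter-recovery tests use reduced lattices (24
  atoms/monomer, 4 repeats) over n_pf 11–15, rise 78–84 Å, tilt 0–75°,
  period 1–6 dimer rises.
- Recovery tolerances: rise 0.1 Å; inter-pf angle 0.1° of 360/n_pf; tilt
  0.5°; periodicity and copy counts exact; seam exact in all grid cells.
- Float-noise floors: near-identity rotation angles 1e-5° (arccos floor);
  orientation-table round trips 5e-6° (same floor after 1e-6-degree angle
  formatting).

## 4. Limitations

- Interface areas on synthetic data are not meaningful (sparse clouds, see
  above); use real atomic models for burial-based association.
- The annotator assumes a roughly straight tubule; strongly curved or
  fragmented tubules would violate the single-axis model.
- The B-tubule is a geometric arc; inter-tubule (junction) interfaces are
  not analysed.
- Seam detection requires at least ~2 repeats; single-repeat lattices are
  degenerate (every monomer is a pf-end) and are rejected rather than
  guessed at.
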