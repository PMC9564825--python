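# mtlattice

Quantitative lattice analysis of microtubule inner proteins (MIPs) in
atomic models of ciliary microtubules.

Cryo-EM models of singlet and doublet microtubules show small proteins
bound to the lumenal wall in regular helical patterns. Interpreting such
models requires answering bookkeeping questions precisely: how many
protofilaments, where is the seam, what is the axial rise, how many MIP
copies decorate one 8-nm tubulin repeat, with what periodicity, handedness
and tilt, and how conformationally uniform are the copies. `mtlattice`
computes these descriptors from coordinates alone, ships a ground-truth
synthetic lattice generator to validate every measurement, and includes a
tool to correct per-class lattice-register misassignments in single-particle
orientation tables.

## What it computes

Given a 13-protofilament microtubule of radius *r* with dimer rise Δz and a
3-start helical stagger δ = 3·(Δz/2)/n_pf per lateral step:

- **Protofilament indexing and seam detection.** Chains are clustered by
  azimuth about a fitted tubule axis. The seam is the unique lateral
  interface whose nearest-monomer contacts are heterotypic (α facing β);
  all other interfaces are homotypic.
- **Lattice spacings.** Consecutive dimer mass-centre distances along each
  protofilament (the axial rise, ≈ 8 nm), and the inter-protofilament
  angle θ = ∠(c_i − a, c_j − a) about the axis point *a*, which for a
  closed tube of n_pf protofilaments must average 360°/n_pf.
- **MIP spiral statistics.** Copies per 8-nm repeat, axial periodicity from
  per-column consecutive z-spacings, handedness from the sign of dz/dφ
  between azimuth-adjacent columns, and tilt of each copy's long principal
  axis relative to the local lattice plane.
- **Interface areas.** Shrake–Rupley solvent-accessible surface areas with
  buried area A_int = (SASA(A) + SASA(B) − SASA(A∪B)) / 2.
- **Conformational spread.** Kabsch (SVD) superposition of the α-tubulin
  subunit associated with each MIP copy, then RMSD between the co-transformed
  copies; the rotation angle is recovered as arccos((tr R − 1)/2).
- **Register realignment.** RELION-convention ZYZ Euler orientations
  R = R_z(rot)·R_y(tilt)·R_z(psi) are composed with per-class corrections
  M′ = M·R_axis(Δφ), origin′ = origin + Δs·(M·axis), undoing k·(360°/n_pf)
  rotations and m·4-nm monomer shifts between misaligned classes.

## Worked example

```python
import mtlattice as mt

params = mt.LatticeParams()                       # 13 pf, 80 Å rise, seam at 12
model, truth = mt.build_singlet(params, mt.build_dimer_template(seed=1))
model, truth = mt.decorate_mips(model, truth, mt.MIPDecoration(class_name="tails"))

res = mt.MicrotubuleLatticeModel(model, compute_interface_areas=False).fit()
print(res.summary())
```

prints

```
Microtubule lattice fit
======================================================
chains: 228   tubules: S
tubule S: n_pf=13 closed=True seam_interface=12
pf numbering: chain-labels
mean dimer spacing: 80.000 Å (8.000 nm rise)
mean interprotofilament angle (non-seam): 27.692 deg
------------------------------------------------------
MIP class TAI: 72 copies
  copies per repeat: 12
  axial periodicity: 8.00 nm
  spiral handedness: left
  tilt angle: 51.5 deg (range 51.5-51.5)
```

The same pipeline is scriptable from the command line:

```sh
mtlattice simulate --config config.yaml --seed 1 --out sim/
mtlattice analyze sim/model.cif --out report/
mtlattice compare sim_a/model.cif sim_b/model.cif --out diff/
mtlattice realign particles.star --corrections corr.json --out realigned/
```

`analyze` writes `report.json`, TSV tables of spacings/angles and a
human-readable `summary.txt`; `realign` rewrites a particle STAR file with
per-class register corrections applied.

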