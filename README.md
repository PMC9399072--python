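# phasefit

Dihedral phase-shift prediction and bonded-parameter fitting for small
(fused-ring) molecules in a CHARMM-style force-field dialect.

CHARMM dihedral potentials are cosine series `k [1 + cos(n φ − δ)]` with
multiplicity `n ∈ {1, 2, 3, 4, 6}` and phase `δ ∈ {0°, 180°}`. Fitters
that let δ float during profile fitting can reproduce a torsion-scan
energy curve perfectly and still place an energy *barrier* on the
equilibrium geometry, which then collapses to a wrong conformation in
simulation. phasefit implements the corrective protocol:

1. **Predict δ from the equilibrium geometry first** — for each term pick
   the δ that minimises `cos(n φ₀ − δ)`; flag near-ties as ambiguous and
   enumerate alternative assignments (`phasefit.phases`).
2. **Fit only the force constants** (k ≥ 0, δ and n fixed) to
   torsion-scan profiles, group-sequentially (double-bond dihedrals
   first, carboxylate/impropers last), with a 10 kcal/mol point-exclusion
   cutoff, per-scan free offsets and an optional second iteration
   (`phasefit.dihedrals`). Extra multiplicities can be introduced one by
   one and kept only when they clearly improve the fit.
3. **Fit bond/angle/improper harmonics** from a Cartesian Hessian by an
   uncoupled Wilson-projection, taking equilibrium values directly from
   the reference geometry so they stay within 0.03 Å / 3° of it
   (`phasefit.bonded`).
4. **Validate** with a desk-scale surrogate: MM-vs-target profile RMSE,
   grid minima location (1D and 2D, with a flip-barrier estimate),
   seeded multi-start conformer search on the full MM model, and GROMOS
   clustering at a 0.2 Å RMSD cutoff with per-cluster RMSD to the
   reference geometry (`phasefit.validation`).

Everything is testable offline: `phasefit.synthetic` generates fused-ring
toy systems with known ground-truth parameters and emits geometries,
relaxed/rigid torsion scans (optionally noisy), finite-difference
Hessians and CGenFF-like stream files with synthetic penalties, including
a flip-mode fixture whose 5-membered ring has two near-degenerate
mirror-pucker conformers.

## Command line

All subcommands live under a single entry point:

```sh
# generate a synthetic fixture (stream files, geometry, scans, Hessian)
phasefit make-fixture --template fused45 --seed 1 --perturb --out demo

# predict phase shifts from the equilibrium geometry
phasefit predict-phases --str demo/start.str --geometry demo/geometry.xyz

# bond/angle/improper fitting from the Hessian + equilibrium check
phasefit fit-bonded --str demo/start.str --geometry demo/geometry.xyz \
    --hessian demo/hessian.dat --out-str demo/bonded.str
phasefit check-geom --str demo/bonded.str --geometry demo/geometry.xyz

# group-sequential dihedral fitting against torsion scans
phasefit fit --str demo/bonded.str --geometry demo/geometry.xyz \
    --scan demo/scan_00.tsv:demo/scan_00_frames.xyz \
    --groups demo/groups.tsv --out-str demo/fitted.str

# optional: introduce extra multiplicities for one group
phasefit augment --str demo/fitted.str --geometry demo/geometry.xyz \
    --scan demo/scan_00.tsv:demo/scan_00_frames.xyz \
    --groups demo/groups.tsv --group fused --out-str demo/extra.str

# MM profile overlay and full validation report
phasefit scan-mm --str demo/fitted.str --geometry demo/geometry.xyz \
    --scan demo/scan_00.tsv:demo/scan_00_frames.xyz
phasefit validate --str demo/fitted.str --geometry demo/geometry.xyz \
    --scan demo/scan_00.tsv:demo/scan_00_frames.xyz --n-starts 30 --seed 1
```

Defaults (10 kcal/mol cutoff, penalty threshold 10, tie tolerance 0.05,
10% augmentation threshold, 0.2 Å cluster cutoff, 0.15 Å verdict RMSD,
0.03 Å / 3° equilibrium tolerances, 2 iterations) can be overridden by a
flat key=value config file (`--config`) or CLI flags (CLI wins); the
effective configuration is echoed at the top of every report.

## File formats

* **Stream files** (`.str`): a CHARMM-dialect subset — MASS/RESI/ATOM/
  BOND/DOUBLE/IMPR topology plus BONDS/ANGLES/DIHEDRALS/IMPROPERS/
  NONBONDED parameter blocks with trailing `! penalty= X` comments.
* **Geometries**: XYZ (single or multi-frame) and PDB (read-only).
* **Scan tables**: plain delimited text (`# driven:`/`# step:`/
  `# range:` headers, then `angle [angle2] energy frame` rows) paired
  with a multi-frame XYZ; the driven torsion is re-measured on every
  frame on read.
* **Hessians**: whitespace-separated full square or lower-triangular
  matrix, in kcal/mol/Å² or Hartree/Bohr².

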