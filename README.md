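# iontraj

Trajectory analysis of cation-bound P-type ATPase conformational
ensembles: metal-ion coordination statistics, ion–ligand distance tables,
binding-event detection, side-chain χ2 state classification, per-domain
RMSD/RMSF, axial-rotation estimation, and Gaussian decomposition of
interdomain Cα–Cα distance distributions — together with synthetic
trajectory generators that encode documented target values as ground
truth, so every analysis stage is validated by parameter recovery.

Internal units are **nm** and **µs** everywhere; PDB Ångström coordinates
are converted at the I/O boundary. Multi-model PDB is the canonical
trajectory interchange format.

## Layout

| module | role |
|---|---|
| `iontraj.structio` | PDB read/write, selection grammar, domain maps |
| `iontraj.geomcore` | Kabsch superposition, RMSD/RMSF, dihedrals, distances, axial rotation |
| `iontraj.ionsite` | coordination numbers, ligand distance tables, binding events, nonbonded energy estimate |
| `iontraj.conformation` | χ2 series + lumen/cytosol classification, carboxyl-pair conventions |
| `iontraj.headpiece` | distance distributions, 1/2-Gaussian fits, model selection, crystal comparison |
| `iontraj.synthgen` | synthetic trajectory generators + ground-truth manifests and presets |
| `iontraj.pipeline` | config-driven orchestration, report bundles, run comparison |

## CLI

```sh
# generate a synthetic fixture bundle (multi-model PDBs + manifest)
iontraj synth --ensemble E1_MG --frames 2000 --seed 1 --out fixtures/

# run the analysis battery from a YAML config
iontraj analyze --config run.yaml --set seed=1

# compare two report bundles
iontraj compare report_a/ report_b/ --out diff.json

# carboxyl-pair distances on single-model structures
iontraj crystal-distances structure1.pdb structure2.pdb --pair D800-E908
```

A minimal `run.yaml`:

```yaml
output_dir: report
frame_dt: 0.0001           # us per frame
ions:
  - name: Mg_site
    trajectory: fixtures/site_mg_site.pdb
    species: MG
    cutoff: 0.21
    rmsf_align: "name CA"
chi2: {trajectory: fixtures/dihedral.pdb, resid: 309}
headpiece: {trajectory: fixtures/headpiece.pdb, pairs: [N-A, N-P, A-P]}
```

The selection grammar accepts `name/resname/element/chain/resid` value
lists (resid ranges as `a:b`), `domain N|P|A|TM` (with a domain map
attached), `backbone`, `sidechain`, `ion`, `water`, `protein`, `all`, and
boolean `and/or/not` with parentheses — e.g.
`resid 771 and name OE1`, `domain TM and backbone`.

## Notes on conventions

- Coordination counting uses a strict `< cutoff` inequality over **all**
  oxygen atoms (protein and water). Bonding thresholds (Mg 0.21 nm,
  K 0.30 nm, Ca 0.25 nm) apply to the per-atom mean distance.
- χ2 windows: lumen |χ2| ≥ 120°, cytosol 40° ≤ |χ2| < 120°, everything
  else reported explicitly as unclassified; occupancies are percentages of
  all frames.
- Mixture fits target the histogram density as a curve (bin width
  0.05 nm), and quality is the Pearson r between fitted and empirical
  density. Order 2 is selected only if it improves r by ≥ 0.01 **and** its
  means separate by more than the larger component sd.
- RMSD/RMSF are mass-unweighted; "backbone" = N, CA, C, O. Domain RMSD
  aligns each frame on the TM backbone and measures each cytosolic domain
  without re-fitting, so rigid-body displacement is captured.
- The interaction energy is an *estimate* (Coulomb constant
  332.0636 kcal·Å·mol⁻¹·e⁻², 12-6 LJ with Lorentz–Berthelot combining, no
  cutoff, dielectric 1 by default) and depends entirely on the parameter
  table supplied.
- The default N/P/A/TM domain map shipped in `iontraj/data/` is a
  documented repository choice, not a published partition.
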