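# memtilt

Analysis toolkit for molecular-dynamics trajectories of a membrane-embedded
receptor dimer — built around the observables used to characterise how a
lipopolysaccharide-bound TLR4 dimer sits in a glycosphingolipid-containing
membrane:

* **Tilt decomposition.** Three body-frame vectors are built per frame:
  V1, the extracellular-domain long axis (membrane-proximal → membrane-distal
  centroid); V2, the inter-monomer "face" axis with its V1 component removed;
  V3 = V1 × V2. The tilt of V1 against the membrane normal n (laboratory z)
  is split into *overall* = arccos|V1·n|, *lateral* = atan2(u_x, u_z) and
  *forward* = atan2(u_y, u_z), where the in-plane x axis is the first frame's
  V2 projected into the membrane plane. These definitions satisfy
  tan²θ_overall = tan²θ_lateral + tan²θ_forward on every frame.
* **Contact statistics.** Dimer integrity and protein–membrane association
  are measured as the number of atom pairs, one atom per selection, within a
  cutoff (0.6 nm default) under orthorhombic minimum-image boundaries. The
  production cell-list search is verified exactly against a brute-force
  all-pairs oracle.
* **Electrostatic potential profile.** Partial charges are binned into
  ρ(z) (e/nm³) and the 1-D Poisson equation is integrated twice:
  ψ(z) = −(1/ε₀)∬ρ dz², with ψ = dψ/dz = 0 at the lower box edge; output in
  volts (e/(ε₀·nm) = 18.0951 V).
* **Bilayer properties.** Acyl-chain order parameters
  S = ⟨(3cos²θ − 1)/2⟩ (carbon-skeleton or C–H mode) and thickness as the
  phosphate-plane separation.
* **Block averaging.** Error estimates (EE) for correlated series:
  EE(b) = SD(block means)/√n_blocks, summarised conservatively as the maximum
  over block sizes retaining ≥ 10 blocks; replicate runs are combined via the
  between-run spread.

Because real multi-microsecond atomistic trajectories are not practical to
re-generate, the package ships a first-class synthetic-data module
(`memtilt.synthetic`) that builds rigid-dimer trajectories with scheduled
tilts and engineered contact pairs, toy bilayers with known order and
thickness, planar charge systems with closed-form potentials, and AR(1)
series with analytic standard errors — every analysis stage is validated
against this ground truth.

## Worked example

```sh
memtilt demo --outdir demo_out --seed 1
```

runs four scenario presets (±ligand, ±glycolipid; scheduled tilts
33/15/57/19° with 2° angular noise, engineered contact levels
337/165/322/187; three runs each, one for the last) through every stage.
`demo_out/summary.tsv` then contains (seed 1, 60 frames/run shown):

```
label          overall_mean_deg  overall_ee_deg  contacts_mean  contacts_ee
+LPS +GluCer          33.356           0.329            337            0
-LPS +GluCer          15.102           0.155            165            0
+LPS -GluCer          57.028           0.133            322            0
-LPS -GluCer          18.735           0.508            187            0
```

i.e. each trailing-window tilt mean recovers its scheduled angle within a few
EE and the contact series sit exactly at their engineered counts.
`demo_out/membranes.tsv` reports both toy bilayers at 4.8 nm thickness, a
higher chain order for the glycolipid-containing one (S 0.888 vs 0.810), and
a 30% electrostatic-potential contrast between the two sheet systems.

The same stages are available individually (`memtilt tilt`, `contacts`,
`potential`, `membrane`, `stats`, `generate`) and as a config-driven pipeline
(`memtilt run-all --config analysis.yaml`) for external structure/trajectory
files (GRO, PDB, multi-frame GRO/XYZ text, or the package's binary frame
stream).

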