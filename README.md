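# condock

Ligand binding-site prediction for GPCR-like receptors by rescoring docked
ligand poses with evolutionary surface conservation.

Blind (global) docking programs search the whole receptor surface and
often score a wrong surface patch best, especially on homology models whose
pocket geometry is imperfect. Functionally important surfaces, however,
tend to be evolutionarily conserved. `condock` combines the two signals:
for each docked pose it extracts the contact residues, averages their
conservation, and multiplies that by the pose's docking energy. Because
docking energies are negative, the most negative product identifies the
most probable binding site — a pose in a conserved pocket beats a decoy
with a slightly better energy on unconserved surface.

## Method

For a pose with binding-site residues *k* = 1..*n* (every receptor residue
with a heavy atom within 3.5 Å of a ligand heavy atom):

```
Conservation Score  C = (1/n) Σₖ cₖ          cₖ ∈ [0, 1]
Combined score          = C × E              E = docking energy score
```

where *cₖ* comes either from an imported ConSurf-style grades table
(integer grades 0–9, normalised as grade/9) or from the package's internal
Jensen–Shannon divergence scorer over a multiple sequence alignment
(column distribution vs. background, log₂, normalised to [0, 1]). Poses
are ranked ascending (most negative first); the rank-1 pose's contact site
is the predicted binding site. Predictions are benchmarked by the distance
between the centers of mass of the predicted and reference ligand
coordinates, which unlike RMSD requires no atom matching.

## Worked example

```bash
python examples/predict_binding_site.py
```

builds a synthetic receptor (a poly-alanine bundle with a conserved
pocket), eleven docked poses (one true pose whose energy is only 8th best
among the decoys) and prints:

```
  pose     energy   cons   combined rank
  c5.0    -3350.4  0.889    -2978.1    1
  c4.0    -3564.9  0.222     -792.2    2
  c7.0    -3502.2  0.222     -778.3    3
  ...
predicted site: pose c5.0, 4 residues, mean conservation 0.889
planted true pose: c5.0 (recovered)
```

The true pose `c5.0` has a worse raw energy than several decoys
(−3350 vs. −3565 for the best decoy), but its contact residues are
conserved (0.889 vs. 0.222), so its product is by far the most negative
and the correct site is ranked first. The other examples demonstrate the
conservation scorer (`conservation_profile.py`), the rescue statistics
over many scenarios (`rescue_demo.py`) and the center-of-mass benchmark
(`evaluate_benchmark.py`).

## Command line

The same workflow is available as a thin CLI:

```bash
condock simulate --seed 7 --out-dir scen          # synthetic fixture
condock predict  --receptor scen/receptor.pdb \
                 --poses scen/poses_swissdock.pdb \
                 --grades scen/grades.txt --out-dir out
condock evaluate --receptor scen/receptor.pdb \
                 --poses scen/poses_swissdock.pdb \
                 --grades scen/grades.txt \
                 --reference scen/reference.pdb --out-dir out
condock profile  --receptor scen/receptor.pdb \
                 --msa scen/alignment.fasta --target-id target --out-dir out
```

Pose inputs may be SwissDock-style cluster PDBs (`--dialect swissdock`,
energies from the per-cluster FullFitness REMARKs), plain multi-model PDBs
with a `pose_id<TAB>energy` sidecar (`--dialect multimodel_pdb --sidecar`),
or SDF with an energy property (`--dialect sdf --energy-tag`). Outputs are
TSV/JSON with a `#` header recording the tool version, config hash and
input checksums, so identical inputs reproduce identical bytes.

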