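# tmbundle

Coarse-grained integrative modeling of a four-helix transmembrane bundle:

- **assembly** of rigid ideal TM helices by replica-exchange Monte Carlo
  (REMC) under a residue-pair-specific short-range Cα contact potential
  with signed side-chain charge wells and harmonic membrane restraints;
- **clustering** of the saved low-temperature ensemble by DRMS
  (superposition-free RMS deviation of inter-helix Cα distances);
- **model selection** against a cysteine cross-linking/accessibility
  table: neighbor-count burial classifies each probed residue as
  surface-accessible or buried, models are ranked by match count and
  coarse-grained energy;
- **docking** of a single partner TM helix under a harmonic salt-bridge
  restraint, with charge-swap point mutations;
- **trajectory analytics** for the intra→inter salt-bridge "lock-switch":
  superposition Cα-RMSD, Cα-geometry helicity, minimal residue-residue
  distances, and per-frame lock-state classification with switch-frame
  detection;
- **synthetic data generators** (truth bundles of known handedness,
  exposure-derived cross-link tables with controlled noise, two-state
  switch trajectories) so that every stage is testable end to end.

Packaged fixtures cover the four TM spans of the TAP1 accessory domain
(residues 20–44, 57–76, 96–123, 137–160), a curated 16-position
cross-link observation table, a default tapasin TM helix bracketing
K428, and the default pair-potential table.

All scores are coarse-grained stand-ins (no all-atom relax/rescore, no
surface-area solvation); every run's provenance log says so explicitly.

## CLI

```sh
tmbundle assemble --seed 0 --steps 100000 --replicas 10 --out out/assemble
tmbundle cluster  --ensemble out/assemble/ensemble.pdb \
                  --energies out/assemble/energies.tsv --out out/cluster
tmbundle score    --models out/cluster/centers.pdb --out out/score
tmbundle dock     --bundle out/score/selected.pdb --out out/dock
tmbundle analyze  --traj switch.pdb --intra A:32,A:64 --inter A:32,B:428 \
                  --out out/analyze
tmbundle synth    --kind switch --out out/synth
tmbundle recover  --seed 1 --out out/recover
```

Every subcommand accepts `--seed`/`--out` and writes a `log.json`
provenance record (config echo, seeds, versions, stand-in notices).
Exchange formats are multi-MODEL PDB (models, ensembles, trajectories),
TSV (segments, observations, restraints, reports) and FASTA.

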