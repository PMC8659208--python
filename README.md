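# mdtriage

MD-driven triage of protein–ligand binders.

Docking scores alone are poor predictors of binding affinity for targets
whose pockets rearrange on ligand binding — the BRD9 bromodomain, whose
Phe44/Phe47/Tyr106 side chains reshape the acetyl-lysine pocket, is the
motivating case. `mdtriage` implements the post-processing side of an
MD-based selection workflow: it computes structural descriptors and
interaction fingerprints from short explicit-solvent trajectories, ingests
the energies produced by external docking/MM-GBSA engines, and combines
seven parameters into a traffic-light rubric that ranks candidate ligands
Excellent / Good / Intermediate / Bad.

## What it computes

**Descriptors** (`mdtriage.descriptors`) — Kabsch superposition; per-frame
backbone RMSD against frame 0; per-residue RMSF about the time-average
structure (mean of backbone and side-chain values); radius of gyration
Rg = √(⟨|rᵢ − r̄|²⟩) with its distribution width (range); deterministic 1-D
k-means clustering of frames by RMSD with medoid representatives; and a
binding-site resemblance filter that counts unliganded snapshots within a
site-RMSD threshold (default 2.5 Å) of each ligand-bound crystal.

**Interactions** (`mdtriage.interactions`) — frame-wise geometric contact
detection (hydrogen bond, hydrophobic, aromatic, π–cation, ionic) and
interaction-fraction fingerprints: per residue and channel, the fraction of
frames in contact. Cumulative per-residue fractions may exceed 1 when one
residue engages the ligand through several channels.

**Energetics** (`mdtriage.energetics`) — conversion of dissociation
constants to binding free energies,

    ΔG_exp = R · T · ln K_D      (K_D in molar, R = 1.987 cal K⁻¹ mol⁻¹,
                                  T = 298.15 K by default)

plus MM-GBSA averaging over cluster representatives and replicas,
per-residue energy means over replicas with a magnitude-thresholded sum
(|E| ≥ 5 kcal/mol, over all residues or over the pocket), and the ordinary
least-squares regression of docking scores on experimental affinities.

**Rubric** (`mdtriage.rubric`) — assembles the seven-parameter panel
(docking score and contacts, MM-GBSA, site and total per-residue energy
sums, persistent-contact count, mean RMSD, RMSF violations, Rg width),
assigns traffic lights, and applies an explicit decision tree. Energetic
parameters decide the label; docking and the purely structural descriptors
are displayed but non-decisive, since they do not separate good from bad
binders on the benchmark.

**Synthetic data** (`mdtriage.synthetic`) — toy structures, trajectories
with planted fluctuation amplitudes / rigid drift / contact schedules, and
energy tables with known truth, so every stage is testable without
downloads.

The bundled benchmark (`mdtriage.datasets`) carries the published BRD9
tables — K_D values, docking scores, per-replica MM-GBSA and RMSD values,
apo-filter counts, and the fifteen assembled panels with reference labels.

## Worked example

```python
from mdtriage import predict, rank
from mdtriage.datasets import load_panels

panels, reference = load_panels()
for r in rank([predict(p) for p in panels])[:3]:
    print(r.panel.system, r.panel.mmgbsa, r.label)
```

prints

```
4UIW -87.8 Excellent
9 -78.88 Excellent
12 -76.08 Good
```

4UIW — the 2 nM binder, with MM-GBSA −87.8 kcal/mol, a −29.1 kcal/mol
binding-site energy sum and five persistent key-residue contacts — tops the
ranking; all fifteen benchmark panels land on their reference labels.
The `examples/` directory has one narrative script per capability
(descriptors, fingerprints, energetics, rubric); each builds or loads a
small input, runs the method, and explains the numbers it prints.

A thin CLI mirrors the library: `mdtriage synth | descriptors |
interactions | energetics | triage | run` (see `mdtriage --help`).

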