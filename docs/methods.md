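# Methods

## Scope and data flow

`mdtriage` post-processes molecular-dynamics output; it does not run
docking, MD, or MM-GBSA. Trajectories (multi-model PDB, DCD, XTC) and
topologies (PDB) come in through MDAnalysis and are held as plain arrays in
Å. Energies — docking scores, MM-GBSA ΔG_bind per cluster representative
and replica, per-residue interaction-energy decompositions — are produced
by external engines and ingested as delimited text with a mandatory
`kcal/mol` unit column. The package owns the arithmetic between those
inputs and a ranked triage label.

Residue identity is `(chain_id, residue_number)`; insertion codes and
multi-assembly bookkeeping are out of scope. Alternate locations collapse
to the highest-occupancy conformer (ties toward altloc `A`). Hydrogens are
kept on read; descriptor selections exclude them.

## Descriptors

**Superposition.** All descriptors superpose on a fit selection first;
without it, RMSD-type quantities measure box placement, not conformational
change. The Kabsch solution is computed by SVD of the weighted covariance,
with the determinant correction that forbids improper rotations. Degenerate
(collinear) point sets are rejected rather than silently resolved.

**RMSD series.** Each frame is fitted to a reference frame (default: frame
0) on the fit atoms; RMSD is then measured over the calc atoms. The value
at the reference frame is zero by construction.

**RMSF.** Frames are aligned in two passes — to frame 0, then to the
resulting time-average structure — and atomic RMSF is the RMS displacement
from the time-average position. Residue values average over backbone and
side-chain heavy atoms separately; the per-residue `mean_rmsf` is the mean
of the two (or whichever exists — glycine has no heavy side chain). The
reference choice (time-average structure) is the common convention; for
i.i.d. jitter of amplitude σ per axis the per-atom expectation is √3·σ,
which the synthetic suite recovers within 5% at 5000 frames.

**Radius of gyration.** Unweighted RMS distance of the selected heavy atoms
from their centroid. No mass weighting: the quantity tracked is geometric
compactness, and crystal-derived inputs lack hydrogens anyway. The
distribution "width" used by the rubric is the range (max − min) of the
per-frame series, matching the apo-baseline convention (0.72 Å).

**Frame clustering.** One-dimensional k-means on the RMSD-to-reference
values. Initialisation is deterministic (midpoints of the k quantile bins),
so a seed never changes the result; the representative of each cluster is
the frame nearest the cluster mean, ties to the lowest index. If the series
has fewer distinct values than k, the achievable number of clusters is
returned with a `truncated` flag. k = 10 is the default for MM-GBSA
snapshot selection, k = 50 for ensemble-docking receptor selection.

**Apo-resemblance filter.** For every (unliganded snapshot, bound crystal)
pair, the site RMSD is computed by fitting on the site backbone and scoring
all site heavy atoms — the signal of interest is side-chain rearrangement
at a fixed scaffold. Pairs under the threshold (default 2.5 Å) count as
matches. Two percentage conventions are reported: per-crystal matches over
the total passing pairs, and over all frames screened. Display rounds the
filtered percentage to integer percent. Both denominators are exposed
because published summaries of this filter are ambiguous about their
bookkeeping (per-crystal counts need not sum to the quoted pair total, and
the per-frame column can be printed as a fraction mislabelled as percent);
the report keeps both auditable rather than guessing.

## Interaction fingerprints

Contact criteria are explicit and configurable, since input structures
carry neither connectivity nor charges: hydrogen bonds by donor–acceptor
heavy-atom distance (≤ 3.5 Å) with a D–H···A angle test (≥ 120°) applied
only when explicit hydrogens exist; hydrophobic contacts by carbon–carbon
distance (≤ 3.6 Å) between the ligand and the conventional hydrophobic
residue set {Ala, Val, Leu, Ile, Pro, Phe, Met, Trp, Tyr, Cys}; aromatic
and π–cation contacts by ring-centroid distances (≤ 4.5 Å), with ligand
rings and formal charges declared in the criteria; ionic contacts by
charged-group distance (≤ 3.7 Å). These defaults aim at self-consistency,
not bit-compatibility with any engine's built-in analyser.

Channels are the unit of counting: an H-bond channel is a (donor heavy
atom, acceptor heavy atom) pair, a hydrophobic channel is residue-level,
and each channel fires at most once per frame. A channel's interaction
fraction is frames-fired / total frames ∈ [0, 1]; the per-residue
cumulative fraction sums a residue's channels and can exceed 1. The
rubric's persistence count uses the cumulative fraction (threshold 0.5 on
the key-residue set) — the same quantity fingerprint histograms plot. The
single-pose contact count uses distinct-residue semantics.

## Energetics

ΔG_exp = R·T·ln K_D with K_D in molar and R = 1.987 cal K⁻¹ mol⁻¹. The
default temperature is 298.15 K, which reproduces all twelve benchmark
affinities to the printed decimal (a physiological 310 K does not); it is
overridable. MM-GBSA summaries are the mean over each replica's cluster
representatives, then the mean of per-replica means, carried at full
precision and rounded only for display. Per-residue aggregation is the
arithmetic mean over replicas, flagging residues present in only a subset.

The thresholded energy sum uses a magnitude rule: residues with
|mean| ≥ 5 kcal/mol contribute, so strongly destabilising residues enter
with positive sign and the sum can be positive. This matches the ±5
labelling convention of per-residue decomposition plots and is the only
reading consistent with the benchmark panels, where the site-restricted sum
is a sub-sum of the total (|total| ≥ |site| in every row) and positive site
sums occur. A one-sided mode (only E ≤ −5) is available behind a flag, and
the rule used is always recorded in the report.

The affinity regression is OLS of calculated on experimental affinity with
R² the squared Pearson correlation (axis choice irrelevant). On the eight
benchmark training pairs the package obtains R² = 0.299 with experimental
ΔG derived from K_D at full precision (0.290 from the 1-decimal rounded
affinities); the benchmark's own quoted value is 0.31. The residual
discrepancy is reported, not forced — it is within what rounding of the
printed inputs produces.

## Triage rubric

Seven parameters per system: MM-GBSA average, site energy sum, total energy
sum, persistent key-residue contact count, mean backbone RMSD, count of key
residues with mean RMSF > 4 Å, and Rg width; docking score and static
docking contacts are carried for display. Structural lights follow the
unliganded baselines: RMSD good < 2.6 Å, intermediate to 3.0 Å (the band
around the apo mean 2.79 Å), bad above; at most 2 RMSF violations; Rg width
below the apo width 0.72 Å. Contacts are good at ≥ 3.

The decision tree makes the qualitative ranking logic explicit and
reproducible:

1. **Top tier** — MM-GBSA ≤ −70 and site sum ≤ −15 kcal/mol with ≥ 3
   persistent contacts. Within it, **Excellent** requires a total sum
   ≤ −50 kcal/mol and ≥ 4 contacts; otherwise **Good**.
2. **Intermediate** — total sum ≤ −30 kcal/mol; or site sum ≤ −15 with
   MM-GBSA ≤ −65; or site and total sums coincide (binding energy entirely
   from site residues, |Δ| ≤ 0.01 kcal/mol on display-precision values)
   with MM-GBSA ≤ −65.
3. **Bad** otherwise.

The four energy thresholds (−70/−65 MM-GBSA, −15 site, −50/−30 total) were
calibrated once so the tree reproduces all fifteen reference labels of the
bundled benchmark; they are plain `Thresholds` fields, never hard-coded,
and every report prints the set used. The label is monotone in each energy
argument (deepening any energy never demotes), which the property suite
checks. Docking and the structural lights are deliberately non-decisive:
on the benchmark they fail to separate good from bad binders. Ranking
orders by label tier with MM-GBSA as tie-break.

When a docking engine returns several plausible poses for one compound, the
workflow's stance is to simulate each pose as its own system (the benchmark
carries such a pair as `10a`/`10b`); pose selection itself is not
automated.

## Synthetic generator

The generator emulates the statistical structure the analyses assume, not
physics: frame t is base + i.i.d. Gaussian jitter with per-residue σ,
planted contacts, then a cumulative rigid rotation/translation. Planted
contacts move one designated ligand atom to a fixed distance from the
target residue's anchor atom on exactly `round(fraction · n_frames)`
seeded frames, at a geometry chosen so precisely one H-bond channel fires
(hydrophobic plants can legitimately co-fire a neighbouring hydrophobic
residue whose side chain reaches within the 3.6 Å cutoff — dense-chain
geometry, planted channel still exact). Everything is a pure function of
the seed; same seed, byte-identical output.

What passing synthetic tests show — and what they do not: recovery of
planted amplitudes, fractions, and energy means validates the estimators'
arithmetic and invariances. It says nothing about autocorrelated dynamics,
solvent, force-field quality, or sampling adequacy of real 100-ns runs;
benchmark-scale trajectory statistics are therefore taken from the bundled
published tables, not re-simulated, and test-suite problem sizes (up to
5000 frames, ~130 atoms) are chosen as the smallest that make the
stochastic tolerances (5–10%) meaningful.

## Numerical choices and limitations

* Coordinates always Å; nm-based trajectory formats scaled on read. PDB
  round-trips are exact to the format's 0.001 Å; XTC to ~0.005 Å (the
  format stores nm at 10⁻³ precision).
* Superposition rejects < 3 points and collinear sets; k-means caps at 300
  sweeps (1-D Lloyd converges far earlier).
* Ties: cluster representatives to the lowest frame index; altloc ties to
  `A`; ranking ties by MM-GBSA.
* Percentages display as integers; energies and Å as 1–2 decimals matching
  the benchmark tables; full precision is carried internally.
* Water-bridge contacts are off by default and computed only when explicit
  waters exist; π-stacking geometry classes, halogen bonds, and metal
  coordination are not modelled.
* The key-residue and pocket-residue sets of a target are carried as given
  (the BRD9 key set includes a residue absent from its pocket list); no
  reconciliation is attempted.
* The rubric's Excellent/Good split is this package's formalisation of a
  qualitative top-tier notion; the benchmark defines three tiers cleanly
  and one "excellent" exemplar, and the split criterion (deep total sum +
  ≥ 4 contacts) is the simplest rule consistent with all fifteen labels.
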