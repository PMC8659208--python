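"""Geometric descriptors of a trajectory with known, planted statistics.

Builds a 19-residue toy chain, simulates 2000 frames of isotropic jitter
(sigma = 0.5 Å per axis) with a slow rigid-body drift, and computes the
stability descriptors. Because superposition removes rigid motion, the
RMSD stays near the jitter floor, and the per-atom RMSF converges to
sqrt(3)·sigma ≈ 0.866 Å — the planted truth.
"""

import numpy as np

from mdtriage import (
    SimSpec,
    cluster_frames,
    make_toy_structure,
    radius_of_gyration,
    rmsd_series,
    rmsf_per_residue,
    select,
    simulate_trajectory,
)

base = make_toy_structure(19, seed=1)
traj = simulate_trajectory(
    base,
    SimSpec(
        n_frames=2000,
        seed=2,
        sigma=0.5,
        drift_rotation_deg=1.0,
        drift_translation=(0.1, 0.0, 0.0),
    ),
)
backbone = select(base, "backbone")

series = rmsd_series(traj, backbone)
print(f"mean backbone RMSD vs frame 0: {series.mean:.2f} A")

profile = rmsf_per_residue(traj, backbone)
print(
    f"mean residue RMSF: {profile.table['mean_rmsf'].mean():.3f} A "
    f"(planted truth sqrt(3)*0.5 = {np.sqrt(3) * 0.5:.3f} A)"
)
print(f"residues fluctuating above 4 A: {profile.violations(4.0)}")

rg = radius_of_gyration(traj, select(base, "heavy"))
print(
    f"Rg mean {rg.mean:.2f} A, distribution width (range) {rg.range:.2f} A"
)

clustering = cluster_frames(series, k=10)
print(
    f"10 RMSD clusters, representative frames: {clustering.representatives}"
)
# The RMSD hovers around the jitter floor (no real drift survives
# superposition); the width of the Rg distribution reflects only noise.
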