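"""Independent numerical oracles shared by the test modules."""

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def brute_force_min_rmsd(mobile, reference, n_starts=600, seed=0):
    """Minimum superposition RMSD by rotation-grid search + refinement.

    Scans seeded random unit quaternions, then polishes the best starts by
    numerically minimising the RMSD over rotation vectors (translation made
    optimal by centring).  Independent of the SVD-based implementation.
    """
    mobile = mobile - mobile.mean(axis=0)
    reference = reference - reference.mean(axis=0)

    def rmsd_of(rotvec):
        moved = Rotation.from_rotvec(rotvec).apply(mobile)
        return np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1)))

    rng = np.random.default_rng(seed)
    quats = rng.normal(size=(n_starts, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    scored = sorted(
        (
            rmsd_of(Rotation.from_quat(q).as_rotvec()),
            tuple(Rotation.from_quat(q).as_rotvec()),
        )
        for q in quats
    )
    best = np.inf
    for _, rotvec in scored[:5]:
        res = minimize(
            rmsd_of,
            np.array(rotvec),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        best = min(best, res.fun)
    return best
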