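"""Independent reference implementations used to cross-check the package.

These deliberately avoid the package's own algorithms: the matcher oracle
enumerates every ordered tuple of points, and the superposition oracle
delegates to scipy's align_vectors.
"""

from itertools import permutations

import numpy as np
from scipy.spatial.transform import Rotation


def oracle_type_ok(slot_type, point_type, hyd_accepts_aromatic=True):
    if slot_type == point_type:
        return True
    return slot_type == "HYD" and point_type == "HYD_ARO" and hyd_accepts_aromatic


def brute_force_match(points, model, hyd_accepts_aromatic=True, tolerance_scale=1.0):
    """Enumerate all ordered k-tuples of distinct points; return
    (matched, best_assignment, max_deviation) minimising the deviation sum
    with lexicographic tie-break."""
    ptypes = points.types()
    pos = points.positions()
    k = model.k
    dmat = model.distance_matrix()
    radii = model.radii()
    best = None
    for assign in permutations(range(len(ptypes)), k):
        if not all(
            oracle_type_ok(model.features[s].feature_type, ptypes[assign[s]], hyd_accepts_aromatic)
            for s in range(k)
        ):
            continue
        ok = True
        devs = []
        for i in range(k):
            for j in range(i + 1, k):
                d = np.linalg.norm(pos[assign[i]] - pos[assign[j]])
                dev = abs(d - dmat[i, j])
                devs.append(dev)
                if dev > tolerance_scale * (radii[i] + radii[j]):
                    ok = False
        if not ok:
            continue
        key = (sum(devs), assign)
        if best is None or key < (best[0], best[1]):
            best = (sum(devs), assign, max(devs))
    if best is None:
        return False, None, None
    return True, best[1], best[2]


def superpose_rmsd_oracle(P, Q):
    """RMSD under the optimal proper rotation + translation via scipy."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    _rot, rssd = Rotation.align_vectors(Qc, Pc)
    return rssd / np.sqrt(len(P))
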