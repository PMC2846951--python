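"""Independent reference implementations used to check the package.

Everything here deliberately avoids the package's own accumulator/chaining
code paths: RMSD goes through scipy's rotation estimation, fragment
enumeration is the naive quartic scan, and chaining optima come from
exhaustive subset enumeration / textbook dynamic programming.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def kabsch_rmsd(a_pts, b_pts) -> float:
    """Optimal-superposition RMSD via scipy's rotation estimation."""
    a = np.asarray(a_pts, dtype=float).reshape(-1, 3)
    b = np.asarray(b_pts, dtype=float).reshape(-1, 3)
    n = a.shape[0]
    if n == 1:
        return 0.0
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    if n == 2:
        return abs(np.linalg.norm(ac[1] - ac[0]) - np.linalg.norm(bc[1] - bc[0])) / 2.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rot, _ = Rotation.align_vectors(ac, bc)
    diff = ac - rot.apply(bc)
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def brute_force_min_rmsd(a_pts, b_pts, n_samples: int = 20000, seed: int = 0) -> float:
    """Minimum RMSD over proper rotations by dense sampling plus local refinement."""
    a = np.asarray(a_pts, dtype=float)
    b = np.asarray(b_pts, dtype=float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    rots = Rotation.random(n_samples, rng=np.random.default_rng(seed))
    mats = rots.as_matrix()
    rotated = np.einsum("sij,nj->sni", mats, bc)
    diffs = rotated - ac[None, :, :]
    rmsds = np.sqrt(np.mean(np.sum(diffs * diffs, axis=2), axis=1))
    best = int(np.argmin(rmsds))

    def objective(rotvec):
        r = Rotation.from_rotvec(rotvec)
        d = ac - r.apply(bc)
        return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))

    res = minimize(objective, rots[best].as_rotvec(), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    return min(float(rmsds[best]), float(res.fun))


def naive_afps(coords_a, coords_b, l_min: int, epsilon: float):
    """Quartic-time fragment enumeration with full Kabsch at every length.

    Applies the same maximality rule as the extractor — per start pair the
    fragment is grown until the first length whose RMSD exceeds epsilon —
    but every RMSD is recomputed from scratch.  Returns [(i, j, l, rmsd)].
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    n, m = a.shape[0], b.shape[0]
    out = []
    for i in range(n):
        for j in range(m):
            max_l = min(n - i, m - j)
            l = 0
            last_rmsd = None
            while l < max_l:
                r = kabsch_rmsd(a[i:i + l + 1], b[j:j + l + 1])
                if r > epsilon:
                    break
                l += 1
                last_rmsd = r
            if l >= l_min:
                out.append((i, j, l, last_rmsd))
    return out


def _intervals_compatible(p, q, sequential: bool) -> bool:
    """p, q are (i, j, l) triples; mirrors the precedence definitions."""
    def prec(x, y):
        xi, xj, xl = x
        yi, yj, yl = y
        if sequential:
            return xi + xl - 1 < yi and xj + xl - 1 < yj
        return xi + xl - 1 < yi and (xj + xl - 1 < yj or xj > yj + yl - 1)

    return prec(p, q) or prec(q, p)


def max_weight_consistent_subset(triples, weights, sequential: bool = False) -> float:
    """Exhaustive maximum-weight mutually non-overlapping subset (<= ~15 AFPs)."""
    n = len(triples)
    best = 0.0
    for r in range(1, n + 1):
        for combo in combinations(range(n), r):
            ok = all(
                _intervals_compatible(triples[x], triples[y], sequential)
                for x, y in combinations(combo, 2)
            )
            if ok:
                total = sum(weights[k] for k in combo)
                best = max(best, total)
    return best


def dp_sequential_optimum(triples, weights) -> float:
    """Classic weighted sequential chaining by dynamic programming.

    Valid when connection costs are zero: S(i) = W(i) + max(0, max over
    strictly-preceding j of S(j)).
    """
    order = sorted(range(len(triples)), key=lambda k: triples[k][0] + triples[k][2])
    scores = {}
    for k in order:
        ik, jk, lk = triples[k]
        best_pred = 0.0
        for q in order:
            if q == k or q not in scores:
                continue
            iq, jq, lq = triples[q]
            if iq + lq - 1 < ik and jq + lq - 1 < jk:
                best_pred = max(best_pred, scores[q])
        scores[k] = weights[k] + best_pred
    return max(scores.values())
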