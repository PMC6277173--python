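"""Independent reference implementations used only as test oracles.

These deliberately share no code with the library: superposition via the
quaternion characteristic-polynomial (Kearsley/Theobald) eigenvalue method,
greedy neighbour-count clustering by literal set manipulation, and scalar
re-implementations of the interaction criteria.
"""

import math

import numpy as np


def quaternion_fit_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD over proper rotations via the 4x4 quaternion key matrix.

    The quaternion parametrisation covers exactly the proper rotations, so
    this is the natural oracle for a reflection-excluded least-squares fit.
    """
    x = np.asarray(mobile, dtype=float)
    y = np.asarray(reference, dtype=float)
    n = x.shape[0]
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    ga = float(np.sum(x * x))
    gb = float(np.sum(y * y))
    s = x.T @ y
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = float(np.linalg.eigvalsh(key)[-1])
    msd = max(0.0, (ga + gb - 2.0 * lam) / n)
    return math.sqrt(msd)


def brute_force_greedy_cluster(distances, cutoff: float):
    """Literal greedy neighbour-count clustering on a distance matrix.

    Returns a list of (center, sorted member list); ties on the neighbour
    count go to the lowest index.  Neighbourhood is strict (< cutoff).
    """
    d = np.asarray(distances, dtype=float)
    remaining = set(range(d.shape[0]))
    clusters = []
    while remaining:
        best = None
        best_neighbours = None
        for i in sorted(remaining):
            neighbours = {j for j in remaining if j != i and d[i, j] < cutoff}
            if best_neighbours is None or len(neighbours) > len(best_neighbours):
                best = i
                best_neighbours = neighbours
        members = sorted(best_neighbours | {best})
        clusters.append((best, members))
        remaining -= set(members)
    return clusters


def naive_hbond(coords, donor: int, hydrogen: int, acceptor: int,
                max_ha: float, min_angle: float) -> bool:
    """Scalar re-implementation of the H-bond criterion (strict boundaries)."""
    h = coords[hydrogen]
    a = coords[acceptor]
    d = coords[donor]
    dist = math.dist(h, a)
    v1 = [d[k] - h[k] for k in range(3)]
    v2 = [a[k] - h[k] for k in range(3)]
    dot = sum(v1[k] * v2[k] for k in range(3))
    n1 = math.sqrt(sum(v * v for v in v1))
    n2 = math.sqrt(sum(v * v for v in v2))
    ang = math.degrees(math.acos(max(-1.0, min(1.0, dot / (n1 * n2)))))
    return dist < max_ha and ang > min_angle


def naive_stacking(coords, idx_a, idx_b, max_dist: float, max_angle: float) -> bool:
    """Scalar re-implementation of the stacking criterion (inclusive)."""

    def plane(points):
        pts = np.asarray(points, dtype=float)
        c = pts.mean(axis=0)
        # normal from the eigenvector of the smallest eigenvalue of the
        # scatter matrix (different algebra than the library's SVD route)
        scatter = (pts - c).T @ (pts - c)
        w, v = np.linalg.eigh(scatter)
        return c, v[:, 0]

    ca, na = plane(coords[idx_a])
    cb, nb = plane(coords[idx_b])
    dist = float(np.linalg.norm(ca - cb))
    cosang = abs(float(na @ nb)) / (np.linalg.norm(na) * np.linalg.norm(nb))
    ang = math.degrees(math.acos(min(1.0, cosang)))
    return dist <= max_dist and ang <= max_angle


def random_point_cloud(rng: np.random.Generator, n: int, scale: float = 1.0):
    return rng.normal(0.0, scale, size=(n, 3))


def random_rigid_motion(rng: np.random.Generator):
    """A uniform random proper rotation (QR-based) and a translation."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-3.0, 3.0, size=3)
    return q, t
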