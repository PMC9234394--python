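"""Independent oracles and small generators shared across the test suite.

Everything here is deliberately naive (double loops, step-by-step
simulation) so it cannot share bugs with the vectorized implementations it
checks.
"""

import numpy as np

from afcv import BinGeometry, Conformation, Distogram


def random_distogram(n, m, rng, geometry=None) -> Distogram:
    """Fully random normalized symmetric distogram."""
    geometry = geometry or BinGeometry(m)
    probs = rng.random((n, n, m))
    probs = probs / probs.sum(axis=2, keepdims=True)
    probs = 0.5 * (probs + probs.transpose(1, 0, 2))
    return Distogram(probs, geometry)


def random_conformation(n, rng, scale=0.8) -> Conformation:
    return Conformation(scale * rng.standard_normal((n, 3)))


def brute_pair_probability(row, centers, d, lam, eps):
    num = den = 0.0
    for k in range(len(row)):
        e = np.exp(-lam * (d - centers[k]) ** 2)
        num += row[k] * e
        den += e
    return num / (eps + den)


def brute_cv(conf, disto, params):
    """Double loop over pairs and bins, straight from the defining formula."""
    coords = conf.coords
    n = coords.shape[0]
    centers = disto.geometry.centers
    subset = params.subset
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if j - i < params.min_separation:
                continue
            if subset is not None and (i not in subset or j not in subset):
                continue
            d = float(np.sqrt(((coords[i] - coords[j]) ** 2).sum()))
            total += brute_pair_probability(disto.probs[i, j], centers, d,
                                            params.lam, params.eps)
    return total


def brute_discrete(conf, disto, params):
    coords = conf.coords
    n = coords.shape[0]
    g = disto.geometry
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if j - i < params.min_separation:
                continue
            if params.subset is not None and (i not in params.subset or j not in params.subset):
                continue
            d = float(np.sqrt(((coords[i] - coords[j]) ** 2).sum()))
            k = int(np.floor((d - g.lower) / g.width))
            k = min(max(k, 0), g.m - 1)
            total += disto.probs[i, j, k]
    return total


def fd_gradient(func, coords, h=1e-6):
    """Central finite-difference gradient of a scalar function of (n,3)."""
    grad = np.zeros_like(coords)
    for i in range(coords.shape[0]):
        for c in range(3):
            plus = coords.copy()
            plus[i, c] += h
            minus = coords.copy()
            minus[i, c] -= h
            grad[i, c] = (func(plus) - func(minus)) / (2 * h)
    return grad


def quaternion_rmsd(a, b):
    """Superposition RMSD via the Kearsley quaternion eigenvalue method."""
    pa = a - a.mean(axis=0)
    pb = b - b.mean(axis=0)
    x1, y1, z1 = pa.T
    x2, y2, z2 = pb.T
    xm, ym, zm = x1 - x2, y1 - y2, z1 - z2
    xp, yp, zp = x1 + x2, y1 + y2, z1 + z2
    K = np.empty((4, 4))
    K[0, 0] = (xm**2 + ym**2 + zm**2).sum()
    K[1, 1] = (yp**2 + zp**2 + xm**2).sum()
    K[2, 2] = (xp**2 + zp**2 + ym**2).sum()
    K[3, 3] = (xp**2 + yp**2 + zm**2).sum()
    K[0, 1] = K[1, 0] = (yp * zm - ym * zp).sum()
    K[0, 2] = K[2, 0] = (xm * zp - xp * zm).sum()
    K[0, 3] = K[3, 0] = (xp * ym - xm * yp).sum()
    K[1, 2] = K[2, 1] = (xm * ym - xp * yp).sum()
    K[1, 3] = K[3, 1] = (xm * zm - xp * zp).sum()
    K[2, 3] = K[3, 2] = (ym * zm - yp * zp).sum()
    lam_min = np.linalg.eigvalsh(K)[0]
    return float(np.sqrt(max(lam_min, 0.0) / len(a)))


def brute_daura(rmsd_matrix, cutoff):
    """Exhaustive re-implementation of largest-neighborhood clustering."""
    n = rmsd_matrix.shape[0]
    remaining = list(range(n))
    labels = [-1] * n
    centers = []
    cid = 0
    while remaining:
        best, best_count = None, -1
        for i in remaining:
            count = sum(1 for j in remaining if rmsd_matrix[i, j] <= cutoff)
            if count > best_count:
                best, best_count = i, count
        members = [j for j in remaining if rmsd_matrix[best, j] <= cutoff]
        for j in members:
            labels[j] = cid
        remaining = [j for j in remaining if j not in members]
        centers.append(best)
        cid += 1
    return np.array(labels), centers


def rigid_motion(coords, rng):
    """Random proper rotation plus translation."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return coords @ R.T + rng.standard_normal(3)
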