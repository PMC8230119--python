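"""Independent reference implementations used only as test oracles.

Each function here deliberately takes a different algorithmic route from the
package code it checks.
"""

import numpy as np


def quaternion_rmsd(ref: np.ndarray, mob: np.ndarray) -> float:
    """Optimal superposition RMSD via the quaternion key-matrix eigenvalue.

    Independent of the SVD/Kabsch route: builds the 4x4 key matrix of the
    correlation tensor and uses its largest eigenvalue (Horn's method).
    """
    a = ref - ref.mean(axis=0)
    b = mob - mob.mean(axis=0)
    M = b.T @ a
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz]])
    lam = np.linalg.eigvalsh(K)[-1]
    e = (a ** 2).sum() + (b ** 2).sum() - 2.0 * lam
    return float(np.sqrt(max(e, 0.0) / len(a)))


def naive_histogram(points: np.ndarray, origin: np.ndarray, voxel: float,
                    dims) -> np.ndarray:
    """Triple-loop voxel histogram with explicit per-point binning."""
    counts = np.zeros(dims, dtype=np.int64)
    lo = np.asarray(origin) - voxel / 2.0
    for p in points:
        idx = []
        ok = True
        for k in range(3):
            i = int(np.floor((p[k] - lo[k]) / voxel))
            if i < 0 or i >= dims[k]:
                ok = False
                break
            idx.append(i)
        if ok:
            counts[idx[0], idx[1], idx[2]] += 1
    return counts


def bfs_components(n_atoms: int, bonds) -> np.ndarray:
    """Brute-force BFS connected components (queue-based, adjacency dict)."""
    from collections import deque

    adj = {i: [] for i in range(n_atoms)}
    for a, b in bonds:
        adj[int(a)].append(int(b))
        adj[int(b)].append(int(a))
    label = np.full(n_atoms, -1)
    comp = 0
    for s in range(n_atoms):
        if label[s] >= 0:
            continue
        q = deque([s])
        label[s] = comp
        while q:
            i = q.popleft()
            for j in adj[i]:
                if label[j] < 0:
                    label[j] = comp
                    q.append(j)
        comp += 1
    return label


def cremer_pople_loop(coords: np.ndarray):
    """Textbook Cremer-Pople formulas as explicit scalar loops.

    Returns (Q, theta_deg, phi_deg); written without numpy vectorisation so
    any broadcasting or sign mistake in the package implementation would
    not be reproduced here.
    """
    import math

    N = 6
    cx = sum(c[0] for c in coords) / N
    cy = sum(c[1] for c in coords) / N
    cz = sum(c[2] for c in coords) / N
    rel = [(c[0] - cx, c[1] - cy, c[2] - cz) for c in coords]
    R1 = [0.0, 0.0, 0.0]
    R2 = [0.0, 0.0, 0.0]
    for j, r in enumerate(rel):
        s = math.sin(2 * math.pi * j / N)
        c = math.cos(2 * math.pi * j / N)
        for k in range(3):
            R1[k] += r[k] * s
            R2[k] += r[k] * c
    n = (R1[1] * R2[2] - R1[2] * R2[1],
         R1[2] * R2[0] - R1[0] * R2[2],
         R1[0] * R2[1] - R1[1] * R2[0])
    norm = math.sqrt(sum(v * v for v in n))
    n = tuple(v / norm for v in n)
    z = [sum(r[k] * n[k] for k in range(3)) for r in rel]
    q2c = math.sqrt(2.0 / N) * sum(z[j] * math.cos(4 * math.pi * j / N)
                                   for j in range(N))
    q2s = -math.sqrt(2.0 / N) * sum(z[j] * math.sin(4 * math.pi * j / N)
                                    for j in range(N))
    q3 = math.sqrt(1.0 / N) * sum(((-1) ** j) * z[j] for j in range(N))
    q2 = math.hypot(q2c, q2s)
    Q = math.hypot(q2, q3)
    theta = math.degrees(math.acos(max(-1.0, min(1.0, q3 / Q))))
    phi = math.degrees(math.atan2(q2s, q2c)) % 360.0
    return Q, theta, phi


def random_rigid(rng):
    """A uniformly random proper rotation matrix and a random translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    return R, t
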