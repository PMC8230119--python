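"""Carbohydrate-specific geometry: ring puckering and chain shape.

Cremer-Pople generalized puckering coordinates classify each pyranose frame
as chair (theta near a pole) or boat/skew-boat (equatorial band); the chain
module measures the centroid-centroid-centroid bend angle of oligosaccharide
chains (beta-(1->3)-galactans bend by roughly 120 degrees, matching the
peripheral-central-peripheral aromatic triads of the Yariv reagent) and
assigns bound saccharide triplets to one of the three cyclic aromatic
triads.

Ring atom convention: O5 first, then C1..C5 (puckering poles swap if the
order is reversed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .interactions import RingDescriptor
from .trajio import MolecularTopology, Trajectory

__all__ = ["PuckerState", "ChainGeometry", "cremer_pople",
           "pucker_timeseries", "chain_bend", "triad_alignment",
           "pyranose_ring_order", "triad_occupancy"]

CHAIR_THETA_LO = 45.0    # theta below this = 4C1-type pole
CHAIR_THETA_HI = 135.0   # theta above this = 1C4-type pole


@dataclass
class PuckerState:
    """Cremer-Pople puckering coordinates of one six-membered ring."""

    atoms: list[int]
    Q: float          # total puckering amplitude, angstrom
    theta: float      # degrees, 0..180; poles are chairs
    phi: float        # degrees, 0..360; pseudorotation phase
    label: str        # 4C1 | 1C4 | boat | skew-boat | planar

    @property
    def is_chair(self) -> bool:
        return self.label in ("4C1", "1C4")


@dataclass
class ChainGeometry:
    """Per-residue ring centroids and derived chain-shape measures."""

    centroids: np.ndarray        # (n_residues, 3) angstrom
    bend_angles: np.ndarray      # (n_residues - 2,) degrees
    torsions: np.ndarray | None = None   # (n_linkages, 2) phi/psi degrees


def cremer_pople(coords: np.ndarray, atoms: list[int] | None = None,
                 label_boat_families: bool = True) -> PuckerState:
    """Cremer-Pople (Q, theta, phi) for six ordered ring atoms.

    ``coords`` is (6, 3) in ring order O5, C1..C5.  The mean plane is the
    standard Cremer-Pople plane (zero net displacement and zero net first
    Fourier moment); theta = 0 corresponds to the 4C1-type pole under this
    atom-order convention.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (6, 3):
        raise ValueError(f"expected 6 ring atoms, got shape {coords.shape}")
    N = 6
    center = coords.mean(axis=0)
    rel = coords - center
    j = np.arange(N)
    R1 = np.sum(rel * np.sin(2 * np.pi * j / N)[:, None], axis=0)
    R2 = np.sum(rel * np.cos(2 * np.pi * j / N)[:, None], axis=0)
    n = np.cross(R1, R2)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("degenerate ring geometry: cannot define mean plane")
    n = n / norm
    z = rel @ n
    q2cos = np.sqrt(2.0 / N) * np.sum(z * np.cos(4 * np.pi * j / N))
    q2sin = -np.sqrt(2.0 / N) * np.sum(z * np.sin(4 * np.pi * j / N))
    q3 = np.sqrt(1.0 / N) * np.sum(((-1.0) ** j) * z)
    q2 = np.hypot(q2cos, q2sin)
    Q = float(np.hypot(q2, q3))
    if Q < 1e-12:
        return PuckerState(list(atoms) if atoms is not None else [],
                           0.0, 0.0, 0.0, "planar")
    theta = float(np.degrees(np.arccos(np.clip(q3 / Q, -1, 1))))
    phi = float(np.degrees(np.arctan2(q2sin, q2cos)) % 360.0)
    if theta < CHAIR_THETA_LO:
        label = "4C1"
    elif theta > CHAIR_THETA_HI:
        label = "1C4"
    elif label_boat_families:
        # boats sit at phi = 60k deg, skew(twist)-boats midway between
        label = "boat" if (phi / 30.0) % 2 < 1.0 else "skew-boat"
    else:
        label = "boat/skew-boat"
    return PuckerState(list(atoms) if atoms is not None else [],
                       Q, theta, phi, label)


def pyranose_ring_order(ring: RingDescriptor,
                        topology: MolecularTopology) -> list[int]:
    """Reorder a detected sugar ring to the O5, C1..C5 convention.

    Uses atom names when they follow the standard pyranose naming; falls
    back to starting at the ring oxygen and walking toward the neighbour
    bonded to an exocyclic oxygen (the anomeric carbon C1).
    """
    atoms = list(ring.atoms)
    names = [topology.names[i] for i in atoms]
    if "O5" in names and "C1" in names:
        start = atoms[names.index("O5")]
    else:
        oxy = [i for i in atoms if topology.elements[i] == "O"]
        if not oxy:
            raise ValueError("ring has no oxygen: not a pyranose")
        start = oxy[0]
    k = atoms.index(start)
    cyc = atoms[k:] + atoms[:k]
    nxt, prv = cyc[1], cyc[-1]
    prefer = None
    for cand in (nxt, prv):
        if topology.names[cand] == "C1":
            prefer = cand
            break
        exo_o = any(topology.elements[j] == "O" and j not in atoms
                    for j in topology.neighbors(cand))
        if exo_o and prefer is None:
            prefer = cand
    if prefer == prv:
        cyc = [cyc[0]] + cyc[1:][::-1]
    return cyc


def pucker_timeseries(traj: Trajectory,
                      rings: list[tuple[str, list[int]]]) -> tuple[pd.DataFrame,
                                                                   dict]:
    """Per-frame puckering table and chair fraction per residue.

    ``rings`` maps residue labels to their 6 ring atom indices in O5,C1..C5
    order.  Returns a DataFrame with columns
    ``frame,residue,Q_A,theta_deg,phi_deg,label`` and a dict of per-residue
    chair fractions (frames with theta in a chair pole / total frames) —
    the quantitative stand-in for visually checking that sugars stay in the
    chair.
    """
    rows = []
    chair_counts = {label: 0 for label, _ in rings}
    for f in range(traj.n_frames):
        for label, atom_ids in rings:
            st = cremer_pople(traj.coords[f, atom_ids], atom_ids)
            rows.append((f, label, st.Q, st.theta, st.phi, st.label))
            if st.is_chair:
                chair_counts[label] += 1
    table = pd.DataFrame(rows, columns=["frame", "residue", "Q_A",
                                        "theta_deg", "phi_deg", "label"])
    fractions = {label: chair_counts[label] / traj.n_frames
                 for label, _ in rings}
    return table, fractions


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1u = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    ang = np.degrees(np.arctan2(np.dot(np.cross(b1u, v), w), np.dot(v, w)))
    return float(-ang if ang == -180.0 else ang)


def chain_bend(centroids: np.ndarray,
               linkage_atoms: np.ndarray | None = None) -> ChainGeometry:
    """Bend angles along a chain of residue ring centroids.

    The angle at interior residue i is the angle centroid_{i-1} -
    centroid_i - centroid_{i+1} in degrees (a hexasaccharide yields 4).
    Fewer than 3 residues give an empty angle list.  ``linkage_atoms``
    (n_linkages, 2, 4, 3) optionally supplies the phi and psi atom
    quadruples of each glycosidic linkage (e.g. O5-C1-O3'-C3' and
    C1-O3'-C3'-C2' for a 1->3 link); torsions come back as
    (n_linkages, 2) signed degrees in (-180, 180].
    """
    centroids = np.asarray(centroids, dtype=float)
    n = len(centroids)
    if n < 3:
        return ChainGeometry(centroids, np.empty(0))
    v1 = centroids[:-2] - centroids[1:-1]
    v2 = centroids[2:] - centroids[1:-1]
    cosang = np.sum(v1 * v2, axis=1) / (np.linalg.norm(v1, axis=1)
                                        * np.linalg.norm(v2, axis=1))
    angles = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
    torsions = None
    if linkage_atoms is not None:
        linkage_atoms = np.asarray(linkage_atoms, dtype=float)
        linkage_atoms = linkage_atoms.reshape(-1, 2, 4, 3)
        torsions = np.array([[_dihedral(*link[0]), _dihedral(*link[1])]
                             for link in linkage_atoms])
    return ChainGeometry(centroids, angles, torsions)


def residue_ring_centroids(traj_or_coords, rings: list[list[int]]) -> np.ndarray:
    """Mean position of each residue's 6 ring atoms (per frame if 3D input).

    Using only the ring atoms keeps the centroid insensitive to exocyclic
    arm motion.
    """
    coords = np.asarray(traj_or_coords.coords
                        if isinstance(traj_or_coords, Trajectory)
                        else traj_or_coords, dtype=float)
    if coords.ndim == 2:
        return np.stack([coords[r].mean(axis=0) for r in rings])
    return np.stack([coords[:, r, :].mean(axis=1) for r in rings], axis=1)


def triad_alignment(res_centroids: np.ndarray,
                    yariv_rings: list[RingDescriptor],
                    max_mean_dist: float = 6.0) -> tuple[str, float]:
    """Assign three adjacent saccharide residues to an aromatic ring triad.

    The three cyclic triads of a Yariv molecule are
    peripheral1-central-peripheral2, peripheral2-central-peripheral3 and
    peripheral3-central-peripheral1 (peripherals ordered by azimuth about
    the central ring normal).  The assignment minimises the summed
    residue-centroid-to-ring-centroid distance over the three cyclic triads
    (both chain directions tried); sums of at least ``3 * max_mean_dist``
    give ``"unbound"``.  Returns ``(triad_label, distance_sum)``.
    """
    central = next((r for r in yariv_rings if r.role == "central"), None)
    periph = [r for r in yariv_rings if r.role == "peripheral"]
    if central is None or len(periph) != 3:
        raise ValueError("triad alignment needs 1 central + 3 peripheral rings")
    rel = [p.centroid - central.centroid for p in periph]
    e1 = rel[0] - np.dot(rel[0], central.normal) * central.normal
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(central.normal, e1)
    azim = [np.arctan2(np.dot(r, e2), np.dot(r, e1)) % (2 * np.pi)
            for r in rel]
    p_sorted = [periph[i] for i in np.argsort(azim)]

    res = np.asarray(res_centroids, dtype=float)
    best_label, best_sum = "unbound", np.inf
    for start in range(3):
        triad = [p_sorted[start], central, p_sorted[(start + 1) % 3]]
        label = f"p{start + 1}-c-p{(start + 1) % 3 + 1}"
        for window in _windows3(res):
            for seq in (window, window[::-1]):
                s = sum(np.linalg.norm(seq[k] - triad[k].centroid)
                        for k in range(3))
                if s < best_sum:
                    best_sum, best_label = s, label
    if best_sum >= 3 * max_mean_dist:
        return "unbound", float(best_sum)
    return best_label, float(best_sum)


def _windows3(res: np.ndarray):
    if len(res) < 3:
        return
    for i in range(len(res) - 2):
        yield res[i:i + 3]


def triad_occupancy(assignments: list[str]) -> dict[str, float]:
    """Fraction of frames in each triad; 'unbound' absorbs the remainder."""
    n = len(assignments)
    out: dict[str, float] = {}
    for a in assignments:
        out[a] = out.get(a, 0.0) + 1.0 / n
    return out
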