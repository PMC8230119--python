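"""Noncovalent-interaction detection and stacking-topology analysis.

Covers the contact types that dominate Yariv-reagent assemblies: face-to-face
and edge-to-face aromatic stacking (pi-pi), carbohydrate-aromatic CH/pi
contacts, and hydrogen bonds; plus the per-frame stacking graph of multi-unit
assemblies with signed inter-unit twist (handedness) and irregularity
metrics (interplanar angle, axial rise, lateral slip).

Geometric thresholds follow common structural-chemistry practice and are
exposed on :class:`Thresholds`; every record carries its raw metrics so
results can be re-thresholded post hoc.

Hydrogens are optional throughout: when a donor lacks explicit hydrogens,
positions are reconstructed at ideal geometry from the heavy-atom neighbours
(hybridisation inferred from the neighbour count), so heavy-atom-only
trajectories are fully supported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .trajio import MolecularTopology

__all__ = [
    "Thresholds", "RingDescriptor", "InteractionRecord", "StackTopology",
    "detect_rings", "classify_pi_pi", "classify_ch_pi", "find_ch_pi",
    "detect_hbonds", "stack_topology", "stack_twist",
    "irregularity_profile", "handedness", "reconstruct_hydrogens",
]

CH_BOND = 1.09
OH_BOND = 0.96
NH_BOND = 1.01


@dataclass(frozen=True)
class Thresholds:
    """Geometric criteria for the interaction classifiers.

    Units: distances in angstrom, angles in degrees.
    """

    pi_pi_dist: float = 5.5       # centroid-centroid, parallel stack
    pi_pi_angle: float = 30.0     # max interplanar angle, parallel
    pi_pi_offset: float = 2.5     # max lateral offset, parallel
    t_dist: float = 6.0           # centroid-centroid, T-shaped
    t_angle: float = 60.0         # min interplanar angle, T-shaped
    chpi_dist: float = 3.0        # H...ring-centroid
    chpi_angle: float = 120.0     # C-H...centroid
    chpi_proj: float = 1.5        # in-plane offset of H from centroid
    hbond_da: float = 3.5         # donor...acceptor
    hbond_angle: float = 130.0    # D-H...A


DEFAULT_THRESHOLDS = Thresholds()


@dataclass
class RingDescriptor:
    """A detected 5- or 6-membered ring with its plane geometry."""

    atoms: list[int]              # ordered around the ring
    centroid: np.ndarray          # angstrom
    normal: np.ndarray            # unit, right-handed w.r.t. atom order
    planarity: float              # RMS deviation from best-fit plane, angstrom
    aromatic: bool
    role: str                     # central | peripheral | saccharide | other
    molecule: int

    @property
    def size(self) -> int:
        return len(self.atoms)


@dataclass
class InteractionRecord:
    """One classified pairwise contact with its raw geometry metrics."""

    frame: int
    kind: str                     # pi_pi_parallel | pi_pi_tshaped | ch_pi | hbond
    mol_a: int
    mol_b: int
    atom_a: int = -1              # donor heavy atom (ch_pi, hbond)
    atom_b: int = -1              # acceptor heavy atom (hbond)
    ring_a: int = -1              # ring list index, where applicable
    ring_b: int = -1
    metrics: dict = field(default_factory=dict)
    intramolecular: bool = False
    donor_name: str = ""


@dataclass
class StackTopology:
    """Per-frame stacking graph of aromatic multi-ring units.

    Nodes are molecule indices; edges connect molecules sharing at least
    ``k`` parallel-stacked ring pairs.  ``order`` ranks the stacked
    molecules by projection onto the stack axis; ``twists`` holds the
    signed inter-unit rotation (degrees, folded to (-60, 60] by the 3-fold
    arm symmetry) for adjacent pairs in that order.
    """

    graph: nx.Graph
    axis: np.ndarray
    order: list[int]
    twists: dict = field(default_factory=dict)       # (i, j) -> degrees
    profile: list = field(default_factory=list)      # per-pair irregularity


# ---------------------------------------------------------------------------
# ring perception
# ---------------------------------------------------------------------------

def _order_cycle(nodes: list[int], adj: dict[int, set]) -> list[int] | None:
    """Order a set of cycle nodes by walking ring-internal bonds."""
    nodeset = set(nodes)
    start = nodes[0]
    order = [start]
    prev = None
    cur = start
    while True:
        nbrs = [n for n in adj[cur] if n in nodeset and n != prev]
        if not nbrs:
            return None
        prev, cur = cur, nbrs[0]
        if cur == start:
            break
        if cur in order:
            return None
        order.append(cur)
        if len(order) > len(nodes):
            return None
    return order if len(order) == len(nodes) else None


def _ring_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Centroid, right-handed unit normal (Newell) and planarity RMS."""
    centroid = coords.mean(axis=0)
    rel = coords - centroid
    # Newell sum respects the loop orientation (sign convention)
    normal = np.sum(np.cross(rel, np.roll(rel, -1, axis=0)), axis=0)
    normal = normal / np.linalg.norm(normal)
    planarity = float(np.sqrt(np.mean((rel @ normal) ** 2)))
    return centroid, normal, planarity


def detect_rings(topology: MolecularTopology, coords: np.ndarray,
                 max_planarity_aromatic: float = 0.1) -> list[RingDescriptor]:
    """Find 5-/6-membered rings and assign aromaticity and roles.

    Rings come from the minimum cycle basis of each molecule's bond graph
    (the smallest-set-of-smallest-rings surrogate).  A six-ring of only C/N
    atoms with planarity RMS below ``max_planarity_aromatic`` is aromatic.
    Roles: ``central`` = aromatic ring bearing >= 3 exocyclic nitrogen
    substituents (the diazenyl-linked hub of a Yariv molecule),
    ``peripheral`` = any other aromatic ring, ``saccharide`` = non-aromatic
    ring containing oxygen, else ``other``.
    """
    coords = np.asarray(coords, dtype=float)
    adj = {i: set() for i in range(topology.n_atoms)}
    for a, b in topology.bonds:
        adj[int(a)].add(int(b))
        adj[int(b)].add(int(a))
    rings: list[RingDescriptor] = []
    for m in range(topology.n_molecules):
        atoms = topology.molecule_atoms(m)
        G = nx.Graph()
        G.add_nodes_from(atoms.tolist())
        G.add_edges_from([(int(a), int(b)) for a, b in topology.bonds
                          if topology.molecule_of[a] == m])
        for cycle in nx.minimum_cycle_basis(G):
            if len(cycle) not in (5, 6):
                continue
            ordered = _order_cycle(cycle, adj)
            if ordered is None:
                continue
            centroid, normal, planarity = _ring_plane(coords[ordered])
            elems = [topology.elements[i] for i in ordered]
            aromatic = (len(ordered) == 6
                        and all(e in ("C", "N") for e in elems)
                        and planarity < max_planarity_aromatic)
            if aromatic:
                exo_n = sum(1 for i in ordered for j in adj[i]
                            if j not in ordered and topology.elements[j] == "N")
                role = "central" if exo_n >= 3 else "peripheral"
            elif "O" in elems:
                role = "saccharide"
            else:
                role = "other"
            rings.append(RingDescriptor(ordered, centroid, normal, planarity,
                                        aromatic, role, m))
    return rings


def update_ring_geometry(rings: list[RingDescriptor], coords: np.ndarray,
                         max_planarity_aromatic: float = 0.1
                         ) -> list[RingDescriptor]:
    """Recompute ring geometry for a new frame, keeping membership and roles.

    Ring membership and role depend only on connectivity, so per-frame
    analysis re-derives centroid, normal, planarity and the aromatic flag
    without re-running cycle perception.
    """
    coords = np.asarray(coords, dtype=float)
    out = []
    for r in rings:
        centroid, normal, planarity = _ring_plane(coords[r.atoms])
        aromatic = (r.role in ("central", "peripheral")
                    and planarity < max_planarity_aromatic)
        out.append(RingDescriptor(r.atoms, centroid, normal, planarity,
                                  aromatic, r.role, r.molecule))
    return out


# ---------------------------------------------------------------------------
# pairwise classifiers
# ---------------------------------------------------------------------------

def _fold_angle(deg: float) -> float:
    """Angle between undirected plane normals, folded into [0, 90]."""
    deg = deg % 180.0
    return 180.0 - deg if deg > 90.0 else deg


def classify_pi_pi(ring_a: RingDescriptor, ring_b: RingDescriptor,
                   thresholds: Thresholds = DEFAULT_THRESHOLDS):
    """Classify an aromatic ring pair as parallel / T-shaped / none.

    Parallel: centroid distance <= 5.5 A, interplanar angle <= 30 deg and
    lateral offset <= 2.5 A.  T-shaped: distance <= 6.0 A and angle >= 60
    deg.  Returns ``(label, metrics)`` with the raw metrics always filled.
    """
    if not (ring_a.aromatic and ring_b.aromatic):
        raise TypeError("pi-pi classification requires two aromatic rings")
    d = ring_b.centroid - ring_a.centroid
    dist = float(np.linalg.norm(d))
    cosang = float(np.clip(np.dot(ring_a.normal, ring_b.normal), -1, 1))
    angle = _fold_angle(np.degrees(np.arccos(cosang)))
    off_a = np.linalg.norm(d - np.dot(d, ring_a.normal) * ring_a.normal)
    off_b = np.linalg.norm(d - np.dot(d, ring_b.normal) * ring_b.normal)
    offset = float(0.5 * (off_a + off_b))
    metrics = {"dist_A": dist, "angle_deg": angle, "offset_A": offset}
    if (dist <= thresholds.pi_pi_dist and angle <= thresholds.pi_pi_angle
            and offset <= thresholds.pi_pi_offset):
        return "pi_pi_parallel", metrics
    if dist <= thresholds.t_dist and angle >= thresholds.t_angle:
        return "pi_pi_tshaped", metrics
    return "none", metrics


def classify_ch_pi(c_pos: np.ndarray, h_pos: np.ndarray,
                   ring: RingDescriptor,
                   thresholds: Thresholds = DEFAULT_THRESHOLDS):
    """Classify one C-H bond against one aromatic ring face.

    CH/pi requires H within 3.0 A of the ring centroid, a C-H...centroid
    angle >= 120 deg, and the in-plane projection of H within 1.5 A of the
    centroid.  Returns ``(label, metrics)``.
    """
    v = ring.centroid - h_pos
    dist = float(np.linalg.norm(v))
    hc = c_pos - h_pos
    # angle at H between the C-H bond and the approach to the centroid
    cosang = float(np.clip(np.dot(hc, v) /
                           (np.linalg.norm(hc) * max(dist, 1e-12)), -1, 1))
    angle = float(np.degrees(np.arccos(cosang)))
    rel = h_pos - ring.centroid
    proj = float(np.linalg.norm(rel - np.dot(rel, ring.normal) * ring.normal))
    metrics = {"dist_A": dist, "angle_deg": angle, "proj_A": proj}
    if (dist <= thresholds.chpi_dist and angle >= thresholds.chpi_angle
            and proj <= thresholds.chpi_proj):
        return "ch_pi", metrics
    return "none", metrics


# ---------------------------------------------------------------------------
# hydrogen handling
# ---------------------------------------------------------------------------

def _unit(v):
    return v / np.linalg.norm(v)


def reconstruct_hydrogens(topology: MolecularTopology, coords: np.ndarray,
                          atom: int, bond_length: float = CH_BOND,
                          aromatic_atoms: set | None = None) -> list[np.ndarray]:
    """Ideal-geometry hydrogen positions for a heavy atom without explicit H.

    Hybridisation is inferred from the heavy-neighbour count: three heavy
    neighbours give one tetrahedral H; two give one in-plane H for atoms in
    aromatic rings, otherwise a tetrahedral CH2 pair; one heavy neighbour
    is rotationally ambiguous and yields an empty list (callers with a
    candidate acceptor should use :func:`best_case_hydrogen` instead).
    """
    heavy = [int(j) for j in topology.neighbors(atom)
             if topology.elements[j] != "H"]
    p = coords[atom]
    if len(heavy) == 3:
        d = -sum(_unit(coords[j] - p) for j in heavy)
        if np.linalg.norm(d) < 1e-8:
            return []
        return [p + bond_length * _unit(d)]
    if len(heavy) == 2:
        u1, u2 = (_unit(coords[j] - p) for j in heavy)
        bis = -(u1 + u2)
        if np.linalg.norm(bis) < 1e-8:
            return []
        bis = _unit(bis)
        if aromatic_atoms and atom in aromatic_atoms:
            return [p + bond_length * bis]
        perp = np.cross(u1, u2)
        if np.linalg.norm(perp) < 1e-8:
            return []
        perp = _unit(perp)
        half = np.radians(54.25)    # half the ideal H-C-H angle
        return [p + bond_length * _unit(np.cos(half) * bis + s * np.sin(half) * perp)
                for s in (+1.0, -1.0)]
    return []


def best_case_hydrogen(topology: MolecularTopology, coords: np.ndarray,
                       donor: int, acceptor_pos: np.ndarray,
                       bond_length: float) -> np.ndarray | None:
    """Optimal rotamer H for a one-neighbour donor (hydroxyl-like).

    The O-H (or N-H) direction about a single heavy neighbour is a free
    rotation; the H is placed in the neighbour-donor-acceptor plane at the
    ideal tetrahedral angle from the neighbour-donor bond, on the acceptor
    side — the most favourable rotamer for the candidate hydrogen bond.
    """
    heavy = [int(j) for j in topology.neighbors(donor)
             if topology.elements[j] != "H"]
    if len(heavy) != 1:
        return None
    p = coords[donor]
    u = _unit(p - coords[heavy[0]])       # neighbour -> donor
    a = acceptor_pos - p
    a_perp = a - np.dot(a, u) * u
    if np.linalg.norm(a_perp) < 1e-8:
        a_perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(a_perp) < 1e-8:
            a_perp = np.cross(u, [0.0, 1.0, 0.0])
    a_perp = _unit(a_perp)
    theta = np.radians(180.0 - 109.5)     # tilt from the extended direction
    direction = np.cos(theta) * u + np.sin(theta) * a_perp
    return p + bond_length * direction


def _explicit_hydrogens(topology: MolecularTopology, atom: int) -> list[int]:
    return [int(j) for j in topology.neighbors(atom)
            if topology.elements[j] == "H"]


# ---------------------------------------------------------------------------
# system-level detectors
# ---------------------------------------------------------------------------

def find_ch_pi(topology: MolecularTopology, coords: np.ndarray,
               rings: list[RingDescriptor] | None = None,
               thresholds: Thresholds = DEFAULT_THRESHOLDS,
               include_intramolecular: bool = False,
               frame: int = 0) -> list[InteractionRecord]:
    """All CH/pi contacts of aliphatic/saccharide C-H donors to aromatic rings.

    Donor hydrogens are explicit where present, else reconstructed at ideal
    geometry.  Each record names the donating carbon (e.g. ``C3``) so
    galactose-face analyses (C3/C4/C5/C6 donation) read directly off the
    table.
    """
    coords = np.asarray(coords, dtype=float)
    if rings is None:
        rings = detect_rings(topology, coords)
    aromatic_rings = [(i, r) for i, r in enumerate(rings) if r.aromatic]
    aromatic_atoms = {a for _, r in aromatic_rings for a in r.atoms}
    records = []
    reach = thresholds.chpi_dist + CH_BOND
    for c in range(topology.n_atoms):
        if topology.elements[c] != "C" or c in aromatic_atoms:
            continue
        h_explicit = _explicit_hydrogens(topology, c)
        h_positions = ([coords[h] for h in h_explicit] if h_explicit
                       else reconstruct_hydrogens(topology, coords, c))
        if not h_positions:
            continue
        for ri, ring in aromatic_rings:
            if not include_intramolecular \
                    and ring.molecule == topology.molecule_of[c]:
                continue
            if np.linalg.norm(ring.centroid - coords[c]) > reach + CH_BOND:
                continue
            for h_pos in h_positions:
                label, metrics = classify_ch_pi(coords[c], h_pos, ring,
                                                thresholds)
                if label == "ch_pi":
                    records.append(InteractionRecord(
                        frame, "ch_pi", int(topology.molecule_of[c]),
                        ring.molecule, atom_a=c, ring_b=ri, metrics=metrics,
                        intramolecular=(ring.molecule
                                        == topology.molecule_of[c]),
                        donor_name=topology.names[c]))
                    break   # one record per C-H...ring contact
    return records


def detect_hbonds(topology: MolecularTopology, coords: np.ndarray,
                  thresholds: Thresholds = DEFAULT_THRESHOLDS,
                  include_intramolecular: bool = False,
                  frame: int = 0) -> list[InteractionRecord]:
    """Hydrogen bonds: O/N donors with H to O/N acceptors.

    Criteria: donor...acceptor distance <= 3.5 A and D-H...A angle >= 130
    deg.  Donors without explicit hydrogens get an ideal-geometry H
    (best-case rotamer for hydroxyl-like donors), which makes the detector
    usable on heavy-atom-only trajectories.
    """
    coords = np.asarray(coords, dtype=float)
    on = [i for i in range(topology.n_atoms)
          if topology.elements[i] in ("O", "N")]

    def _plausible_implicit_donor(i: int) -> bool:
        # without explicit H, only donate where the heavy-atom valence
        # implies one: hydroxyl-like O, or amine N not in an azo/diazenyl
        # group (ethers and N=N linkers carry no hydrogen)
        heavy = [int(j) for j in topology.neighbors(i)
                 if topology.elements[j] != "H"]
        if topology.elements[i] == "O":
            return len(heavy) <= 1
        return (len(heavy) <= 2
                and not any(topology.elements[j] == "N" for j in heavy))

    records = []
    for d in on:
        h_explicit = _explicit_hydrogens(topology, d)
        if not h_explicit and not _plausible_implicit_donor(d):
            continue
        bond_length = OH_BOND if topology.elements[d] == "O" else NH_BOND
        for a in on:
            if a == d:
                continue
            if not include_intramolecular and \
                    topology.molecule_of[a] == topology.molecule_of[d]:
                continue
            da = float(np.linalg.norm(coords[a] - coords[d]))
            if da > thresholds.hbond_da:
                continue
            if h_explicit:
                h_positions = [coords[h] for h in h_explicit]
            else:
                h = best_case_hydrogen(topology, coords, d, coords[a],
                                       bond_length)
                if h is None:
                    h_positions = reconstruct_hydrogens(
                        topology, coords, d, bond_length)
                else:
                    h_positions = [h]
            best = None
            for h_pos in h_positions:
                dh = h_pos - coords[d]
                ha = coords[a] - h_pos
                cosang = float(np.clip(
                    np.dot(dh, ha) /
                    (np.linalg.norm(dh) * max(np.linalg.norm(ha), 1e-12)),
                    -1, 1))
                angle = 180.0 - np.degrees(np.arccos(cosang))
                if best is None or angle > best:
                    best = angle
            if best is not None and best >= thresholds.hbond_angle:
                records.append(InteractionRecord(
                    frame, "hbond", int(topology.molecule_of[d]),
                    int(topology.molecule_of[a]), atom_a=d, atom_b=a,
                    metrics={"dist_A": da, "angle_deg": best},
                    intramolecular=(topology.molecule_of[a]
                                    == topology.molecule_of[d]),
                    donor_name=topology.names[d]))
    return records


# ---------------------------------------------------------------------------
# stacking topology
# ---------------------------------------------------------------------------

def stack_topology(rings: list[RingDescriptor], k: int = 1,
                   thresholds: Thresholds = DEFAULT_THRESHOLDS) -> StackTopology:
    """Build the stacking graph of one frame from its detected rings.

    Molecules owning at least one aromatic ring are nodes; an edge requires
    at least ``k`` parallel-stacked (pi_pi_parallel) ring pairs between two
    molecules.  The stack axis is the principal axis of the central-ring
    centroids (all aromatic centroids when no central rings exist); node
    order is the rank of each molecule's aromatic-centroid projection on
    that axis.
    """
    by_mol: dict[int, list[RingDescriptor]] = {}
    for r in rings:
        if r.aromatic:
            by_mol.setdefault(r.molecule, []).append(r)
    nodes = sorted(by_mol)
    G = nx.Graph()
    G.add_nodes_from(nodes)
    for ii, mi in enumerate(nodes):
        for mj in nodes[ii + 1:]:
            n_parallel = sum(
                1 for ra in by_mol[mi] for rb in by_mol[mj]
                if classify_pi_pi(ra, rb, thresholds)[0] == "pi_pi_parallel")
            if n_parallel >= k:
                G.add_edge(mi, mj, n_parallel=n_parallel)

    centrals = {m: next((r for r in rl if r.role == "central"), None)
                for m, rl in by_mol.items()}
    axis_pts = np.array([centrals[m].centroid if centrals[m] is not None
                         else np.mean([r.centroid for r in by_mol[m]], axis=0)
                         for m in nodes]) if nodes else np.zeros((0, 3))
    if len(axis_pts) >= 2:
        rel = axis_pts - axis_pts.mean(axis=0)
        _, _, vt = np.linalg.svd(rel, full_matrices=False)
        axis = vt[0]
        if axis[np.argmax(np.abs(axis))] < 0:
            axis = -axis
    else:
        axis = np.array([0.0, 0.0, 1.0])

    stacked = [m for m in nodes if G.degree[m] > 0]
    proj = {m: float(np.dot(axis_pts[nodes.index(m)], axis)) for m in nodes}
    order = sorted(stacked, key=lambda m: proj[m])
    if len(nx.cycle_basis(G)):
        warnings.warn("stacking graph contains a cycle; order reported by "
                      "axis projection within each connected path",
                      stacklevel=2)

    topo = StackTopology(G, axis, order)
    for a, b in zip(order[:-1], order[1:]):
        if not G.has_edge(a, b):
            continue
        try:
            topo.twists[(a, b)] = stack_twist(by_mol[a], by_mol[b], axis)
        except ValueError:
            pass
        ca, cb = centrals[a], centrals[b]
        if ca is not None and cb is not None:
            d = cb.centroid - ca.centroid
            rise = float(abs(np.dot(d, axis)))
            slip = float(np.linalg.norm(d - np.dot(d, axis) * axis))
            cosang = float(np.clip(np.dot(ca.normal, cb.normal), -1, 1))
            angle = _fold_angle(np.degrees(np.arccos(cosang)))
            topo.profile.append({"pair": (a, b), "angle_deg": angle,
                                 "rise_A": rise, "slip_A": slip})
    return topo


def stack_twist(rings_i: list[RingDescriptor], rings_j: list[RingDescriptor],
                axis: np.ndarray) -> float:
    """Signed inter-unit rotation about the stack axis, in (-60, 60] degrees.

    Each unit's in-plane reference vector runs from its central-ring
    centroid to a peripheral-ring centroid; because the three arms are
    chemically equivalent the twist is defined modulo 120 degrees and
    folded to a unique representative.  Positive twist = right-handed screw
    along the axis oriented from unit i to unit j.
    """
    def _ref(rings):
        central = next((r for r in rings if r.role == "central"), None)
        periph = [r for r in rings if r.role == "peripheral"]
        if central is None or not periph:
            raise ValueError("twist undefined: unit lacks central or "
                             "peripheral rings")
        return central.centroid, periph[0].centroid - central.centroid

    ci, vi = _ref(rings_i)
    cj, vj = _ref(rings_j)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    if np.dot(cj - ci, axis) < 0:
        axis = -axis
    vi = vi - np.dot(vi, axis) * axis
    vj = vj - np.dot(vj, axis) * axis
    ang = np.degrees(np.arctan2(np.dot(np.cross(vi, vj), axis),
                                np.dot(vi, vj)))
    folded = (ang + 60.0) % 120.0 - 60.0
    if folded <= -60.0 + 1e-12 and not np.isclose(ang % 120.0, 60.0):
        folded = 60.0
    if np.isclose(folded, -60.0):
        folded = 60.0
    return float(folded)


def irregularity_profile(stack: StackTopology) -> list[dict]:
    """Per-adjacent-pair deviation from ideal stacking.

    Each entry holds the interplanar angle between central-ring normals
    (degrees), the axial rise and the lateral slip (angstrom).  Empty for
    single molecules or unstacked systems.
    """
    return list(stack.profile)


def handedness(twists) -> float:
    """Mean sign of the twist angles: +1 all right-handed, -1 all left.

    Exact zeros contribute 0; the statistic negates under mirror inversion
    of the coordinates.
    """
    t = np.asarray(list(twists), dtype=float)
    if len(t) == 0:
        return 0.0
    return float(np.mean(np.sign(t)))
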