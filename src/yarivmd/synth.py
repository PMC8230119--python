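"""Synthetic trajectories with known ground truth.

Every generator returns ``(topology, trajectory, ground_truth)`` where the
ground truth is a JSON-serialisable record of the parameters and any latent
state (well indices, face states, conformer labels), enabling closed-loop
parameter-recovery tests of the analysis pipeline.

Two deliberate simplifications, documented here because they bound what the
generators can validate:

* Boltzmann clouds are drawn directly from the target distribution
  (Gaussian sampling), not integrated by molecular dynamics — they test the
  map analysis, not dynamics.
* The Yariv mimic is schematic: correct ring count (1 central + 3
  peripheral aromatic six-rings on diazenyl linkers, optional pyranoses),
  exact 3-fold arm arrangement and planarity, but no chemically
  parameterised bond lengths beyond typical values.  This is sufficient for
  every classifier's geometric contract.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import DEFAULT_TEMPERATURE, kT
from .trajio import MolecularTopology, Trajectory, write_structure, \
    write_trajectory

__all__ = [
    "SyntheticSpec", "generate", "build_yariv_mimic", "build_benzene",
    "build_pyranose_templates",
    "gen_boltzmann_cloud", "gen_rigid_stack", "gen_galactan_chain",
    "gen_face_migration", "gen_pucker_mix", "write_outputs",
]

RING_CC = 1.39        # aromatic C-C, angstrom
AZO_CN = 1.40         # C-N single
AZO_NN = 1.25         # N=N
PYRANOSE_R = 1.46     # pyranose ring "radius"
CHAIR_Z = 0.25        # chair out-of-plane displacement
BOAT_Z = 0.30


@dataclass
class SyntheticSpec:
    """Declarative recipe for a synthetic trajectory.

    ``kind`` is one of ``boltzmann_cloud``, ``rigid_stack``,
    ``galactan_chain``, ``face_migration``, ``pucker_mix``; ``params`` holds
    kind-specific keyword arguments.  A fixed seed yields byte-identical
    output files.
    """

    kind: str
    params: dict = field(default_factory=dict)
    temperature: float = DEFAULT_TEMPERATURE
    seed: int = 0

    @classmethod
    def from_config(cls, path) -> "SyntheticSpec":
        """Parse a ``key = value`` config file (one pair per line, # comments).

        Keys ``kind``, ``temperature`` and ``seed`` are reserved; all others
        go to ``params``.  Values are parsed as JSON where possible (so
        lists and numbers work), else kept as strings.
        """
        kind, temperature, seed, params = None, DEFAULT_TEMPERATURE, 0, {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"expected 'key = value', got {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            try:
                val = json.loads(val)
            except json.JSONDecodeError:
                pass
            if key == "kind":
                kind = val
            elif key == "temperature":
                temperature = float(val)
            elif key == "seed":
                seed = int(val)
            else:
                params[key] = val
        if kind is None:
            raise ValueError("config missing required key 'kind'")
        return cls(kind, params, temperature, seed)


def generate(spec: SyntheticSpec):
    """Dispatch a spec to its generator."""
    generators = {
        "boltzmann_cloud": gen_boltzmann_cloud,
        "rigid_stack": gen_rigid_stack,
        "galactan_chain": gen_galactan_chain,
        "face_migration": gen_face_migration,
        "pucker_mix": gen_pucker_mix,
    }
    if spec.kind not in generators:
        raise ValueError(f"unknown generator kind {spec.kind!r}; "
                         f"choose from {sorted(generators)}")
    kwargs = dict(spec.params)
    if spec.kind in ("boltzmann_cloud", "face_migration"):
        kwargs.setdefault("temperature", spec.temperature)
    return generators[spec.kind](seed=spec.seed, **kwargs)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _hexagon(radius: float, z: np.ndarray | float = 0.0) -> np.ndarray:
    ang = np.radians(60.0 * np.arange(6))
    pts = np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                           np.broadcast_to(z, 6)])
    return pts


def build_benzene() -> tuple[list, list, np.ndarray, np.ndarray]:
    """Names, elements, bonds and coordinates of a flat aromatic six-ring."""
    names = [f"C{i + 1}" for i in range(6)]
    elements = ["C"] * 6
    bonds = np.array([[i, (i + 1) % 6] for i in range(6)])
    return names, elements, bonds, _hexagon(RING_CC)


def build_pyranose_templates() -> dict[str, np.ndarray]:
    """Chair and boat templates for an O5,C1..C5 pyranose ring (6,3).

    The chair alternates +/- z (theta = 0, the 4C1-type pole under the
    O5-first ordering); the boat has zero q3 and theta = 90 degrees.
    """
    j = np.arange(6)
    chair = _hexagon(PYRANOSE_R, CHAIR_Z * (-1.0) ** (j + 1))
    boat = _hexagon(PYRANOSE_R, BOAT_Z * np.cos(4 * np.pi * j / 6))
    return {"chair": chair, "boat": boat}


def build_yariv_mimic(with_sugars: bool = False):
    """Schematic planar Yariv molecule: names, elements, bonds, coords.

    Central aromatic ring at the origin; three arms at 120-degree azimuths,
    each a diazenyl (N=N) linker to a peripheral aromatic ring; optional
    chair pyranoses glycosidically attached beyond each peripheral ring.
    All aromatic rings lie exactly in z = 0.
    """
    names: list[str] = []
    elements: list[str] = []
    bonds: list[tuple[int, int]] = []
    coords: list[np.ndarray] = []

    def add(name, element, xyz):
        names.append(name)
        elements.append(element)
        coords.append(np.asarray(xyz, dtype=float))
        return len(names) - 1

    central = [add(f"CC{i + 1}", "C",
                   [RING_CC * np.cos(np.radians(60 * i)),
                    RING_CC * np.sin(np.radians(60 * i)), 0.0])
               for i in range(6)]
    bonds += [(central[i], central[(i + 1) % 6]) for i in range(6)]

    templates = build_pyranose_templates()
    for k, arm in enumerate("ABC"):
        phi = np.radians(120.0 * k)
        u = np.array([np.cos(phi), np.sin(phi), 0.0])
        attach = central[2 * k]          # azimuths 0, 120, 240 deg
        n1 = add(f"N1{arm}", "N", (RING_CC + AZO_CN) * u)
        n2 = add(f"N2{arm}", "N", (RING_CC + AZO_CN + AZO_NN) * u)
        bonds += [(attach, n1), (n1, n2)]
        pc = (RING_CC + AZO_CN + AZO_NN + AZO_CN + RING_CC)   # ring center
        ring = []
        for m in range(6):
            ang = phi + np.pi + np.radians(60 * m)
            pos = pc * u + RING_CC * np.array([np.cos(ang), np.sin(ang), 0.0])
            ring.append(add(f"CP{m + 1}{arm}", "C", pos))
        bonds += [(ring[m], ring[(m + 1) % 6]) for m in range(6)]
        bonds.append((n2, ring[0]))      # ring[0] points back to the hub
        if with_sugars:
            og = add(f"OG{arm}", "O", (pc + RING_CC + AZO_CN) * u)
            bonds.append((ring[3], og))  # para position
            sugar_center = (pc + RING_CC + AZO_CN + 1.6) * u \
                + np.array([0.0, 0.0, 0.9])
            ring_xyz = templates["chair"] + sugar_center
            sug = [add(f"{nm}{arm}", el, ring_xyz[j])
                   for j, (nm, el) in enumerate(
                       [("O5", "O"), ("C1", "C"), ("C2", "C"),
                        ("C3", "C"), ("C4", "C"), ("C5", "C")])]
            bonds += [(sug[j], sug[(j + 1) % 6]) for j in range(6)]
            bonds.append((og, sug[1]))   # glycosidic O to C1
    return names, elements, np.array(bonds), np.array(coords)


def _single_residue_topology(names, elements, bonds, resname="YRV",
                             resid=0) -> MolecularTopology:
    n = len(names)
    return MolecularTopology(list(names), list(elements),
                             np.full(n, resid), [resname] * n, bonds)


def _concat_units(units):
    """Merge (names, elements, bonds, coords, resname) unit tuples."""
    names, elements, resids, resnames, bonds, coords = [], [], [], [], [], []
    offset = 0
    for rid, (nm, el, bd, xy, resname) in enumerate(units):
        names += list(nm)
        elements += list(el)
        resids += [rid] * len(nm)
        resnames += [resname] * len(nm)
        if len(bd):
            bonds.append(np.asarray(bd) + offset)
        coords.append(np.asarray(xy, dtype=float))
        offset += len(nm)
    bonds = np.concatenate(bonds) if bonds else np.empty((0, 2), dtype=int)
    top = MolecularTopology(names, elements, np.array(resids), resnames, bonds)
    return top, np.concatenate(coords)


def _rotation_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    axis = np.asarray(axis, dtype=float)
    return Rotation.from_rotvec(angle_rad * axis / np.linalg.norm(axis)
                                ).as_matrix()


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def gen_boltzmann_cloud(kappa: float = 1.0,
                        centers=((0.0, 0.0, 0.0),),
                        n_frames: int = 10_000,
                        temperature: float = DEFAULT_TEMPERATURE,
                        seed: int = 0):
    """Probe atom Boltzmann-distributed in one or more harmonic wells.

    Positions are drawn directly from the exact stationary distribution of
    U(r) = (kappa/2)|r - c|^2 (isotropic Gaussian, sigma^2 = kT/kappa per
    axis); multi-well specs pick a well uniformly per frame.  A static
    aromatic six-ring at the origin serves as the reference molecule.
    """
    if kappa <= 0:
        raise ValueError("potential curvature kappa must be positive")
    rng = np.random.default_rng(seed)
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    sigma = float(np.sqrt(kT(temperature) / kappa))
    bz_names, bz_el, bz_bonds, bz_xyz = build_benzene()
    top, base = _concat_units([
        (bz_names, bz_el, bz_bonds, bz_xyz, "BNZ"),
        (["C"], ["C"], np.empty((0, 2), int), np.zeros((1, 3)), "PRB"),
    ])
    wells = rng.integers(0, len(centers), size=n_frames)
    probe = centers[wells] + rng.normal(0.0, sigma, size=(n_frames, 3))
    coords = np.repeat(base[None], n_frames, axis=0)
    coords[:, -1, :] = probe
    truth = {"kind": "boltzmann_cloud", "kappa": kappa,
             "sigma": sigma, "temperature": temperature,
             "centers": centers.tolist(), "well_index": wells.tolist(),
             "probe_atom": top.n_atoms - 1, "seed": seed}
    return top, Trajectory(coords), truth


def gen_rigid_stack(n_units: int = 4, twist_deg: float = 10.0,
                    rise: float = 3.5, jitter_angle_deg: float = 0.0,
                    jitter_offset: float = 0.0, n_frames: int = 1,
                    with_sugars: bool = False, seed: int = 0):
    """Stack of planar Yariv mimics with controlled twist, rise and jitter.

    Unit u sits at z = u * rise, rotated by u * twist_deg about +z
    (positive twist = right-handed screw up the stack).  Per frame and per
    unit, ``jitter_angle_deg`` tilts the unit about a random in-plane axis
    and ``jitter_offset`` displaces it isotropically (both Gaussian sigmas).
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if rise <= 0:
        raise ValueError("rise must be positive")
    rng = np.random.default_rng(seed)
    nm, el, bd, base = build_yariv_mimic(with_sugars=with_sugars)
    top, _ = _concat_units([(nm, el, bd, base, "YRV")] * n_units)
    n_atoms_unit = len(nm)
    coords = np.empty((n_frames, n_units * n_atoms_unit, 3))
    for f in range(n_frames):
        for u in range(n_units):
            R = _rotation_about([0, 0, 1], np.radians(u * twist_deg))
            xyz = base @ R.T + np.array([0.0, 0.0, u * rise])
            if jitter_angle_deg > 0:
                ax_phi = rng.uniform(0, 2 * np.pi)
                tilt = np.radians(rng.normal(0.0, jitter_angle_deg))
                Rj = _rotation_about([np.cos(ax_phi), np.sin(ax_phi), 0.0],
                                     tilt)
                c = xyz.mean(axis=0)
                xyz = (xyz - c) @ Rj.T + c
            if jitter_offset > 0:
                xyz = xyz + rng.normal(0.0, jitter_offset, size=3)
            coords[f, u * n_atoms_unit:(u + 1) * n_atoms_unit] = xyz
    truth = {"kind": "rigid_stack", "n_units": n_units,
             "twist_deg": twist_deg, "rise": rise,
             "jitter_angle_deg": jitter_angle_deg,
             "jitter_offset": jitter_offset, "order": list(range(n_units)),
             "with_sugars": with_sugars, "seed": seed}
    return top, Trajectory(coords), truth


def gen_galactan_chain(n_units: int = 3, bend_deg: float = 120.0,
                       spacing: float = 4.6, wobble_deg: float = 0.0,
                       dihedral_wobble_deg: float = 0.0,
                       n_frames: int = 1, with_hydroxyls: bool = False,
                       seed: int = 0):
    """Chain of pyranose mimics with a controlled inter-centroid bend.

    Ring centroids follow a 3D walk with fixed step length; each step turns
    by (180 - bend_deg) from the previous direction, so the angle at every
    interior centroid equals ``bend_deg`` exactly at zero wobble.
    ``wobble_deg`` perturbs the turn (and hence the bend) per frame;
    ``dihedral_wobble_deg`` rotates each step about the previous one, which
    kinks the chain out of plane without changing the bend angles.
    ``with_hydroxyls`` adds schematic O2/O4 hydroxyl oxygens to every
    residue, enabling hydrogen-bond analyses on the mimic.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    rng = np.random.default_rng(seed)
    templates = build_pyranose_templates()
    chair = templates["chair"]
    sugar_names = ["O5", "C1", "C2", "C3", "C4", "C5"]
    sugar_elems = ["O", "C", "C", "C", "C", "C"]
    sugar_bonds = [[j, (j + 1) % 6] for j in range(6)]
    unit_xyz = chair
    if with_hydroxyls:
        sugar_names = sugar_names + ["O2", "O4"]
        sugar_elems = sugar_elems + ["O", "O"]
        sugar_bonds = sugar_bonds + [[2, 6], [4, 7]]
        oh = []
        for ci in (2, 4):
            outward = chair[ci].copy()
            outward[2] = 0.0
            outward /= np.linalg.norm(outward)
            oh.append(chair[ci] + 1.4 * outward)
        unit_xyz = np.vstack([chair, oh])
    n_per = len(sugar_names)
    units = [(sugar_names, sugar_elems, np.array(sugar_bonds),
              unit_xyz, "GAL") for _ in range(n_units)]
    top, _ = _concat_units(units)
    # glycosidic bridges: C1 of residue i to C3 of residue i+1 (via nothing;
    # the direct bond keeps the bond graph a single molecule)
    extra = np.array([[n_per * i + 1, n_per * (i + 1) + 4]
                      for i in range(n_units - 1)]).reshape(-1, 2)
    top = MolecularTopology(top.names, top.elements, top.resids, top.resnames,
                            np.vstack([top.bonds, extra]))
    coords = np.empty((n_frames, n_per * n_units, 3))
    bends_truth = []
    for f in range(n_frames):
        centroids = [np.zeros(3)]
        d = np.array([1.0, 0.0, 0.0])
        normal = np.array([0.0, 0.0, 1.0])
        frame_bends = []
        for i in range(1, n_units):
            if i == 1:
                step = d
            else:
                bend = bend_deg + (rng.normal(0.0, wobble_deg)
                                   if wobble_deg > 0 else 0.0)
                frame_bends.append(bend)
                turn = np.radians(180.0 - bend)
                step = _rotation_about(normal, turn) @ d
                if dihedral_wobble_deg > 0:
                    tw = np.radians(rng.normal(0.0, dihedral_wobble_deg))
                    step = _rotation_about(d, tw) @ step
                    normal = _rotation_about(d, tw) @ normal
            d = step / np.linalg.norm(step)
            centroids.append(centroids[-1] + spacing * d)
        for i, c in enumerate(centroids):
            coords[f, n_per * i:n_per * (i + 1)] = unit_xyz + c
        bends_truth.append(frame_bends)
    truth = {"kind": "galactan_chain", "n_units": n_units,
             "bend_deg": bend_deg, "spacing": spacing,
             "wobble_deg": wobble_deg,
             "dihedral_wobble_deg": dihedral_wobble_deg,
             "bend_angles": bends_truth, "with_hydroxyls": with_hydroxyls,
             "ring_atoms": [list(range(n_per * i, n_per * i + 6))
                            for i in range(n_units)], "seed": seed}
    return top, Trajectory(coords), truth


def gen_face_migration(n_frames: int = 2000,
                       mean_lifetime: float = 200.0,
                       z0: float = 4.0, sigma: float = 0.8,
                       temperature: float = DEFAULT_TEMPERATURE,
                       seed: int = 0):
    """Two-state hopping of a probe between the two faces of a Yariv mimic.

    The probe binds at (0, 0, +/- z0) with isotropic Gaussian jitter
    ``sigma``; dwell times in each state are exponential with the given
    mean (in frames; ``float('inf')`` disables switching).  The ground
    truth records the face state of every frame.
    """
    rng = np.random.default_rng(seed)
    nm, el, bd, base = build_yariv_mimic()
    top, ref = _concat_units([
        (nm, el, bd, base, "YRV"),
        (["C"], ["C"], np.empty((0, 2), int), np.zeros((1, 3)), "PRB"),
    ])
    states = np.empty(n_frames, dtype=int)
    t, s = 0, 0
    while t < n_frames:
        if np.isinf(mean_lifetime):
            dwell = n_frames - t
        else:
            dwell = max(1, int(round(rng.exponential(mean_lifetime))))
        states[t:t + dwell] = s
        t += dwell
        s = 1 - s
    signs = np.where(states == 0, 1.0, -1.0)
    probe = np.column_stack([rng.normal(0, sigma, n_frames),
                             rng.normal(0, sigma, n_frames),
                             signs * z0 + rng.normal(0, sigma, n_frames)])
    coords = np.repeat(ref[None], n_frames, axis=0)
    coords[:, -1, :] = probe
    truth = {"kind": "face_migration", "mean_lifetime": mean_lifetime,
             "z0": z0, "sigma": sigma, "states": states.tolist(),
             "probe_atom": top.n_atoms - 1, "temperature": temperature,
             "seed": seed}
    return top, Trajectory(coords), truth


def gen_pucker_mix(n_frames: int = 10_000, chair_fraction: float = 0.9,
                   noise: float = 0.05, seed: int = 0):
    """One pyranose ring drawn per frame from chair/boat templates + noise.

    ``chair_fraction`` is the Bernoulli probability of the chair template;
    ``noise`` is the per-coordinate Gaussian sigma (angstrom).
    """
    if not 0.0 <= chair_fraction <= 1.0:
        raise ValueError("chair_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    templates = build_pyranose_templates()
    top = _single_residue_topology(
        ["O5", "C1", "C2", "C3", "C4", "C5"],
        ["O", "C", "C", "C", "C", "C"],
        np.array([[j, (j + 1) % 6] for j in range(6)]), resname="GAL")
    is_chair = rng.random(n_frames) < chair_fraction
    coords = np.where(is_chair[:, None, None], templates["chair"],
                      templates["boat"])
    coords = coords + rng.normal(0.0, noise, size=coords.shape)
    truth = {"kind": "pucker_mix", "chair_fraction": chair_fraction,
             "noise": noise, "is_chair": is_chair.tolist(), "seed": seed}
    return top, Trajectory(coords), truth


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_outputs(prefix, topology: MolecularTopology, traj: Trajectory,
                  truth: dict) -> dict[str, str]:
    """Write PDB (frame 0 + CONECT), XTC (all frames) and ground-truth JSON.

    Returns the mapping of artifact kind to file path.  Identical inputs
    produce byte-identical files.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {"pdb": f"{prefix}.pdb", "xtc": f"{prefix}.xtc",
             "json": f"{prefix}.json"}
    write_structure(paths["pdb"], topology, traj.coords[0],
                    None if traj.box is None else traj.box[0])
    write_trajectory(paths["xtc"], topology, traj)
    with open(paths["json"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths


def file_digest(path) -> str:
    """SHA-256 of a file, for determinism checks."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
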