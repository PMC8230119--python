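"""Structure/trajectory I/O, atom selections and periodic-image handling.

All coordinates are in angstrom internally; formats that store nanometres
(XTC, mdtraj's in-memory representation) are converted on read and write.
Atom and frame indices are 0-based; PDB serial numbers are 1-based only in
the files themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import mdtraj as md
import numpy as np

from .constants import COVALENT_RADII, DEFAULT_COVALENT_RADIUS

__all__ = [
    "MolecularTopology",
    "Trajectory",
    "AtomSelection",
    "FormatError",
    "EmptyInputError",
    "AtomCountMismatch",
    "SelectionError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "make_whole",
    "select",
]

NM_TO_ANGSTROM = 10.0


class FormatError(ValueError):
    """File could not be parsed as the expected molecular format."""


class EmptyInputError(ValueError):
    """Input contained no atoms or no frames."""


class AtomCountMismatch(ValueError):
    """Trajectory atom count disagrees with the topology."""


class SelectionError(ValueError):
    """Selection expression could not be parsed."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MolecularTopology:
    """Atoms, bonds and the molecule partition of a system.

    The molecule partition is always the connected components of the bond
    graph; it is recomputed whenever bonds change, never stored
    independently.
    """

    names: list[str]
    elements: list[str]
    resids: np.ndarray          # (n_atoms,) int, 0-based residue index
    resnames: list[str]         # per atom
    bonds: np.ndarray           # (n_bonds, 2) int, unordered pairs
    molecule_of: np.ndarray = field(default=None)  # (n_atoms,) int

    def __post_init__(self):
        self.resids = np.asarray(self.resids, dtype=int)
        self.bonds = np.asarray(self.bonds, dtype=int).reshape(-1, 2)
        n = self.n_atoms
        if len(self.bonds) and (self.bonds.min() < 0 or self.bonds.max() >= n):
            raise ValueError("bond references an atom index outside the topology")
        if self.molecule_of is None:
            self.molecule_of = _connected_components(n, self.bonds)
        else:
            self.molecule_of = np.asarray(self.molecule_of, dtype=int)

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def n_molecules(self) -> int:
        return 0 if self.n_atoms == 0 else int(self.molecule_of.max()) + 1

    def molecule_atoms(self, imol: int) -> np.ndarray:
        return np.flatnonzero(self.molecule_of == imol)

    def neighbors(self, i: int) -> np.ndarray:
        b = self.bonds
        return np.concatenate([b[b[:, 0] == i, 1], b[b[:, 1] == i, 0]])

    def adjacency(self) -> list[list[int]]:
        adj = [[] for _ in range(self.n_atoms)]
        for a, b in self.bonds:
            adj[int(a)].append(int(b))
            adj[int(b)].append(int(a))
        return adj


@dataclass
class Trajectory:
    """Frames of coordinates (angstrom) with optional periodic box and time.

    ``box`` holds per-frame 3x3 row-vector cells (angstrom) or ``None`` for
    non-periodic data; ``time`` is per-frame time in ps or ``None``.
    """

    coords: np.ndarray                 # (n_frames, n_atoms, 3), angstrom
    box: np.ndarray | None = None      # (n_frames, 3, 3) row vectors, angstrom
    time: np.ndarray | None = None     # (n_frames,), ps

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.ndim == 2 or self.box.shape[0] == 1:
                self.box = np.broadcast_to(
                    self.box.reshape(-1, 3, 3)[0],
                    (self.n_frames, 3, 3)).copy()
            vol = np.linalg.det(self.box)
            if np.any(vol <= 0):
                raise ValueError("periodic cell must be right-handed with positive volume")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def copy(self) -> "Trajectory":
        return Trajectory(
            self.coords.copy(),
            None if self.box is None else self.box.copy(),
            None if self.time is None else self.time.copy(),
        )


@dataclass(frozen=True)
class AtomSelection:
    """Sorted, duplicate-free list of atom indices with a provenance label."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self):
        idx = np.unique(np.asarray(self.indices, dtype=int))
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _connected_components(n_atoms: int, bonds: np.ndarray) -> np.ndarray:
    """Molecule labels = connected components of the bond graph (BFS)."""
    adj = [[] for _ in range(n_atoms)]
    for a, b in bonds:
        adj[int(a)].append(int(b))
        adj[int(b)].append(int(a))
    label = np.full(n_atoms, -1, dtype=int)
    current = 0
    for start in range(n_atoms):
        if label[start] >= 0:
            continue
        stack = [start]
        label[start] = current
        while stack:
            i = stack.pop()
            for j in adj[i]:
                if label[j] < 0:
                    label[j] = current
                    stack.append(j)
        current += 1
    return label


def perceive_bonds(elements: list[str], coords: np.ndarray,
                   scale: float = 1.3) -> np.ndarray:
    """Distance-based bond perception: d < scale * (r_i + r_j) covalent radii."""
    from scipy.spatial import cKDTree

    coords = np.asarray(coords, dtype=float)
    n = len(elements)
    if n == 0:
        return np.empty((0, 2), dtype=int)
    radii = np.array([COVALENT_RADII.get(e, DEFAULT_COVALENT_RADIUS)
                      for e in elements])
    cutoff = scale * 2 * radii.max()
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=int)
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    keep = d < scale * (radii[pairs[:, 0]] + radii[pairs[:, 1]])
    return pairs[keep]


def _scan_pdb_for_bad_line(path: Path) -> int | None:
    """Return the 1-based line number of the first malformed coordinate line."""
    try:
        text = Path(path).read_text().splitlines()
    except (OSError, UnicodeDecodeError):
        return None
    for lineno, line in enumerate(text, start=1):
        if line.startswith(("ATOM", "HETATM")):
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except (ValueError, IndexError):
                return lineno
    return None


def _mdtraj_topology(top: MolecularTopology) -> md.Topology:
    mtop = md.Topology()
    chain = mtop.add_chain()
    residues = {}
    for i in range(top.n_atoms):
        rid = int(top.resids[i])
        if rid not in residues:
            residues[rid] = mtop.add_residue(top.resnames[i], chain, resSeq=rid + 1)
        try:
            elem = md.element.get_by_symbol(top.elements[i])
        except KeyError:
            elem = md.element.virtual
        mtop.add_atom(top.names[i], elem, residues[rid])
    atoms = list(mtop.atoms)
    for a, b in top.bonds:
        mtop.add_bond(atoms[int(a)], atoms[int(b)])
    return mtop


def _from_mdtraj(t: md.Trajectory) -> tuple[MolecularTopology, Trajectory]:
    names = [a.name for a in t.top.atoms]
    elements = [a.element.symbol if a.element is not None else "X"
                for a in t.top.atoms]
    resids = np.array([a.residue.index for a in t.top.atoms], dtype=int)
    resnames = [a.residue.name for a in t.top.atoms]
    bonds = np.array([[b[0].index, b[1].index] for b in t.top.bonds],
                     dtype=int).reshape(-1, 2)
    if len(bonds) == 0 and t.n_atoms > 1:
        bonds = perceive_bonds(elements, t.xyz[0] * NM_TO_ANGSTROM)
    top = MolecularTopology(names, elements, resids, resnames, bonds)
    box = None
    if t.unitcell_vectors is not None:
        box = t.unitcell_vectors * NM_TO_ANGSTROM
    time = t.time.copy() if t.time is not None else None
    traj = Trajectory(t.xyz * NM_TO_ANGSTROM, box, time)
    return top, traj


# ---------------------------------------------------------------------------
# read / write
# ---------------------------------------------------------------------------

def read_structure(path) -> tuple[MolecularTopology, np.ndarray]:
    """Read a PDB file into a topology plus first-frame coordinates (angstrom).

    Bonds come from CONECT records (and template matching for standard
    residues); if the file provides none, they are perceived from
    interatomic distances against covalent radii. The molecule partition is
    the connected components of the resulting bond graph.
    """
    path = Path(path)
    try:
        t = md.load(str(path))
    except Exception as exc:
        bad = _scan_pdb_for_bad_line(path)
        loc = f" (first malformed coordinate record at line {bad})" if bad else ""
        raise FormatError(f"could not parse {path} as PDB{loc}: {exc}") from exc
    if t.n_atoms == 0:
        raise EmptyInputError(f"{path} contains no atoms")
    top, traj = _from_mdtraj(t)
    return top, traj.coords[0]


def read_trajectory(path, topology: MolecularTopology) -> Trajectory:
    """Read XTC, DCD or (multi-model) PDB frames against a known topology.

    Frames are returned in file order with coordinates in angstrom.
    """
    path = Path(path)
    mtop = _mdtraj_topology(topology)
    try:
        t = md.load(str(path), top=mtop)
    except ValueError as exc:
        # mdtraj raises on atom-count mismatch; recover both counts
        n_file = _probe_atom_count(path)
        if n_file is not None and n_file != topology.n_atoms:
            raise AtomCountMismatch(
                f"{path} has {n_file} atoms but topology has "
                f"{topology.n_atoms}") from exc
        raise FormatError(f"could not read trajectory {path}: {exc}") from exc
    if t.n_atoms != topology.n_atoms:
        raise AtomCountMismatch(
            f"{path} has {t.n_atoms} atoms but topology has {topology.n_atoms}")
    if t.n_frames == 0:
        raise EmptyInputError(f"{path} contains no frames")
    _, traj = _from_mdtraj(t)
    return traj


def _probe_atom_count(path: Path) -> int | None:
    suffix = path.suffix.lower()
    try:
        if suffix == ".xtc":
            with md.formats.XTCTrajectoryFile(str(path)) as f:
                xyz, *_ = f.read(1)
                return xyz.shape[1]
        if suffix == ".dcd":
            with md.formats.DCDTrajectoryFile(str(path)) as f:
                xyz, *_ = f.read(1)
                return xyz.shape[1]
    except Exception:
        return None
    return None


def write_structure(path, topology: MolecularTopology, coords: np.ndarray,
                    box: np.ndarray | None = None) -> None:
    """Write a single-frame PDB (with CONECT records for all bonds)."""
    traj = Trajectory(np.asarray(coords, dtype=float)[None],
                      None if box is None else np.asarray(box)[None])
    write_trajectory(path, topology, traj)


def write_trajectory(path, topology: MolecularTopology,
                     traj: Trajectory) -> None:
    """Write XTC, DCD, or multi-model PDB, chosen by file extension."""
    path = Path(path)
    mtop = _mdtraj_topology(topology)
    xyz = traj.coords / NM_TO_ANGSTROM
    t = md.Trajectory(xyz, mtop, time=traj.time)
    if traj.box is not None:
        t.unitcell_vectors = traj.box / NM_TO_ANGSTROM
    suffix = path.suffix.lower()
    if suffix == ".pdb":
        t.save_pdb(str(path))
    elif suffix == ".xtc":
        t.save_xtc(str(path))
    elif suffix == ".dcd":
        t.save_dcd(str(path))
    else:
        raise FormatError(f"unsupported trajectory format: {suffix}")


# ---------------------------------------------------------------------------
# periodic-image handling
# ---------------------------------------------------------------------------

def make_whole(traj: Trajectory, topology: MolecularTopology) -> Trajectory:
    """Unwrap molecules across periodic boundaries and re-image the system.

    Each molecule is made spatially contiguous by walking its bond graph and
    shifting every atom to the minimum image relative to its already-placed
    bonded neighbour; whole molecules are then shifted to the minimum image
    of their centroid relative to molecule 0's centroid.  Idempotent on
    already-whole systems.
    """
    if traj.box is None:
        raise ValueError("make_whole requires a periodic box")
    out = traj.copy()
    adj = topology.adjacency()
    mols = [topology.molecule_atoms(m) for m in range(topology.n_molecules)]
    flagged = []
    for f in range(out.n_frames):
        box = out.box[f]
        inv = np.linalg.inv(box)
        x = out.coords[f]
        for atoms in mols:
            placed = np.zeros(topology.n_atoms, dtype=bool)
            stack = [int(atoms[0])]
            placed[atoms[0]] = True
            while stack:
                i = stack.pop()
                for j in adj[i]:
                    if not placed[j]:
                        d = x[j] - x[i]
                        shift = np.round(d @ inv)
                        x[j] = x[j] - shift @ box
                        placed[j] = True
                        stack.append(j)
        # re-image molecules relative to molecule 0's centroid
        ref = x[mols[0]].mean(axis=0)
        for atoms in mols[1:]:
            c = x[atoms].mean(axis=0)
            shift = np.round((c - ref) @ inv)
            x[atoms] -= shift @ box
        # sanity: no bond longer than half the shortest box edge
        if len(topology.bonds):
            d = np.linalg.norm(x[topology.bonds[:, 0]] - x[topology.bonds[:, 1]],
                               axis=1)
            half = 0.5 * np.linalg.norm(box, axis=1).min()
            if d.max() > half:
                flagged.append(f)
    if flagged:
        warnings.warn(
            f"make_whole: bond longer than half the box edge after unwrapping "
            f"in frames {flagged[:10]}{'...' if len(flagged) > 10 else ''}",
            stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# selection language
# ---------------------------------------------------------------------------
# grammar:  expr   := term ('or' term)*
#           term   := factor ('and' factor)*
#           factor := 'not' factor | '(' expr ')' | primary
#           primary:= 'element' SYM | 'name' SYM | 'resname' SYM
#                   | 'molecule' INT | 'resid' INT | 'all' | 'none'

def _tokenize(expression: str) -> list[tuple[str, int]]:
    tokens, i = [], 0
    while i < len(expression):
        c = expression[i]
        if c.isspace():
            i += 1
        elif c in "()":
            tokens.append((c, i))
            i += 1
        else:
            j = i
            while j < len(expression) and not expression[j].isspace() \
                    and expression[j] not in "()":
                j += 1
            tokens.append((expression[i:j], i))
            i = j
    return tokens


class _Parser:
    KEYWORDS = {"element", "name", "resname", "molecule", "resid"}

    def __init__(self, topology: MolecularTopology, expression: str):
        self.top = topology
        self.expr = expression
        self.tokens = _tokenize(expression)
        self.pos = 0

    def _peek(self):
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def _next(self):
        if self.pos >= len(self.tokens):
            raise SelectionError(
                f"unexpected end of selection expression: {self.expr!r}")
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self._expr()
        if self.pos != len(self.tokens):
            tok, at = self.tokens[self.pos]
            raise SelectionError(
                f"unexpected token {tok!r} at position {at} in {self.expr!r}")
        return mask

    def _expr(self):
        mask = self._term()
        while self._peek() == "or":
            self._next()
            mask = mask | self._term()
        return mask

    def _term(self):
        mask = self._factor()
        while self._peek() == "and":
            self._next()
            mask = mask & self._factor()
        return mask

    def _factor(self):
        tok = self._peek()
        if tok == "not":
            self._next()
            return ~self._factor()
        if tok == "(":
            self._next()
            mask = self._expr()
            closing, at = self._next()
            if closing != ")":
                raise SelectionError(
                    f"expected ')' at position {at} in {self.expr!r}")
            return mask
        return self._primary()

    def _primary(self):
        tok, at = self._next()
        n = self.top.n_atoms
        if tok == "all":
            return np.ones(n, dtype=bool)
        if tok == "none":
            return np.zeros(n, dtype=bool)
        if tok not in self.KEYWORDS:
            raise SelectionError(
                f"unknown token {tok!r} at position {at} in {self.expr!r}")
        value, vat = self._next()
        if tok == "element":
            return np.array([e == value for e in self.top.elements])
        if tok == "name":
            return np.array([nm == value for nm in self.top.names])
        if tok == "resname":
            return np.array([rn == value for rn in self.top.resnames])
        try:
            ival = int(value)
        except ValueError:
            raise SelectionError(
                f"expected integer after {tok!r}, got {value!r} at position "
                f"{vat} in {self.expr!r}") from None
        if tok == "molecule":
            return self.top.molecule_of == ival
        return self.top.resids == ival


def select(topology: MolecularTopology, expression: str) -> AtomSelection:
    """Evaluate a selection expression against the topology.

    Supported predicates: ``element C``, ``name C1``, ``resname GAL``,
    ``molecule 0``, ``resid 2``; combine with ``and``/``or``/``not`` and
    parentheses; ``all`` selects everything.
    """
    mask = _Parser(topology, expression).parse()
    return AtomSelection(np.flatnonzero(mask), label=expression)
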