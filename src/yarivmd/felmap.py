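"""3D occupancy histograms and Boltzmann-inverted free-energy-like maps.

The map protocol: after body-frame fitting, pooled positions of a selection
(e.g. all carbon atoms of the mobile molecule) are histogrammed on a cubic
voxel grid (default 1 angstrom edge) and converted per voxel to

    A_i = -kT ln(P_i),   P_i = raw histogram count,

with the global minimum subtracted so min(A) = 0.  Voxels never visited are
masked rather than capped.  Because the minimum is subtracted, any positive
rescaling of the counts (normalisation of P_i) leaves A unchanged.

The result differs from a molecular free energy in that it pools *any*
selected atom rather than a single molecular reference point, trading
thermodynamic interpretation for spatial resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .constants import BOHR_TO_ANGSTROM, DEFAULT_TEMPERATURE, kT
from .trajio import AtomSelection, Trajectory

__all__ = [
    "OccupancyGrid", "FELMap", "MapRegion",
    "accumulate_occupancy", "boltzmann_invert", "map_minima",
    "isolevel_volume", "harmonic_fit", "region_table",
    "write_volumetric", "read_cube", "read_dx",
]

#: value written to masked (never-visited) voxels in volumetric exports
MASK_SENTINEL = 999.0


@dataclass
class OccupancyGrid:
    """Integer voxel counts on a cubic grid.

    ``origin`` is the *center* of voxel (0,0,0); binning is half-open,
    voxel index = floor((x - origin + voxel/2) / voxel).
    """

    origin: np.ndarray            # (3,) angstrom, center of voxel (0,0,0)
    voxel: float                  # edge length, angstrom
    counts: np.ndarray            # (nx, ny, nz) int64
    n_total: int                  # frames x selected atoms
    n_out_of_range: int = 0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis arrays of voxel center coordinates (angstrom)."""
        return tuple(self.origin[k] + self.voxel * np.arange(self.shape[k])
                     for k in range(3))


@dataclass
class FELMap:
    """Free-energy-like values (kJ/mol) on the same grid as its histogram."""

    origin: np.ndarray
    voxel: float
    values: np.ndarray            # (nx, ny, nz) float, NaN where masked
    mask: np.ndarray              # True where voxel had zero counts
    temperature: float = DEFAULT_TEMPERATURE

    @property
    def shape(self):
        return self.values.shape

    def voxel_centers(self):
        return tuple(self.origin[k] + self.voxel * np.arange(self.shape[k])
                     for k in range(3))


@dataclass
class MapRegion:
    """A connected low-A region: a candidate binding site on the map."""

    voxels: np.ndarray            # (m, 3) integer voxel indices
    centroid: np.ndarray          # (3,) angstrom, unweighted mean of centers
    volume: float                 # angstrom^3
    depth: float = field(default=0.0)  # minimum A inside the region, kJ/mol


def accumulate_occupancy(traj: Trajectory, sel: AtomSelection,
                         voxel: float = 1.0,
                         bounds: tuple | None = None) -> OccupancyGrid:
    """Histogram selected atoms over all frames into cubic voxels.

    ``bounds`` is ``((xlo, ylo, zlo), (xhi, yhi, zhi))`` in angstrom or
    ``None`` for automatic bounds (data extent padded by 2 voxels).  Samples
    outside explicit bounds are tallied as out-of-range, with a warning when
    they exceed 1% of all samples.
    """
    if voxel <= 0:
        raise ValueError("voxel edge length must be positive")
    if len(sel) == 0:
        raise ValueError("empty selection")
    pts = traj.coords[:, sel.indices, :].reshape(-1, 3)
    n_total = pts.shape[0]
    if bounds is None:
        lo = pts.min(axis=0) - 2 * voxel
        hi = pts.max(axis=0) + 2 * voxel
    else:
        lo = np.asarray(bounds[0], dtype=float)
        hi = np.asarray(bounds[1], dtype=float)
    dims = np.maximum(np.ceil((hi - lo) / voxel).astype(int), 1)
    idx = np.floor((pts - lo) / voxel).astype(int)
    inside = np.all((idx >= 0) & (idx < dims), axis=1)
    n_out = int(n_total - inside.sum())
    if n_out > 0.01 * n_total:
        warnings.warn(f"{n_out}/{n_total} samples fall outside explicit "
                      f"grid bounds", stacklevel=2)
    counts = np.zeros(dims, dtype=np.int64)
    np.add.at(counts, tuple(idx[inside].T), 1)
    origin = lo + voxel / 2
    return OccupancyGrid(origin, float(voxel), counts, n_total, n_out)


def boltzmann_invert(grid: OccupancyGrid,
                     temperature: float = DEFAULT_TEMPERATURE) -> FELMap:
    """Convert counts to A_i = -kT ln(P_i), shifted so the minimum is 0.

    Zero-count voxels are masked (the log is undefined there); the global
    minimum over unmasked voxels is exactly 0 after the shift.
    """
    mask = grid.counts == 0
    if mask.all():
        raise ValueError("all voxels empty: cannot Boltzmann-invert")
    values = np.full(grid.shape, np.nan)
    occ = ~mask
    values[occ] = -kT(temperature) * np.log(grid.counts[occ].astype(float))
    values[occ] -= values[occ].min()
    return FELMap(grid.origin.copy(), grid.voxel, values, mask, temperature)


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def map_minima(fel: FELMap, level: float) -> list[MapRegion]:
    """Connected components (26-connectivity) of {A <= level}, by volume.

    Each region carries its unweighted voxel-center centroid, volume and
    depth (the minimum A inside it).  Regions are sorted by volume,
    largest first.  A level below every unmasked value yields an empty
    list.
    """
    if level <= 0:
        raise ValueError("isolevel must be positive")
    low = (~fel.mask) & (fel.values <= level)
    labels, n = ndimage.label(low, structure=_STRUCT_26)
    regions = []
    for lab in range(1, n + 1):
        vox = np.argwhere(labels == lab)
        centers = fel.origin + fel.voxel * vox
        depth = float(np.nanmin(fel.values[tuple(vox.T)]))
        regions.append(MapRegion(vox, centers.mean(axis=0),
                                 len(vox) * fel.voxel ** 3, depth))
    regions.sort(key=lambda r: -r.volume)
    return regions


def isolevel_volume(fel: FELMap, level: float) -> float:
    """Volume (angstrom^3) enclosed by the isolevel: voxels with A <= level."""
    if level < 0:
        raise ValueError("isolevel must be nonnegative")
    n = int(((~fel.mask) & (fel.values <= level)).sum())
    return n * fel.voxel ** 3


def region_table(regions: list[MapRegion]) -> pd.DataFrame:
    """Region summary with columns region_id,volume_A3,depth_kJmol,cx,cy,cz."""
    return pd.DataFrame({
        "region_id": np.arange(len(regions)),
        "volume_A3": [r.volume for r in regions],
        "depth_kJmol": [r.depth for r in regions],
        "cx": [r.centroid[0] for r in regions],
        "cy": [r.centroid[1] for r in regions],
        "cz": [r.centroid[2] for r in regions],
    })


def harmonic_fit(fel: FELMap, center: np.ndarray | None = None,
                 r_max: float | None = None) -> float:
    """Fit A(r) = A0 + (kappa/2) r^2 and return kappa (kJ/mol/A^2).

    For Boltzmann samples from an isotropic harmonic well U = (kappa/2) r^2
    the map satisfies A = U + const, so the fitted curvature recovers kappa.
    ``center`` defaults to the Boltzmann-weighted centroid exp(-A/kT); the
    fit uses unmasked voxels with r < r_max (default 2 sigma estimated from
    the fitted well via an initial pass over all voxels).
    """
    xs, ys, zs = fel.voxel_centers()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    occ = ~fel.mask
    if center is None:
        w = np.exp(-fel.values[occ] / kT(fel.temperature))
        w /= w.sum()
        center = np.array([np.sum(w * X[occ]), np.sum(w * Y[occ]),
                           np.sum(w * Z[occ])])
    r2 = ((X - center[0]) ** 2 + (Y - center[1]) ** 2
          + (Z - center[2]) ** 2)
    if r_max is None:
        # second moment of the Boltzmann weight gives sigma^2 per axis
        w = np.exp(-fel.values[occ] / kT(fel.temperature))
        w /= w.sum()
        sigma2 = np.sum(w * r2[occ]) / 3.0
        r_max = 2.0 * np.sqrt(sigma2)
    use = occ & (r2 < r_max ** 2)
    design = np.column_stack([np.ones(use.sum()), 0.5 * r2[use]])
    coef, *_ = np.linalg.lstsq(design, fel.values[use], rcond=None)
    return float(coef[1])


# ---------------------------------------------------------------------------
# volumetric file formats
# ---------------------------------------------------------------------------

def _grid_data(obj) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(obj, OccupancyGrid):
        return obj.counts.astype(float), np.zeros(obj.shape, dtype=bool)
    return obj.values, obj.mask


def write_volumetric(obj, path, fmt: str = "cube") -> None:
    """Write a map or histogram as Gaussian cube (Bohr) or OpenDX (angstrom).

    Masked voxels are written as the sentinel value 999.0 in both formats so
    external viewers render them outside any sensible isolevel.
    """
    if fmt == "cube":
        _write_cube(obj, path)
    elif fmt == "dx":
        _write_dx(obj, path)
    else:
        raise ValueError(f"unknown volumetric format {fmt!r} (cube|dx)")


def _write_cube(obj, path) -> None:
    values, mask = _grid_data(obj)
    out = np.where(mask, MASK_SENTINEL, values)
    nx, ny, nz = out.shape
    o = np.asarray(obj.origin) / BOHR_TO_ANGSTROM
    dv = obj.voxel / BOHR_TO_ANGSTROM
    lines = ["free-energy-like map (kJ/mol); masked voxels = 999.0",
             "cubic grid; origin at center of voxel (0,0,0)",
             f"{1:5d}{o[0]:12.6f}{o[1]:12.6f}{o[2]:12.6f}",
             f"{nx:5d}{dv:12.6f}{0.0:12.6f}{0.0:12.6f}",
             f"{ny:5d}{0.0:12.6f}{dv:12.6f}{0.0:12.6f}",
             f"{nz:5d}{0.0:12.6f}{0.0:12.6f}{dv:12.6f}",
             f"{6:5d}{0.0:12.6f}{o[0]:12.6f}{o[1]:12.6f}{o[2]:12.6f}"]
    flat = out.reshape(nx * ny, nz)
    for row in range(nx * ny):
        vals = flat[row]
        for start in range(0, nz, 6):
            chunk = vals[start:start + 6]
            lines.append("".join(f"{v:13.5E}" for v in chunk))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_cube(path) -> tuple[np.ndarray, np.ndarray, float]:
    """Read a Gaussian cube written by this package.

    Returns ``(values, origin_A, voxel_A)`` with the sentinel left in place.
    """
    with open(path) as fh:
        lines = fh.read().split("\n")
    natoms = int(lines[2].split()[0])
    origin = np.array([float(v) for v in lines[2].split()[1:4]])
    dims, spacings = [], []
    for k in range(3):
        parts = lines[3 + k].split()
        dims.append(int(parts[0]))
        spacings.append(float(parts[1 + k]))
    data = []
    for line in lines[6 + natoms:]:
        data.extend(float(v) for v in line.split())
    values = np.array(data).reshape(dims)
    return values, origin * BOHR_TO_ANGSTROM, spacings[0] * BOHR_TO_ANGSTROM


def _write_dx(obj, path) -> None:
    values, mask = _grid_data(obj)
    out = np.where(mask, MASK_SENTINEL, values)
    nx, ny, nz = out.shape
    o = np.asarray(obj.origin)
    d = obj.voxel
    lines = [f"# free-energy-like map (kJ/mol); masked voxels = {MASK_SENTINEL}",
             f"object 1 class gridpositions counts {nx} {ny} {nz}",
             f"origin {o[0]:.6f} {o[1]:.6f} {o[2]:.6f}",
             f"delta {d:.6f} 0.000000 0.000000",
             f"delta 0.000000 {d:.6f} 0.000000",
             f"delta 0.000000 0.000000 {d:.6f}",
             f"object 2 class gridconnections counts {nx} {ny} {nz}",
             f"object 3 class array type double rank 0 items {nx * ny * nz} "
             f"data follows"]
    flat = out.ravel()
    for start in range(0, len(flat), 3):
        chunk = flat[start:start + 3]
        lines.append(" ".join(f"{v:.6e}" for v in chunk))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "map" class field')
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_dx(path) -> tuple[np.ndarray, np.ndarray, float]:
    """Read an OpenDX scalar grid. Returns ``(values, origin_A, voxel_A)``."""
    origin = None
    deltas = []
    dims = None
    data = []
    in_data = False
    n_items = None
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if in_data:
                if s.startswith("attribute") or s.startswith("object"):
                    in_data = False
                    continue
                data.extend(float(v) for v in s.split())
                if n_items is not None and len(data) >= n_items:
                    in_data = False
                continue
            if s.startswith("object 1"):
                dims = [int(v) for v in s.split()[-3:]]
            elif s.startswith("origin"):
                origin = np.array([float(v) for v in s.split()[1:4]])
            elif s.startswith("delta"):
                deltas.append([float(v) for v in s.split()[1:4]])
            elif "data follows" in s:
                n_items = int(s.split("items")[1].split()[0])
                in_data = True
    values = np.array(data).reshape(dims)
    return values, origin, float(deltas[0][0])
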