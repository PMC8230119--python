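"""End-to-end per-system analysis and cross-replica summaries.

``run_pipeline`` chains the stages — read, make whole (if periodic), fit the
reference molecule, accumulate the occupancy map, Boltzmann-invert, find
low-A regions, classify interactions and stacking, check sugar geometry —
and writes a reproducible bundle: volumetric maps (cube + dx), CSV tables,
a stack report and a summary JSON.  Outputs carry no timestamps, so reruns
with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import carbgeom, felmap, fitting, interactions, trajio
from .constants import DEFAULT_TEMPERATURE

__all__ = ["PipelineConfig", "run_pipeline", "summarize_replicas",
           "box_concentration"]

log = logging.getLogger(__name__)

#: TIP3P-like water: molar mass (g/mol) and liquid density (g/cm^3) at
#: ambient conditions, giving a molecular volume of ~29.9 A^3.
WATER_MOLAR_MASS = 18.01528
WATER_DENSITY = 0.997
AVOGADRO = 6.02214076e23


def box_concentration(n_solute: int, n_waters: int,
                      solute_volume_A3: float = 0.0) -> float:
    """Molar concentration (mol/L) implied by solutes in an aqueous box.

    The box volume is estimated analytically from the water molecular
    volume (molar mass over liquid density), optionally plus an explicit
    solute volume.  Useful to relate a simulation box to experimental
    concentrations.
    """
    v_water_A3 = WATER_MOLAR_MASS / (WATER_DENSITY * AVOGADRO) * 1e24
    volume_L = (n_waters * v_water_A3 + solute_volume_A3) * 1e-27
    return n_solute / (AVOGADRO * volume_L)


@dataclass
class PipelineConfig:
    """Everything a run needs; serialisable and round-trippable."""

    topology: str
    trajectory: str | None = None
    fit_select: str = "molecule 0 and not element H"
    map_select: str = "molecule 1 and element C"
    ref_frame: int = 0
    voxel: float = 1.0
    temperature: float = DEFAULT_TEMPERATURE
    isolevels: tuple = (5.0, 10.0)
    thresholds: dict = field(default_factory=dict)
    outdir: str = "yarivmd_out"
    seed: int = 0
    log_level: str = "INFO"
    #: classify interactions/stacking every Nth frame (maps use all frames)
    interaction_stride: int = 1

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        data["isolevels"] = tuple(data.get("isolevels", (5.0, 10.0)))
        return cls(**data)

    def analysis_params(self) -> dict:
        """The parameters that must match across replicas of one study."""
        return {"fit_select": self.fit_select, "map_select": self.map_select,
                "voxel": self.voxel, "temperature": self.temperature,
                "isolevels": tuple(self.isolevels),
                "thresholds": dict(self.thresholds)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis for one system; returns the bundle summary.

    The bundle directory holds: ``fel.cube``/``fel.dx``, per-isolevel region
    tables, ``interactions.csv``, ``stack.json``, ``pucker.csv`` and
    ``bend.csv`` when saccharide rings are present, ``rmsd.csv``,
    ``summary.json`` and the resolved ``config.json``.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    thr = interactions.Thresholds(**config.thresholds)
    log.info("run: voxel=%.2f A, T=%.1f K, isolevels=%s, thresholds=%s",
             config.voxel, config.temperature, config.isolevels, thr)

    top, coords0 = trajio.read_structure(config.topology)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.trajectory:
        traj = trajio.read_trajectory(config.trajectory, top)
    else:
        traj = trajio.Trajectory(coords0[None])
    if traj.n_frames == 0 or traj.n_atoms == 0:
        raise trajio.EmptyInputError("trajectory has no frames or atoms")
    if traj.box is not None:
        traj = trajio.make_whole(traj, top)

    fit_sel = trajio.select(top, config.fit_select)
    map_sel = trajio.select(top, config.map_select)
    fitted, fit_result = fitting.fit_reference(traj, fit_sel,
                                               config.ref_frame)
    fitting.fit_rmsd_series(fit_result).to_csv(outdir / "rmsd.csv",
                                               index=False)

    grid = felmap.accumulate_occupancy(fitted, map_sel, voxel=config.voxel)
    fel = felmap.boltzmann_invert(grid, config.temperature)
    felmap.write_volumetric(fel, outdir / "fel.cube", "cube")
    felmap.write_volumetric(fel, outdir / "fel.dx", "dx")
    region_counts = {}
    for level in config.isolevels:
        regions = felmap.map_minima(fel, level)
        felmap.region_table(regions).to_csv(
            outdir / f"regions_{level:g}kJmol.csv", index=False)
        region_counts[f"{level:g}"] = len(regions)

    rings0 = interactions.detect_rings(top, fitted.coords[0])
    inter_rows = []
    twists_all = []
    stack_last = None
    for f in range(0, fitted.n_frames, max(1, config.interaction_stride)):
        rings = interactions.update_ring_geometry(rings0, fitted.coords[f])
        stack = interactions.stack_topology(rings, thresholds=thr)
        stack_last = stack
        twists_all.extend(stack.twists.values())
        for rec in (interactions.find_ch_pi(top, fitted.coords[f], rings,
                                            thr, frame=f)
                    + interactions.detect_hbonds(top, fitted.coords[f], thr,
                                                 frame=f)):
            inter_rows.append(_record_row(rec))
        aromatic = [(i, r) for i, r in enumerate(rings) if r.aromatic]
        for ii, (ia, ra) in enumerate(aromatic):
            for ib, rb in aromatic[ii + 1:]:
                if ra.molecule == rb.molecule:
                    continue
                label, metrics = interactions.classify_pi_pi(ra, rb, thr)
                if label != "none":
                    inter_rows.append({
                        "frame": f, "type": label, "mol_a": ra.molecule,
                        "mol_b": rb.molecule, "ring_a": ia, "ring_b": ib,
                        "dist_A": metrics["dist_A"],
                        "angle_deg": metrics["angle_deg"],
                        "offset_A": metrics["offset_A"], "donor_atom": ""})
    inter_df = pd.DataFrame(
        inter_rows, columns=["frame", "type", "mol_a", "mol_b", "ring_a",
                             "ring_b", "dist_A", "angle_deg", "offset_A",
                             "donor_atom"])
    inter_df.to_csv(outdir / "interactions.csv", index=False)

    stack_report = {
        "order": list(stack_last.order) if stack_last else [],
        "edges": sorted(map(list, stack_last.graph.edges))
        if stack_last else [],
        "twists_deg": [float(t) for t in twists_all],
        "mean_twist_deg": float(np.mean(twists_all)) if twists_all else None,
        "handedness": interactions.handedness(twists_all),
        "irregularity": interactions.irregularity_profile(stack_last)
        if stack_last else [],
    }
    _dump_json(stack_report, outdir / "stack.json")

    sugar_summary = _sugar_geometry(top, fitted, rings0, outdir)

    summary = {
        "n_frames": fitted.n_frames,
        "n_atoms": top.n_atoms,
        "n_molecules": top.n_molecules,
        "fit_rmsd_mean_A": float(fit_result.rmsd.mean()),
        "region_counts": region_counts,
        "isolevel_volumes_A3": {f"{lv:g}": felmap.isolevel_volume(fel, lv)
                                for lv in config.isolevels},
        "interaction_counts": inter_df["type"].value_counts().to_dict(),
        "stack": stack_report,
        **sugar_summary,
        "analysis_params": _jsonable(config.analysis_params()),
    }
    _dump_json(summary, outdir / "summary.json")
    config.to_json(outdir / "config.json")
    return summary


def _record_row(rec) -> dict:
    return {"frame": rec.frame, "type": rec.kind, "mol_a": rec.mol_a,
            "mol_b": rec.mol_b, "ring_a": rec.ring_a, "ring_b": rec.ring_b,
            "dist_A": rec.metrics.get("dist_A", np.nan),
            "angle_deg": rec.metrics.get("angle_deg", np.nan),
            "offset_A": rec.metrics.get("offset_A",
                                        rec.metrics.get("proj_A", np.nan)),
            "donor_atom": rec.donor_name}


def _sugar_geometry(top, fitted, rings0, outdir) -> dict:
    sugar_rings = [r for r in rings0 if r.role == "saccharide"]
    out: dict = {}
    if not sugar_rings:
        return out
    ordered = []
    for r in sugar_rings:
        try:
            atoms = carbgeom.pyranose_ring_order(r, top)
        except ValueError:
            continue
        ordered.append((f"res{top.resids[r.atoms[0]]}", atoms))
    if not ordered:
        return out
    table, fractions = carbgeom.pucker_timeseries(fitted, ordered)
    table.to_csv(outdir / "pucker.csv", index=False)
    out["chair_fraction"] = fractions
    # chain bend per molecule with >= 3 sugar residues
    by_mol: dict[int, list] = {}
    for r in sugar_rings:
        by_mol.setdefault(r.molecule, []).append(r)
    bend_rows = []
    for m, rl in sorted(by_mol.items()):
        if len(rl) < 3:
            continue
        rl = sorted(rl, key=lambda r: top.resids[r.atoms[0]])
        cents = carbgeom.residue_ring_centroids(fitted, [r.atoms for r in rl])
        for f in range(fitted.n_frames):
            geo = carbgeom.chain_bend(cents[f])
            for i, ang in enumerate(geo.bend_angles):
                bend_rows.append((f, m, i + 1, ang))
    if bend_rows:
        bend_df = pd.DataFrame(bend_rows, columns=["frame", "molecule",
                                                   "position", "bend_deg"])
        bend_df.to_csv(outdir / "bend.csv", index=False)
        out["mean_bend_deg"] = float(bend_df["bend_deg"].mean())
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _dump_json(obj, path):
    Path(path).write_text(json.dumps(_jsonable(obj), indent=1,
                                     sort_keys=True) + "\n")


def summarize_replicas(summaries: list[dict | str | Path]) -> pd.DataFrame:
    """Cross-replica table: region counts, handedness, triad/chair stats.

    Accepts summary dicts or paths to ``summary.json`` files.  Replicas
    analysed with different parameters are refused, with the differing keys
    reported — mixing them would make the shape tallies meaningless.  The
    returned table carries a ``modal_region_count`` attribute: the modal
    number of low-A regions at the first isolevel (the map "shape class").
    """
    loaded = []
    for s in summaries:
        if isinstance(s, (str, Path)):
            s = json.loads(Path(s).read_text())
        loaded.append(s)
    if not loaded:
        raise ValueError("no replica summaries given")
    ref_params = loaded[0].get("analysis_params", {})
    for i, s in enumerate(loaded[1:], start=1):
        params = s.get("analysis_params", {})
        if params != ref_params:
            diff = {k for k in set(ref_params) | set(params)
                    if ref_params.get(k) != params.get(k)}
            raise ValueError(f"replica {i} was analysed with different "
                             f"parameters; differing keys: {sorted(diff)}")
    rows = []
    for i, s in enumerate(loaded):
        row = {"replica": i}
        for lv, n in s.get("region_counts", {}).items():
            row[f"regions_{lv}kJmol"] = n
        row["handedness"] = s.get("stack", {}).get("handedness")
        row["mean_twist_deg"] = s.get("stack", {}).get("mean_twist_deg")
        if "mean_bend_deg" in s:
            row["mean_bend_deg"] = s["mean_bend_deg"]
        cf = s.get("chair_fraction")
        if cf:
            row["chair_fraction"] = float(np.mean(list(cf.values())))
        rows.append(row)
    table = pd.DataFrame(rows)
    first_level = next(iter(loaded[0].get("region_counts", {})), None)
    if first_level is not None:
        counts = table[f"regions_{first_level}kJmol"]
        table.attrs["modal_region_count"] = int(counts.mode().iloc[0])
        table.attrs["modal_region_tally"] = \
            f"{int((counts == counts.mode().iloc[0]).sum())}/{len(counts)}"
    return table
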