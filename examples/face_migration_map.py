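"""Resolve two binding faces from a hopping trajectory.

A probe alternates between the top and bottom faces of a static Yariv mimic
with exponential dwell times.  The free-energy-like map should show two
disconnected basins on opposite sides of the molecular plane, and assigning
each frame to its nearest basin should recover the latent face state.
"""

import numpy as np

from yarivmd import felmap, synth, trajio

top, traj, truth = synth.gen_face_migration(n_frames=20_000,
                                            mean_lifetime=500, seed=0)
sel = trajio.AtomSelection([truth["probe_atom"]], "probe")
fel = felmap.boltzmann_invert(felmap.accumulate_occupancy(traj, sel))
regions = felmap.map_minima(fel, level=5.0)

print(f"low-A regions at 5 kJ/mol: {len(regions)}")
for r in regions:
    print(f"  centroid z = {r.centroid[2]:+.1f} A, volume {r.volume:.0f} A^3,"
          f" depth {r.depth:.2f} kJ/mol")

pts = traj.coords[:, truth["probe_atom"], :]
dist = np.stack([np.linalg.norm(pts - r.centroid, axis=1) for r in regions])
assign = np.argmin(dist, axis=0)
top_region = int(np.argmax([r.centroid[2] for r in regions]))
recovered = np.where(assign == top_region, 0, 1)
accuracy = (recovered == np.array(truth["states"])).mean()
print(f"frame-level face recovery: {accuracy:.4f}")
# Two basins with near-equal depths and >99% state recovery show the map
# machinery separates metastable binding sites cleanly.
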