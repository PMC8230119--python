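"""Measure stacking order, per-unit twist and handedness of a Yariv stack.

A four-unit stack is generated with a +10 degree right-handed twist per
unit.  The analysis rebuilds the stacking graph from parallel pi-pi ring
contacts and reports the signed twist of every adjacent pair (folded into
(-60, 60] by the molecule's 3-fold arm symmetry).
"""

from yarivmd import interactions, synth

top, traj, truth = synth.gen_rigid_stack(n_units=4, twist_deg=10.0,
                                         rise=3.5, n_frames=1, seed=0)
rings = interactions.detect_rings(top, traj.coords[0])
stack = interactions.stack_topology(rings)

print(f"stack order (molecule indices along the axis): {stack.order}")
for (i, j), twist in stack.twists.items():
    print(f"  units {i}-{j}: twist {twist:+.2f} deg")
print(f"handedness statistic: {interactions.handedness(stack.twists.values()):+.1f} "
      f"(+1 = uniformly right-handed screw)")
for entry in interactions.irregularity_profile(stack):
    print(f"  pair {entry['pair']}: interplanar {entry['angle_deg']:.2f} deg,"
          f" rise {entry['rise_A']:.2f} A, slip {entry['slip_A']:.2f} A")
# Recovering +10 deg on every pair with handedness +1 demonstrates the
# chirality-sensitive twist measurement behind helical-stacking analysis.
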