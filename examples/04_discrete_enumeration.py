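"""Enumerate every good-scoring combination of discrete placements.

Two components each have a handful of candidate positions; a distance
restraint links them.  The divide-and-conquer enumerator returns exactly
the combinations in which every restraint is at or below its threshold —
the same set the brute-force product finds.  With contradictory
restraints the set is empty: the platform's signature for inconsistent
input data.
"""

import numpy as np

import assemblage as asm

model = asm.Model()
model.create_particle("x.p", (0, 0, 0), 1.0, 1.0, subunit="x")
model.create_particle("y.p", (0, 0, 0), 1.0, 1.0, subunit="y")

states = {
    "x": [{"x.p": np.array([float(v), 0.0, 0.0])} for v in (0, 5, 10)],
    "y": [{"y.p": np.array([float(v), 0.0, 0.0])} for v in (4, 9, 30)],
}
space = asm.DiscreteStateSpace(model, states)

# consistent data: |x - y| should be about 4
scoring = asm.ScoringFunction(
    [asm.HarmonicDistanceRestraint("x.p", "y.p", d0=4.0, k=1.0, threshold=0.5)]
)
good = asm.domino_sample(space, scoring)
oracle = asm.brute_force_enumerate(space, scoring)
print("good-scoring assignments (x state, y state):", good)
print("brute force agrees:", good == oracle)
for gx, gy in good:
    d = abs(states["x"][gx]["x.p"][0] - states["y"][gy]["y.p"][0])
    print(f"  x={states['x'][gx]['x.p'][0]:4.0f}  y={states['y'][gy]['y.p'][0]:4.0f}  |d-4| = {abs(d-4):.1f}")

# contradictory data: no placement can be both near and far
contradictory = asm.ScoringFunction(
    [
        asm.HarmonicDistanceRestraint("x.p", "y.p", d0=4.0, k=1.0, threshold=0.5, name="near"),
        asm.HarmonicDistanceRestraint("x.p", "y.p", d0=25.0, k=1.0, threshold=0.5, name="far"),
    ]
)
print("\nwith contradictory restraints:", asm.domino_sample(space, contradictory),
      "<- empty set = the data are inconsistent")
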