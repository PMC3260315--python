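"""Build a coarse-grained two-protein model and score it.

Each protein chain becomes a few beads (mass and volume conserved), the
two chains are declared rigid bodies, and a scoring function with an
excluded-volume term and one cross-link-style distance bound evaluates
the arrangement.
"""

import numpy as np

import assemblage as asm

model = asm.Model()
for label, n_residues, n_beads, origin in (
    ("A", 300, 3, (0.0, 0.0, 0.0)),
    ("B", 150, 2, (0.0, 30.0, 0.0)),
):
    for bead in asm.coarse_grain_chain(label, n_residues, n_beads, origin=origin):
        model.add_particle(bead)
    model.create_rigid_body(label, model.hierarchy[label])

print("particles:")
for p in model.particles.values():
    print(f"  {p.id}: r={p.radius:5.2f} A  m={p.mass:7.1f} Da  residues {p.residue_range}")

scoring = asm.ScoringFunction(
    [
        asm.ExcludedVolumeRestraint(k=1.0, threshold=1.0),
        # proximity bound between the first beads of A and B, 32 A centre distance
        asm.HarmonicDistanceRestraint("A.1", "B.1", d0=32.0, k=0.5, kind="upper",
                                      threshold=0.5),
    ]
)
total = scoring.evaluate(model)
print(f"\ntotal score: {total:.3f}  (0 means every restraint is perfectly satisfied)")
print("per-term raw scores:", {k: round(v, 3) for k, v in scoring.evaluate_terms(model).items()})
print("good-scoring (every term at or below threshold):", scoring.is_good_scoring(model))

# move B away: the proximity bound starts to pay
model.transform_rigid_body("B", (1, 0, 0, 0), (0.0, 30.0, 0.0))
print(f"\nafter moving B 30 A away: total = {scoring.evaluate(model):.3f}, "
      f"good-scoring = {scoring.is_good_scoring(model)}")
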