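"""Synthetic ground-truth assemblies and simulated "experimental" data.

Every other module is testable offline against fixtures built here: a
random multi-subunit bead assembly with known coordinates (the ground
truth), a density map forward-simulated from it at a stated resolution,
and noisy proximity (cross-link) records drawn from its contact pairs.
:func:`write_fixture_bundle` packages all of that, plus ready-to-run
configurations for a two-round experiment — round 1 scores against the
map alone, round 2 adds the cross-links — mirroring the situation where a
density map by itself is too ambiguous to resolve an assembly uniquely
and interaction data break the tie.

Defaults are the toy scale the test suite runs at: 4 subunits of 1-3
beads with radii 8-14 Å, a 20 Å map on a 48³ grid.  All randomness flows
from one per-fixture seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .core import Model, Particle, RESIDUE_VOLUME
from .density import GridSpec, sigma_from_resolution, simulate_density
from .io.crosslinks import CrosslinkRecord
from .io.mrc import write_mrc
from .io.pdb import write_pdb

__all__ = [
    "Contact",
    "GroundTruth",
    "generate_assembly",
    "simulate_crosslinks",
    "perturb_configuration",
    "write_crosslink_csv",
    "write_fixture_bundle",
]

#: Maximum tolerated inter-subunit bead overlap in a ground truth, Å.
MAX_OVERLAP = 0.1

_PLACEMENT_ATTEMPTS = 10_000


@dataclass(frozen=True)
class Contact:
    """A subunit pair in surface contact, with the realizing bead pair."""

    subunit1: str
    subunit2: str
    particle1: str
    particle2: str
    gap: float  # surface gap d − r1 − r2, Å


@dataclass
class GroundTruth:
    """A generated assembly with its contact list and provenance."""

    model: Model
    contacts: List[Contact]
    contact_cutoff: float
    seed: int
    params: Dict[str, object] = field(default_factory=dict)

    @property
    def subunits(self) -> List[str]:
        return list(self.model.hierarchy)

    def min_radius(self) -> float:
        return float(min(p.radius for p in self.model.particles.values()))


def _bead_mass(radius: float, residue_mass: float = 110.0) -> float:
    """Mass consistent with the volume rule: one residue per 130 Å³."""
    volume = 4.0 / 3.0 * np.pi * radius**3
    return volume / RESIDUE_VOLUME * residue_mass


def _subunit_beads(
    label: str, radii: Sequence[float], rng: np.random.Generator
) -> List[Particle]:
    """Collinear touching beads along a random direction, centroid at 0."""
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    beads = []
    x = 0.0
    prev = 0.0
    for i, r in enumerate(radii, start=1):
        x += prev + r if beads else 0.0
        beads.append(
            Particle(
                id=f"{label}.{i}",
                xyz=direction * x,
                radius=float(r),
                mass=_bead_mass(float(r)),
                subunit=label,
            )
        )
        prev = r
    centroid = np.mean([b.xyz for b in beads], axis=0)
    for b in beads:
        b.xyz = b.xyz - centroid
    return beads


def _pair_gaps(model: Model) -> Dict[Tuple[str, str], Tuple[str, str, float]]:
    """Per subunit pair: the (bead1, bead2, gap) of the closest bead pair."""
    out: Dict[Tuple[str, str], Tuple[str, str, float]] = {}
    hierarchy = model.hierarchy
    labels = list(hierarchy)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            best = None
            for pa in hierarchy[a]:
                for pb in hierarchy[b]:
                    p, q = model.particles[pa], model.particles[pb]
                    gap = float(np.linalg.norm(p.xyz - q.xyz)) - p.radius - q.radius
                    if best is None or gap < best[2]:
                        best = (pa, pb, gap)
            out[(a, b)] = best  # type: ignore[assignment]
    return out


def generate_assembly(
    n_subunits: int = 4,
    beads_per_subunit: Tuple[int, int] = (1, 3),
    bead_radius_range: Tuple[float, float] = (8.0, 14.0),
    contact_cutoff: float = 2.0,
    seed: int = 0,
) -> GroundTruth:
    """Generate a connected, non-overlapping bead assembly.

    Subunits are placed by sequential random attachment: each new subunit
    is rotated randomly and positioned so one of its beads touches a bead
    of an already-placed subunit (surface gap below half the contact
    cutoff), then rejected and retried if any inter-subunit overlap
    exceeds 0.1 Å.  The result is deterministic in ``seed`` and always
    connected under ``contact_cutoff``.
    """
    if n_subunits < 2:
        raise ValueError("n_subunits must be >= 2")
    lo_b, hi_b = beads_per_subunit
    lo_r, hi_r = bead_radius_range
    if not (1 <= lo_b <= hi_b):
        raise ValueError(f"bad beads_per_subunit range {beads_per_subunit}")
    if not (0 < lo_r <= hi_r):
        raise ValueError(f"bad bead_radius_range {bead_radius_range}")
    rng = np.random.default_rng(seed)
    labels = [chr(ord("A") + i) for i in range(n_subunits)]
    model = Model()
    placed: List[str] = []
    # The assembly is asymmetric by design: subunit size scales are spread
    # evenly across the radius range (random assignment), and within a
    # multi-bead subunit the bead radii spread around that scale.  Two
    # subunits of near-identical size would be interchangeable in any
    # coarse density map — a degeneracy of the fixture, not of the method.
    scales = np.linspace(lo_r, hi_r, n_subunits)
    rng.shuffle(scales)
    half_span = (hi_r - lo_r) / (2.0 * max(1, n_subunits - 1))
    for label, scale in zip(labels, scales):
        n_beads = int(rng.integers(lo_b, hi_b + 1))
        if n_beads == 1:
            radii = np.array([scale])
        else:
            radii = np.clip(
                np.linspace(scale - half_span, scale + half_span, n_beads), lo_r, hi_r
            )
            rng.shuffle(radii)
        beads = _subunit_beads(label, radii, rng)
        if not placed:
            for b in beads:
                model.add_particle(b)
        else:
            local = np.array([b.xyz for b in beads])
            others = [model.particles[pid] for pid in model.ids]
            for attempt in range(_PLACEMENT_ATTEMPTS):
                rot = Rotation.random(rng=rng)
                oriented = rot.apply(local)
                anchor_new = int(rng.integers(len(beads)))
                target_label = placed[int(rng.integers(len(placed)))]
                target_ids = model.hierarchy[target_label]
                target = model.particles[target_ids[int(rng.integers(len(target_ids)))]]
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                gap = rng.uniform(0.0, 0.5 * contact_cutoff)
                shift = (
                    target.xyz
                    + direction * (target.radius + beads[anchor_new].radius + gap)
                    - oriented[anchor_new]
                )
                coords = oriented + shift
                ok = all(
                    np.linalg.norm(c - o.xyz) >= r + o.radius - MAX_OVERLAP
                    for c, r in zip(coords, (b.radius for b in beads))
                    for o in others
                )
                if ok:
                    for b, c in zip(beads, coords):
                        b.xyz = c
                        model.add_particle(b)
                    break
            else:
                raise RuntimeError(
                    f"could not place subunit {label!r} after {_PLACEMENT_ATTEMPTS} "
                    "attempts; widen the bead radius spread or the contact cutoff"
                )
        placed.append(label)
        model.create_rigid_body(label, model.hierarchy[label])
    contacts = [
        Contact(a, b, pa, pb, gap)
        for (a, b), (pa, pb, gap) in _pair_gaps(model).items()
        if gap <= contact_cutoff
    ]
    return GroundTruth(
        model=model,
        contacts=contacts,
        contact_cutoff=contact_cutoff,
        seed=seed,
        params={
            "n_subunits": n_subunits,
            "beads_per_subunit": list(beads_per_subunit),
            "bead_radius_range": list(bead_radius_range),
            "contact_cutoff": contact_cutoff,
        },
    )


def simulate_crosslinks(
    ground_truth: GroundTruth,
    cutoff: Optional[float] = None,
    false_positive_rate: float = 0.0,
    n_links: Optional[int] = None,
    seed: int = 0,
) -> List[CrosslinkRecord]:
    """Draw proximity records from an assembly's bead pairs.

    True links come uniformly from inter-subunit bead pairs with surface
    gap ≤ ``cutoff``; each emitted link is instead false (drawn from pairs
    with gap > cutoff) with probability ``false_positive_rate``.  Each
    record's centre-distance bound is cutoff + both radii and names the
    bead pair it was drawn for.  Defaults: cutoff = the ground truth's
    contact cutoff.  With the defaults ``n_links=None`` and a zero false
    rate the complete true set is emitted — every distinct in-cutoff pair
    exactly once, in sorted order; otherwise ``n_links`` records are drawn
    with replacement.
    """
    if not 0 <= false_positive_rate < 1:
        raise ValueError(f"false_positive_rate must be in [0, 1), got {false_positive_rate}")
    cutoff = ground_truth.contact_cutoff if cutoff is None else float(cutoff)
    model = ground_truth.model
    hierarchy = model.hierarchy
    labels = list(hierarchy)
    true_pool: List[Tuple[str, str, str, str]] = []
    false_pool: List[Tuple[str, str, str, str]] = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            for pa in hierarchy[a]:
                for pb in hierarchy[b]:
                    p, q = model.particles[pa], model.particles[pb]
                    gap = float(np.linalg.norm(p.xyz - q.xyz)) - p.radius - q.radius
                    (true_pool if gap <= cutoff else false_pool).append((a, b, pa, pb))
    if not true_pool:
        raise ValueError(f"no bead pairs within cutoff {cutoff} Å")
    if n_links is not None and false_positive_rate == 0.0 and n_links > len(true_pool):
        raise ValueError(
            f"requested {n_links} links but only {len(true_pool)} true pairs "
            f"exist within {cutoff} Å"
        )

    def record(i: int, pair: Tuple[str, str, str, str]) -> CrosslinkRecord:
        a, b, pa, pb = pair
        bound = cutoff + model.particles[pa].radius + model.particles[pb].radius
        return CrosslinkRecord(
            subunit1=a,
            subunit2=b,
            max_distance=float(bound),
            weight=1.0,
            particle1=pa,
            particle2=pb,
            line=i + 2,
        )

    if n_links is None and false_positive_rate == 0.0:
        return [record(i, pair) for i, pair in enumerate(sorted(true_pool))]
    if n_links is None:
        n_links = len(true_pool)
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_links):
        use_false = false_pool and rng.random() < false_positive_rate
        pool = false_pool if use_false else true_pool
        records.append(record(i, pool[int(rng.integers(len(pool)))]))
    return records


def pairwise_crosslinks(
    ground_truth: GroundTruth, margin: Optional[float] = None
) -> List[CrosslinkRecord]:
    """The complete all-true pairwise proximity set, bead-resolved.

    One record for *every* inter-subunit bead pair, with a centre-distance
    upper bound of its true distance plus ``margin`` (default: the contact
    cutoff).  This is the idealized exhaustive proximity experiment the
    two-round demonstration adds in round 2: with every bead multiply
    anchored the good-scoring set shrinks to (a mirror pair of) one
    arrangement, and the density map decides the hand.
    """
    margin = ground_truth.contact_cutoff if margin is None else float(margin)
    model = ground_truth.model
    hierarchy = model.hierarchy
    labels = list(hierarchy)
    records = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            for pa in hierarchy[a]:
                for pb in hierarchy[b]:
                    p, q = model.particles[pa], model.particles[pb]
                    d = float(np.linalg.norm(p.xyz - q.xyz))
                    records.append(
                        CrosslinkRecord(
                            subunit1=a,
                            subunit2=b,
                            max_distance=d + margin,
                            weight=1.0,
                            particle1=pa,
                            particle2=pb,
                            line=len(records) + 2,
                        )
                    )
    return records


def perturb_configuration(
    ground_truth: GroundTruth,
    translation_sigma: float,
    rotation_max: float,
    seed: int = 0,
) -> Model:
    """A randomized starting model: each subunit rigidly displaced.

    Translations are isotropic Gaussians of the given sigma (Å); rotations
    use a uniformly random axis and an angle uniform in [0, rotation_max]
    degrees, about the subunit centroid.  Zero sigmas reproduce the ground
    truth.  The ground truth itself is left untouched.
    """
    if translation_sigma < 0 or rotation_max < 0:
        raise ValueError("perturbation magnitudes must be >= 0")
    rng = np.random.default_rng(seed)
    model = _copy_model(ground_truth.model)
    for bid in model.rigid_bodies:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = np.deg2rad(rotation_max) * rng.random()
        translation = rng.normal(0.0, translation_sigma, size=3) if translation_sigma else np.zeros(3)
        model.transform_rigid_body(bid, Rotation.from_rotvec(axis * angle), translation)
    return model


def _copy_model(model: Model) -> Model:
    out = Model()
    for p in model.particles.values():
        out.create_particle(
            p.id, p.xyz.copy(), p.radius, p.mass, p.subunit, p.residue_range, **p.extra
        )
    for bid, body in model.rigid_bodies.items():
        out.create_rigid_body(bid, list(body.member_ids))
    return out


def write_crosslink_csv(records: Sequence[CrosslinkRecord], path) -> None:
    lines = ["# simulated proximity records", "subunit1,subunit2,max_distance,weight,particle1,particle2"]
    for r in records:
        lines.append(
            f"{r.subunit1},{r.subunit2},{r.max_distance:.3f},{r.weight:g},{r.particle1},{r.particle2}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def centered_grid_spec(
    model: Model, resolution: float, n_voxels: int = 48
) -> GridSpec:
    """A cubic n³ grid centred on the model covering it plus 4σ padding."""
    coords = model.coords()
    center = 0.5 * (coords.min(axis=0) + coords.max(axis=0))
    # one sigma of margin beyond the largest sphere: enough to hold the bulk
    # of the density while keeping the box tight, so the voxel correlation
    # is not diluted by empty background
    pad = sigma_from_resolution(resolution) + float(model.radii().max())
    extent = float((coords.max(axis=0) - coords.min(axis=0)).max()) + 2.0 * pad
    spacing = extent / (n_voxels - 1)
    origin = center - 0.5 * extent
    return GridSpec(tuple(origin), spacing, (n_voxels, n_voxels, n_voxels))


def write_fixture_bundle(
    ground_truth: GroundTruth,
    resolution: float,
    out_dir,
    n_voxels: int = 48,
    n_runs: int = 12,
    n_steps: int = 3000,
) -> Dict[str, str]:
    """Write a self-contained two-round modeling experiment.

    Produces truth.pdb, a simulated map.mrc at ``resolution``, xlinks.csv
    (the complete noise-free pairwise proximity set over beads),
    round1.json (map + excluded volume only) and round2.json (the same
    plus the cross-links), and a manifest.  Returns the manifest mapping.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = ground_truth.model
    write_pdb(model, out_dir / "truth.pdb")
    spec = centered_grid_spec(model, resolution, n_voxels)
    grid = simulate_density(model, resolution, spec)
    write_mrc(grid, out_dir / "map.mrc")
    records = pairwise_crosslinks(ground_truth)
    write_crosslink_csv(records, out_dir / "xlinks.csv")

    representation = [
        {"label": label, "pdb": "truth.pdb", "chain": label}
        for label in ground_truth.subunits
    ]
    em_term = {
        "type": "em_fit",
        "map": "map.mrc",
        "resolution": resolution,
        "weight": 100.0,
        "threshold": 0.2,
    }
    ev_term = {"type": "excluded_volume", "k": 1.0, "weight": 1.0, "threshold": 10.0}
    coords = model.coords()
    start_radius = float(np.linalg.norm(coords - coords.mean(axis=0), axis=1).max()) + 10.0
    sampling = {
        "method": "monte_carlo",
        "n_runs": n_runs,
        "n_steps": n_steps,
        "t_start": 5.0,
        "t_end": 0.1,
        "start": "anchor",
        "start_radius": start_radius,
        "moves": [
            {"kind": "rigid_body", "max_translation": 3.0, "max_rotation": 25.0},
            {"kind": "rigid_body", "max_translation": 3.0, "max_rotation": 25.0},
            {"kind": "rigid_body", "max_translation": 1.5, "max_rotation": 180.0},
            {"kind": "swap"},
        ],
    }
    analysis = {
        "cluster_method": "binning",
        "rmsd_cutoff": ground_truth.min_radius(),
        "good_scoring_only": True,
    }
    round1 = {
        "representation": representation,
        "restraints": [em_term, ev_term],
        "sampling": dict(sampling, rectify=False),
        "analysis": analysis,
        "output_dir": "round1_out",
        "seed": int(ground_truth.seed),
    }
    round2 = {
        "representation": representation,
        "restraints": [
            dict(em_term, threshold=0.003),
            ev_term,
            {"type": "crosslinks", "path": "xlinks.csv", "k": 0.2, "threshold": 0.01},
        ],
        "sampling": sampling,
        "analysis": analysis,
        "output_dir": "round2_out",
        "seed": int(ground_truth.seed) + 1,
    }
    (out_dir / "round1.json").write_text(json.dumps(round1, indent=2) + "\n")
    (out_dir / "round2.json").write_text(json.dumps(round2, indent=2) + "\n")
    manifest = {
        "truth": "truth.pdb",
        "map": "map.mrc",
        "crosslinks": "xlinks.csv",
        "round1": "round1.json",
        "round2": "round2.json",
        "seed": int(ground_truth.seed),
        "resolution": float(resolution),
        "params": ground_truth.params,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
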