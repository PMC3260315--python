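"""Particle-based model representation.

Candidate structures are encoded as collections of particles — identified
spheres carrying coordinates (Å), a radius (Å), a mass (Da) and free-form
labels.  Groups of particles can be declared rigid bodies, which move as a
unit under rotations/translations and preserve their internal geometry.
Coordinates use a right-handed frame; lengths are Å, masses Da throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Particle",
    "RigidBody",
    "Model",
    "Configuration",
    "coarse_grain_chain",
    "RESIDUE_VOLUME",
]

#: Average partial volume of one amino-acid residue, Å³.  Used by the
#: coarse-graining bead-radius rule so bead volume matches chain volume.
RESIDUE_VOLUME = 130.0

_QUAT_NORM_TOL = 1e-6


def _as_xyz(xyz: Sequence[float]) -> np.ndarray:
    arr = np.asarray(xyz, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {arr.shape}")
    return arr


def _check_quaternion(q: Sequence[float]) -> np.ndarray:
    """Validate a scalar-first (w, x, y, z) unit quaternion.

    Quaternions within 1e-6 of unit norm are renormalised; anything further
    off is rejected as a malformed rotation.
    """
    q = np.asarray(q, dtype=float)
    if q.shape != (4,):
        raise ValueError("quaternion must have 4 components (w, x, y, z)")
    n = float(np.linalg.norm(q))
    if abs(n - 1.0) > _QUAT_NORM_TOL:
        raise ValueError(f"quaternion norm {n:.8f} deviates from 1 by more than {_QUAT_NORM_TOL}")
    return q / n


def quaternion_to_rotation(q: Sequence[float]) -> Rotation:
    """Scalar-first quaternion -> scipy Rotation."""
    return Rotation.from_quat(_check_quaternion(q), scalar_first=True)


def rotation_to_quaternion(rot: Rotation) -> np.ndarray:
    """scipy Rotation -> scalar-first quaternion with non-negative w."""
    q = rot.as_quat(scalar_first=True)
    return q if q[0] >= 0 else -q


@dataclass
class Particle:
    """A sphere with attributes.

    ``extra`` is an open string→number map for user-defined attributes, so
    new per-particle quantities can be attached without changing the type.
    """

    id: str
    xyz: np.ndarray
    radius: float
    mass: float
    subunit: str = ""
    residue_range: Optional[Tuple[int, int]] = None
    rigid_body: Optional[str] = None
    extra: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xyz = _as_xyz(self.xyz)
        if not self.radius > 0:
            raise ValueError(f"particle {self.id!r}: radius must be > 0, got {self.radius}")
        if not self.mass > 0:
            raise ValueError(f"particle {self.id!r}: mass must be > 0, got {self.mass}")
        if self.residue_range is not None:
            a, b = self.residue_range
            if a > b:
                raise ValueError(
                    f"particle {self.id!r}: residue_range start {a} > end {b}"
                )
            self.residue_range = (int(a), int(b))


@dataclass
class RigidBody:
    """A group of particles that moves as a unit.

    ``frame`` records the cumulative motion applied since construction as a
    scalar-first unit quaternion plus a translation (Å); the internal
    geometry of the members is invariant under frame updates.
    """

    id: str
    member_ids: List[str]
    quaternion: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0]))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if len(self.member_ids) < 1:
            raise ValueError(f"rigid body {self.id!r} must have at least one member")
        self.quaternion = _check_quaternion(self.quaternion)
        self.translation = _as_xyz(self.translation)

    @property
    def frame(self) -> Tuple[np.ndarray, np.ndarray]:
        return self.quaternion, self.translation


@dataclass(frozen=True)
class Configuration:
    """Snapshot of all particle positions and rigid-body frames.

    Restoring a snapshot reproduces coordinates bit-identically, which is
    what Monte Carlo reject/restore and ensemble bookkeeping rely on.
    """

    xyz: Mapping[str, np.ndarray]
    frames: Mapping[str, Tuple[np.ndarray, np.ndarray]]

    def coords(self, ids: Sequence[str]) -> np.ndarray:
        """Stack coordinates for ``ids`` into an (n, 3) array."""
        return np.array([self.xyz[i] for i in ids], dtype=float)

    def __eq__(self, other: object) -> bool:  # bitwise coordinate equality
        if not isinstance(other, Configuration):
            return NotImplemented
        if set(self.xyz) != set(other.xyz):
            return False
        return all(np.array_equal(self.xyz[i], other.xyz[i]) for i in self.xyz)


class Model:
    """An ordered collection of particles plus rigid-body declarations."""

    def __init__(self) -> None:
        self.particles: Dict[str, Particle] = {}
        self.rigid_bodies: Dict[str, RigidBody] = {}

    # -- construction -------------------------------------------------

    def create_particle(
        self,
        id: str,
        xyz: Sequence[float],
        radius: float,
        mass: float,
        subunit: str = "",
        residue_range: Optional[Tuple[int, int]] = None,
        **extra: float,
    ) -> Particle:
        if id in self.particles:
            raise ValueError(f"duplicate particle id {id!r}")
        p = Particle(
            id=id,
            xyz=_as_xyz(xyz),
            radius=radius,
            mass=mass,
            subunit=subunit,
            residue_range=residue_range,
            extra=dict(extra),
        )
        self.particles[id] = p
        return p

    def add_particle(self, particle: Particle) -> Particle:
        if particle.id in self.particles:
            raise ValueError(f"duplicate particle id {particle.id!r}")
        self.particles[particle.id] = particle
        return particle

    def create_rigid_body(self, id: str, member_ids: Sequence[str]) -> RigidBody:
        if id in self.rigid_bodies:
            raise ValueError(f"duplicate rigid body id {id!r}")
        for pid in member_ids:
            if pid not in self.particles:
                raise KeyError(f"rigid body {id!r} references unknown particle {pid!r}")
            if self.particles[pid].rigid_body is not None:
                raise ValueError(
                    f"particle {pid!r} already belongs to rigid body "
                    f"{self.particles[pid].rigid_body!r}"
                )
        body = RigidBody(id=id, member_ids=list(member_ids))
        for pid in member_ids:
            self.particles[pid].rigid_body = id
        self.rigid_bodies[id] = body
        return body

    # -- access --------------------------------------------------------

    @property
    def ids(self) -> List[str]:
        return list(self.particles)

    @property
    def hierarchy(self) -> Dict[str, List[str]]:
        """subunit label -> particle ids, in insertion order."""
        h: Dict[str, List[str]] = {}
        for pid, p in self.particles.items():
            h.setdefault(p.subunit, []).append(pid)
        return h

    def coords(self, ids: Optional[Sequence[str]] = None) -> np.ndarray:
        ids = self.ids if ids is None else list(ids)
        return np.array([self.particles[i].xyz for i in ids], dtype=float)

    def set_coords(self, coords: np.ndarray, ids: Optional[Sequence[str]] = None) -> None:
        ids = self.ids if ids is None else list(ids)
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(ids), 3):
            raise ValueError(f"coordinate array shape {coords.shape} != ({len(ids)}, 3)")
        for pid, row in zip(ids, coords):
            self.particles[pid].xyz = row.copy()

    def radii(self, ids: Optional[Sequence[str]] = None) -> np.ndarray:
        ids = self.ids if ids is None else list(ids)
        return np.array([self.particles[i].radius for i in ids], dtype=float)

    def masses(self, ids: Optional[Sequence[str]] = None) -> np.ndarray:
        ids = self.ids if ids is None else list(ids)
        return np.array([self.particles[i].mass for i in ids], dtype=float)

    def subunit_ids(self, subunit: str) -> List[str]:
        ids = [pid for pid, p in self.particles.items() if p.subunit == subunit]
        if not ids:
            raise KeyError(f"no particles with subunit label {subunit!r}")
        return ids

    # -- rigid motion --------------------------------------------------

    def transform_rigid_body(
        self,
        body_id: str,
        rotation: Sequence[float] | Rotation,
        translation: Sequence[float],
    ) -> None:
        """Rotate a body about its centroid, then translate it.

        ``rotation`` is a scalar-first unit quaternion (normalised if within
        1e-6 of unit norm) or a scipy Rotation.
        """
        if body_id not in self.rigid_bodies:
            raise KeyError(f"unknown rigid body {body_id!r}")
        body = self.rigid_bodies[body_id]
        rot = rotation if isinstance(rotation, Rotation) else quaternion_to_rotation(rotation)
        t = _as_xyz(translation)
        coords = self.coords(body.member_ids)
        centroid = coords.mean(axis=0)
        moved = rot.apply(coords - centroid) + centroid + t
        self.set_coords(moved, body.member_ids)
        # accumulate the frame for the record
        prev = quaternion_to_rotation(body.quaternion)
        body.quaternion = rotation_to_quaternion(rot * prev)
        body.translation = body.translation + t

    # -- snapshots -----------------------------------------------------

    def snapshot(self) -> Configuration:
        return Configuration(
            xyz={pid: p.xyz.copy() for pid, p in self.particles.items()},
            frames={
                bid: (b.quaternion.copy(), b.translation.copy())
                for bid, b in self.rigid_bodies.items()
            },
        )

    def restore(self, configuration: Configuration) -> None:
        if set(configuration.xyz) != set(self.particles):
            raise ValueError(
                "configuration topology mismatch: particle id sets differ "
                f"({len(configuration.xyz)} vs {len(self.particles)} particles)"
            )
        for pid, xyz in configuration.xyz.items():
            self.particles[pid].xyz = xyz.copy()
        for bid, (q, t) in configuration.frames.items():
            if bid in self.rigid_bodies:
                self.rigid_bodies[bid].quaternion = q.copy()
                self.rigid_bodies[bid].translation = t.copy()

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        seen: Dict[str, str] = {}
        for bid, body in self.rigid_bodies.items():
            for pid in body.member_ids:
                if pid not in self.particles:
                    raise ValueError(f"rigid body {bid!r} references missing particle {pid!r}")
                if pid in seen:
                    raise ValueError(
                        f"particle {pid!r} is in two rigid bodies: {seen[pid]!r} and {bid!r}"
                    )
                seen[pid] = bid


def _partition_residues(n_residues: int, n_beads: int) -> List[Tuple[int, int]]:
    """Contiguous 1-based residue blocks, sizes differing by ≤1, earlier larger."""
    base, rem = divmod(n_residues, n_beads)
    ranges = []
    start = 1
    for i in range(n_beads):
        size = base + (1 if i < rem else 0)
        ranges.append((start, start + size - 1))
        start += size
    return ranges


def bead_radius(n_residues: int, residue_volume: float = RESIDUE_VOLUME) -> float:
    """Radius of a sphere whose volume equals ``n_residues`` residues."""
    return float((3.0 * residue_volume * n_residues / (4.0 * np.pi)) ** (1.0 / 3.0))


def coarse_grain_chain(
    subunit: str,
    n_residues: int,
    n_beads: int,
    residue_mass: float = 110.0,
    residue_volume: float = RESIDUE_VOLUME,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> List[Particle]:
    """Represent a chain of ``n_residues`` residues as ``n_beads`` spheres.

    Residues are split into contiguous near-equal blocks (ceiling rule:
    earlier blocks larger).  Each bead gets the block's mass and a radius
    from the volume rule, so total mass and total volume are conserved
    exactly.  Beads are initially collinear along +x with touching surfaces;
    particle ids are "<subunit>.<index>" with 1-based indices.
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    if n_beads > n_residues:
        raise ValueError(f"n_beads ({n_beads}) exceeds n_residues ({n_residues})")
    ranges = _partition_residues(n_residues, n_beads)
    origin = _as_xyz(origin)
    beads: List[Particle] = []
    x = 0.0
    prev_r = 0.0
    for i, (a, b) in enumerate(ranges, start=1):
        n_res = b - a + 1
        r = bead_radius(n_res, residue_volume)
        x += prev_r + r if beads else 0.0
        beads.append(
            Particle(
                id=f"{subunit}.{i}",
                xyz=origin + np.array([x, 0.0, 0.0]),
                radius=r,
                mass=n_res * residue_mass,
                subunit=subunit,
                residue_range=(a, b),
            )
        )
        prev_r = r
    return beads
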