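"""Ensemble comparison, clustering and reporting.

Good-scoring ensembles are rarely a single structure: this module measures
how alike members are (least-squares superposition / RMSD, per-subunit
placement scores), groups them (k-means or greedy RMSD binning), summarises
where a subunit lives across the ensemble (localization probability
density, an EM-map-like average), and checks which restraints each member
satisfies — flagging the ensemble as inconsistent when no member satisfies
everything, the signature of contradictory input data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation
from sklearn.cluster import KMeans

from .core import Model, rotation_to_quaternion
from .density import DensityGrid, GridSpec, simulate_density
from .restraints import ScoringFunction
from .sampling import ScoredConfiguration

__all__ = [
    "Transform",
    "ClusterSet",
    "SatisfactionReport",
    "kabsch_superpose",
    "placement_score",
    "rmsd",
    "align_ensemble",
    "cluster_ensemble",
    "localization_density",
    "satisfaction_report",
]


@dataclass(frozen=True)
class Transform:
    """A proper rigid motion x ↦ R·x + t (quaternion scalar-first, t in Å)."""

    quaternion: np.ndarray
    translation: np.ndarray
    degenerate: bool = False  # True when fitted from a collinear point set

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.quaternion, scalar_first=True)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return self.rotation.apply(np.asarray(coords, dtype=float)) + self.translation

    def inverse(self) -> "Transform":
        rinv = self.rotation.inv()
        return Transform(
            rotation_to_quaternion(rinv), -rinv.apply(self.translation), self.degenerate
        )

    def compose(self, other: "Transform") -> "Transform":
        """self ∘ other: apply ``other`` first."""
        r = self.rotation * other.rotation
        t = self.rotation.apply(other.translation) + self.translation
        return Transform(rotation_to_quaternion(r), t)

    @property
    def angle_degrees(self) -> float:
        """Rotation angle 2·arccos(|q_w|) in degrees, in [0, 180]."""
        w = min(1.0, abs(float(self.quaternion[0])))
        return float(np.degrees(2.0 * np.arccos(w)))


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between matched coordinate sets (no fit)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_superpose(
    coords_ref: np.ndarray, coords_mov: np.ndarray
) -> Tuple[Transform, float]:
    """Least-squares superposition of ``coords_mov`` onto ``coords_ref``.

    Returns the proper rigid motion (rotation via SVD with reflection
    excluded, then translation) minimising the RMSD between the matched
    point sets, together with that minimised RMSD.  Point sets whose
    centred covariance has rank < 2 (all points collinear) cannot pin down
    a rotation; they get a translation-only fit flagged ``degenerate``.
    """
    ref = np.asarray(coords_ref, dtype=float)
    mov = np.asarray(coords_mov, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError(f"matched (n, 3) sets required, got {ref.shape} and {mov.shape}")
    n = ref.shape[0]
    if n < 3:
        raise ValueError(f"at least 3 points required, got {n}")
    cref = ref.mean(axis=0)
    cmov = mov.mean(axis=0)
    h = (ref - cref).T @ (mov - cmov)
    if np.linalg.matrix_rank(h, tol=1e-9) < 2:
        t = cref - cmov
        return (
            Transform(np.array([1.0, 0.0, 0.0, 0.0]), t, degenerate=True),
            rmsd(ref, mov + t),
        )
    rot, _ = Rotation.align_vectors(ref - cref, mov - cmov)
    t = cref - rot.apply(cmov)
    transform = Transform(rotation_to_quaternion(rot), t)
    return transform, rmsd(ref, transform.apply(mov))


def placement_score(
    ref_subunit_coords: np.ndarray, model_subunit_coords: np.ndarray
) -> Tuple[float, float]:
    """(centroid displacement Å, rotation angle °) of a subunit placement.

    The distance is the norm of the centroid displacement; the angle is the
    rotation angle of the least-squares superposition of the subunit onto
    its reference, reported in [0, 180]°.  (0, 0) iff exactly placed.
    """
    ref = np.asarray(ref_subunit_coords, dtype=float)
    mov = np.asarray(model_subunit_coords, dtype=float)
    distance = float(np.linalg.norm(mov.mean(axis=0) - ref.mean(axis=0)))
    transform, _ = kabsch_superpose(ref, mov)
    return distance, transform.angle_degrees


# ---------------------------------------------------------------------------
# ensembles


def _ensemble_coords(
    ensemble: Sequence[ScoredConfiguration], ids: Sequence[str]
) -> np.ndarray:
    return np.array([sc.configuration.coords(ids) for sc in ensemble])


def align_ensemble(
    ensemble: Sequence[ScoredConfiguration], ids: Sequence[str]
) -> np.ndarray:
    """Superpose every member onto the best-scoring one; (m, n, 3) array.

    Removes the global-pose degeneracy (the scoring terms other than the EM
    map are invariant under rigid motion) before any RMSD comparison.
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    coords = _ensemble_coords(ensemble, ids)
    ref_idx = int(np.argmin([sc.total for sc in ensemble]))
    ref = coords[ref_idx]
    out = np.empty_like(coords)
    for i, c in enumerate(coords):
        transform, _ = kabsch_superpose(ref, c)
        out[i] = transform.apply(c)
    return out


@dataclass
class ClusterSet:
    """A partition of an ensemble with per-cluster representatives."""

    assignment: List[int]
    representatives: Dict[int, int]  # cluster id -> ensemble index of lowest-score member
    sizes: Dict[int, int]

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def cluster_ensemble(
    ensemble: Sequence[ScoredConfiguration],
    ids: Sequence[str],
    method: str = "binning",
    k: Optional[int] = None,
    rmsd_cutoff: Optional[float] = None,
    seed: int = 0,
) -> ClusterSet:
    """Cluster an ensemble on flattened, pre-aligned coordinates.

    ``kmeans`` runs seeded k-means (10 restarts, best inertia) with ``k``
    clusters.  ``binning`` is greedy leader clustering: members are visited
    in ascending score order and join the first cluster whose representative
    (its founder — necessarily its lowest-score member) is within
    ``rmsd_cutoff`` RMSD, else found a new cluster; every member is thus
    within the cutoff of its representative.
    """
    if not ensemble:
        raise ValueError("cannot cluster an empty ensemble")
    aligned = align_ensemble(ensemble, ids)
    m = len(ensemble)
    if method == "kmeans":
        if k is None:
            raise ValueError("kmeans requires k")
        if k > m:
            raise ValueError(f"k={k} exceeds ensemble size {m}")
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(aligned.reshape(m, -1)).tolist()
    elif method == "binning":
        if rmsd_cutoff is None:
            raise ValueError("binning requires rmsd_cutoff")
        order = sorted(range(m), key=lambda i: (ensemble[i].total, i))
        labels = [-1] * m
        founders: List[int] = []
        for i in order:
            for cid, f in enumerate(founders):
                if rmsd(aligned[f], aligned[i]) <= rmsd_cutoff:
                    labels[i] = cid
                    break
            else:
                labels[i] = len(founders)
                founders.append(i)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    reps: Dict[int, int] = {}
    sizes: Dict[int, int] = {}
    for i, lab in enumerate(labels):
        sizes[lab] = sizes.get(lab, 0) + 1
        if lab not in reps or ensemble[i].total < ensemble[reps[lab]].total:
            reps[lab] = i
    return ClusterSet(assignment=labels, representatives=reps, sizes=sizes)


def localization_density(
    ensemble: Sequence[ScoredConfiguration],
    model: Model,
    subunit: str,
    grid_spec: GridSpec,
    resolution: float,
) -> DensityGrid:
    """Ensemble-averaged simulated density of one subunit.

    The mean over members of the subunit's forward-modelled map — a 3-D
    probability map, resembling an EM map, whose integral equals the
    subunit mass (each member's map carries that mass).
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    ids = model.subunit_ids(subunit)
    snap = model.snapshot()
    try:
        acc = None
        for sc in ensemble:
            model.restore(sc.configuration)
            g = simulate_density(
                [model.particles[i] for i in ids], resolution, grid_spec
            )
            acc = g.values if acc is None else acc + g.values
        values = acc / len(ensemble)
    finally:
        model.restore(snap)
    return DensityGrid(grid_spec.origin, grid_spec.spacing, values, resolution=resolution)


# ---------------------------------------------------------------------------
# satisfaction


@dataclass
class SatisfactionReport:
    """Per-model, per-restraint satisfaction with an ensemble-level verdict."""

    term_names: List[str]
    thresholds: List[float]
    scores: np.ndarray  # (n_models, n_terms) raw term scores
    satisfied: np.ndarray  # boolean, same shape

    @property
    def n_models(self) -> int:
        return self.scores.shape[0]

    @property
    def models_all_satisfied(self) -> np.ndarray:
        return self.satisfied.all(axis=1)

    @property
    def fraction_satisfied(self) -> Dict[str, float]:
        """Per-term fraction of models satisfying it."""
        frac = self.satisfied.mean(axis=0)
        return dict(zip(self.term_names, frac.tolist()))

    @property
    def inconsistent(self) -> bool:
        """True when no model satisfies every restraint — the signature of
        contradictory input data."""
        return not bool(self.models_all_satisfied.any())

    def to_dict(self) -> dict:
        return {
            "terms": [
                {"name": n, "threshold": t, "fraction_satisfied": f}
                for n, t, f in zip(
                    self.term_names,
                    self.thresholds,
                    self.satisfied.mean(axis=0).tolist(),
                )
            ],
            "n_models": self.n_models,
            "n_models_all_satisfied": int(self.models_all_satisfied.sum()),
            "inconsistent": self.inconsistent,
        }

    def summary(self) -> str:
        lines = [f"{'restraint':<28}{'threshold':>12}{'satisfied':>12}"]
        for name, thr, frac in zip(
            self.term_names, self.thresholds, self.satisfied.mean(axis=0)
        ):
            lines.append(f"{name:<28}{thr:>12.4g}{frac:>11.0%} ")
        verdict = (
            "INCONSISTENT: no model satisfies all restraints"
            if self.inconsistent
            else f"{int(self.models_all_satisfied.sum())}/{self.n_models} models satisfy all restraints"
        )
        lines.append(verdict)
        return "\n".join(lines)


def satisfaction_report(
    ensemble: Sequence[ScoredConfiguration],
    model: Model,
    scoring: ScoringFunction,
) -> SatisfactionReport:
    """Evaluate every restraint on every ensemble member.

    A term is satisfied iff its raw score is at or below its threshold; the
    ensemble is flagged inconsistent iff no member satisfies all terms.
    """
    names = [t.name for t in scoring.terms]
    thresholds = [t.threshold for t in scoring.terms]
    scores = np.zeros((len(ensemble), len(scoring.terms)))
    snap = model.snapshot()
    try:
        for i, sc in enumerate(ensemble):
            model.restore(sc.configuration)
            for j, term in enumerate(scoring.terms):
                scores[i, j] = term.evaluate(model)
    finally:
        model.restore(snap)
    satisfied = scores <= np.asarray(thresholds)[None, :]
    return SatisfactionReport(names, thresholds, scores, satisfied)
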