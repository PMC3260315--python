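"""Restraint terms and the composite scoring function.

A restraint maps a model to a nonnegative score measuring how badly the
model disagrees with one piece of information; zero means the term is
perfectly satisfied.  A scoring function is a weighted sum of restraints.
Each term also carries a threshold: a model is *good-scoring* when every
raw term score is at or below its threshold, which is what the discrete
enumerator prunes on and what satisfaction reports test.

Implemented terms:

* harmonic distance (two particles; plain, upper-bound or lower-bound),
* soft-sphere excluded volume over particle pairs,
* minimum-spanning-tree connectivity over a particle set (emulating
  proximity/composition data),
* EM density fit: one minus the cross-correlation between the model's
  forward-simulated map and an experimental map.

Gradients are analytic for the pairwise/MST terms and central finite
differences (step 0.1·voxel) for the grid-based EM term.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .core import Model
from .density import (
    DensityGrid,
    cross_correlation,
    gaussian_block,
    sigma_from_resolution,
    simulate_density,
)

__all__ = [
    "Restraint",
    "ScoringFunction",
    "HarmonicDistanceRestraint",
    "ExcludedVolumeRestraint",
    "ConnectivityRestraint",
    "EMFitRestraint",
    "harmonic_distance_score",
    "excluded_volume_score",
    "connectivity_score",
    "em_fit_score",
]


class Restraint:
    """Base class: a named, weighted, thresholded scoring term."""

    def __init__(self, name: str, weight: float = 1.0, threshold: float = np.inf):
        if weight < 0:
            raise ValueError(f"restraint {name!r}: weight must be >= 0")
        if threshold < 0:
            raise ValueError(f"restraint {name!r}: threshold must be >= 0")
        self.name = name
        self.weight = float(weight)
        self.threshold = float(threshold)

    def evaluate(self, model: Model) -> float:
        raise NotImplementedError

    def particle_ids(self, model: Model) -> List[str]:
        """Particle ids the term depends on (used for pruning and gradients)."""
        raise NotImplementedError

    def _check_ids(self, model: Model, ids: Sequence[str]) -> List[str]:
        missing = [i for i in ids if i not in model.particles]
        if missing:
            raise KeyError(f"restraint {self.name!r} references missing particles {missing}")
        return list(ids)

    # Default gradient: central finite differences of the raw score.
    _fd_step = 1e-4

    def gradient(self, model: Model) -> Dict[str, np.ndarray]:
        """Raw (unweighted) per-particle gradient, id -> 3-vector."""
        ids = self.particle_ids(model)
        h = self._fd_step
        grad: Dict[str, np.ndarray] = {}
        for pid in ids:
            g = np.zeros(3)
            base = model.particles[pid].xyz.copy()
            for k in range(3):
                model.particles[pid].xyz = base + np.eye(3)[k] * h
                plus = self.evaluate(model)
                model.particles[pid].xyz = base - np.eye(3)[k] * h
                minus = self.evaluate(model)
                g[k] = (plus - minus) / (2 * h)
            model.particles[pid].xyz = base
            grad[pid] = g
        return grad

    def satisfied(self, model: Model) -> bool:
        return self.evaluate(model) <= self.threshold

    def __repr__(self) -> str:
        return f"<{type(self).__name__} {self.name!r} w={self.weight} thr={self.threshold}>"


class ScoringFunction:
    """Weighted sum of restraints: total = sum_i weight_i * score_i."""

    def __init__(self, terms: Sequence[Restraint] = ()):
        self.terms: List[Restraint] = list(terms)

    def add(self, term: Restraint) -> "ScoringFunction":
        self.terms.append(term)
        return self

    def evaluate(self, model: Model, want_gradient: bool = False):
        """Total weighted score, optionally with the summed gradient.

        The gradient is an (n, 3) array aligned to ``model.ids``.
        """
        total = 0.0
        if not want_gradient:
            for term in self.terms:
                total += term.weight * term.evaluate(model)
            return total
        index = {pid: i for i, pid in enumerate(model.ids)}
        grad = np.zeros((len(index), 3))
        for term in self.terms:
            total += term.weight * term.evaluate(model)
            for pid, g in term.gradient(model).items():
                grad[index[pid]] += term.weight * g
        return total, grad

    def evaluate_terms(self, model: Model) -> Dict[str, float]:
        """Raw (unweighted) per-term scores by name."""
        return {term.name: term.evaluate(model) for term in self.terms}

    def is_good_scoring(self, model: Model) -> bool:
        """True iff every raw term score is at or below its threshold."""
        return all(term.evaluate(model) <= term.threshold for term in self.terms)


# ---------------------------------------------------------------------------
# harmonic distance


def harmonic_distance_score(
    d: float, d0: float, k: float, kind: str = "harmonic"
) -> float:
    """0.5·k·(d−d0)² — plain, or one-sided (upper: 0 when d ≤ d0; lower: 0 when d ≥ d0)."""
    if kind == "upper" and d <= d0:
        return 0.0
    if kind == "lower" and d >= d0:
        return 0.0
    return 0.5 * k * (d - d0) ** 2


class HarmonicDistanceRestraint(Restraint):
    """Harmonic restraint on the centre distance between two particles.

    ``kind`` is "harmonic" (two-sided), "upper" (penalise d > d0 only — the
    natural encoding of a cross-link/proximity bound) or "lower".
    """

    KINDS = ("harmonic", "upper", "lower")

    def __init__(
        self,
        p1: str,
        p2: str,
        d0: float,
        k: float,
        kind: str = "harmonic",
        name: Optional[str] = None,
        weight: float = 1.0,
        threshold: float = np.inf,
    ):
        if p1 == p2:
            raise ValueError(f"distance restraint between identical particles {p1!r}")
        if not k > 0:
            raise ValueError(f"spring constant must be > 0, got {k}")
        if d0 < 0:
            raise ValueError(f"equilibrium distance must be >= 0, got {d0}")
        if kind not in self.KINDS:
            raise ValueError(f"kind must be one of {self.KINDS}, got {kind!r}")
        super().__init__(name or f"dist:{p1}-{p2}", weight, threshold)
        self.p1, self.p2, self.d0, self.k, self.kind = p1, p2, float(d0), float(k), kind

    def particle_ids(self, model: Model) -> List[str]:
        return self._check_ids(model, [self.p1, self.p2])

    def evaluate(self, model: Model) -> float:
        self._check_ids(model, [self.p1, self.p2])
        d = float(np.linalg.norm(model.particles[self.p1].xyz - model.particles[self.p2].xyz))
        return harmonic_distance_score(d, self.d0, self.k, self.kind)

    def gradient(self, model: Model) -> Dict[str, np.ndarray]:
        r = model.particles[self.p1].xyz - model.particles[self.p2].xyz
        d = float(np.linalg.norm(r))
        active = not (
            (self.kind == "upper" and d <= self.d0)
            or (self.kind == "lower" and d >= self.d0)
        )
        if not active or d == 0.0:
            z = np.zeros(3)
            return {self.p1: z, self.p2: z.copy()}
        g = self.k * (d - self.d0) * r / d
        return {self.p1: g, self.p2: -g}


# ---------------------------------------------------------------------------
# excluded volume


def excluded_volume_score(model: Model, k: float, ids: Optional[Sequence[str]] = None) -> float:
    """Soft-sphere overlap penalty, same-rigid-body pairs excluded."""
    return ExcludedVolumeRestraint(k, ids=ids).evaluate(model)


class ExcludedVolumeRestraint(Restraint):
    """0.5·k·sum over unordered pairs of max(0, r_i + r_j − d_ij)².

    Pairs inside one rigid body are skipped: their overlap is fixed by the
    body's internal geometry and carries no information.
    """

    def __init__(
        self,
        k: float,
        ids: Optional[Sequence[str]] = None,
        name: str = "excluded_volume",
        weight: float = 1.0,
        threshold: float = np.inf,
    ):
        if not k > 0:
            raise ValueError(f"spring constant must be > 0, got {k}")
        super().__init__(name, weight, threshold)
        self.k = float(k)
        self.ids = list(ids) if ids is not None else None

    def particle_ids(self, model: Model) -> List[str]:
        ids = self.ids if self.ids is not None else model.ids
        return self._check_ids(model, ids)

    def _pairs(self, model: Model):
        ids = self.particle_ids(model)
        coords = model.coords(ids)
        radii = model.radii(ids)
        bodies = [model.particles[i].rigid_body for i in ids]
        n = len(ids)
        if n < 2:
            return ids, np.empty((0, 2), dtype=int), coords, radii
        iu = np.triu_indices(n, k=1)
        same_body = np.array(
            [bodies[i] is not None and bodies[i] == bodies[j] for i, j in zip(*iu)]
        )
        pairs = np.stack(iu, axis=1)[~same_body]
        return ids, pairs, coords, radii

    def evaluate(self, model: Model) -> float:
        ids, pairs, coords, radii = self._pairs(model)
        if len(pairs) == 0:
            return 0.0
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        overlap = np.maximum(0.0, radii[pairs[:, 0]] + radii[pairs[:, 1]] - d)
        return float(0.5 * self.k * np.sum(overlap**2))

    def gradient(self, model: Model) -> Dict[str, np.ndarray]:
        ids, pairs, coords, radii = self._pairs(model)
        grad = {pid: np.zeros(3) for pid in ids}
        for i, j in pairs:
            r = coords[i] - coords[j]
            d = float(np.linalg.norm(r))
            overlap = radii[i] + radii[j] - d
            if overlap > 0 and d > 0:
                g = -self.k * overlap * r / d
                grad[ids[i]] += g
                grad[ids[j]] -= g
        return grad


# ---------------------------------------------------------------------------
# connectivity


def _mst_edges(gaps: np.ndarray) -> List[Tuple[int, int]]:
    """Edges of a minimum spanning tree of the complete gap graph.

    A constant offset keeps zero gaps as real edges (the sparse MST routine
    treats exact zeros as absent); adding a constant to every edge does not
    change which tree is minimal.
    """
    tree = minimum_spanning_tree(gaps + 1.0)
    rows, cols = tree.nonzero()
    return list(zip(rows.tolist(), cols.tolist()))


def connectivity_score(
    model: Model, ids: Sequence[str], k: float, slack: float = 0.0
) -> float:
    """MST-based connectivity penalty over a particle set."""
    return ConnectivityRestraint(ids, k, slack).evaluate(model)


class ConnectivityRestraint(Restraint):
    """Pull a particle set into one connected cluster.

    Edge weight between members is the surface gap
    g_ij = max(0, d_ij − r_i − r_j − slack); the score is 0.5·k·Σ g² over
    the edges of a minimum spanning tree of the complete gap graph, so a
    mutually touching set scores zero.
    """

    def __init__(
        self,
        ids: Sequence[str],
        k: float,
        slack: float = 0.0,
        name: str = "connectivity",
        weight: float = 1.0,
        threshold: float = np.inf,
    ):
        if len(ids) < 2:
            raise ValueError("connectivity requires at least two particles")
        if not k > 0:
            raise ValueError(f"spring constant must be > 0, got {k}")
        if slack < 0:
            raise ValueError(f"slack must be >= 0, got {slack}")
        super().__init__(name, weight, threshold)
        self.ids = list(ids)
        self.k = float(k)
        self.slack = float(slack)

    def particle_ids(self, model: Model) -> List[str]:
        return self._check_ids(model, self.ids)

    def _gaps(self, model: Model) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        ids = self.particle_ids(model)
        coords = model.coords(ids)
        radii = model.radii(ids)
        d = squareform(pdist(coords))
        gaps = np.maximum(0.0, d - radii[:, None] - radii[None, :] - self.slack)
        np.fill_diagonal(gaps, 0.0)
        return coords, radii, gaps

    def evaluate(self, model: Model) -> float:
        _, _, gaps = self._gaps(model)
        edges = _mst_edges(gaps)
        return float(0.5 * self.k * sum(gaps[i, j] ** 2 for i, j in edges))

    def gradient(self, model: Model) -> Dict[str, np.ndarray]:
        # Subgradient: the MST edge set is held fixed at the current
        # configuration (it changes only at ties, a measure-zero set).
        ids = self.particle_ids(model)
        coords, _, gaps = self._gaps(model)
        grad = {pid: np.zeros(3) for pid in ids}
        for i, j in _mst_edges(gaps):
            g = gaps[i, j]
            if g > 0:
                r = coords[i] - coords[j]
                d = float(np.linalg.norm(r))
                v = self.k * g * r / d
                grad[ids[i]] += v
                grad[ids[j]] -= v
        return grad


# ---------------------------------------------------------------------------
# EM fit


def em_fit_score(
    model: Model,
    experimental: DensityGrid,
    resolution: float,
    weight: float = 1.0,
) -> float:
    """weight · (1 − CCC(simulated map, experimental map)); in [0, 2·weight]."""
    simulated = simulate_density(model, resolution, experimental.spec)
    return weight * (1.0 - cross_correlation(simulated, experimental))


class EMFitRestraint(Restraint):
    """Fit to an experimental density map via the forward model.

    Raw score is 1 − CCC between the model's simulated map (on the
    experimental grid's geometry, at ``resolution``) and the experimental
    map; the restraint weight scales it in the total as usual.  Unlike the
    pairwise terms, the score is *not* invariant under global rigid motion
    of the model — the map fixes the absolute frame.
    """

    def __init__(
        self,
        experimental: DensityGrid,
        resolution: Optional[float] = None,
        ids: Optional[Sequence[str]] = None,
        name: str = "em_fit",
        weight: float = 1.0,
        threshold: float = np.inf,
    ):
        super().__init__(name, weight, threshold)
        self.experimental = experimental
        if resolution is None:
            resolution = experimental.resolution
        if resolution is None or not resolution > 0:
            raise ValueError("a positive map resolution is required")
        self.resolution = float(resolution)
        self.ids = list(ids) if ids is not None else None
        # finite-difference step for the grid-based gradient
        self._fd_step = 0.1 * experimental.spacing
        # per-particle rasterisation cache: between successive evaluations
        # only the particles a move touched need re-rasterising
        self._blocks: Dict[str, tuple] = {}
        exp = experimental.values.ravel()
        self._exp_centered = exp - exp.mean()
        self._exp_norm = float(np.linalg.norm(self._exp_centered))
        if self._exp_norm == 0.0:
            raise ValueError("experimental map is constant; EM fit undefined")

    def particle_ids(self, model: Model) -> List[str]:
        ids = self.ids if self.ids is not None else model.ids
        return self._check_ids(model, ids)

    def _simulated_values(self, model: Model) -> np.ndarray:
        spec = self.experimental.spec
        sigma = sigma_from_resolution(self.resolution)
        values = np.zeros(spec.dims, dtype=float)
        for pid in self.particle_ids(model):
            p = model.particles[pid]
            key = p.xyz.tobytes()
            cached = self._blocks.get(pid)
            if cached is None or cached[0] != key:
                cached = (key, gaussian_block(spec, p.xyz, p.mass, sigma))
                self._blocks[pid] = cached
            ent = cached[1]
            if ent is not None:
                slices, block = ent
                values[slices] += block
        return values

    def evaluate(self, model: Model) -> float:
        sim = self._simulated_values(model).ravel()
        centered = sim - sim.mean()
        norm = float(np.linalg.norm(centered))
        if norm == 0.0:
            return 1.0  # model entirely off the map: correlation treated as 0
        ccc = float(np.dot(centered, self._exp_centered) / (norm * self._exp_norm))
        return 1.0 - min(1.0, max(-1.0, ccc))

    def gradient(self, model: Model) -> Dict[str, np.ndarray]:
        """Exact gradient of 1 − CCC through the Gaussian forward model.

        d(sim)/dx for one particle is its own Gaussian block times
        (voxel − centre)/σ²; the mean-removal term vanishes because the
        correlation weights sum to zero.  Truncation-boundary motion is
        neglected (the Gaussian is ~3·10⁻⁴ of peak at 4σ).
        """
        spec = self.experimental.spec
        sigma = sigma_from_resolution(self.resolution)
        sim = self._simulated_values(model).ravel()
        centered = sim - sim.mean()
        norm = float(np.linalg.norm(centered))
        ids = self.particle_ids(model)
        if norm == 0.0:
            return {pid: np.zeros(3) for pid in ids}
        ccc = float(np.dot(centered, self._exp_centered) / (norm * self._exp_norm))
        # d(1-ccc)/d(sim_i), reshaped onto the grid
        w = -(
            self._exp_centered / (norm * self._exp_norm)
            - ccc * centered / norm**2
        ).reshape(spec.dims)
        origin = np.asarray(spec.origin)
        h = spec.spacing
        grad: Dict[str, np.ndarray] = {}
        for pid in ids:
            p = model.particles[pid]
            ent = gaussian_block(spec, p.xyz, p.mass, sigma)
            g = np.zeros(3)
            if ent is not None:
                slices, block = ent
                wb = w[slices] * block
                for k in range(3):
                    ax = origin[k] + h * np.arange(slices[k].start, slices[k].stop) - p.xyz[k]
                    shape = [1, 1, 1]
                    shape[k] = ax.size
                    g[k] = float((wb * (ax.reshape(shape) / sigma**2)).sum())
            grad[pid] = g
        return grad
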