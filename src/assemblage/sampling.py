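"""Searching for good-scoring models.

Three complementary samplers:

* :func:`conjugate_gradients` — continuous local minimisation of a
  differentiable scoring function (free particles);
* :func:`monte_carlo` — Metropolis Monte Carlo over symmetric particle- and
  rigid-body moves with a geometric annealing schedule;
* :func:`domino_sample` — a divide-and-conquer enumerator over discrete
  per-component states that returns *exactly* the set of good-scoring
  combinations, pruning partial assignments that already violate a
  fully-contained restraint (admissible because every term is nonnegative
  and thresholds are per-term).  :func:`brute_force_enumerate` is the
  exhaustive oracle it is tested against.

All stochastic samplers take an explicit integer seed and are bit
reproducible given it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy.optimize import minimize

from .core import Configuration, Model
from .restraints import Restraint, ScoringFunction
from scipy.spatial.transform import Rotation

__all__ = [
    "MCMove",
    "BallMove",
    "RigidBodyMove",
    "SwapMove",
    "Schedule",
    "ScoredConfiguration",
    "SamplingResult",
    "metropolis_accept",
    "monte_carlo",
    "conjugate_gradients",
    "refine_rigid_bodies",
    "DiscreteStateSpace",
    "domino_sample",
    "brute_force_enumerate",
]


# ---------------------------------------------------------------------------
# moves and schedules


class MCMove:
    """A symmetric Monte Carlo proposal (P(x→x') = P(x'→x))."""

    def propose(self, model: Model, rng: np.random.Generator) -> None:
        raise NotImplementedError


@dataclass
class BallMove(MCMove):
    """Displace one free particle uniformly within a sphere.

    ``targets`` limits the move to the given particle ids; by default all
    particles outside rigid bodies are eligible.
    """

    max_translation: float
    targets: Optional[Sequence[str]] = None

    def _eligible(self, model: Model) -> List[str]:
        ids = self.targets if self.targets is not None else model.ids
        ids = [i for i in ids if model.particles[i].rigid_body is None]
        if not ids:
            raise ValueError("ball move has no eligible (non-rigid) particles")
        return ids

    def propose(self, model: Model, rng: np.random.Generator) -> None:
        ids = self._eligible(model)
        pid = ids[rng.integers(len(ids))]
        model.particles[pid].xyz = model.particles[pid].xyz + _uniform_in_ball(
            self.max_translation, rng
        )


@dataclass
class RigidBodyMove(MCMove):
    """Rotate one rigid body about its centroid and translate it.

    Rotation: uniformly random axis, angle uniform in [0, max_rotation]
    degrees; translation: uniform within a sphere of radius
    ``max_translation`` Å.  Both are symmetric proposals.
    """

    max_translation: float
    max_rotation: float  # degrees
    targets: Optional[Sequence[str]] = None

    def propose(self, model: Model, rng: np.random.Generator) -> None:
        bodies = list(self.targets) if self.targets is not None else list(model.rigid_bodies)
        if not bodies:
            raise ValueError("rigid-body move but the model has no rigid bodies")
        bid = bodies[rng.integers(len(bodies))]
        axis = _uniform_direction(rng)
        angle = np.deg2rad(self.max_rotation) * rng.random()
        rot = Rotation.from_rotvec(axis * angle)
        t = _uniform_in_ball(self.max_translation, rng)
        model.transform_rigid_body(bid, rot, t)


@dataclass
class SwapMove(MCMove):
    """Exchange the centroid positions of two rigid bodies.

    Orientations are kept; the two bodies are translated so their
    centroids trade places.  The move is its own inverse and hence
    symmetric.  It lets the sampler tunnel between assignments of
    subunits to density lobes that small rigid motions cannot reach.
    """

    targets: Optional[Sequence[str]] = None

    def propose(self, model: Model, rng: np.random.Generator) -> None:
        bodies = list(self.targets) if self.targets is not None else list(model.rigid_bodies)
        if len(bodies) < 2:
            raise ValueError("swap move requires at least two rigid bodies")
        i, j = rng.choice(len(bodies), size=2, replace=False)
        a, b = bodies[int(i)], bodies[int(j)]
        ca = model.coords(model.rigid_bodies[a].member_ids).mean(axis=0)
        cb = model.coords(model.rigid_bodies[b].member_ids).mean(axis=0)
        identity = np.array([1.0, 0.0, 0.0, 0.0])
        model.transform_rigid_body(a, identity, cb - ca)
        model.transform_rigid_body(b, identity, ca - cb)


def _uniform_direction(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _uniform_in_ball(radius: float, rng: np.random.Generator) -> np.ndarray:
    return _uniform_direction(rng) * radius * rng.random() ** (1.0 / 3.0)


@dataclass(frozen=True)
class Schedule:
    """Geometric annealing schedule T_i = T_start·(T_end/T_start)^(i/(n−1))."""

    t_start: float
    t_end: float
    n_steps: int

    def __post_init__(self) -> None:
        if not (self.t_start >= self.t_end > 0):
            raise ValueError(
                f"need T_start >= T_end > 0, got {self.t_start}, {self.t_end}"
            )
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    def temperature(self, step: int) -> float:
        if self.n_steps == 1:
            return self.t_start
        frac = step / (self.n_steps - 1)
        return float(self.t_start * (self.t_end / self.t_start) ** frac)


# ---------------------------------------------------------------------------
# results


@dataclass(frozen=True)
class ScoredConfiguration:
    configuration: Configuration
    total: float
    per_term: Mapping[str, float]


@dataclass
class SamplingResult:
    """An ordered ensemble of scored configurations plus run statistics."""

    ensemble: List[ScoredConfiguration] = field(default_factory=list)
    n_proposed: int = 0
    n_accepted: int = 0
    seed: Optional[int] = None

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_proposed if self.n_proposed else 0.0

    @property
    def best(self) -> ScoredConfiguration:
        if not self.ensemble:
            raise ValueError("empty sampling result")
        return min(self.ensemble, key=lambda sc: sc.total)


# ---------------------------------------------------------------------------
# Metropolis Monte Carlo


def metropolis_accept(delta: float, temperature: float, rng: np.random.Generator) -> bool:
    """Metropolis rule: accept if Δ ≤ 0, else with probability exp(−Δ/T)."""
    if delta <= 0:
        return True
    if temperature <= 0:
        return False
    return bool(rng.random() < np.exp(-delta / temperature))


def monte_carlo(
    model: Model,
    scoring: ScoringFunction,
    moves: Sequence[MCMove],
    schedule: Schedule,
    seed: int,
    sample_interval: Optional[int] = None,
) -> SamplingResult:
    """Annealed Metropolis Monte Carlo; leaves ``model`` at the best state.

    One proposal per step: a move drawn uniformly from ``moves`` is applied,
    and accepted by the Metropolis rule at the schedule's temperature.  The
    best configuration seen is always recorded (first ensemble entry) and
    restored into the model on return; with ``sample_interval`` the current
    state is additionally recorded every that many steps.
    """
    if not moves:
        raise ValueError("at least one move is required")
    rng = np.random.default_rng(seed)
    result = SamplingResult(seed=seed)
    current = scoring.evaluate(model)
    best = current
    best_snapshot = model.snapshot()
    for step in range(schedule.n_steps):
        t = schedule.temperature(step)
        snapshot = model.snapshot()
        move = moves[rng.integers(len(moves))]
        move.propose(model, rng)
        proposed = scoring.evaluate(model)
        result.n_proposed += 1
        if metropolis_accept(proposed - current, t, rng):
            result.n_accepted += 1
            current = proposed
            if current < best:
                best = current
                best_snapshot = model.snapshot()
        else:
            model.restore(snapshot)
        if sample_interval and (step + 1) % sample_interval == 0:
            result.ensemble.append(
                ScoredConfiguration(model.snapshot(), current, scoring.evaluate_terms(model))
            )
    model.restore(best_snapshot)
    result.ensemble.insert(
        0, ScoredConfiguration(best_snapshot, best, scoring.evaluate_terms(model))
    )
    return result


# ---------------------------------------------------------------------------
# conjugate gradients


def conjugate_gradients(
    model: Model,
    scoring: ScoringFunction,
    max_steps: int = 500,
    gtol: float = 1e-6,
) -> SamplingResult:
    """Conjugate-gradient minimisation over free particle coordinates.

    Terminates when the gradient max-norm drops below ``gtol`` or after
    ``max_steps`` iterations; the final score never exceeds the initial one.
    Models containing rigid bodies are rejected — rigid-body search is the
    Monte Carlo sampler's job.
    """
    if model.rigid_bodies:
        raise ValueError(
            "conjugate_gradients operates on free particles only; "
            "use monte_carlo for models with rigid bodies"
        )
    ids = model.ids
    x0 = model.coords(ids).ravel()
    initial = scoring.evaluate(model)

    def fun(x: np.ndarray):
        model.set_coords(x.reshape(-1, 3), ids)
        total, grad = scoring.evaluate(model, want_gradient=True)
        if not np.isfinite(total) or not np.all(np.isfinite(grad)):
            raise FloatingPointError(
                f"non-finite score or gradient at x={x[:6]}... (score={total})"
            )
        return total, grad.ravel()

    res = minimize(
        fun,
        x0,
        jac=True,
        method="CG",
        options={"maxiter": max_steps, "gtol": gtol, "norm": np.inf},
    )
    final = float(res.fun)
    if final > initial:  # line search cannot increase, but be safe
        model.set_coords(x0.reshape(-1, 3), ids)
        final = initial
    else:
        model.set_coords(res.x.reshape(-1, 3), ids)
    snap = model.snapshot()
    return SamplingResult(
        ensemble=[ScoredConfiguration(snap, final, scoring.evaluate_terms(model))]
    )


def refine_rigid_bodies(
    model: Model,
    scoring: ScoringFunction,
    max_iters: int = 150,
    step: float = 1.0,
    min_step: float = 1e-3,
) -> float:
    """Local refinement of rigid-body poses by force/torque descent.

    Each iteration sums the per-particle score gradients into a net force
    and torque per body (and a plain gradient step for free particles),
    applies a step scaled so the largest particle displacement is about
    ``step`` Å, and keeps it only if the total score decreased; the step
    size adapts (grow on success, halve on failure).  A cheap, derivative-
    based polish for the basin Monte Carlo ends in — not a global search.
    Returns the final total score.
    """
    index = {pid: i for i, pid in enumerate(model.ids)}
    current = scoring.evaluate(model)
    alpha = step
    for _ in range(max_iters):
        _, grad = scoring.evaluate(model, want_gradient=True)
        moves: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        free_steps: Dict[str, np.ndarray] = {}
        scale_basis = 0.0
        for bid, body in model.rigid_bodies.items():
            idx = [index[p] for p in body.member_ids]
            coords = model.coords(body.member_ids)
            centroid = coords.mean(axis=0)
            g = grad[idx]
            force = -g.sum(axis=0)
            torque = -np.sum(np.cross(coords - centroid, g), axis=0)
            moves[bid] = (force, torque)
            radius = float(np.linalg.norm(coords - centroid, axis=1).max())
            scale_basis = max(
                scale_basis, float(np.linalg.norm(force)) + float(np.linalg.norm(torque)) * radius
            )
        for pid, p in model.particles.items():
            if p.rigid_body is None:
                free_steps[pid] = -grad[index[pid]]
                scale_basis = max(scale_basis, float(np.linalg.norm(free_steps[pid])))
        if scale_basis == 0.0:
            break
        snapshot = model.snapshot()
        s = alpha / scale_basis
        for bid, (force, torque) in moves.items():
            model.transform_rigid_body(
                bid, Rotation.from_rotvec(s * torque), s * force
            )
        for pid, d in free_steps.items():
            model.particles[pid].xyz = model.particles[pid].xyz + s * d
        proposed = scoring.evaluate(model)
        if proposed < current - 1e-12:
            current = proposed
            alpha = min(alpha * 1.3, 3.0)
        else:
            model.restore(snapshot)
            alpha *= 0.5
            if alpha < min_step:
                break
    return current


# ---------------------------------------------------------------------------
# discrete divide-and-conquer enumeration


class DiscreteStateSpace:
    """Per-component candidate states over a shared model.

    ``states[c]`` is an ordered list of coordinate fragments (particle id →
    xyz) for component ``c``; applying an assignment writes one fragment per
    component into the model.  The restraint graph connects components that
    share a scoring term.
    """

    def __init__(
        self,
        model: Model,
        states: Mapping[str, Sequence[Mapping[str, np.ndarray]]],
    ):
        self.model = model
        self.components: List[str] = list(states)
        self.states: Dict[str, List[Dict[str, np.ndarray]]] = {
            c: [dict(s) for s in slist] for c, slist in states.items()
        }
        for c, slist in self.states.items():
            if not slist:
                raise ValueError(f"component {c!r} has no states")
            for s in slist:
                for pid in s:
                    if pid not in model.particles:
                        raise KeyError(f"state of {c!r} references unknown particle {pid!r}")
        self._owner: Dict[str, str] = {}
        for c, slist in self.states.items():
            for pid in slist[0]:
                if pid in self._owner:
                    raise ValueError(
                        f"particle {pid!r} is claimed by components "
                        f"{self._owner[pid]!r} and {c!r}"
                    )
                self._owner[pid] = c

    def n_states(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.states.items()}

    def cover(self, term: Restraint) -> FrozenSet[str]:
        """Components a term's score depends on."""
        return frozenset(
            self._owner[pid] for pid in term.particle_ids(self.model) if pid in self._owner
        )

    def apply_partial(self, assignment: Mapping[str, int]) -> None:
        for c, idx in assignment.items():
            for pid, xyz in self.states[c][idx].items():
                self.model.particles[pid].xyz = np.asarray(xyz, dtype=float)

    def apply(self, assignment: Sequence[int]) -> None:
        self.apply_partial(dict(zip(self.components, assignment)))

    def restraint_graph(self, scoring: ScoringFunction) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.components)
        for term in scoring.terms:
            cover = sorted(self.cover(term))
            for a, b in itertools.combinations(cover, 2):
                if g.has_edge(a, b):
                    g[a][b]["weight"] += 1
                else:
                    g.add_edge(a, b, weight=1)
        return g


def _thresholds_for(
    scoring: ScoringFunction, overrides: Optional[Mapping[str, float]]
) -> List[float]:
    thr = []
    for term in scoring.terms:
        t = term.threshold
        if overrides and term.name in overrides:
            t = overrides[term.name]
        thr.append(float(t))
    return thr


def brute_force_enumerate(
    state_space: DiscreteStateSpace,
    scoring: ScoringFunction,
    thresholds: Optional[Mapping[str, float]] = None,
    max_product: int = 10**6,
) -> List[Tuple[int, ...]]:
    """Exhaustively list good-scoring assignments, lexicographically sorted.

    The oracle for :func:`domino_sample`: every combination of one state per
    component is applied and scored; an assignment is kept iff every term's
    raw score is at or below its threshold.
    """
    sizes = [len(state_space.states[c]) for c in state_space.components]
    product = int(np.prod(sizes)) if sizes else 1
    if product > max_product:
        raise ValueError(f"state-space product {product} exceeds guard {max_product}")
    thr = _thresholds_for(scoring, thresholds)
    good: List[Tuple[int, ...]] = []
    for assignment in itertools.product(*(range(n) for n in sizes)):
        state_space.apply(assignment)
        if all(
            term.evaluate(state_space.model) <= t
            for term, t in zip(scoring.terms, thr)
        ):
            good.append(assignment)
    return good  # itertools.product already yields lexicographic order


def domino_sample(
    state_space: DiscreteStateSpace,
    scoring: ScoringFunction,
    thresholds: Optional[Mapping[str, float]] = None,
    max_partial_states: int = 10**5,
) -> List[Tuple[int, ...]]:
    """Divide-and-conquer enumeration of good-scoring assignments.

    Components are merged along a maximum-weight spanning forest of the
    restraint graph (edge weight = number of shared terms); at each merge,
    any partial assignment violating a term fully contained in the merged
    subset is pruned.  Because every term score is nonnegative and the
    good-scoring test is per-term, pruning never discards a completion that
    could become good — the result equals the brute-force enumeration
    exactly.  An empty result is a valid outcome and signals inconsistent
    data.  If a merged subset would exceed ``max_partial_states`` surviving
    partial assignments the run aborts rather than silently truncating.
    """
    comps = state_space.components
    thr = _thresholds_for(scoring, thresholds)
    terms = list(zip(scoring.terms, thr))
    covers = [state_space.cover(term) for term, _ in terms]

    # constant terms (no component dependence) gate everything
    for (term, t), cover in zip(terms, covers):
        if not cover and term.evaluate(state_space.model) > t:
            return []

    def surviving(
        members: FrozenSet[str],
        assignments: List[Dict[str, int]],
        already: FrozenSet[int],
    ) -> Tuple[List[Dict[str, int]], FrozenSet[int]]:
        check = [
            i
            for i, cover in enumerate(covers)
            if cover and cover <= members and i not in already
        ]
        if not check:
            return assignments, already
        kept = []
        for assignment in assignments:
            state_space.apply_partial(assignment)
            if all(
                terms[i][0].evaluate(state_space.model) <= terms[i][1] for i in check
            ):
                kept.append(assignment)
        return kept, already | frozenset(check)

    # leaves: one subset per component, unary terms applied
    subsets: Dict[FrozenSet[str], Tuple[List[Dict[str, int]], FrozenSet[int]]] = {}
    for c in comps:
        members = frozenset([c])
        assignments = [{c: i} for i in range(len(state_space.states[c]))]
        subsets[members] = surviving(members, assignments, frozenset())
        if not subsets[members][0]:
            return []  # a component with zero surviving states short-circuits

    # merge along a maximum-weight spanning forest, heaviest edges first
    graph = state_space.restraint_graph(scoring)
    forest = nx.maximum_spanning_tree(graph, weight="weight")
    edges = sorted(
        forest.edges(data="weight"), key=lambda e: (-e[2], e[0], e[1])
    )
    key_of = {c: frozenset([c]) for c in comps}

    def merge(ka: FrozenSet[str], kb: FrozenSet[str]) -> None:
        a_assign, a_done = subsets.pop(ka)
        b_assign, b_done = subsets.pop(kb)
        members = ka | kb
        if len(a_assign) * len(b_assign) > max_partial_states:
            raise RuntimeError(
                f"partial-state cap exceeded merging {sorted(members)}: "
                f"{len(a_assign)}×{len(b_assign)} > {max_partial_states}"
            )
        combined = [{**x, **y} for x in a_assign for y in b_assign]
        subsets[members] = surviving(members, combined, a_done | b_done)
        for c in members:
            key_of[c] = members

    for u, v, _ in edges:
        if key_of[u] != key_of[v]:
            merge(key_of[u], key_of[v])
    # disconnected remainder: no shared terms, plain products
    while len(subsets) > 1:
        keys = sorted(subsets, key=lambda k: sorted(k)[0])
        merge(keys[0], keys[1])

    (final_assignments, _), = subsets.values()
    return sorted(
        tuple(a[c] for c in comps) for a in final_assignments
    )
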