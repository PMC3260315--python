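"""End-to-end modeling runs driven by a configuration file.

Implements the four-stage cycle: gather (load maps/cross-links), represent
and score (build the bead model and scoring function), sample (independent
annealed Monte Carlo runs or conjugate gradients), analyze (good-scoring
filter, clustering, localization densities, satisfaction report).  Every
run directory receives the resolved config echo, a log with version, seed
and per-stage wall-clock, representative structures as PDB and reports as
JSON — the artefacts someone else needs to rerun and extend the model.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
from scipy.spatial.transform import Rotation
from sklearn.cluster import KMeans

from . import __version__
from .analysis import ClusterSet, SatisfactionReport, cluster_ensemble, satisfaction_report
from .core import Model, coarse_grain_chain
from .io.config import RunConfig, load_config, write_config_echo
from .io.crosslinks import crosslink_restraints, read_crosslinks
from .io.mrc import read_mrc, write_mrc
from .io.pdb import read_pdb, write_pdb
from .restraints import (
    ConnectivityRestraint,
    EMFitRestraint,
    ExcludedVolumeRestraint,
    HarmonicDistanceRestraint,
    Restraint,
    ScoringFunction,
)
from .sampling import (
    BallMove,
    MCMove,
    RigidBodyMove,
    SwapMove,
    SamplingResult,
    Schedule,
    ScoredConfiguration,
    conjugate_gradients,
    monte_carlo,
    refine_rigid_bodies,
)
from .analysis import localization_density
from .synthetic import centered_grid_spec

__all__ = ["RunResult", "build_model", "build_scoring", "run"]

logger = logging.getLogger(__name__)


@dataclass
class RunResult:
    """Everything a finished run produced, in memory."""

    config: RunConfig
    model: Model
    scoring: ScoringFunction
    ensemble: List[ScoredConfiguration]
    good: List[ScoredConfiguration]
    clusters: Optional[ClusterSet]
    report: SatisfactionReport
    summary: Dict[str, object] = field(default_factory=dict)


def build_model(config: RunConfig, base_dir: Path) -> Model:
    """Stage 2a: the particle representation from the config."""
    model = Model()
    pdb_cache: Dict[str, Model] = {}
    offset = 0.0
    for spec in config.representation:
        if spec.pdb is not None:
            path = str(base_dir / spec.pdb)
            if path not in pdb_cache:
                pdb_cache[path], _ = read_pdb(path)
            source = pdb_cache[path]
            chain = spec.chain or spec.label
            try:
                ids = source.subunit_ids(chain)
            except KeyError:
                raise ValueError(
                    f"subunit {spec.label!r}: chain {chain!r} not found in {spec.pdb}"
                ) from None
            for pid in ids:
                p = source.particles[pid]
                model.create_particle(
                    f"{spec.label}.{pid.split('.')[-1]}",
                    p.xyz.copy(),
                    p.radius,
                    p.mass,
                    subunit=spec.label,
                    residue_range=p.residue_range,
                )
        else:
            beads = coarse_grain_chain(
                spec.label,
                spec.n_residues,
                spec.n_beads,
                residue_mass=spec.residue_mass,
                origin=(offset, 0.0, 0.0),
            )
            for b in beads:
                model.add_particle(b)
            offset += 2.0 * max(b.radius for b in beads) * spec.n_beads + 10.0
        model.create_rigid_body(spec.label, model.hierarchy[spec.label])
    return model


def build_scoring(config: RunConfig, model: Model, base_dir: Path) -> ScoringFunction:
    """Stage 2b: the scoring function from the config's restraint block."""
    scoring = ScoringFunction()
    counter: Dict[str, int] = {}

    def unique(name: str) -> str:
        counter[name] = counter.get(name, 0) + 1
        return name if counter[name] == 1 else f"{name}_{counter[name]}"

    for spec in config.restraints:
        term: Restraint
        if spec.type == "distance":
            term = HarmonicDistanceRestraint(
                spec.p1, spec.p2, spec.d0, spec.k, spec.kind,
                name=unique(f"dist:{spec.p1}-{spec.p2}"),
                weight=spec.weight, threshold=spec.threshold,
            )
            scoring.add(term)
        elif spec.type == "excluded_volume":
            scoring.add(
                ExcludedVolumeRestraint(
                    spec.k, name=unique("excluded_volume"),
                    weight=spec.weight, threshold=spec.threshold,
                )
            )
        elif spec.type == "connectivity":
            ids = [pid for s in spec.subunits for pid in model.subunit_ids(s)]
            scoring.add(
                ConnectivityRestraint(
                    ids, spec.k, spec.slack, name=unique("connectivity"),
                    weight=spec.weight, threshold=spec.threshold,
                )
            )
        elif spec.type == "em_fit":
            grid = read_mrc(base_dir / spec.map)
            scoring.add(
                EMFitRestraint(
                    grid, spec.resolution, name=unique("em_fit"),
                    weight=spec.weight, threshold=spec.threshold,
                )
            )
        elif spec.type == "crosslinks":
            records = read_crosslinks(base_dir / spec.path)
            for term in crosslink_restraints(
                records, model, k=spec.k, threshold=spec.threshold, path=spec.path
            ):
                scoring.add(term)
        else:  # pragma: no cover - schema forbids
            raise ValueError(f"unknown restraint type {spec.type!r}")
    return scoring


def _moves(config: RunConfig) -> List[MCMove]:
    moves: List[MCMove] = []
    for m in config.sampling.moves:
        if m.kind == "ball":
            moves.append(BallMove(m.max_translation))
        elif m.kind == "swap":
            moves.append(SwapMove())
        else:
            moves.append(RigidBodyMove(m.max_translation, m.max_rotation))
    return moves


def _scatter_start(
    model: Model, scoring: ScoringFunction, radius: float, rng: np.random.Generator
) -> None:
    """Randomize the start: each body rotated uniformly and its centroid
    placed uniformly in a sphere (centred on the EM map if one is used)."""
    center = None
    for term in scoring.terms:
        if isinstance(term, EMFitRestraint):
            g = term.experimental
            center = np.asarray(g.origin) + 0.5 * g.spacing * (np.asarray(g.dims) - 1)
            break
    if center is None:
        center = model.coords().mean(axis=0)
    for bid, body in model.rigid_bodies.items():
        coords = model.coords(body.member_ids)
        centroid = coords.mean(axis=0)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        target = center + direction * radius * rng.random() ** (1.0 / 3.0)
        model.transform_rigid_body(bid, Rotation.random(rng=rng), target - centroid)
    free = [pid for pid, p in model.particles.items() if p.rigid_body is None]
    for pid in free:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        model.particles[pid].xyz = center + direction * radius * rng.random() ** (1.0 / 3.0)


def _flip_axis(coords: np.ndarray) -> Optional[np.ndarray]:
    """An axis perpendicular to a body's long axis, or None if degenerate."""
    u = coords[-1] - coords[0]
    norm = np.linalg.norm(u)
    if norm == 0:
        return None
    u /= norm
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    axis = np.cross(u, ref)
    return axis / np.linalg.norm(axis)


def _discrete_rectify(
    model: Model,
    scoring: ScoringFunction,
    seed: int,
    max_bodies: int = 6,
    top_k: int = 5,
) -> float:
    """Fix discrete placement errors an annealed run ended in.

    The slow degrees of freedom at the end of an anneal are discrete: which
    subunit occupies which density lobe, and whether a rod-like subunit
    lies end-for-end reversed in its lobe.  This pass enumerates all body
    permutations (bodies translated onto each other's centroids) crossed
    with end-over-end flips of multi-particle bodies, scores every variant
    (cheap, thanks to the per-particle density cache), and — if a variant
    beats the current state — re-seats it with a short low-temperature
    quench plus gradient polish.  The ``top_k`` best-ranked variants are
    re-seated and the best polished result kept (only if it beats the
    incoming state).  Skipped for more than ``max_bodies`` bodies, where
    the factorial enumeration would not be worth it.
    """
    import itertools

    bodies = list(model.rigid_bodies)
    if not 2 <= len(bodies) <= max_bodies:
        return scoring.evaluate(model)
    base = model.snapshot()
    centroids = {b: model.coords(model.rigid_bodies[b].member_ids).mean(axis=0) for b in bodies}
    axes = {
        b: _flip_axis(model.coords(model.rigid_bodies[b].member_ids))
        for b in bodies
        if len(model.rigid_bodies[b].member_ids) >= 2
    }
    flippable = [b for b, ax in axes.items() if ax is not None]
    identity = np.array([1.0, 0.0, 0.0, 0.0])
    current = scoring.evaluate(model)
    # raw scores of every discrete variant; the interesting ones are far
    # from polished (bodies roughly dropped onto each other's centroids),
    # so they are ranked against each other, not against the current state
    variants = []
    for perm in itertools.permutations(range(len(bodies))):
        for flips in itertools.product((False, True), repeat=len(flippable)):
            if all(i == j for i, j in enumerate(perm)) and not any(flips):
                continue
            model.restore(base)
            for b, target in zip(bodies, perm):
                model.transform_rigid_body(
                    b, identity, centroids[bodies[target]] - centroids[b]
                )
            for b, do_flip in zip(flippable, flips):
                if do_flip:
                    model.transform_rigid_body(
                        b, Rotation.from_rotvec(np.pi * axes[b]), (0, 0, 0)
                    )
            variants.append((scoring.evaluate(model), model.snapshot()))
    variants.sort(key=lambda v: v[0])
    best_total = current
    best_snapshot = base
    for rank, (_, snapshot) in enumerate(variants[:top_k]):
        model.restore(snapshot)
        monte_carlo(
            model,
            scoring,
            [RigidBodyMove(1.5, 11.0)],
            Schedule(0.5, 0.01, 800),
            seed=seed + rank,
        )
        refine_rigid_bodies(model, scoring, max_iters=150)
        total = scoring.evaluate(model)
        if total < best_total - 1e-9:
            best_total = total
            best_snapshot = model.snapshot()
    model.restore(best_snapshot)
    return best_total


def _anchor_start(
    model: Model, scoring: ScoringFunction, rng: np.random.Generator
) -> None:
    """Seed a run from the density's lobes (anchor points).

    Anchor points are the centres of a mass-weighted k-means over the
    brightest map voxels (as many anchors as rigid bodies); bodies are
    dealt onto them in a per-run random permutation with uniformly random
    orientations.  Each run thus starts with a plausible association of
    subunits to density lobes and explores a different discrete
    hypothesis.  Without an EM term this falls back to the random
    scatter."""
    em = next((t for t in scoring.terms if isinstance(t, EMFitRestraint)), None)
    n_bodies = len(model.rigid_bodies)
    if em is None or n_bodies < 1:
        _scatter_start(model, scoring, 40.0, rng)
        return
    g = em.experimental
    values = g.values
    positive = values[values > 0]
    if positive.size == 0:
        _scatter_start(model, scoring, 40.0, rng)
        return
    threshold = np.percentile(positive, 70)
    idx = np.argwhere(values > threshold)
    coords = np.asarray(g.origin) + g.spacing * idx
    weights = values[values > threshold]
    km = KMeans(
        n_clusters=n_bodies, n_init=4, random_state=int(rng.integers(2**31))
    ).fit(coords, sample_weight=weights)
    anchors = km.cluster_centers_
    order = rng.permutation(n_bodies)
    for bid, anchor_index in zip(model.rigid_bodies, order):
        body = model.rigid_bodies[bid]
        centroid = model.coords(body.member_ids).mean(axis=0)
        model.transform_rigid_body(
            bid, Rotation.random(rng=rng), anchors[anchor_index] - centroid
        )


def _run_seed(seed: int, run: int) -> int:
    return int(np.random.SeedSequence([seed, run]).generate_state(1)[0] % 2**31)


def sample(config: RunConfig, model: Model, scoring: ScoringFunction) -> SamplingResult:
    """Stage 3: independent seeded runs; best configuration of each run."""
    s = config.sampling
    merged = SamplingResult(seed=config.seed)
    if s.method == "conjugate_gradients":
        result = conjugate_gradients(model, scoring, s.max_steps, s.gtol)
        merged.ensemble.extend(result.ensemble)
        return merged
    moves = _moves(config)
    schedule = Schedule(s.t_start, s.t_end, s.n_steps)
    # refinement quench: smaller moves at near-zero temperature, polishing
    # the basin the anneal ended in
    quench_moves: List[MCMove] = []
    for m in moves:
        if isinstance(m, BallMove):
            quench_moves.append(BallMove(0.25 * m.max_translation, m.targets))
        elif isinstance(m, RigidBodyMove):
            quench_moves.append(
                RigidBodyMove(0.25 * m.max_translation, 0.25 * m.max_rotation, m.targets)
            )
    quench = Schedule(s.t_end, s.t_end / 50.0, max(1, s.n_steps // 2))
    start = model.snapshot()
    for run_index in range(s.n_runs):
        run_seed = _run_seed(config.seed, run_index)
        model.restore(start)
        if s.start == "anchor":
            _anchor_start(model, scoring, np.random.default_rng(run_seed))
        elif s.start == "random":
            _scatter_start(model, scoring, s.start_radius, np.random.default_rng(run_seed))
        result = monte_carlo(model, scoring, moves, schedule, seed=run_seed)
        polish = monte_carlo(model, scoring, quench_moves, quench, seed=run_seed + 1)
        if model.rigid_bodies:
            refine_rigid_bodies(model, scoring)
            if s.rectify:
                _discrete_rectify(model, scoring, seed=run_seed + 2)
        refined = ScoredConfiguration(
            model.snapshot(), scoring.evaluate(model), scoring.evaluate_terms(model)
        )
        merged.ensemble.append(
            refined if refined.total <= polish.best.total else polish.best
        )
        merged.n_proposed += result.n_proposed + polish.n_proposed
        merged.n_accepted += result.n_accepted + polish.n_accepted
    model.restore(start)
    return merged


def analyze(
    config: RunConfig,
    model: Model,
    scoring: ScoringFunction,
    ensemble: List[ScoredConfiguration],
    out_dir: Optional[Path] = None,
) -> RunResult:
    """Stage 4: satisfaction, clustering, localization, reporting."""
    a = config.analysis
    report = satisfaction_report(ensemble, model, scoring)
    good = [
        sc for sc, ok in zip(ensemble, report.models_all_satisfied) if ok
    ]
    pool = good if a.good_scoring_only else list(ensemble)
    clusters = None
    if pool:
        cutoff = a.rmsd_cutoff
        if cutoff is None and a.cluster_method == "binning":
            cutoff = float(model.radii().min())
        clusters = cluster_ensemble(
            pool,
            model.ids,
            method=a.cluster_method,
            k=a.k,
            rmsd_cutoff=cutoff,
            seed=config.seed or 0,
        )
    summary: Dict[str, object] = {
        "n_models": len(ensemble),
        "n_good_scoring": len(good),
        "n_clusters": clusters.n_clusters if clusters else 0,
        "cluster_sizes": dict(sorted(clusters.sizes.items())) if clusters else {},
        "best_score": min((sc.total for sc in ensemble), default=None),
        "inconsistent": report.inconsistent,
    }
    result = RunResult(config, model, scoring, ensemble, good, clusters, report, summary)
    if out_dir is not None:
        _write_outputs(result, pool, out_dir)
    return result


def _write_outputs(result: RunResult, pool, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    model, config = result.model, result.config
    if result.clusters and pool:
        reps = [pool[i].configuration for _, i in sorted(result.clusters.representatives.items())]
        write_pdb(model, out_dir / "cluster_representatives.pdb", configurations=reps)
    if pool:
        write_pdb(
            model,
            out_dir / "ensemble.pdb",
            configurations=[sc.configuration for sc in pool],
        )
    for label in config.analysis.localization_subunits:
        spec = centered_grid_spec(model, config.analysis.localization_resolution)
        grid = localization_density(
            pool or result.ensemble, model, label, spec,
            config.analysis.localization_resolution,
        )
        write_mrc(grid, out_dir / f"localization_{label}.mrc")
    (out_dir / "report.json").write_text(
        json.dumps({"summary": result.summary, "satisfaction": result.report.to_dict()},
                   indent=2, default=str) + "\n"
    )
    (out_dir / "report.txt").write_text(result.report.summary() + "\n")


def run(config_or_path, base_dir: Optional[Path] = None) -> RunResult:
    """Execute the full cycle for a config file or RunConfig.

    Relative paths inside the config (maps, cross-links, output_dir) are
    resolved against the config file's directory (or ``base_dir``).
    """
    if isinstance(config_or_path, RunConfig):
        config = config_or_path
        base = Path(base_dir) if base_dir else Path.cwd()
    else:
        config = load_config(config_or_path)
        base = Path(config_or_path).parent if base_dir is None else Path(base_dir)
    out_dir = base / config.output_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    write_config_echo(config, out_dir)
    timings: Dict[str, float] = {}

    t0 = time.perf_counter()
    model = build_model(config, base)
    scoring = build_scoring(config, model, base)
    timings["represent_and_score"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    sampled = sample(config, model, scoring)
    timings["sample"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    result = analyze(config, model, scoring, sampled.ensemble, out_dir=out_dir)
    timings["analyze"] = time.perf_counter() - t0

    result.summary["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    log_lines = [
        f"assemblage {__version__}",
        f"seed {config.seed}",
        *(f"{stage}: {elapsed:.3f} s" for stage, elapsed in timings.items()),
        f"summary: {json.dumps(result.summary, default=str)}",
    ]
    (out_dir / "log.txt").write_text("\n".join(log_lines) + "\n")
    return result
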