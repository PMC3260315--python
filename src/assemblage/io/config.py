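"""Run configuration: schema, loading, and the reproducibility echo.

A run is driven by one JSON or YAML file with four blocks — representation
(subunits), restraints (typed term list), sampling and analysis — plus an
output directory and a seed.  The schema is strict: unknown or misspelled
keys are rejected with the offending key named.  Every run writes an echo
of the fully resolved configuration (defaults filled, seed recorded) next
to its outputs, so the run can be repeated bit-identically.
"""

from __future__ import annotations

import json
import logging
import secrets
from pathlib import Path
from typing import List, Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["RunConfig", "load_config", "write_config_echo"]

logger = logging.getLogger(__name__)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SubunitSpec(_Strict):
    """One subunit: either a coarse-grained chain or a PDB source."""

    label: str
    n_residues: Optional[int] = Field(default=None, gt=0)
    n_beads: int = Field(default=1, ge=1)
    residue_mass: float = Field(default=110.0, gt=0)
    pdb: Optional[str] = None
    chain: Optional[str] = None

    @model_validator(mode="after")
    def _one_source(self) -> "SubunitSpec":
        if (self.n_residues is None) == (self.pdb is None):
            raise ValueError(
                f"subunit {self.label!r}: give exactly one of n_residues or pdb"
            )
        return self


class DistanceSpec(_Strict):
    type: Literal["distance"] = "distance"
    p1: str
    p2: str
    d0: float = Field(ge=0)
    k: float = Field(default=1.0, gt=0)
    kind: Literal["harmonic", "upper", "lower"] = "harmonic"
    weight: float = Field(default=1.0, ge=0)
    threshold: float = Field(default=float("inf"), ge=0)


class ExcludedVolumeSpec(_Strict):
    type: Literal["excluded_volume"] = "excluded_volume"
    k: float = Field(default=1.0, gt=0)
    weight: float = Field(default=1.0, ge=0)
    threshold: float = Field(default=float("inf"), ge=0)


class ConnectivitySpec(_Strict):
    type: Literal["connectivity"] = "connectivity"
    subunits: List[str]
    k: float = Field(default=1.0, gt=0)
    slack: float = Field(default=0.0, ge=0)
    weight: float = Field(default=1.0, ge=0)
    threshold: float = Field(default=float("inf"), ge=0)


class EMFitSpec(_Strict):
    type: Literal["em_fit"] = "em_fit"
    map: str  # MRC path, relative to the config file
    resolution: float = Field(gt=0)
    weight: float = Field(default=1.0, ge=0)
    threshold: float = Field(default=float("inf"), ge=0)


class CrosslinksSpec(_Strict):
    type: Literal["crosslinks"] = "crosslinks"
    path: str  # CSV path, relative to the config file
    k: float = Field(default=1.0, gt=0)
    threshold: float = Field(default=float("inf"), ge=0)


RestraintSpec = Union[
    DistanceSpec, ExcludedVolumeSpec, ConnectivitySpec, EMFitSpec, CrosslinksSpec
]


class MoveSpec(_Strict):
    kind: Literal["ball", "rigid_body", "swap"] = "rigid_body"
    max_translation: float = Field(default=5.0, gt=0)
    max_rotation: float = Field(default=30.0, ge=0)  # degrees, rigid_body only


class SamplingSpec(_Strict):
    method: Literal["monte_carlo", "conjugate_gradients"] = "monte_carlo"
    n_runs: int = Field(default=10, ge=1)
    n_steps: int = Field(default=2000, ge=1)
    t_start: float = Field(default=20.0, gt=0)
    t_end: float = Field(default=0.2, gt=0)
    moves: List[MoveSpec] = Field(default_factory=lambda: [MoveSpec()])
    # how each run is started: scatter subunits randomly, or keep as built
    start: Literal["random", "anchor", "as_is"] = "random"
    # cross-basin discrete rectification (permutations/flips) after each run;
    # disable when the aim is to sample the whole good-scoring set rather
    # than converge each run to its best reachable model
    rectify: bool = True
    start_radius: float = Field(default=40.0, gt=0)  # Å, random-placement sphere
    # conjugate-gradients parameters
    max_steps: int = Field(default=500, ge=1)
    gtol: float = Field(default=1e-6, gt=0)


class AnalysisSpec(_Strict):
    cluster_method: Literal["binning", "kmeans"] = "binning"
    rmsd_cutoff: Optional[float] = Field(default=None, gt=0)  # binning; default: min radius
    k: Optional[int] = Field(default=None, ge=1)  # kmeans
    good_scoring_only: bool = True
    localization_subunits: List[str] = Field(default_factory=list)
    localization_resolution: float = Field(default=20.0, gt=0)


class RunConfig(_Strict):
    representation: List[SubunitSpec]
    restraints: List[RestraintSpec] = Field(default_factory=list)
    sampling: SamplingSpec = Field(default_factory=SamplingSpec)
    analysis: AnalysisSpec = Field(default_factory=AnalysisSpec)
    output_dir: str = "output"
    seed: Optional[int] = None

    @model_validator(mode="after")
    def _nonempty(self) -> "RunConfig":
        if not self.representation:
            raise ValueError("representation must list at least one subunit")
        labels = [s.label for s in self.representation]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate subunit labels in representation: {labels}")
        return self


def load_config(path) -> RunConfig:
    """Load and validate a JSON or YAML run configuration.

    A missing seed is drawn from the OS entropy pool and recorded (with a
    warning) so the echoed config still reruns identically.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    config = RunConfig.model_validate(raw)
    if config.seed is None:
        config.seed = secrets.randbelow(2**31)
        logger.warning("config %s has no seed; drew %d", path, config.seed)
    return config


def write_config_echo(config: RunConfig, out_dir) -> Path:
    """Write the resolved config (defaults filled) next to the outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    echo = out_dir / "config_echo.json"
    echo.write_text(json.dumps(config.model_dump(), indent=2, sort_keys=True) + "\n")
    return echo
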