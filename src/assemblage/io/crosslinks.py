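"""Cross-link / proximity tables.

CSV with header ``subunit1,subunit2,max_distance,weight``; '#' comment
lines and blank lines are ignored.  Optional ``particle1,particle2``
columns name the bead pair the proximity was observed between (the
synthetic generator annotates them); without the annotation each record is
anchored to the bead of each subunit nearest that subunit's centroid.
Each record becomes one upper-bound harmonic distance restraint with
d0 = max_distance.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np

from ..core import Model
from ..restraints import HarmonicDistanceRestraint

__all__ = ["CrosslinkRecord", "read_crosslinks", "crosslink_restraints"]

_REQUIRED = ("subunit1", "subunit2", "max_distance", "weight")


@dataclass(frozen=True)
class CrosslinkRecord:
    subunit1: str
    subunit2: str
    max_distance: float  # centre-distance bound, Å
    weight: float
    particle1: Optional[str] = None
    particle2: Optional[str] = None
    line: int = field(default=0, compare=False)  # 1-based source line, for errors


def read_crosslinks(path) -> List[CrosslinkRecord]:
    """Parse a cross-link CSV into records, keeping source line numbers."""
    path = Path(path)
    numbered = [
        (i, line)
        for i, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1)
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if not numbered:
        raise ValueError(f"{path}: no content lines")
    header_line = numbered[0][1]
    reader = csv.DictReader([header_line] + [l for _, l in numbered[1:]])
    fields = [f.strip() for f in reader.fieldnames or []]
    missing = [c for c in _REQUIRED if c not in fields]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing} (header: {fields})")
    records: List[CrosslinkRecord] = []
    for (lineno, _), row in zip(numbered[1:], reader):
        row = {(k or "").strip(): (v or "").strip() for k, v in row.items()}
        try:
            max_distance = float(row["max_distance"])
            weight = float(row["weight"])
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}, line {lineno}: malformed numeric field ({exc})")
        if not max_distance > 0:
            raise ValueError(
                f"{path}, line {lineno}: max_distance must be > 0, got {max_distance}"
            )
        records.append(
            CrosslinkRecord(
                subunit1=row["subunit1"],
                subunit2=row["subunit2"],
                max_distance=max_distance,
                weight=weight,
                particle1=row.get("particle1") or None,
                particle2=row.get("particle2") or None,
                line=lineno,
            )
        )
    return records


def _anchor(model: Model, subunit: str, particle: Optional[str], line: int, path) -> str:
    if particle is not None:
        if particle not in model.particles:
            raise ValueError(
                f"{path}, line {line}: unknown particle {particle!r}"
            )
        return particle
    try:
        ids = model.subunit_ids(subunit)
    except KeyError:
        raise ValueError(
            f"{path}, line {line}: unknown subunit {subunit!r}"
        ) from None
    coords = model.coords(ids)
    centroid = coords.mean(axis=0)
    return ids[int(np.argmin(np.linalg.norm(coords - centroid, axis=1)))]


def crosslink_restraints(
    records: List[CrosslinkRecord],
    model: Model,
    k: float = 1.0,
    threshold: float = np.inf,
    path="crosslinks",
) -> List[HarmonicDistanceRestraint]:
    """One upper-bound distance restraint per record.

    ``k`` is the spring constant and ``threshold`` the per-term
    good-scoring cutoff (score units), both shared across records; the
    per-record ``weight`` scales each term in the total.
    """
    out = []
    for i, rec in enumerate(records):
        p1 = _anchor(model, rec.subunit1, rec.particle1, rec.line, path)
        p2 = _anchor(model, rec.subunit2, rec.particle2, rec.line, path)
        out.append(
            HarmonicDistanceRestraint(
                p1,
                p2,
                d0=rec.max_distance,
                k=k,
                kind="upper",
                name=f"xlink{i}:{rec.subunit1}-{rec.subunit2}",
                weight=rec.weight,
                threshold=threshold,
            )
        )
    return out
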