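"""Bead-model PDB reading and writing.

Coarse beads are encoded so standard viewers (Chimera, PyMOL) render them:
one HETATM per bead with atom name "CA", residue name "BEA", one residue
per bead, chain = subunit label, occupancy = mass/1000 (kDa) and B-factor =
radius (Å).  Ensembles are written as MODEL/ENDMDL blocks.  Subunit labels
longer than one character are mapped onto single chain ids and recorded in
``REMARK  99 SUBUNIT <chain> <label>`` lines so a read round-trips them.

Reading goes through gemmi and also accepts ordinary CA-only atomic chains
(ATOM records), which become one particle per residue with generic
per-residue mass/radius defaults.
"""

from __future__ import annotations

import string
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import gemmi
import numpy as np

from ..core import Configuration, Model

__all__ = ["write_pdb", "read_pdb"]

_CHAIN_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits
_BEAD_RESNAME = "BEA"

# defaults for particles built from plain atomic CA records
_CA_MASS = 110.0  # Da, one average residue
_CA_RADIUS = 2.4  # Å, sphere of one residue volume


def _chain_map(subunits: Sequence[str]) -> Dict[str, str]:
    if len(subunits) > len(_CHAIN_ALPHABET):
        raise ValueError(
            f"{len(subunits)} subunits exceed the {len(_CHAIN_ALPHABET)} available chain ids"
        )
    used = set()
    mapping: Dict[str, str] = {}
    pending = []
    for label in subunits:
        if len(label) == 1 and label in _CHAIN_ALPHABET and label not in used:
            mapping[label] = label
            used.add(label)
        else:
            pending.append(label)
    free = iter(c for c in _CHAIN_ALPHABET if c not in used)
    for label in pending:
        mapping[label] = next(free)
    return mapping


def _atom_line(
    serial: int, chain: str, resseq: int, xyz: np.ndarray, occ: float, bfac: float
) -> str:
    return (
        f"HETATM{serial:5d}  CA  {_BEAD_RESNAME} {chain}{resseq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}{bfac:6.2f}"
        f"          {'C':>2s}"
    )


def write_pdb(
    model: Model,
    path,
    configurations: Optional[Sequence[Configuration]] = None,
) -> None:
    """Write a model (or an ensemble of its configurations) as PDB.

    With ``configurations`` each one becomes a MODEL/ENDMDL block; the
    model's own coordinates are ignored in that case.
    """
    if len(model.particles) > 99999:
        raise ValueError("PDB serial numbers support at most 99,999 particles")
    subunits = list(model.hierarchy)
    mapping = _chain_map(subunits)
    lines: List[str] = []
    for label in subunits:
        if mapping[label] != label:
            lines.append(f"REMARK  99 SUBUNIT {mapping[label]} {label}")

    def emit_block(xyz_of) -> None:
        serial = 0
        for label, ids in model.hierarchy.items():
            for resseq, pid in enumerate(ids, start=1):
                serial += 1
                p = model.particles[pid]
                lines.append(
                    _atom_line(
                        serial, mapping[label], resseq, xyz_of(pid), p.mass / 1000.0, p.radius
                    )
                )

    if configurations is None:
        emit_block(lambda pid: model.particles[pid].xyz)
    else:
        for i, conf in enumerate(configurations, start=1):
            lines.append(f"MODEL {i:>8d}")
            emit_block(lambda pid: conf.xyz[pid])
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdb(path) -> Tuple[Model, List[Configuration]]:
    """Read a bead-model or CA-only atomic PDB file.

    Returns the model built from the first MODEL block plus one
    Configuration per block (one for a single-model file).  Bead records
    (HETATM/BEA) decode occupancy as mass/1000 and B-factor as radius;
    plain ATOM records become one particle per residue with generic
    defaults (mass 110 Da, radius 2.4 Å).  Particle ids are
    "<subunit>.<residue number>".  Malformed fixed-width lines raise with
    the offending line number.
    """
    path = str(path)
    try:
        st = gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"failed to parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"no MODEL blocks in {path}")
    label_of: Dict[str, str] = {}
    for remark in st.raw_remarks:
        parts = remark.split()
        if len(parts) >= 5 and parts[1] == "99" and parts[2] == "SUBUNIT":
            label_of[parts[3]] = parts[4]

    model = Model()
    first = st[0]
    for chain in first:
        label = label_of.get(chain.name, chain.name)
        for res in chain:
            for atom in res:
                pid = f"{label}.{res.seqid.num}"
                if res.name == _BEAD_RESNAME:
                    mass = atom.occ * 1000.0
                    radius = atom.b_iso
                else:
                    mass, radius = _CA_MASS, _CA_RADIUS
                if not radius > 0 or not mass > 0:
                    raise ValueError(
                        f"{path}: particle {pid} decodes non-positive "
                        f"mass/radius ({mass}, {radius})"
                    )
                model.create_particle(
                    pid,
                    (atom.pos.x, atom.pos.y, atom.pos.z),
                    radius=radius,
                    mass=mass,
                    subunit=label,
                    residue_range=(res.seqid.num, res.seqid.num),
                )

    configurations: List[Configuration] = []
    for block in st:
        xyz: Dict[str, np.ndarray] = {}
        for chain in block:
            label = label_of.get(chain.name, chain.name)
            for res in chain:
                for atom in res:
                    xyz[f"{label}.{res.seqid.num}"] = np.array(
                        [atom.pos.x, atom.pos.y, atom.pos.z]
                    )
        if set(xyz) != set(model.particles):
            raise ValueError(f"{path}: MODEL blocks have differing particle sets")
        configurations.append(Configuration(xyz=xyz, frames={}))
    return model, configurations
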