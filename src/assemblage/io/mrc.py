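"""MRC2014 / CCP4 density map I/O (mode 2, 32-bit float), via gemmi.

Only the plain dialect is accepted: axis order MAPC=1, MAPR=2, MAPS=3
(x fastest on disk) and cubic voxels.  The origin is taken from the
MRC2014 ORIGIN header words (50-52, Å); when those are all zero but
NXSTART/NYSTART/NZSTART are set, the start indices times the spacing are
used instead, and a disagreement between the two conventions is logged
with ORIGIN winning.  Write → read round trips are voxel-bit-exact for
float32 values.
"""

from __future__ import annotations

import logging

import gemmi
import numpy as np

from ..density import DensityGrid

__all__ = ["read_mrc", "write_mrc"]

logger = logging.getLogger(__name__)

_SPACING_TOL = 1e-4


def write_mrc(grid: DensityGrid, path) -> None:
    """Write a density grid as an MRC2014 mode-2 map."""
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(np.ascontiguousarray(grid.values, dtype=np.float32))
    nx, ny, nz = grid.dims
    h = grid.spacing
    ccp4.grid.unit_cell = gemmi.UnitCell(nx * h, ny * h, nz * h, 90.0, 90.0, 90.0)
    ccp4.grid.spacegroup = gemmi.SpaceGroup("P 1")
    ccp4.update_ccp4_header()
    for word, value in zip((50, 51, 52), grid.origin):
        ccp4.set_header_float(word, float(value))
    ccp4.write_ccp4_map(str(path))


def read_mrc(path) -> DensityGrid:
    """Read an MRC2014 mode-2 map with cubic, axis-aligned voxels.

    Rejects non-mode-2 files, permuted MAPC/MAPR/MAPS axis orders (rather
    than silently permuting) and non-cubic voxel spacings; a payload
    shorter than NX·NY·NZ raises.
    """
    path = str(path)
    try:
        ccp4 = gemmi.read_ccp4_map(path)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"failed to read MRC map {path}: {exc}") from exc
    mode = ccp4.header_i32(4)
    if mode != 2:
        raise ValueError(f"{path}: MRC mode {mode} unsupported (mode 2 float required)")
    axes = tuple(ccp4.header_i32(w) for w in (17, 18, 19))
    if axes != (1, 2, 3):
        raise ValueError(
            f"{path}: axis order MAPC/MAPR/MAPS = {axes} is not the plain "
            "(1, 2, 3) layout; refusing to permute silently"
        )
    spacing = ccp4.grid.spacing
    if abs(spacing[0] - spacing[1]) > _SPACING_TOL or abs(spacing[0] - spacing[2]) > _SPACING_TOL:
        raise ValueError(f"{path}: voxels are not cubic (spacing {spacing})")
    h = float(spacing[0])
    origin = np.array([ccp4.header_float(w) for w in (50, 51, 52)])
    starts = np.array([ccp4.header_i32(w) for w in (5, 6, 7)])
    start_origin = starts * h
    if np.all(origin == 0.0) and np.any(starts != 0):
        origin = start_origin
    elif np.any(starts != 0) and not np.allclose(origin, start_origin, atol=1e-3):
        logger.warning(
            "%s: ORIGIN header %s disagrees with NXSTART-based origin %s; using ORIGIN",
            path,
            tuple(origin),
            tuple(start_origin),
        )
    values = np.array(ccp4.grid, copy=True, dtype=np.float32)
    return DensityGrid(tuple(origin), h, values.astype(float))
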