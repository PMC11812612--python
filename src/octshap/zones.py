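"""Posterior-pole grid handling: scans, anatomical zones, zone aggregation.

The Spectralis posterior-pole protocol reports macular thickness of each
segmented retinal layer on an 8x8 cell grid centred on the fovea.  This
module fixes the grid orientation convention (row 1 = superior, column 1 =
temporal, in right-eye orientation), assigns grid cells to six anatomical
analysis zones, and aggregates cell thicknesses into per-zone means.

Zones (right-eye orientation):

    1  central papillomacular bundle
    2  peripheral papillomacular bundle
    3  supero-nasal quadrant
    4  infero-nasal quadrant
    5  infero-temporal quadrant
    6  supero-temporal quadrant

For the left eye the map is mirrored column-wise so that nasal/temporal
cells stay anatomically matched across eyes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GRID_SHAPE = (8, 8)

#: Segmented layers measured directly by the instrument.
BASE_LAYERS = ("mRNFL", "mGCL", "mIPL")
#: All analysed structures; mIRL is derived as mRNFL + mGCL + mIPL.
ALL_LAYERS = ("mRNFL", "mGCL", "mIPL", "mIRL")

EYES = ("OD", "OS")
ZONES = (1, 2, 3, 4, 5, 6)


class GridValidationError(ValueError):
    """A grid or zone map violates a structural invariant."""


@dataclass(frozen=True)
class GridScan:
    """One eye's 8x8 thickness grid for one retinal layer of one subject.

    ``cells[r, c]`` is thickness in micrometres; row 0 is superior, and in
    right-eye (OD) orientation column 0 is temporal.
    """

    subject_id: str
    eye: str
    layer: str
    cells: np.ndarray

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=float)
        if cells.shape != GRID_SHAPE:
            raise GridValidationError(
                f"grid for {self.subject_id}/{self.eye}/{self.layer}: "
                f"expected shape {GRID_SHAPE}, got {cells.shape}"
            )
        if not np.all(np.isfinite(cells)) or np.any(cells <= 0):
            raise GridValidationError(
                f"grid for {self.subject_id}/{self.eye}/{self.layer}: "
                "all 64 cells must be finite and > 0"
            )
        if self.eye not in EYES:
            raise GridValidationError(f"eye must be one of {EYES}, got {self.eye!r}")
        object.__setattr__(self, "cells", cells)


@dataclass(frozen=True)
class ZoneMap:
    """Assignment of the 64 grid cells to analysis zones.

    ``cells[r, c]`` holds a label in 0..6 (0 = unassigned), defined in
    right-eye orientation.  Every zone 1-6 must be non-empty.
    """

    cells: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=int)
        if cells.shape != GRID_SHAPE:
            raise GridValidationError(
                f"zone map must be {GRID_SHAPE}, got {cells.shape}"
            )
        if cells.min() < 0 or cells.max() > 6:
            raise GridValidationError("zone labels must lie in 0..6")
        for z in ZONES:
            if not np.any(cells == z):
                raise GridValidationError(f"zone {z} has no member cells")
        object.__setattr__(self, "cells", cells)

    def members(self, zone: int) -> np.ndarray:
        """Boolean 8x8 mask of the cells belonging to ``zone``."""
        return self.cells == zone


def default_zone_map() -> ZoneMap:
    """The package's documented default cell-to-zone assignment.

    Zone 1 is the 2x4 block spanning the two foveal rows immediately
    temporal of centre; zone 2 is the ring of temporal-central cells
    surrounding it; the remaining cells split into the four quadrants
    defined by the horizontal and vertical grid midlines.  Every cell is
    assigned (no zone-0 cells).  The assignment is a convention, not a
    vendor map, and can be overridden with any :class:`ZoneMap`.
    """
    z = np.zeros(GRID_SHAPE, dtype=int)
    # quadrants first (rows 0-3 superior, cols 0-3 temporal in OD view)
    z[0:4, 0:4] = 6  # supero-temporal
    z[0:4, 4:8] = 3  # supero-nasal
    z[4:8, 0:4] = 5  # infero-temporal
    z[4:8, 4:8] = 4  # infero-nasal
    # papillomacular bundle overrides the central-temporal region
    z[2:6, 0:6] = 2  # peripheral ring
    z[3:5, 1:5] = 1  # central 2x4 block
    return ZoneMap(z)


def mirror_zone_map(zone_map: ZoneMap) -> ZoneMap:
    """Flip a right-eye zone map into left-eye orientation (and back).

    A horizontal column flip: nasal and temporal columns swap sides, so the
    same anatomical zones apply to an OS grid stored in its own view.
    Applying the mirror twice returns the original map.
    """
    return ZoneMap(zone_map.cells[:, ::-1])


def zone_means(grid: GridScan, zone_map: ZoneMap) -> dict[int, float]:
    """Mean thickness (um) of each zone's member cells.

    ``zone_map`` must already be in the orientation of the grid's eye
    (use :func:`mirror_zone_map` for OS grids).
    """
    return {z: float(grid.cells[zone_map.members(z)].mean()) for z in ZONES}


def derive_irl(scans: dict[tuple[str, str], GridScan], subject_id: str, eye: str) -> GridScan:
    """Cellwise mIRL = mRNFL + mGCL + mIPL for one eye (exact sum).

    ``scans`` maps ``(eye, layer)`` to the base-layer grids of a subject.
    """
    parts = []
    for layer in BASE_LAYERS:
        scan = scans.get((eye, layer))
        if scan is None:
            raise GridValidationError(
                f"cannot derive mIRL: missing {subject_id}/{eye}/{layer}"
            )
        parts.append(scan.cells)
    return GridScan(subject_id, eye, "mIRL", parts[0] + parts[1] + parts[2])


def read_zone_map(path: str | Path) -> ZoneMap:
    """Read a zone map from an 8x8 CSV of integers or a JSON list of lists."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        cells = np.asarray(json.loads(path.read_text()), dtype=int)
    else:
        cells = pd.read_csv(path, header=None).to_numpy(dtype=int)
    return ZoneMap(cells)


def write_zone_map(zone_map: ZoneMap, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(zone_map.cells.tolist()) + "\n")
    else:
        pd.DataFrame(zone_map.cells).to_csv(path, header=False, index=False)
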