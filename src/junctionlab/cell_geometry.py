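"""Cell perimeter paths and morphology from user-supplied waypoint traces.

A cell is described by an ordered polygon of waypoints (pixel vertices,
implicitly closed).  The *cell path* is the Bresenham rasterization of that
polygon: an ordered, closed chain of distinct pixels in which consecutive
pixels are 8-neighbours.  The path is the denominator of every junction
coverage percentage, and the filled polygon is the basis of the morphology
metrics (area, perimeter, circularity ``4*pi*A/P**2``, solidity
``A/A_convex``).

Two length notions coexist deliberately: the *pixel count* of the path
(used by the continuous-junction criterion, which is stated in pixels) and
the *Euclidean chain length* (axial step 1, diagonal step sqrt(2), times the
pixel calibration) used for the morphological perimeter.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon as _ShPolygon
from skimage.draw import line as _draw_line
from skimage.draw import polygon as _draw_polygon
from skimage.morphology import convex_hull_image

from .errors import GeometryError, ShapeError
from .imaging_io import DEFAULT_PIXEL_SIZE_UM, IntensityImage


@dataclass(frozen=True)
class WaypointTrace:
    """Ordered polygon vertices for one cell; closure last->first is implicit."""

    cell_id: str
    vertices: np.ndarray  # (n, 2) int array of (row, col)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 2:
            raise GeometryError(f"vertices must be an (n, 2) array, got {v.shape}")
        object.__setattr__(self, "vertices", v)

    def validate(self, image_shape: tuple[int, int] | None = None) -> None:
        """Check vertex count, bounds and polygon simplicity.

        Raises GeometryError for degenerate/self-intersecting polygons and
        for out-of-bounds vertices.
        """
        v = self.vertices
        if len(v) < 3:
            raise GeometryError(f"cell {self.cell_id}: need >= 3 waypoints, got {len(v)}")
        if image_shape is not None:
            if (v < 0).any() or (v[:, 0] >= image_shape[0]).any() or (
                v[:, 1] >= image_shape[1]
            ).any():
                raise GeometryError(
                    f"cell {self.cell_id}: waypoint outside image bounds {image_shape}"
                )
        poly = _ShPolygon([(c, r) for r, c in v])
        if poly.area == 0:
            raise GeometryError(f"cell {self.cell_id}: polygon has zero area")
        if not poly.is_valid:
            raise GeometryError(f"cell {self.cell_id}: polygon is self-intersecting")

    def touches_border(self, image_shape: tuple[int, int]) -> bool:
        """True if any waypoint lies on the image boundary (partially visible cell)."""
        v = self.vertices
        return bool(
            (v[:, 0] == 0).any()
            or (v[:, 1] == 0).any()
            or (v[:, 0] == image_shape[0] - 1).any()
            or (v[:, 1] == image_shape[1] - 1).any()
        )


@dataclass(frozen=True)
class CellPath:
    """Closed rasterized perimeter of one cell.

    ``path_pixels`` is ordered; consecutive pixels (including last->first)
    are 8-neighbours and no pixel repeats.
    """

    cell_id: str
    path_pixels: np.ndarray  # (n, 2) int array of (row, col)
    image_shape: tuple[int, int]
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    channel_label: str = ""

    @property
    def path_length_px(self) -> int:
        return len(self.path_pixels)

    @property
    def path_length_um(self) -> float:
        """Closed Euclidean chain length (1 / sqrt(2) steps) times calibration."""
        steps = self.path_pixels - np.roll(self.path_pixels, -1, axis=0)
        return float(np.hypot(steps[:, 0], steps[:, 1]).sum()) * self.pixel_size

    def pixel_index_map(self) -> dict[tuple[int, int], int]:
        """Map (row, col) -> position along the path."""
        return {(int(r), int(c)): i for i, (r, c) in enumerate(self.path_pixels)}


@dataclass(frozen=True)
class MorphologyMetrics:
    """Shape descriptors of one traced cell."""

    area_px2: int
    area_um2: float
    perimeter_um: float
    convex_area_px2: int
    convex_area_um2: float
    circularity: float
    solidity: float


def build_cell_path(
    trace: WaypointTrace,
    image_shape: tuple[int, int],
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    channel_label: str = "",
) -> CellPath:
    """Rasterize a waypoint polygon into a closed 8-connected pixel chain.

    Each consecutive waypoint pair (and last->first) is connected by
    Bresenham line rasterization; shared segment endpoints are deduplicated
    so no pixel appears twice.
    """
    trace.validate(image_shape)
    v = trace.vertices
    segments = []
    for i in range(len(v)):
        r0, c0 = v[i]
        r1, c1 = v[(i + 1) % len(v)]
        rr, cc = _draw_line(int(r0), int(c0), int(r1), int(c1))
        # drop the segment's endpoint: the next segment re-adds it
        segments.append(np.column_stack([rr, cc])[:-1])
    path = np.concatenate([s for s in segments if len(s)])
    if len(path) == 0:
        raise GeometryError(f"cell {trace.cell_id}: empty rasterized path")
    # remove any later duplicates (edges that touch at pixel resolution),
    # keeping the first occurrence so the walking order is preserved
    _, first = np.unique(path, axis=0, return_index=True)
    path = path[np.sort(first)]
    return CellPath(trace.cell_id, path, tuple(image_shape), pixel_size, channel_label)


def project_path(path: CellPath, target: IntensityImage) -> CellPath:
    """Re-associate a path with a second channel of the same field of view.

    Coordinates are unchanged; only the channel label differs.  Used when
    cells are traced on one stain (e.g. ZO-1) and the same perimeters are
    quantified on another (e.g. VE-cadherin).
    """
    if target.shape != path.image_shape:
        raise ShapeError(
            f"target shape {target.shape} != path image shape {path.image_shape}"
        )
    return dataclasses.replace(path, channel_label=target.channel_label)


def fill_cell(trace: WaypointTrace, path: CellPath) -> np.ndarray:
    """Boolean mask of the cell's interior plus its perimeter path pixels."""
    mask = np.zeros(path.image_shape, dtype=bool)
    rr, cc = _draw_polygon(trace.vertices[:, 0], trace.vertices[:, 1],
                           shape=path.image_shape)
    mask[rr, cc] = True
    mask[path.path_pixels[:, 0], path.path_pixels[:, 1]] = True
    return mask


def compute_morphology(
    trace: WaypointTrace,
    path: CellPath,
    pixel_size: float | None = None,
) -> MorphologyMetrics:
    """Area, perimeter, convex area, circularity and solidity of one cell.

    Area counts interior plus boundary pixels (the traced perimeter belongs
    to the cell); the perimeter is the Euclidean chain length of the path.
    """
    ps = path.pixel_size if pixel_size is None else pixel_size
    filled = fill_cell(trace, path)
    area_px = int(filled.sum())
    if area_px == 0:
        raise GeometryError(f"cell {trace.cell_id}: degenerate polygon")
    hull = convex_hull_image(filled)
    conv_px = int(hull.sum())
    area_um2 = area_px * ps * ps
    conv_um2 = conv_px * ps * ps
    perim_um = path.path_length_um if pixel_size is None else (
        path.path_length_um / path.pixel_size * ps
    )
    circularity = 4.0 * np.pi * area_um2 / (perim_um**2)
    solidity = area_px / conv_px
    return MorphologyMetrics(
        area_px2=area_px,
        area_um2=area_um2,
        perimeter_um=perim_um,
        convex_area_px2=conv_px,
        convex_area_um2=conv_um2,
        circularity=float(circularity),
        solidity=float(solidity),
    )


def snap_waypoints(
    trace: WaypointTrace, image: IntensityImage, radius: int = 2
) -> WaypointTrace:
    """Move each waypoint to the brightest pixel within a Chebyshev radius.

    Optional refinement for hand-placed traces that sit slightly off the
    junction ridge; off by default in the pipeline.  Ties keep the smallest
    offset (original position preferred).
    """
    if radius <= 0:
        return trace
    h, w = image.shape
    out = []
    for r, c in trace.vertices:
        r0, r1 = max(0, r - radius), min(h, r + radius + 1)
        c0, c1 = max(0, c - radius), min(w, c + radius + 1)
        win = image.pixels[r0:r1, c0:c1]
        if win.max() > image.pixels[r, c]:
            dr, dc = np.unravel_index(int(win.argmax()), win.shape)
            out.append((r0 + dr, c0 + dc))
        else:
            out.append((r, c))
    return WaypointTrace(trace.cell_id, np.array(out, dtype=np.int64))


# ---------------------------------------------------------------------------
# Waypoint tables (delimited text; columns cell_id, vertex_index, row, col)

def read_waypoints(path: str | Path) -> dict[str, WaypointTrace]:
    """Read a waypoint table (CSV) into traces keyed by cell_id."""
    df = pd.read_csv(path)
    required = {"cell_id", "vertex_index", "row", "col"}
    missing = required - set(df.columns)
    if missing:
        raise GeometryError(f"waypoint table {path}: missing columns {sorted(missing)}")
    traces: dict[str, WaypointTrace] = {}
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("vertex_index")
        traces[str(cid)] = WaypointTrace(
            str(cid), grp[["row", "col"]].to_numpy(dtype=np.int64)
        )
    return traces


def write_waypoints(traces: dict[str, WaypointTrace], path: str | Path) -> None:
    """Write traces to a waypoint table (CSV)."""
    rows = []
    for cid in sorted(traces):
        for i, (r, c) in enumerate(traces[cid].vertices):
            rows.append({"cell_id": cid, "vertex_index": i, "row": int(r), "col": int(c)})
    pd.DataFrame(rows, columns=["cell_id", "vertex_index", "row", "col"]).to_csv(
        path, index=False
    )
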