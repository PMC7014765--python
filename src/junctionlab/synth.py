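"""Synthetic endothelial-monolayer fixtures with known ground truth.

The generator emulates what the analysis pipeline consumes: a confluent
monolayer whose cell borders carry junction signal of known phenotype
composition, plus an optional avidin-leak channel with planted permeated
regions (PRs).  Cells are Voronoi cells of uniformly sampled (minimum
distance enforced) seed points, clipped to the image; each unique border
between two cells is planned once and painted once, so the two cells
sharing a border see the same junction marks, as in real monolayers.

Per border, junction marks are laid out along the rasterized border line:

* a **continuous** run paints the border pixels themselves over a stretch
  longer than 15 px;
* a **punctate** mark is a near-isotropic 3x3 disc centred on the border
  (it registers ~5 path pixels through the corridor);
* a **perpendicular** mark is a 3 px x 9 px bar rotated to the border
  normal (also ~5 path pixels, with normal/tangential extent 3).

The ground truth records, per cell, the *expected measured* path-pixel
length of every planted segment (including the one-pixel corridor
spill-over at the free ends of a continuous run), so recovery tests can
compare pipeline output against the plan directly.  Everything is
deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from shapely.geometry import LineString, Point
from shapely.geometry import Polygon as _ShPolygon
from shapely.geometry import box as _sh_box
from skimage.draw import disk as _draw_disk
from skimage.draw import line as _draw_line

from .cell_geometry import CellPath, WaypointTrace, build_cell_path
from .errors import GenerationError
from .imaging_io import DEFAULT_PIXEL_SIZE_UM, IntensityImage
from .junction_phenotyping import CONTINUOUS, PERPENDICULAR, PHENOTYPES, PUNCTATE

#: path pixels reserved per punctate / perpendicular mark (and their
#: expected measured coverage through the radius-1 corridor)
_MARK_SPAN = 5
_GAP = 3  # none-pixels left between consecutive marks on a border
_END_MARGIN = 2  # none-pixels left next to each border vertex


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian background plus a fixed junction paint intensity."""

    background_mean: float = 5.0
    background_sd: float = 0.0
    junction_intensity: int = 200


@dataclass(frozen=True)
class PlannedSegment:
    """One planted junction mark on a border."""

    phenotype: str
    pixels: np.ndarray  # (k, 2) canonical border pixels reserved by the mark
    expected_length: int  # path pixels the pipeline should measure for it
    start: int = 0  # index of the first reserved pixel within the border


@dataclass
class EdgePlan:
    """One unique border (polygon edge) with its planted segments."""

    key: tuple[tuple[int, int], tuple[int, int]]
    pixels: np.ndarray  # (L, 2) canonical rasterization
    cells: frozenset[str]
    on_boundary: bool
    segments: list[PlannedSegment] = field(default_factory=list)


@dataclass(frozen=True)
class PRBlobSpec:
    """A planted permeated-region blob.

    ``shape`` is ``"disk"`` (uses ``radius``), ``"rect"`` (uses
    ``half_size = (hr, hc)``, footprint ``(2hr+1) x (2hc+1)``) or
    ``"pixels"`` (explicit ``pixels`` array).  ``intended_cells`` is the
    planned association (the ground-truth category).
    """

    center: tuple[int, int]
    intended_cells: frozenset[str]
    shape: str = "disk"
    radius: float = 10.0
    half_size: tuple[int, int] = (10, 10)
    pixels: np.ndarray | None = None


@dataclass
class SyntheticGroundTruth:
    """Everything the generator planted, for checking downstream metrics."""

    image_size: int
    pixel_size: float
    composition: tuple[float, float, float]
    noise: NoiseModel
    seed: int
    traces: dict[str, WaypointTrace]
    paths: dict[str, CellPath]
    border_cells: set[str]
    edges: dict[tuple, EdgePlan]
    planned: pd.DataFrame  # per-cell planted lengths and fractions

    def interior_cells(self) -> list[str]:
        """Cells whose perimeter is fully visible (not touching the image edge)."""
        return [cid for cid in sorted(self.traces) if cid not in self.border_cells]


@dataclass
class MonolayerSample:
    """Generated junction channel plus its traces and ground truth."""

    junction_image: IntensityImage
    traces: dict[str, WaypointTrace]
    truth: SyntheticGroundTruth


# ---------------------------------------------------------------------------
# geometry helpers

def _sample_seed_points(rng: np.random.Generator, n: int, size: int) -> np.ndarray:
    margin = max(8, size // 32)
    d_min = 0.65 * (size - 2 * margin) / math.sqrt(n)
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        p = rng.uniform(margin, size - 1 - margin, 2)
        if all(np.abs(p - q).max() >= d_min for q in pts):
            pts.append(p)
            tries = 0
        else:
            tries += 1
            if tries > 2000:  # relax spacing rather than loop forever
                d_min *= 0.9
                tries = 0
    return np.array(pts)


def _voronoi_polygons(points: np.ndarray, size: int) -> list[np.ndarray]:
    """Clipped integer Voronoi polygons, one per input point.

    Seed points are mirrored across the four image edges so every real
    region is finite; regions are then clipped to the image box and their
    vertices rounded to the pixel grid.  Adjacent cells share float
    vertices exactly, hence also rounded ones, which is what lets borders
    be planned once per cell pair.
    """
    hi = size - 1
    mirrored = [points]
    for axis, bound in ((0, 0), (0, hi), (1, 0), (1, hi)):
        m = points.copy()
        m[:, axis] = 2 * bound - m[:, axis]
        mirrored.append(m)
    vor = Voronoi(np.vstack(mirrored))
    bbox = _sh_box(0, 0, hi, hi)
    polys = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            raise GenerationError("unbounded Voronoi region despite mirroring")
        poly = _ShPolygon(vor.vertices[region]).intersection(bbox)
        coords = np.asarray(poly.exterior.coords[:-1])
        verts = np.clip(np.rint(coords).astype(np.int64), 0, hi)
        # drop consecutive duplicates created by rounding (incl. wrap)
        keep = [0]
        for j in range(1, len(verts)):
            if not np.array_equal(verts[j], verts[keep[-1]]):
                keep.append(j)
        if len(keep) > 1 and np.array_equal(verts[keep[-1]], verts[keep[0]]):
            keep.pop()
        verts = verts[keep]
        if len(verts) < 3:
            raise GenerationError(f"cell {i} degenerated to < 3 vertices")
        polys.append(verts)
    return polys


def _edge_registry(traces: dict[str, WaypointTrace], size: int) -> dict[tuple, EdgePlan]:
    hi = size - 1
    edges: dict[tuple, EdgePlan] = {}
    for cid in sorted(traces):
        v = traces[cid].vertices
        for i in range(len(v)):
            a = (int(v[i][0]), int(v[i][1]))
            b = (int(v[(i + 1) % len(v)][0]), int(v[(i + 1) % len(v)][1]))
            if a == b:
                continue
            key = (a, b) if a <= b else (b, a)
            if key in edges:
                edges[key].cells = frozenset(edges[key].cells | {cid})
                continue
            rr, cc = _draw_line(key[0][0], key[0][1], key[1][0], key[1][1])
            on_boundary = (
                (a[0] == b[0] == 0) or (a[0] == b[0] == hi)
                or (a[1] == b[1] == 0) or (a[1] == b[1] == hi)
            )
            edges[key] = EdgePlan(key=key, pixels=np.column_stack([rr, cc]),
                                  cells=frozenset({cid}), on_boundary=on_boundary)
    return edges


def _plan_edge(edge: EdgePlan, composition: tuple[float, float, float]) -> None:
    """Allocate phenotype runs along one border, in place."""
    f_cont, f_punct, f_perp = composition
    L = len(edge.pixels)
    full_cont = f_cont >= 0.999 and f_punct == 0 and f_perp == 0
    if full_cont:
        edge.segments.append(PlannedSegment(CONTINUOUS, edge.pixels, L, start=0))
        return
    cursor = _END_MARGIN
    end = L - _END_MARGIN
    cont_len = int(round(L * f_cont))
    if cont_len > 15:
        cont_len = min(cont_len, end - cursor)
        if cont_len > 15:
            edge.segments.append(
                PlannedSegment(CONTINUOUS, edge.pixels[cursor:cursor + cont_len],
                               cont_len + 2,  # corridor spill-over at both ends
                               start=cursor)
            )
            cursor += cont_len + _GAP
    for phenotype, frac in ((PUNCTATE, f_punct), (PERPENDICULAR, f_perp)):
        n_marks = int(round(L * frac / _MARK_SPAN))
        for _ in range(n_marks):
            if cursor + _MARK_SPAN > end:
                break
            edge.segments.append(
                PlannedSegment(phenotype, edge.pixels[cursor:cursor + _MARK_SPAN],
                               _MARK_SPAN, start=cursor)
            )
            cursor += _MARK_SPAN + _GAP


def _paint_segment(canvas: np.ndarray, seg: PlannedSegment, intensity: int) -> None:
    size = canvas.shape[0]
    if seg.phenotype == CONTINUOUS:
        canvas[seg.pixels[:, 0], seg.pixels[:, 1]] = intensity
        return
    center = seg.pixels[len(seg.pixels) // 2]
    if seg.phenotype == PUNCTATE:
        rr, cc = _draw_disk((int(center[0]), int(center[1])), 1.8, shape=canvas.shape)
        canvas[rr, cc] = intensity
        return
    # perpendicular: 3 px (tangential) x 9 px (normal) bar
    d = (seg.pixels[-1] - seg.pixels[0]).astype(np.float64)
    t = d / np.hypot(*d)
    nvec = np.array([-t[1], t[0]])
    for s in range(-4, 5):
        for w in (-1, 0, 1):
            p = np.rint(center + s * nvec + w * t).astype(int)
            if 0 <= p[0] < size and 0 <= p[1] < size:
                canvas[p[0], p[1]] = intensity


def generate_monolayer(
    n_cells: int = 20,
    image_size: int = 512,
    composition: tuple[float, float, float] = (0.4, 0.1, 0.05),
    noise: NoiseModel | None = None,
    seed: int = 0,
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    channel_label: str = "ZO-1",
) -> MonolayerSample:
    """Generate one synthetic monolayer junction channel with ground truth.

    ``composition`` gives the target (continuous, punctate, perpendicular)
    fractions of border length; fractions must each lie in [0, 1] and sum
    to at most 1 (the remainder is junction-free border).  The planted
    per-cell fractions recorded in the ground truth are what allocation
    actually achieved, which can fall slightly short of the request on
    short borders.
    """
    if n_cells < 1:
        raise GenerationError(f"n_cells must be >= 1, got {n_cells}")
    comp = tuple(float(f) for f in composition)
    if any(not 0 <= f <= 1 for f in comp) or sum(comp) > 1 + 1e-9:
        raise GenerationError(f"infeasible composition {comp}: fractions must be "
                              "in [0, 1] and sum to <= 1")
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    pts = _sample_seed_points(rng, n_cells, image_size)
    polys = _voronoi_polygons(pts, image_size)
    traces = {f"cell{i:03d}": WaypointTrace(f"cell{i:03d}", verts)
              for i, verts in enumerate(polys)}
    shape = (image_size, image_size)
    paths = {cid: build_cell_path(tr, shape, pixel_size, channel_label)
             for cid, tr in traces.items()}
    border_cells = {cid for cid, tr in traces.items() if tr.touches_border(shape)}

    edges = _edge_registry(traces, image_size)
    for edge in edges.values():
        if not edge.on_boundary:
            _plan_edge(edge, comp)

    canvas = np.full(shape, float(noise.background_mean))
    if noise.background_sd > 0:
        canvas += rng.normal(0.0, noise.background_sd, shape)
    for edge in edges.values():
        for seg in edge.segments:
            _paint_segment(canvas, seg, noise.junction_intensity)
    image = IntensityImage(np.clip(np.rint(canvas), 0, 255).astype(np.uint8),
                           bit_depth=8, pixel_size=pixel_size,
                           channel_label=channel_label)

    rows = []
    for cid in sorted(traces):
        planned = {ph: 0 for ph in PHENOTYPES}
        for edge in edges.values():
            if cid not in edge.cells:
                continue
            for seg in edge.segments:
                planned[seg.phenotype] += seg.expected_length
        n_path = paths[cid].path_length_px
        row = {"cell_id": cid, "path_length_px": n_path,
               "border_cell": cid in border_cells}
        for ph in PHENOTYPES:
            row[f"planned_len_{ph}"] = planned[ph]
            row[f"planned_pct_{ph}"] = min(100.0, 100.0 * planned[ph] / n_path)
        rows.append(row)
    planned_df = pd.DataFrame(rows)

    truth = SyntheticGroundTruth(
        image_size=image_size, pixel_size=pixel_size, composition=comp,
        noise=noise, seed=seed, traces=traces, paths=paths,
        border_cells=border_cells, edges=edges, planned=planned_df,
    )
    return MonolayerSample(junction_image=image, traces=traces, truth=truth)


# ---------------------------------------------------------------------------
# permeated-region overlay

def _blob_pixels(spec: PRBlobSpec, size: int) -> np.ndarray:
    if spec.shape == "pixels":
        if spec.pixels is None:
            raise GenerationError("shape='pixels' requires an explicit pixel array")
        return np.asarray(spec.pixels, dtype=np.int64)
    r0, c0 = spec.center
    if spec.shape == "disk":
        rr, cc = _draw_disk((int(r0), int(c0)), spec.radius, shape=(size, size))
        return np.column_stack([rr, cc])
    if spec.shape == "rect":
        hr, hc = spec.half_size
        rr, cc = np.mgrid[max(0, r0 - hr):min(size, r0 + hr + 1),
                          max(0, c0 - hc):min(size, c0 + hc + 1)]
        return np.column_stack([rr.ravel(), cc.ravel()])
    raise GenerationError(f"unknown blob shape {spec.shape!r}")


def generate_pr_overlay(
    truth: SyntheticGroundTruth,
    pr_plan: list[PRBlobSpec],
    seed: int = 0,
    background_mean: float = 10.0,
    background_sd: float = 3.0,
) -> tuple[IntensityImage, pd.DataFrame]:
    """Render an avidin channel with planted PR blobs plus a truth table.

    Blobs are painted at 255 on a sub-threshold noisy background.
    Overlapping blobs merge into one PR in the truth table (area of the
    union, union of intended cell associations).  The table lists each
    planted PR's area, category, and planned border-overlap length per
    phenotype (border pixels within Chebyshev distance 1 of the PR, each
    counted once per associated cell sharing that border, mirroring the
    per-cell path profiling downstream).
    """
    from scipy import ndimage as ndi

    from .local_permeability import CATEGORY_NAMES

    size = truth.image_size
    rng = np.random.default_rng(seed)
    canvas = np.full((size, size), float(background_mean))
    if background_sd > 0:
        canvas += rng.normal(0.0, background_sd, (size, size))
    canvas = np.clip(np.rint(canvas), 0, 239)  # background strictly sub-threshold
    blob_px = [_blob_pixels(spec, size) for spec in pr_plan]
    union = np.zeros((size, size), dtype=bool)
    for px in blob_px:
        canvas[px[:, 0], px[:, 1]] = 255
        union[px[:, 0], px[:, 1]] = True
    image = IntensityImage(canvas.astype(np.uint8), bit_depth=8,
                           pixel_size=truth.pixel_size, channel_label="avidin")

    labels, n = ndi.label(union, structure=np.ones((3, 3), dtype=bool))
    # phenotype tag per planted border pixel; a continuous run also claims
    # the adjacent border pixel at each free end (its corridor spill-over),
    # but actual mark pixels take precedence over spill-over claims
    tag: dict[tuple[int, int], str] = {}
    for edge in truth.edges.values():
        for seg in edge.segments:
            if seg.phenotype == CONTINUOUS:
                for j in (seg.start - 1, seg.start + len(seg.pixels)):
                    if 0 <= j < len(edge.pixels):
                        r, c = edge.pixels[j]
                        tag.setdefault((int(r), int(c)), CONTINUOUS)
    for edge in truth.edges.values():
        for seg in edge.segments:
            for r, c in seg.pixels:
                tag[(int(r), int(c))] = seg.phenotype
    rows = []
    for lab in range(1, n + 1):
        comp_mask = labels == lab
        area = int(comp_mask.sum())
        cells: set[str] = set()
        for spec, px in zip(pr_plan, blob_px):
            if comp_mask[px[:, 0], px[:, 1]].any():
                cells |= set(spec.intended_cells)
        k = len(cells)
        category = "Multi" if k >= 5 else CATEGORY_NAMES.get(k, "Unassigned")
        near = ndi.binary_dilation(comp_mask, structure=np.ones((3, 3), dtype=bool))
        lengths = {ph: 0 for ph in PHENOTYPES}
        none_len = 0
        for edge in truth.edges.values():
            mult = len(edge.cells & cells)
            if mult == 0:
                continue
            on = near[edge.pixels[:, 0], edge.pixels[:, 1]]
            for r, c in edge.pixels[on]:
                ph = tag.get((int(r), int(c)))
                if ph is None:
                    none_len += mult
                else:
                    lengths[ph] += mult
        row = {"pr_id": lab, "area_px2": area, "category": category,
               "cells": ",".join(sorted(cells)), "planned_len_none": none_len}
        for ph in PHENOTYPES:
            row[f"planned_len_{ph}"] = lengths[ph]
        rows.append(row)
    table = pd.DataFrame(rows)
    return image, table


def make_pr_plan(
    truth: SyntheticGroundTruth,
    n_uni: int = 2,
    n_bi: int = 3,
    n_tri: int = 1,
    seed: int = 0,
    radius_range: tuple[float, float] = (9.0, 14.0),
) -> list[PRBlobSpec]:
    """Choose well-separated blob sites with unambiguous intended categories.

    Uni blobs sit deep inside one cell, Bi blobs on the midpoint of a long
    interior border, Tri blobs at an interior junction vertex shared by
    three cells.  Sites too close to uninvolved borders are rejected so the
    planted category matches what adjacency-based categorization should
    find; fewer blobs than requested may be returned on crowded layouts.
    """
    rng = np.random.default_rng(seed)
    clearance = 4.0  # adjacency radius + raster slack
    edge_lines = {k: LineString([k[0], k[1]]) for k in truth.edges}
    specs: list[PRBlobSpec] = []
    placed: list[tuple[np.ndarray, float]] = []

    def _ok(center: np.ndarray, radius: float, involved: frozenset[str]) -> bool:
        for other_center, other_r in placed:
            if np.hypot(*(center - other_center)) < radius + other_r + 3:
                return False
        for key, edge in truth.edges.items():
            if edge.cells and edge.cells <= involved:
                continue
            if edge_lines[key].distance(Point(center)) < radius + clearance:
                return False
        return True

    # Uni: deep-interior points of interior cells
    cells = truth.interior_cells()
    rng.shuffle(cells)
    for cid in cells:
        if sum(s.shape != "pixels" and len(s.intended_cells) == 1 for s in specs) >= n_uni:
            break
        radius = float(rng.uniform(*radius_range))
        poly = _ShPolygon(truth.traces[cid].vertices)
        shrunk = poly.buffer(-(radius + clearance))
        if shrunk.is_empty:
            continue
        pt = shrunk.representative_point()
        center = np.array([pt.x, pt.y])
        if _ok(center, radius, frozenset({cid})):
            specs.append(PRBlobSpec(center=(int(round(center[0])), int(round(center[1]))),
                                    intended_cells=frozenset({cid}), radius=radius))
            placed.append((center, radius))

    # Bi: midpoints of long interior borders
    bi_edges = [e for e in truth.edges.values()
                if len(e.cells) == 2 and not e.on_boundary]
    rng.shuffle(bi_edges)
    got_bi = 0
    for edge in bi_edges:
        if got_bi >= n_bi:
            break
        radius = float(rng.uniform(*radius_range))
        if len(edge.pixels) < 2 * (radius + clearance):
            continue
        center = edge.pixels[len(edge.pixels) // 2].astype(np.float64)
        if _ok(center, radius, edge.cells):
            specs.append(PRBlobSpec(center=(int(center[0]), int(center[1])),
                                    intended_cells=edge.cells, radius=radius))
            placed.append((center, radius))
            got_bi += 1

    # Tri: interior vertices shared by three cells
    vertex_cells: dict[tuple[int, int], set[str]] = {}
    for edge in truth.edges.values():
        for v in edge.key:
            vertex_cells.setdefault(v, set()).update(edge.cells)
    tri_vs = [(v, c) for v, c in vertex_cells.items() if len(c) == 3]
    rng.shuffle(tri_vs)
    got_tri = 0
    for v, involved in tri_vs:
        if got_tri >= n_tri:
            break
        radius = float(rng.uniform(radius_range[0], radius_range[0] + 2))
        center = np.array(v, dtype=np.float64)
        if _ok(center, radius, frozenset(involved)):
            specs.append(PRBlobSpec(center=v, intended_cells=frozenset(involved),
                                    radius=radius))
            placed.append((center, radius))
            got_tri += 1
    return specs
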