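"""Independent reference implementations used as test oracles.

These deliberately avoid scipy.ndimage / skimage so that the library code
they check is exercised against a different algorithmic route: breadth-first
flood fill and two-pass union-find for connected components, explicit
per-pixel loops for raster ops, ray-casting for polygon area, and the
closed-form normal equations for the least-squares line.
"""

from __future__ import annotations

import numpy as np


def flood_fill_components(mask: np.ndarray) -> list[frozenset[tuple[int, int]]]:
    """8-connected components by BFS flood fill."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            stack = [(r0, c0)]
            seen[r0, c0] = True
            comp = set()
            while stack:
                r, c = stack.pop()
                comp.add((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] \
                                and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            comps.append(frozenset(comp))
    return comps


def union_find_components(mask: np.ndarray) -> list[frozenset[tuple[int, int]]]:
    """8-connected components by classic two-pass union-find labeling."""
    h, w = mask.shape
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    labels = np.zeros((h, w), dtype=np.int64)
    nxt = 1
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            neigh = []
            for dr, dc in ((-1, -1), (-1, 0), (-1, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and labels[rr, cc]:
                    neigh.append(labels[rr, cc])
            if not neigh:
                labels[r, c] = nxt
                parent[nxt] = nxt
                nxt += 1
            else:
                lab = min(neigh)
                labels[r, c] = lab
                for other in neigh:
                    union(lab, other)
    comps: dict[int, set] = {}
    for r in range(h):
        for c in range(w):
            if labels[r, c]:
                comps.setdefault(find(labels[r, c]), set()).add((r, c))
    return [frozenset(s) for s in comps.values()]


def chebyshev_covered_indices(
    comp: frozenset[tuple[int, int]], path_pixels: np.ndarray, radius: int
) -> frozenset[int]:
    """Path indices within Chebyshev `radius` of the component (brute force)."""
    comp_arr = np.array(sorted(comp))
    out = set()
    for i, (r, c) in enumerate(path_pixels):
        d = np.abs(comp_arr - np.array([r, c])).max(axis=1).min()
        if d <= radius:
            out.add(i)
    return frozenset(out)


def point_in_polygon_count(vertices: np.ndarray, shape: tuple[int, int],
                           extra_pixels: np.ndarray | None = None) -> int:
    """Pixels inside a polygon by even-odd ray casting, plus extra pixels.

    A pixel counts when its (row, col) centre is strictly inside under the
    even-odd rule; `extra_pixels` (e.g. the rasterized perimeter) are
    unioned in, matching an interior-plus-boundary area definition.
    """
    return len(pixels_inside_polygon(vertices, shape, extra_pixels))


def convex_hull_pixel_count(pixel_set: set[tuple[int, int]],
                            shape: tuple[int, int]) -> int:
    """Pixels inside the convex hull of a pixel region, by ray casting.

    Pixels are treated as unit squares (hull of their corners), matching
    the filled-hull convex-area definition; membership of each candidate
    pixel centre is tested with the same even-odd rule as
    `point_in_polygon_count`.
    """
    from scipy.spatial import ConvexHull

    corners = []
    for r, c in pixel_set:
        corners += [(r - 0.5, c - 0.5), (r - 0.5, c + 0.5),
                    (r + 0.5, c - 0.5), (r + 0.5, c + 0.5)]
    corners = np.array(corners)
    hull_vertices = corners[ConvexHull(corners).vertices]
    return point_in_polygon_count(hull_vertices, shape)


def pixels_inside_polygon(vertices: np.ndarray, shape: tuple[int, int],
                          extra_pixels: np.ndarray | None = None
                          ) -> set[tuple[int, int]]:
    """The pixel set behind `point_in_polygon_count` (even-odd rule)."""
    v = vertices.astype(np.float64)
    n = len(v)
    inside = set()
    rmin, rmax = int(v[:, 0].min()), int(np.ceil(v[:, 0].max()))
    cmin, cmax = int(v[:, 1].min()), int(np.ceil(v[:, 1].max()))
    for r in range(max(0, rmin), min(shape[0], rmax + 1)):
        for c in range(max(0, cmin), min(shape[1], cmax + 1)):
            cnt = False
            for i in range(n):
                r1, c1 = v[i]
                r2, c2 = v[(i + 1) % n]
                if (r1 > r) != (r2 > r):
                    x = c1 + (r - r1) * (c2 - c1) / (r2 - r1)
                    if c < x:
                        cnt = not cnt
            if cnt:
                inside.add((r, c))
    if extra_pixels is not None:
        inside |= {(int(r), int(c)) for r, c in extra_pixels}
    return inside


def ols_line(points: np.ndarray) -> tuple[float, float]:
    """Slope/intercept from the closed-form normal equations."""
    x, y = points[:, 0], points[:, 1]
    n = len(x)
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return float(slope), float(intercept)
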