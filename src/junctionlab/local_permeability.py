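"""Permeated-region detection, categorization and junction profiling.

In the local-permeability assay a fluorescent tracer (FITC-avidin) binds
the biotinylated matrix wherever the monolayer leaks, producing bright
*permeated regions* (PRs) in the avidin channel.  This module:

* binarizes the (8-bit converted) avidin channel at an inclusive threshold
  of 240 and labels 8-connected PRs;
* categorizes each PR by the number of cells it is associated with
  (Uni / Bi / Tri / Quad / Multi for 1 / 2 / 3 / 4 / 5+ cells), a cell
  being associated when the PR touches its filled interior or comes within
  a small Chebyshev radius of its perimeter path;
* profiles the junction phenotypes along the stretch of cell path that
  overlaps each sufficiently large PR (strictly greater than 400 px^2);
* computes per-phenotype co-localization, 100 * A_PR / A_total, the share
  of a phenotype's junction pixel area that falls inside PR footprints.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .cell_geometry import CellPath, WaypointTrace, fill_cell
from .errors import ShapeError
from .imaging_io import BinaryMask, IntensityImage, apply_threshold, to_uint8
from .junction_phenotyping import (
    CODE_PHENOTYPE,
    NONE_CODE,
    PHENOTYPE_CODE,
    PHENOTYPES,
    JunctionCoverage,
)

#: Default inclusive binarization threshold for the avidin channel (8-bit).
PR_THRESHOLD = 240
#: PRs must exceed this area (px^2), strictly, to be path-profiled.
PR_MIN_PROFILE_AREA = 400

CATEGORY_NAMES = {1: "Uni", 2: "Bi", 3: "Tri", 4: "Quad"}
CATEGORIES = ("Uni", "Bi", "Tri", "Quad", "Multi")
UNASSIGNED = "Unassigned"

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class PermeatedRegion:
    """One 8-connected component of the binarized avidin channel."""

    pr_id: int
    pixel_set: np.ndarray  # (m, 2) (row, col)
    image_shape: tuple[int, int]
    associated_cell_ids: frozenset[str] | None = None
    category: str | None = None

    @property
    def area_px2(self) -> int:
        return len(self.pixel_set)


@dataclass(frozen=True)
class TracedCell:
    """A cell path plus its filled interior mask, for PR association tests."""

    path: CellPath
    filled: np.ndarray  # bool mask, interior + path

    @classmethod
    def from_trace(cls, trace: WaypointTrace, path: CellPath) -> "TracedCell":
        return cls(path=path, filled=fill_cell(trace, path))

    @property
    def cell_id(self) -> str:
        return self.path.cell_id


@dataclass(frozen=True)
class PRPathProfile:
    """Junction composition of the cell-path stretch overlapping one PR.

    Lengths are path pixels summed over all associated cells (a border
    shared by two cells contributes once per cell, as each cell's path is
    traced).  Phenotype lengths plus the no-junction length equal the PR
    path length exactly.
    """

    pr_id: int
    pr_path_length: int
    phenotype_lengths: dict[str, int]
    phenotype_counts: dict[str, int]
    no_junction_length: int
    no_junction_count: int

    def pct(self, phenotype: str) -> float:
        if self.pr_path_length == 0:
            return 0.0
        if phenotype == "none":
            return 100.0 * self.no_junction_length / self.pr_path_length
        return 100.0 * self.phenotype_lengths[phenotype] / self.pr_path_length


@dataclass(frozen=True)
class ColocalizationResult:
    """Share of one phenotype's junction area lying inside PR footprints."""

    phenotype: str
    a_total: int
    a_pr: int

    @property
    def pct_colocalization(self) -> float | None:
        """100 * A_PR / A_total, or None when the phenotype is absent."""
        if self.a_total == 0:
            return None
        return 100.0 * self.a_pr / self.a_total


def detect_permeated_regions(
    avidin: IntensityImage, threshold: float = PR_THRESHOLD
) -> list[PermeatedRegion]:
    """Label permeated regions in the avidin channel.

    16-bit input is first converted to 8-bit (min-max rescale); the mask is
    intensity >= threshold and components are 8-connected.  No size filter
    is applied at detection time.
    """
    img8 = to_uint8(avidin)
    mask = apply_threshold(img8, threshold)
    labels, n = ndi.label(mask.pixels, structure=_STRUCT8)
    prs = []
    for lab in range(1, n + 1):
        comp = np.column_stack(np.nonzero(labels == lab))
        prs.append(PermeatedRegion(pr_id=lab, pixel_set=comp, image_shape=img8.shape))
    return prs


def categorize_pr(
    pr: PermeatedRegion,
    cells: list[TracedCell],
    adjacency_radius: int = 2,
) -> PermeatedRegion:
    """Count associated cells and map the count to a PR category.

    A cell is associated when any PR pixel lies in its filled interior or
    within Chebyshev distance ``adjacency_radius`` of its path.  Counts
    1/2/3/4 map to Uni/Bi/Tri/Quad, five or more to Multi; a PR touching no
    traced cell is flagged "Unassigned" and excluded from category
    summaries.
    """
    rr, cc = pr.pixel_set[:, 0], pr.pixel_set[:, 1]
    associated = set()
    for cell in cells:
        if cell.filled[rr, cc].any():
            associated.add(cell.cell_id)
            continue
        near = _near_path_mask(cell, adjacency_radius)
        if near[rr, cc].any():
            associated.add(cell.cell_id)
    k = len(associated)
    if k == 0:
        category = UNASSIGNED
    elif k >= 5:
        category = "Multi"
    else:
        category = CATEGORY_NAMES[k]
    return replace(pr, associated_cell_ids=frozenset(associated), category=category)


def _near_path_mask(cell: TracedCell, radius: int) -> np.ndarray:
    """Boolean mask of pixels within Chebyshev `radius` of the cell path."""
    mask = np.zeros(cell.path.image_shape, dtype=bool)
    mask[cell.path.path_pixels[:, 0], cell.path.path_pixels[:, 1]] = True
    if radius > 0:
        mask = ndi.binary_dilation(mask, structure=np.ones((2 * radius + 1,) * 2))
    return mask


def _pr_mask(pr: PermeatedRegion, radius: int) -> np.ndarray:
    mask = np.zeros(pr.image_shape, dtype=bool)
    mask[pr.pixel_set[:, 0], pr.pixel_set[:, 1]] = True
    if radius > 0:
        mask = ndi.binary_dilation(mask, structure=np.ones((2 * radius + 1,) * 2))
    return mask


def profile_pr_path(
    pr: PermeatedRegion,
    cells: list[TracedCell],
    coverages: dict[str, JunctionCoverage],
    min_area: int = PR_MIN_PROFILE_AREA,
    overlap_radius: int = 1,
) -> PRPathProfile | None:
    """Junction phenotype lengths/counts along the PR-overlapping cell path.

    Returns None for PRs with area <= min_area (the inclusion rule is
    strictly greater than 400 px^2), signalling absence rather than
    zero-filling.  The PR path is the set of path pixels of associated
    cells within Chebyshev distance ``overlap_radius`` of the PR; each such
    pixel contributes the phenotype it was assigned in the per-cell
    coverage step, or "no junction" when unassigned.  Piece counts are
    distinct pieces intersecting the PR path; no-junction counts are
    maximal unassigned runs along it.
    """
    if pr.area_px2 <= min_area:
        return None
    if pr.associated_cell_ids is None:
        raise ValueError("PR must be categorized before profiling")
    near_pr = _pr_mask(pr, overlap_radius)
    total = 0
    lengths = {ph: 0 for ph in PHENOTYPES}
    nj_len = 0
    nj_count = 0
    piece_keys: dict[str, set] = {ph: set() for ph in PHENOTYPES}
    for cell in cells:
        if cell.cell_id not in pr.associated_cell_ids:
            continue
        cov = coverages.get(cell.cell_id)
        if cov is None:
            continue
        px = cell.path.path_pixels
        on_pr = near_pr[px[:, 0], px[:, 1]]
        idxs = np.nonzero(on_pr)[0]
        if idxs.size == 0:
            continue
        total += int(idxs.size)
        codes = cov.path_assignment[idxs]
        for ph in PHENOTYPES:
            sel = codes == PHENOTYPE_CODE[ph]
            lengths[ph] += int(sel.sum())
            for pid in np.unique(cov.piece_assignment[idxs[sel]]):
                piece_keys[ph].add((cell.cell_id, int(pid)))
        nj_sel = codes == NONE_CODE
        nj_len += int(nj_sel.sum())
        nj_count += _count_runs(idxs[nj_sel], cov.path_length_px)
    return PRPathProfile(
        pr_id=pr.pr_id,
        pr_path_length=total,
        phenotype_lengths=lengths,
        phenotype_counts={ph: len(piece_keys[ph]) for ph in PHENOTYPES},
        no_junction_length=nj_len,
        no_junction_count=nj_count,
    )


def _count_runs(indices: np.ndarray, path_len: int) -> int:
    """Number of maximal runs of consecutive path indices (circularly)."""
    if indices.size == 0:
        return 0
    idx = np.sort(indices)
    breaks = int((np.diff(idx) > 1).sum())
    runs = breaks + 1
    # wrap-around: first and last indices adjacent on the closed path
    if runs > 1 and (idx[0] + path_len - idx[-1]) == 1:
        runs -= 1
    return runs


def compute_colocalization(
    phenotype_masks: dict[str, BinaryMask], pr_mask: BinaryMask
) -> list[ColocalizationResult]:
    """Per-phenotype co-localization with the PR footprint.

    For each phenotype mask, A_total is its true-pixel count, A_PR the
    pixels also inside the PR mask, and the percentage 100 * A_PR/A_total
    (undefined when the phenotype is absent from the image).  Phenotype
    masks must be pairwise disjoint.
    """
    shape = pr_mask.shape
    results = []
    stacked = np.zeros(shape, dtype=np.int32)
    for name, mask in phenotype_masks.items():
        if mask.shape != shape:
            raise ShapeError(f"mask {name!r} shape {mask.shape} != PR mask {shape}")
        stacked += mask.pixels
    if (stacked > 1).any():
        raise ShapeError("phenotype masks must be pairwise disjoint")
    for name, mask in phenotype_masks.items():
        a_total = mask.count()
        a_pr = int((mask.pixels & pr_mask.pixels).sum())
        results.append(ColocalizationResult(phenotype=name, a_total=a_total, a_pr=a_pr))
    return results


def summarize_prs(
    prs_by_image: dict[str, list[PermeatedRegion]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-image category counts and pooled per-category area statistics.

    Returns ``(counts, areas)``: counts has one row per image with the
    number of PRs in each category (Unassigned PRs excluded); areas has one
    row per category with mean, SEM and n of PR area pooled over all PRs of
    that category across images.
    """
    count_rows = []
    area_rows = {cat: [] for cat in CATEGORIES}
    for image_id in sorted(prs_by_image):
        row = {"image_id": image_id, **{cat: 0 for cat in CATEGORIES}}
        for pr in prs_by_image[image_id]:
            if pr.category in CATEGORIES:
                row[pr.category] += 1
                area_rows[pr.category].append(pr.area_px2)
        count_rows.append(row)
    counts = pd.DataFrame(count_rows, columns=["image_id", *CATEGORIES])
    stats = []
    for cat in CATEGORIES:
        areas = np.asarray(area_rows[cat], dtype=np.float64)
        n = areas.size
        mean = float(areas.mean()) if n else np.nan
        sem = float(areas.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        stats.append({"category": cat, "n": int(n), "mean_area_px2": mean,
                      "sem_area_px2": sem})
    return counts, pd.DataFrame(stats, columns=["category", "n", "mean_area_px2",
                                                "sem_area_px2"])
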