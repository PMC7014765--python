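"""Batch project processing: images + waypoint traces + config -> tidy tables.

A *project* is a directory of per-image channel files and waypoint tables
described by a YAML config.  ``run_project`` pushes every image through
junction phenotyping (per junction channel) and, when an avidin channel is
configured, through the permeated-region analysis, and writes delimited
tables ready for downstream statistics:

* ``cells.csv``       one row per fully-visible cell per junction channel
                      (morphology + coverage percentages and piece counts);
* ``prs.csv``         one row per PR per junction channel (area, category,
                      path-profile lengths/counts/percents);
* ``colocalization.csv``  per image x channel x phenotype A_total/A_PR/%;
* ``pr_summary_counts.csv`` / ``pr_summary_areas.csv``  category summaries;
* ``run_log.json``    config hash, package version, warnings, exclusions.

All tables are deterministic for a fixed project; rerunning an unchanged
project reproduces them byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cell_geometry import (
    build_cell_path,
    compute_morphology,
    project_path,
    read_waypoints,
    snap_waypoints,
)
from .errors import ConfigError
from .imaging_io import BinaryMask, load_channel
from .junction_phenotyping import (
    PHENOTYPES,
    compute_cell_coverage,
    classify_junction_piece,
    extract_junction_pieces,
    isolate_junction_mask,
)
from .local_permeability import (
    PR_MIN_PROFILE_AREA,
    PR_THRESHOLD,
    TracedCell,
    categorize_pr,
    compute_colocalization,
    detect_permeated_regions,
    profile_pr_path,
    summarize_prs,
)

logger = logging.getLogger("junctionlab")


@dataclass(frozen=True)
class ChannelSpec:
    label: str
    pattern: str  # filename pattern with {image_id}
    role: str  # junction | avidin | nuclei
    threshold: float | None = None


@dataclass(frozen=True)
class ProjectConfig:
    """Validated analysis configuration for one project directory."""

    channels: tuple[ChannelSpec, ...]
    images: tuple[str, ...]
    waypoints: str  # filename pattern with {image_id}
    pixel_size: float = 0.18
    corridor_radius: int = 1
    adjacency_radius: int = 2
    min_pr_area: int = PR_MIN_PROFILE_AREA
    smooth_sigma: float | None = None
    snap_radius: int = 0
    max_pr_area: int | None = None  # optional oversized-PR exclusion, off by default
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        junction = [c for c in self.channels if c.role == "junction"]
        avidin = [c for c in self.channels if c.role == "avidin"]
        if not junction:
            raise ConfigError("config defines no junction channel")
        for c in junction:
            if c.threshold is None:
                raise ConfigError(f"junction channel {c.label!r} has no threshold")
        if len(avidin) > 1:
            raise ConfigError("at most one avidin channel is allowed")
        if self.min_pr_area < 0:
            raise ConfigError(f"min_pr_area must be >= 0, got {self.min_pr_area}")

    @property
    def junction_channels(self) -> list[ChannelSpec]:
        return [c for c in self.channels if c.role == "junction"]

    @property
    def avidin_channel(self) -> ChannelSpec | None:
        av = [c for c in self.channels if c.role == "avidin"]
        return av[0] if av else None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProjectConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ProjectConfig":
        try:
            channels = tuple(
                ChannelSpec(label=label, pattern=spec["pattern"],
                            role=spec.get("role", "junction"),
                            threshold=spec.get("threshold"))
                for label, spec in raw["channels"].items()
            )
            return cls(
                channels=channels,
                images=tuple(raw["images"]),
                waypoints=raw["waypoints"],
                pixel_size=float(raw.get("pixel_size", 0.18)),
                corridor_radius=int(raw.get("corridor_radius", 1)),
                adjacency_radius=int(raw.get("adjacency_radius", 2)),
                min_pr_area=int(raw.get("min_pr_area", PR_MIN_PROFILE_AREA)),
                smooth_sigma=raw.get("smooth_sigma"),
                snap_radius=int(raw.get("snap_radius", 0)),
                max_pr_area=raw.get("max_pr_area"),
                seed=int(raw.get("seed", 0)),
                output_dir=str(raw.get("output_dir", "results")),
            )
        except KeyError as exc:
            raise ConfigError(f"config missing required key: {exc}") from exc

    def digest(self) -> str:
        payload = json.dumps(
            {
                "channels": [(c.label, c.pattern, c.role, c.threshold)
                             for c in self.channels],
                "images": list(self.images),
                "waypoints": self.waypoints,
                "pixel_size": self.pixel_size,
                "corridor_radius": self.corridor_radius,
                "adjacency_radius": self.adjacency_radius,
                "min_pr_area": self.min_pr_area,
                "smooth_sigma": self.smooth_sigma,
                "snap_radius": self.snap_radius,
                "max_pr_area": self.max_pr_area,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ResultBundle:
    """Tables produced by one project run."""

    cells: pd.DataFrame
    prs: pd.DataFrame | None
    colocalization: pd.DataFrame | None
    pr_summary_counts: pd.DataFrame | None
    pr_summary_areas: pd.DataFrame | None
    log: dict = field(default_factory=dict)


def run_project(
    config: ProjectConfig,
    project_dir: str | Path,
    overlays: bool = False,
) -> ResultBundle:
    """Process every image of a project through the full analysis."""
    project_dir = Path(project_dir)
    out_dir = project_dir / config.output_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {"config_hash": config.digest(), "version": __version__,
                 "warnings": [], "excluded_prs": []}

    cell_rows: list[dict] = []
    pr_rows: list[dict] = []
    coloc_rows: list[dict] = []
    prs_by_image: dict[str, list] = {}

    for image_id in config.images:
        wp_path = project_dir / config.waypoints.format(image_id=image_id)
        if not wp_path.exists():
            msg = f"{image_id}: waypoint table {wp_path.name} missing; image skipped"
            logger.warning(msg)
            log["warnings"].append(msg)
            continue
        traces = read_waypoints(wp_path)
        shape = None

        per_channel_masks: dict[str, BinaryMask] = {}
        per_channel_pieces: dict[str, dict[str, list]] = {}
        per_channel_cov: dict[str, dict] = {}
        cells_cache: dict[str, TracedCell] = {}

        for chan in config.junction_channels:
            img_path = project_dir / chan.pattern.format(image_id=image_id)
            image = load_channel(img_path, pixel_size=config.pixel_size,
                                 label=chan.label)
            shape = image.shape
            mask = isolate_junction_mask(image, threshold=chan.threshold,
                                         smooth_sigma=config.smooth_sigma)
            per_channel_masks[chan.label] = mask
            pieces_by_cell: dict[str, list] = {}
            cov_by_cell: dict[str, object] = {}
            for cid in sorted(traces):
                trace = traces[cid]
                if config.snap_radius > 0:
                    trace = snap_waypoints(trace, image, config.snap_radius)
                path = build_cell_path(trace, shape, config.pixel_size, chan.label)
                if cid not in cells_cache:
                    cells_cache[cid] = TracedCell.from_trace(trace, path)
                pieces = extract_junction_pieces(mask, path, config.corridor_radius)
                for p in pieces:
                    classify_junction_piece(p, path)
                cov = compute_cell_coverage(pieces, path)
                pieces_by_cell[cid] = pieces
                cov_by_cell[cid] = cov
                if trace.touches_border(shape):
                    continue  # partially visible cells excluded from per-cell table
                morph = compute_morphology(trace, path)
                row = {
                    "image_id": image_id, "cell_id": cid, "channel": chan.label,
                    "area_um2": morph.area_um2, "perimeter_um": morph.perimeter_um,
                    "circularity": morph.circularity, "solidity": morph.solidity,
                    "pct_continuous": cov.pct_continuous,
                    "pct_punctate": cov.pct_punctate,
                    "pct_perpendicular": cov.pct_perpendicular,
                    "pct_discontinuous": cov.pct_discontinuous,
                    "pct_total": cov.pct_total,
                }
                for ph in PHENOTYPES:
                    row[f"count_{ph}"] = cov.counts[ph]
                cell_rows.append(row)
            per_channel_pieces[chan.label] = pieces_by_cell
            per_channel_cov[chan.label] = cov_by_cell

        av = config.avidin_channel
        if av is not None and shape is not None:
            av_path = project_dir / av.pattern.format(image_id=image_id)
            if av_path.exists():
                avidin = load_channel(av_path, pixel_size=config.pixel_size,
                                      label=av.label)
                threshold = av.threshold if av.threshold is not None else PR_THRESHOLD
                prs = detect_permeated_regions(avidin, threshold)
                cells = list(cells_cache.values())
                prs = [categorize_pr(pr, cells, config.adjacency_radius) for pr in prs]
                if config.max_pr_area is not None:
                    kept = []
                    for pr in prs:
                        if pr.area_px2 > config.max_pr_area:
                            log["excluded_prs"].append(
                                {"image_id": image_id, "pr_id": pr.pr_id,
                                 "area_px2": pr.area_px2,
                                 "reason": f"area > max_pr_area={config.max_pr_area}"})
                        else:
                            kept.append(pr)
                    prs = kept
                prs_by_image[image_id] = prs
                pr_mask = np.zeros(shape, dtype=bool)
                for pr in prs:
                    pr_mask[pr.pixel_set[:, 0], pr.pixel_set[:, 1]] = True
                for chan in config.junction_channels:
                    cov_by_cell = per_channel_cov[chan.label]
                    for pr in prs:
                        profile = profile_pr_path(
                            pr, cells, cov_by_cell,
                            min_area=config.min_pr_area, overlap_radius=1)
                        row = {
                            "image_id": image_id, "pr_id": pr.pr_id,
                            "channel": chan.label, "area_px2": pr.area_px2,
                            "category": pr.category,
                            "associated_cell_ids": ",".join(
                                sorted(pr.associated_cell_ids or [])),
                            "profiled": profile is not None,
                        }
                        if profile is not None:
                            row["pr_path_length"] = profile.pr_path_length
                            for ph in PHENOTYPES:
                                row[f"len_{ph}"] = profile.phenotype_lengths[ph]
                                row[f"count_{ph}"] = profile.phenotype_counts[ph]
                                row[f"pct_{ph}"] = profile.pct(ph)
                            row["len_none"] = profile.no_junction_length
                            row["count_none"] = profile.no_junction_count
                            row["pct_none"] = profile.pct("none")
                        pr_rows.append(row)
                    phenotype_masks = _phenotype_masks(
                        per_channel_pieces[chan.label], shape)
                    for res in compute_colocalization(phenotype_masks,
                                                      BinaryMask(pr_mask)):
                        coloc_rows.append({
                            "image_id": image_id, "channel": chan.label,
                            "phenotype": res.phenotype, "a_total": res.a_total,
                            "a_pr": res.a_pr,
                            "pct_colocalization": res.pct_colocalization,
                        })
                if overlays:
                    _render_overlay(out_dir / f"{image_id}_overlay.png", shape,
                                    per_channel_pieces, pr_mask)

    cells_df = pd.DataFrame(cell_rows)
    prs_df = pd.DataFrame(pr_rows) if pr_rows else None
    coloc_df = pd.DataFrame(coloc_rows) if coloc_rows else None
    counts_df = areas_df = None
    if prs_by_image:
        counts_df, areas_df = summarize_prs(prs_by_image)

    cells_df.to_csv(out_dir / "cells.csv", index=False)
    if prs_df is not None:
        prs_df.to_csv(out_dir / "prs.csv", index=False)
    if coloc_df is not None:
        coloc_df.to_csv(out_dir / "colocalization.csv", index=False)
    if counts_df is not None:
        counts_df.to_csv(out_dir / "pr_summary_counts.csv", index=False)
        areas_df.to_csv(out_dir / "pr_summary_areas.csv", index=False)
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)

    return ResultBundle(cells=cells_df, prs=prs_df, colocalization=coloc_df,
                        pr_summary_counts=counts_df, pr_summary_areas=areas_df,
                        log=log)


def _phenotype_masks(pieces_by_cell: dict[str, list],
                     shape: tuple[int, int]) -> dict[str, BinaryMask]:
    """Union of piece pixels per phenotype (a shared-border piece counts once)."""
    masks = {ph: np.zeros(shape, dtype=bool) for ph in PHENOTYPES}
    for pieces in pieces_by_cell.values():
        for p in pieces:
            masks[p.phenotype][p.pixel_set[:, 0], p.pixel_set[:, 1]] = True
    # a component near two cells may classify differently per cell; give
    # contested pixels to a single phenotype (priority order) to keep the
    # co-localization masks disjoint
    order = list(PHENOTYPES)
    for i, ph in enumerate(order):
        for other in order[i + 1:]:
            masks[other] &= ~masks[ph]
    return {ph: BinaryMask(m) for ph, m in masks.items()}


def _render_overlay(path: Path, shape, per_channel_pieces, pr_mask) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"continuous": (0.2, 0.4, 1.0), "punctate": (1.0, 0.2, 0.8),
              "perpendicular": (0.3, 0.9, 1.0)}
    rgb = np.zeros((*shape, 3))
    rgb[pr_mask] = (0.35, 0.35, 0.35)
    for pieces_by_cell in per_channel_pieces.values():
        for pieces in pieces_by_cell.values():
            for p in pieces:
                rgb[p.pixel_set[:, 0], p.pixel_set[:, 1]] = colors[p.phenotype]
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(rgb, interpolation="nearest")
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def export_regression_inputs(per_pr_table: pd.DataFrame) -> pd.DataFrame:
    """Long-format (PR area, series, percent, count) rows for line fitting.

    One row per profiled PR per series: the three phenotypes plus the
    discontinuous (punctate + perpendicular) and no-junction aggregates.
    Downstream regression (e.g. count vs PR area) is left to standard
    statistics tools.
    """
    profiled = per_pr_table[per_pr_table["profiled"]]
    rows = []
    for _, r in profiled.iterrows():
        base = {"image_id": r["image_id"], "pr_id": r["pr_id"],
                "channel": r["channel"], "area_px2": r["area_px2"]}
        for ph in PHENOTYPES:
            rows.append({**base, "series": ph, "pct": r[f"pct_{ph}"],
                         "count": r[f"count_{ph}"]})
        rows.append({**base, "series": "discontinuous",
                     "pct": r["pct_punctate"] + r["pct_perpendicular"],
                     "count": r["count_punctate"] + r["count_perpendicular"]})
        rows.append({**base, "series": "no_junction", "pct": r["pct_none"],
                     "count": r["count_none"]})
    return pd.DataFrame(rows)
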