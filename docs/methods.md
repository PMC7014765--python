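# Methods

This note records the measurement model implemented by `junctionlab`, the
defaults and why they were chosen, what the synthetic fixtures do and do
not emulate, and the numerical choices made where the procedure is
genuinely open.

## Cell paths and morphology

A cell is defined by an ordered waypoint polygon (≥ 3 vertices, simple,
inside the image). The *cell path* is its per-edge Bresenham
rasterization with shared endpoints deduplicated: a closed, ordered chain
of distinct pixels in which consecutive pixels are 8-neighbours. For
polygons whose edges touch at pixel resolution (needle-thin spikes) a
strictly 8-connected simple cycle may not exist; deduplication then keeps
the first visit and the walk can locally jump. Realistic cell traces and
all generated fixtures are fat enough that this never occurs.

Two length notions are deliberately kept separate:

- **path length in pixels** — the denominator of all coverage percentages
  and the unit of the continuous-junction criterion, which is stated in
  pixels;
- **Euclidean chain length** (axial step 1, diagonal step √2, times the
  pixel calibration) — the morphological perimeter `P`.

Area `A` counts interior plus boundary pixels (the traced perimeter
belongs to the cell); whether the upstream interactive tool uses a
shoelace or a filled-pixel area is not documented, and the filled-pixel
definition was chosen because it is consistent with the convex area, which
is necessarily pixel-based (`skimage.morphology.convex_hull_image`).
Circularity is `4πA/P²` and solidity `A/A_convex`. On a digitized disk of
radius 50 px circularity lands within ~5 % of 1; the residual is
rasterization bias of the chain-length perimeter, which is why the
disk-limit test uses a 10 % band.

Default calibration is 0.18 µm/px (60× oil objective; 15 px ≈ 2.7 µm),
always overridable per project.

An optional waypoint refinement (`snap_waypoints`) moves each vertex to
the brightest pixel within a ±2 px Chebyshev window. It is off by
default: the upstream tool's path "filtering" step is unspecified, so the
default pipeline takes traces literally.

## Junction phenotyping

Isolation thresholds are inclusive (signal ≥ threshold), with per-protein
defaults ZO-1 → 15, VE-cadherin → 5, claudin-5 → 5 on the 8-bit scale.
The comparison direction is not stated by the source protocol; the
lower-bound-inclusive convention of interactive threshold tools was
adopted. Optional Gaussian smoothing before thresholding is provided and
off by default.

"Coinciding with the path" is operationalized as Chebyshev distance ≤ 1
(the corridor radius, configurable): a supra-threshold 8-connected
component is a junction piece of a cell iff it enters the cell's corridor,
and the path pixels it covers are those within the same distance of the
component. One component stays one piece even if it leaves and re-enters
the corridor.

Classification applies two strict rules in order: `L_path > 15 px` ⇒
continuous; otherwise aspect ratio > 1.2 ⇒ perpendicular, else punctate.
The aspect ratio is measured in the rotated frame of the covered chord:
the tangent is the chord between the first and last covered path pixels
(shortest circular arc; neighbouring path pixels when only one is
covered), extents are `max − min + 1` of the piece-pixel projections onto
tangent and normal. Values exactly at a threshold fall to the lower class,
as the strict inequalities require.

Per-cell coverage assigns each path pixel to at most one piece — nearest
piece by Chebyshev distance, ties toward the larger piece, then the lower
piece id — so the four percentages (three phenotypes + none) sum to 100
exactly. Raising the isolation threshold can only shrink the mask, so
total coverage is monotone non-increasing in the threshold.

## Local permeability

The avidin channel is converted to 8-bit by observed min–max linear
rescaling (the original conversion ran in an interactive tool whose
display-range semantics are unrecorded; min–max is the reproducible
choice) and thresholded inclusively at 240. 8-connected components are
permeated regions; no size filter applies at detection.

Cell association is automated: a cell is associated with a PR when any PR
pixel lies in the cell's filled interior or within Chebyshev distance 2 of
its path (`adjacency_radius`, configurable). The radius reflects that
manual adjacency judgments tolerate small gaps. Counts 1/2/3/4/5+ map to
Uni/Bi/Tri/Quad/Multi; PRs touching no traced cell are flagged
"Unassigned" and excluded from category summaries.

Only PRs strictly larger than 400 px² are path-profiled. The PR path is
the set of path pixels of associated cells within Chebyshev distance 1 of
the PR, summed over cells — a border shared by two associated cells
contributes once per cell, since each cell's path is traced (mirroring
per-cell manual tracing of the overlap). Each PR-path pixel carries the
phenotype it received in the per-cell assignment, or "no junction";
lengths therefore conserve exactly (`Σ phenotype + no-junction = PR path
length`). Deep-interior (Uni) PRs can legitimately have a PR path of
length zero. Piece counts are distinct (cell, piece) pairs intersecting
the PR path; no-junction counts are maximal unassigned runs along it.
Absence of a profile (PR too small) is signalled as absence, never as
zeros. An optional maximum-area exclusion filter (off by default) removes
oversized Multi PRs from the tables and logs each exclusion.

Co-localization per phenotype is `100 · A_PR / A_total` over pixel areas
of the per-phenotype masks (pairwise disjoint by construction; a component
classified differently by two adjacent cells is resolved by fixed
phenotype priority) and is reported as undefined when a phenotype is
absent.

## Transwell permeability

`P_app = (V · C_abluminal) / (A · C_luminal · t)` in cm/s, the
single-time-point sink-condition form. The standard curve is an
ordinary-least-squares line with free intercept (forcing through the
origin is not documented in the source protocol); it requires at least two
distinct fluorescence values. Membrane area is a required input — it is
insert-specific and never inferred.

## Synthetic monolayers

The generator emulates the *geometry and composition* of a confluent
monolayer, not its optics. Cells are Voronoi regions of uniformly sampled
seed points with a minimum-spacing rejection step (fat, convex-ish cells,
as in real endothelial monolayers), mirrored across the image edges so
every region is finite, clipped to the image and rounded to the pixel
grid. Cells touching the image edge are generated and traced but flagged:
per-cell statistics use only fully visible cells, while the PR stage uses
every trace.

Each unique border is planned and painted once, so adjacent cells see the
same marks. Per border, the target composition (default 40 % continuous,
10 % punctate, 5 % perpendicular of border length — a mid-range barrier
phenotype) is laid out as: one continuous run (> 15 px, painted on the
border pixels), punctate marks (3×3 discs, aspect 1) and perpendicular
bars (3 × 9 px, rotated to the border normal, aspect 3), each reserving
5 path px, separated by ≥ 3 px junction-free gaps and kept 2 px clear of
vertices so pieces never merge. The ground truth records each segment's
*expected measured* path coverage — including the 1 px corridor
spill-over at free ends of continuous runs — which is what makes
zero-noise recovery pixel-exact. Requested fractions that cannot be
packed onto short borders are planted short; the truth table records what
was actually planted, and recovery is always checked against the plan.
Noise is additive Gaussian background (default mean 5, sd 0) under fixed
supra-threshold paint (intensity 200); with increasing background sd,
spurious components appear and coverage error grows — the fixtures do not
emulate PSF blur, photobleaching, staining heterogeneity or out-of-focus
light, so passing recovery tests demonstrates correctness of the
measurement, not robustness to real microscopy artifacts.

PR blobs are painted at 255 on a sub-threshold background (clipped at
239). Overlapping blobs merge, and the truth table records the merged
component's union pixel count (what a connected-component area genuinely
is) with unioned cell associations. Planted categories come from blob
placement: deep-interior points (Uni), long-border midpoints (Bi) and
three-cell vertices (Tri), each with clearance from uninvolved borders so
the intended category is unambiguous; crowded layouts may yield fewer
blobs than requested.

## Problem sizes and determinism

Tests and the acceptance script run on 256–512 px images with 10–20 cells
per monolayer and a handful of planted PRs — large enough for every border
to carry multi-segment plans, small enough to keep the full suite in tens
of seconds. All randomness flows through `numpy.random.default_rng`
seeded from a single integer; identical seeds give bit-identical images,
tables and results.

## Known limitations

- Exact per-pixel parity with the original interactive tool cannot be
  guaranteed: its 8-bit display-range conversion, path filtering and
  piece-splitting behaviour are unrecorded. All such choices here are
  explicit and documented above.
- Whether a component that re-enters the corridor should split into
  multiple pieces is unknown; this implementation keeps one piece per
  component.
- Statistical comparisons across conditions (rank tests, regressions) are
  out of scope by design: the pipeline emits tidy long-format tables for
  standard statistics environments.
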