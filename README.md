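# junctionlab

Quantitative cell–cell junction phenotyping and local barrier-permeability
analysis for endothelial monolayers.

## The problem

The paracellular tightness of endothelial barriers — most prominently the
blood–brain barrier — is set by tight- and adherens-junction proteins
(ZO-1, VE-cadherin, claudin-5) at the borders between cells.
Immunofluorescence shows not just *how much* junction protein sits at a
border but *how* it is organized: mature barriers present junction signal
running **continuously** along the border, while immature or remodeling
borders show **punctate** fragments or **perpendicular** strands crossing
the border. `junctionlab` turns these qualitative descriptions into
per-cell numbers and links them to permeability measured both globally
(Transwell tracer flux) and locally (a biotin–avidin leak assay that marks
*permeated regions* of the monolayer).

## The method

**Junction phenotyping.** Each cell is traced as a waypoint polygon and
rasterized into a closed 8-connected pixel chain, the *cell path*. The
junction channel is binarized at a per-protein intensity threshold
(defaults: ZO-1 → 15, VE-cadherin → 5, claudin-5 → 5 on the 8-bit scale)
and its 8-connected components that coincide with the path (Chebyshev
corridor, radius 1 px) become *junction pieces*. Each piece is classified
with strict rules:

- covered path length `L_path > 15 px` → **continuous**;
- otherwise, aspect ratio (extent along the local path normal / extent
  along the tangent) `> 1.2` → **perpendicular**, else **punctate**.

Per cell, every path pixel is assigned to at most one piece (nearest wins)
so that `%continuous + %punctate + %perpendicular + %none = 100`.
Morphology accompanies each cell: area `A`, perimeter `P`, circularity
`4πA/P²`, and solidity `A/A_convex`.

**Local permeability.** The avidin leak channel is converted to 8-bit and
thresholded at 240; each 8-connected component is a permeated region (PR).
PRs are categorized Uni/Bi/Tri/Quad/Multi by the number of adjacent cells
(1/2/3/4/5+). For PRs larger than 400 px² (strictly), the junction
composition of the PR-overlapping cell path is profiled, and per-phenotype
co-localization is computed as `100 · A_PR / A_total`.

**Global permeability.** The Transwell apparent permeability coefficient is

```
P_app = (V · C_abluminal) / (A · C_luminal · t)    [cm/s]
```

with abluminal concentrations read off an ordinary-least-squares
fluorescence standard curve.

A synthetic monolayer generator (Voronoi cells with planted phenotype
segments and PR blobs) provides fully known ground truth for every metric.

## Worked example

```python
from junctionlab import (generate_monolayer, isolate_junction_mask,
                         extract_junction_pieces, compute_cell_coverage,
                         compute_morphology)

sample = generate_monolayer(n_cells=20, image_size=512,
                            composition=(0.4, 0.1, 0.05), seed=0)
mask = isolate_junction_mask(sample.junction_image, threshold=15)
cid = sample.truth.interior_cells()[0]
path = sample.truth.paths[cid]
cov = compute_cell_coverage(extract_junction_pieces(mask, path, 1), path)
morph = compute_morphology(sample.traces[cid], path)
```

prints, for the first fully visible cell:

```
cell000: area 387.6 um^2, circularity 0.699, solidity 0.985
  continuous 39.8%  punctate 11.4%  perpendicular 3.8%  none 44.9%
```

i.e. ~40 % of this cell's border carries mature continuous junction and
~15 % discontinuous (punctate + perpendicular) signal — matching the 40/10/5
composition this monolayer was generated with. Running the planted avidin
channel through the PR stage prints, per region:

```
  PR 1: 553 px^2, Bi, profiled: path 50 px, 96% no junction
  PR 2: 261 px^2, Uni, below 400 px^2
  ...
```

a bi-cellular leak of 553 px² whose overlapping border is almost entirely
junction-free — the local-permeability signature the method is built to
detect.

The same analysis runs from the shell on a project directory of TIFFs,
waypoint tables and a YAML config:

```
junctionlab simulate --out demo --n-cells 20 --seed 0
junctionlab analyze --config demo/config.yaml
```

which writes `cells.csv`, `prs.csv`, `colocalization.csv`, PR category
summaries and a run log under `demo/results/`.

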