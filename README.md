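# osteogrid

Whole-bone cortical and trabecular microarchitecture analysis for
micro-CT volumes of short bones, with synthetic bone phantoms for
validation. The design case is the primate capitate (the central wrist
bone): a thin, porous cortical shell enclosing a trabecular lattice, with
no medullary canal to separate the two compartments for you.

The package is aimed at comparative skeletal biologists who want the full
chain — segmentation, cortical/trabecular compartmentalisation,
grid-sphere morphometry, proximal/distal regional ratios, and the
nonparametric + allometric statistical battery — as tested, reusable
library code rather than a chain of GUI tools.

## What it computes

Per specimen, per region (whole bone / proximal VOI / distal VOI):

| parameter | definition |
|---|---|
| trabecular BV/TV | trabecular bone voxels / (trabecular + marrow) voxels |
| total BV/TV | all bone voxels / enclosed-volume voxels |
| DA | 1 − (smallest / largest mean-intercept-length ellipsoid semi-axis) |
| Tb.Th, Ct.Th | mean maximal-inscribed-sphere diameter of the trabecular / cortical bone phase |
| Tb.Sp | the same sphere measure on the marrow phase |
| Tb.N | 1 / (Tb.Th + Tb.Sp), per mm |

Trabecular parameters are sampled by a sphere (default 5 mm diameter)
moving over a background grid (default 2.5 mm node spacing) and averaged
per region. Compartments come from ray casting onto the periosteal
surface plus morphological closing sized by the average trabecular
thickness, with the pores kept inside the cortex so porosity stays
measurable. Statistics: Kruskal–Wallis + Holm-adjusted pairwise Wilcoxon
rank-sum across groups, Wilcoxon signed-rank on distal:proximal ratios,
and reduced major axis (RMA) regression of each log parameter on the log
cube-root bone volume with classification into Positive / Negative /
Isometry / Uncorrelated against the parameter's isometric slope (0 for
shape-like, 1 for size-like parameters).

Because comparative micro-CT collections are not redistributable, the
`phantoms` module generates capitate-like synthetic bones — ellipsoidal
graded-thickness shells with carved pores around von Mises–Fisher
oriented rod lattices — with ground truth counted directly from the
generated volume, so every stage is testable against known answers.
See `docs/methods.md` for models, conventions and limitations.

## Worked example

```python
from osteogrid import phantoms as ph, pipeline as pl
from osteogrid.volume_io import SpecimenRecord

grey, truth, gt = ph.make_phantom(ph.PhantomSpec(seed=2))
cfg = pl.RunConfig.for_phantoms()          # grid/sphere scaled to phantom size
rec = SpecimenRecord("demo", "g", cut_plane_index=gt.cut_plane_index)
res = pl.run_specimen(cfg, rec, grey)
s = res.summaries["whole"]
print(f"trab BV/TV {s.trab_bvtv:.3f}  DA {s.da:.3f}  Tb.Th {s.tbth_mm:.3f} mm"
      f"  Tb.Sp {s.tbsp_mm:.3f} mm  Ct.Th {s.ctth_mm:.3f} mm")
```

prints (seed 2 phantom, ~20 s on one CPU):

```
trab BV/TV 0.159  DA 0.352  Tb.Th 0.167 mm  Tb.Sp 0.492 mm  Ct.Th 0.305 mm
```

The phantom was built with 0.12 mm rods on a 0.5 mm lattice inside a
0.35–0.6 mm shell: the measured Tb.Th sits just under the 0.24 mm rod
diameter (voxelization bias, documented in the methods note), Tb.Sp
reflects the lattice gaps, and Ct.Th the graded shell.

A full cohort analysis is the four numbered drivers:

```sh
python analysis/01_simulate_phantoms.py --seed 0     # phantom stacks + truth
python analysis/02_measure_specimens.py              # summaries, ratios, QC
python analysis/03_compare_groups.py                 # KW / Holm / signed-rank
python analysis/04_allometry.py                      # RMA tables + replay
```

Tables land under `results/`. The same chain is available as a console
tool (`osteogrid all --seed 0 --out results/run`).

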