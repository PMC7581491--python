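# octseg

Fully automatic retinal boundary segmentation for macular OCT volume
scans in Stargardt disease, pairing a **fully semantic segmentation
network** with **graph-search boundary delineation**, plus the clinical
evaluation layer (boundary errors, ETDRS thickness/volume,
Bland–Altman) and a ground-truthed **synthetic OCT phantom generator**
so the whole pipeline is testable without clinical data.

## Who this is for

Stargardt disease (ABCA4 maculopathy) produces outer-retinal and RPE
atrophy, hyperreflective flecks and Bruch's membrane disruption that
defeat the segmentation built into commercial OCT software, forcing
graders to correct boundaries by hand before retinal thickness or
macular volume can be tracked. `octseg` is aimed at reading-centre /
research users who need reproducible, per-column delineation of the two
boundaries that define total retinal thickness: the internal limiting
membrane (ILM) and the RPE base (Bruch's membrane where the RPE is
absent).

## Method

1. **Preprocessing** — per-A-scan attenuation-compensating contrast
   enhancement, `E(i,j) = I(i,j)^n / (2 Σ_{k≥i} I(k,j)^n + ε)`, and 16
   rows of zero padding at the image top.
2. **Semantic network** — a U-Net-style encoder–decoder classifying
   each pixel into vitreous+padding / retina / choroid+sclera. Each
   level is a residual block of three `conv 3×3 → BN → ReLU` units
   (first and last outputs added), 8 filters at the first level doubled
   after each of 4 (or 5) 2×2 max-pools, optional concurrent
   spatial & channel squeeze-and-excitation (scSE) at every level, 50%
   bottleneck dropout, 1×1 conv + softmax head. Trained with Adam on
   soft Dice loss, batch size 3, per-epoch reshuffling and on-the-fly
   augmentation (flip / Gaussian noise with variance ~ U[250, 1000]);
   the epoch with the best hard validation Dice is kept. The effective
   receptive field is 202×202 px for the 4-pool variant and 410×410 px
   for the 5-pool variant. Layers run on a small NumPy reverse-mode
   autodiff engine (`octseg.nn`) — no GPU or external DL framework
   required.
3. **Graph search** — each boundary gets an edge map (positive row-wise
   rise of the cumulative class probability); pixels form a
   left-to-right graph with 3-neighbour connectivity and edge weight
   `w(s,d) = 2 − (p_s + p_d)`; the minimum-cost corner-to-corner path
   (Dijkstra-equivalent column sweep) is the predicted boundary.
4. **Cohorting & ensembling** — participants are split into low/high
   macular-volume groups at the cohort median; k-fold training rotates
   one validation participant per group. Fold networks are combined
   either by averaging their boundary-error tables (*average*) or by
   per-pixel majority vote of their label maps followed by a single
   graph search (*ensemble*).
5. **Evaluation** — boundary MAE / signed mean error in pixels
   (positive = prediction below the truth), hard Dice overlap, ETDRS
   9-subfield mean thickness and volume over the central 6 mm disc,
   and Bland–Altman limits of agreement (±1.96 SD).

## Worked example

```python
import numpy as np
from octseg import (PhantomConfig, NetConfig, receptive_field,
                    generate_boundary_surfaces)
from octseg.phantom import ground_truth_boundaries, gt_macular_volume_mm3
from octseg.preprocess import boundaries_to_regions
from octseg.graphsearch import extract_boundaries
from octseg.metrics import thickness_map, etdrs_stats

print(receptive_field(NetConfig(n_pool=4)), receptive_field(NetConfig(n_pool=5)))
# 202 410

cfg = PhantomConfig(atrophy_severity=0.6)          # desk-scale phantom
surf = generate_boundary_surfaces(cfg, rng_seed=7)
b = ground_truth_boundaries(surf, scan_index=7)
labels = boundaries_to_regions(b, cfg.height_px, cfg.width_px)
rec = extract_boundaries(labels, pad_rows=0)       # graph search on ideal map
print(np.abs(rec.ilm_rows - np.floor(b.ilm_rows)).max())
# 0.0                                              # exact recovery

bnds = [ground_truth_boundaries(surf, s) for s in range(cfg.n_slices)]
tm = thickness_map(bnds, cfg.axial_res_um, cfg.lateral_res_um,
                   cfg.scan_spacing_um)
print(etdrs_stats(tm).to_string(index=False))
```

The ETDRS table printed by the last line (values in µm and mm³; this
phantom has a severity-0.6 atrophy lesion, hence the thinned subfields):

```
      subfield  mean_thickness_um  volume_mm3  n_cells
       central         236.361734    0.193580       70
inner_superior         320.479229    0.517446      138
   inner_nasal         349.497237    0.560209      137
inner_inferior         344.511488    0.556248      138
inner_temporal         284.667337    0.456293      137
outer_superior         372.367208    1.934373      444
   outer_nasal         389.048769    2.052894      451
outer_inferior         387.419792    2.012568      444
outer_temporal         339.549697    1.791702      451
         total         357.318641   10.075314     2410
```

The central subfield is thinnest (foveal pit) and the nine subfield
volumes sum exactly to the 6 mm-disc total.

### Command line

```bash
octseg simulate --out ds --n-participants 12 --seed 0
octseg train    --dataset ds --out models --epochs 20 --folds 2 --runs 1
octseg predict  --dataset ds --checkpoints models --out preds
octseg evaluate --dataset ds --pred preds --out report
```

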