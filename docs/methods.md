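# Methods

This note documents the models, conventions and design choices behind
`octseg`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic phantom does and does not
establish about real clinical data.

## 1. Problem and data model

A macular OCT volume is a stack of grayscale B-scans (rows = depth,
columns = lateral position). Total retinal thickness at a column is the
axial distance from the internal limiting membrane (ILM) to the base of
the RPE — or Bruch's membrane where the RPE is atrophic — and macular
volume is thickness integrated over the central 6 mm-diameter zone.
Clinical geometry: 1536×496 px B-scans at 5.7 µm/px lateral and
3.9 µm/px axial (8.8 × 1.9 mm per scan), 61 scans per volume at 119 µm
spacing. Boundaries are stored per column as fractional pixel rows; a
`BoundarySet` also records the valid column range left by scan cleaning
(outside it, pixels are zeroed and boundary rows are repeated from the
nearest retained endpoint).

Region maps use three classes — 0 vitreous+padding, 1 retina,
2 choroid+sclera — and the rasterization convention that `floor(row)`
is the first image row of the region *below* the boundary. All
boundary/region round-trips and error metrics in the package are exact
under this convention, and predictions are therefore integer rows
compared against (possibly fractional) truth rows.

## 2. Preprocessing and augmentation

*Contrast enhancement.* Per A-scan (column) attenuation compensation
`E(i,j) = I(i,j)^n / (2 Σ_{k≥i} I(k,j)^n + ε)` with exponent `n = 2`
by default and `ε = 1e-8` guarding all-zero columns, followed by a
global rescale to [0, 255]. The compensation itself is strictly
column-local; the rescale applies one global constant, so no
cross-column structure is introduced. The exact constants of the
published attenuation-compensation filter this emulates are not fully
specified in our source; the exponent is therefore exposed as
configuration.

*Padding.* 16 rows of zeros at the top of every image (keeps all
network variants' pooled sizes integral and gives the graph search
headroom above the ILM); padding rows carry class 0.

*Augmentation.* When a sample is presented to the network, exactly one
of four equiprobable cases applies: unchanged, left–right flip, added
Gaussian noise, or flip + noise. Noise is zero-mean with variance drawn
uniformly from [250, 1000] on the 8-bit scale, re-drawn each
presentation, clipped to [0, 255]; flips mirror the boundary arrays,
noise never moves them. Noise is added *after* contrast enhancement:
enhancement is treated as a dataset-level preprocess and augmentation
as a training-time transform. (Whether noise should be applied to raw
or enhanced intensities is genuinely open; the pipeline applies it to
whatever representation feeds the network, and enhancement can be
switched off.)

## 3. Network family

U-Net-topology encoder–decoder, NCHW float32:

- **Level block**: `convs_per_level = 3` units of `conv 3×3 (same) →
  batch-norm → ReLU`; the outputs of the first and last units are added
  (residual connection). Batch-norm precedes ReLU; the residual add is
  taken *before* any scSE block so the recalibration acts on the
  level's final output.
- **Filters**: 8 at the first level, doubled after each 2×2 stride-2
  max-pool; `n_pool ∈ {4, 5}` pooling layers, mirrored decoder with 2×2
  stride-2 transposed-convolution upsampling (nearest-neighbour + conv
  available by config) and skip concatenation.
- **scSE** (optional, per level): channel path = global average pool →
  FC(C→C/r) → ReLU → FC(C/r→C) → sigmoid channel gates; spatial path =
  1×1 conv → sigmoid spatial gates; combined element-wise by maximum
  (sum available by config). Reduction ratio r = 2, clamped to 1 when
  C < r. The combination operator and ratio are package choices; the
  block's original formulation uses independent recalibration of both
  axes with an element-wise merge.
- **Head**: 50% dropout at the bottleneck, 1×1 conv to 3 classes,
  softmax. Spatial size is preserved end to end; inputs must be
  divisible by `2^n_pool` (the padding guarantees this for the bundled
  geometries).

*Effective receptive field.* Iterating `r ← r + (k−1)·j` (j = cumulative
stride product; each pool adds `j` and doubles `j`) over three 3×3
convs per encoder level, a pool per level, and three bottleneck convs
gives 202 px for `n_pool = 4` and 410 px for `n_pool = 5`.

*Loss.* Soft Dice, `L = 1 − mean_c (2 Σ p_c t_c + ε)/(Σ p_c + Σ t_c + ε)`
with `ε = 1e-6`; a class absent from both prediction and truth
contributes Dice 1 (perfect agreement on absence).

*Engine.* The layers run on a purpose-built NumPy reverse-mode autodiff
engine (`octseg.nn`): ~15 operations with hand-written adjoints,
convolutions as k² shifted GEMMs over the zero-padded input, Adam with
standard defaults (lr 1e-3, β = 0.9/0.999, ε = 1e-8), He-normal
initialization. Every adjoint is verified against central finite
differences in the test suite.

## 4. Training protocol

Participants are labelled "low"/"high" macular volume by the cohort
median of baseline ground-truth volumes (ties broken by participant id;
with an even cohort the split is exactly half/half). `make_folds`
rotates one validation participant per group per fold over sorted ids,
so with one fold per group member every participant validates at least
once; a participant's volumes never straddle train/validation. Defaults
follow the protocol the package implements: 100 epochs, batch size 3,
reshuffling every epoch, Adam defaults, model selection by the highest
hard (argmax) validation Dice averaged over the 3 classes, 6 folds,
5 repeated runs with seeds `base + 1000·run + fold` recorded in the
report. NaN loss aborts the run with a diagnostic.

Fold combination: *average* = arithmetic mean of the per-fold
boundary-error tables; *ensemble* = per-pixel majority vote over the
fold networks' argmax label maps, ties broken by the highest mean class
probability, then a single graph search on the voted map. Voting on
hard label maps is a deliberate operationalization: continuous
probability maps have no natural per-pixel mode. A consequence is that
the ensemble and average paths consume different map types (hard vs
soft); on clean maps — where all folds agree and probabilities are
saturated — the two coincide exactly, which is the property the tests
pin down.

## 5. Graph-search delineation

For each boundary an edge (boundary-probability) map is the positive
part of the row-wise rise of the probability of lying at or below the
boundary: `P(class ≥ 1)` for the ILM and `P(class = 2)` for the RPE.
Using the cumulative form (rather than the retina class alone) leaves
clean maps unchanged and makes the two boundary paths coincide in the
degenerate zero-thickness case. The first row has no rise by
definition; values are clipped to [0, 1].

Pixels are vertices in a left-to-right DAG connected to the three
rightmost neighbours; edge weight `w(s,d) = 2 − (p_s + p_d)` ≥ 0. A
dummy probability-1, vertically connected column on each side lets the
corner-to-corner path enter and exit at any row; analytically the dummy
columns reduce to an entry cost `1 − p(r, 0)` and exit cost
`1 − p(r, W−1)`. The printed form of this weight in our source reads
`2 − p_s + p_d`; that reading would penalize high-probability
destinations and contradict the stated interpretation of the shortest
path as the boundary, so the symmetric form is the default and the
literal form is retained behind `weight_form="literal"` for audit.

Because all edges point rightward the minimum-cost path is computed by
a column-sweep relaxation — exactly Dijkstra's result on this graph,
verified in tests against `scipy.sparse.csgraph.dijkstra` on the
explicit graph and against exhaustive path enumeration on small maps.
Tie-breaks are deterministic: horizontal predecessor preferred, then
diagonal-up, then diagonal-down, and the topmost end row among
equal-cost paths. Extraction subtracts the 16-row padding offset, and
predictions are defined at every column of the scan.

## 6. ETDRS statistics and agreement

Thickness = `(rpe_row − ilm_row) × axial_res`. En-face positions come
from column × lateral resolution and scan × scan spacing, centred on
the fovea (the phantom's pit centre; for real data the centre is a
required input, not estimated). The nine ETDRS subfields are the 1 mm
central disc and the inner (1–3 mm) and outer (3–6 mm) rings cut along
the ±45° diagonals; cells exactly on a diagonal belong to the
superior/inferior quadrants, "superior" is the −y (lower scan index)
half-plane, and nasal/temporal are resolved by an eye-laterality flag
(OD: nasal = +x). Cells are assigned by cell-centre membership with no
inter-scan interpolation — scan spacing dominates the discretization,
and with the bundled geometries the disc-area error stays below 1%.
Subfield volume = Σ thickness × cell area; by construction the nine
subfield volumes partition the 6 mm-disc total exactly. Bland–Altman
agreement reports the mean paired difference and limits of agreement at
±1.96 SD (n−1 denominator).

Boundary-error SDs are reported three ways (over pooled columns, over
per-scan mean errors, over per-scan MAEs) because the convention is not
standardized; the tables label all three.

## 7. Synthetic phantom

The phantom emulates what makes Stargardt OCT hard to segment, not
retinal reflectivity physics. Surfaces: the RPE follows low-frequency
cosine undulation; the ILM lies above it by a thickness field =
baseline − en-face Gaussian foveal pit − atrophy thinning. Atrophy
lesions are en-face Gaussians; at full severity a lesion removes
`MAX_ATROPHY_FRACTION = 0.45` of the baseline thickness (outer-retinal
loss), suppresses the bright RPE band toward retina intensity and
brightens the sub-RPE signal (hypertransmission). Rendering adds
hyperreflective flecks (Gaussian blobs in the outer retina),
multiplicative Gamma speckle with mean 1 and relative SD
`speckle_scale` (the standard multi-look OCT speckle model), and
columnar vessel shadows. An analytic bound on the combined surface
slope is validated at configuration time and kept ≤ 1 px/column because
the boundary graph moves at most one row per column step.

Default desk-scale geometry: 256×128 px, 15 slices, 26 µm lateral /
7.5 µm axial / 450 µm scan spacing, chosen so the volume covers the
6 mm ETDRS disc at roughly the clinical aspect ratio; baseline
thickness 390 µm, pit 150 µm deep (σ = 600 µm), RPE band 30 µm, layer
means (vitreous 25, retina 110, RPE 200, choroid 90, sclera 50 on the
8-bit scale), speckle scale 0.25. The full clinical geometry is
available via `PhantomConfig.paper_scale()`. Lesion morphology in
Stargardt disease is not quantified in our source; the phantom's
lesion knobs are free parameters chosen to look plausible at desk
scale, not calibrated to any clinical cohort.

Cohorts draw half the participants with mild severity (U[0, 0.2]) and
half severe (U[0.55, 0.9]) plus ±15 µm thickness jitter, so baseline
volumes straddle the median; group labels then come from the measured
median split. Consequently, passing the end-to-end test shows the
pipeline machinery is correct and trainable on layered, lesioned,
speckled images — it does *not* establish clinical accuracy: real
scans have texture, curvature, pathology diversity and grader noise the
phantom lacks, and the headline clinical error levels reported for this
class of method can only be measured on clinical data.

## 8. Problem sizes used in the bundled checks

The end-to-end check trains the default network (4 pools, 8 base
filters, scSE) on a 12-participant desk-scale cohort (1 volume × 6
scans each), 2 folds × 20 epochs, and evaluates on 4 held-out
participants; validation Dice > 0.95 and ensemble MAE < 1.5 px are
implementation-established sanity bounds on this synthetic cohort.
Property suites run the graph search against brute-force enumeration on
100 random maps up to 5×6, exact recovery on 20 seeded phantom slices,
and the ETDRS identities on the desk geometry. These sizes were chosen
as the smallest that exercise every pipeline stage meaningfully.

## 9. Known limitations

- The network engine is CPU-only and sized for desk-scale experiments;
  clinical-geometry training is possible but slow.
- Boundary extraction returns integer rows (no sub-pixel refinement),
  so even perfect maps carry a ≤ 1 px floor against fractional truths.
- ILM and RPE are delineated independently; ordering is enforced only
  by a final clamp, not by a joint search.
- The scSE combination operator and reduction ratio, the decoder
  upsampler, and the BN/residual ordering are package choices where the
  source architecture leaves them open; all are configurable.
- Intra-retinal sublayers, proprietary scanner formats and
  comparison-tool pipelines are out of scope.
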