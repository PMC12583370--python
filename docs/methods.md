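# Methods

This note documents the models, conventions and numerical choices behind
mitomorph, in the order the pipeline runs.

## Skeleton topology and the morphology metrics

A binary mask of the mitochondrial marker channel is thinned to a
1-pixel-wide skeleton (Zhang–Suen-type thinning via scikit-image, which
preserves connected-component count and is idempotent on already-thin
input).  All binary operations use 8-connected foreground, (row, col)
coordinates, origin top-left.

Skeleton pixels are classified by their 8-neighbour count: ≤1 endpoint,
2 path interior, ≥3 junction.  Conventions that the underlying literature
leaves open, fixed here:

* **Junction clusters.**  Thinning often produces 2–4 mutually adjacent
  junction pixels at one physical branch point.  Adjacent junction pixels
  merge into a single junction node, so J counts branch points, not
  pixels.
* **Branches.**  The 8-connected components of the non-junction pixels;
  each touches at most two junction nodes (a pixel touching a cluster
  mid-segment would itself be a junction).  A closed loop is one branch
  whose ends coincide.  An isolated pixel is a 1-px branch.
* **Rods.**  A connected component of the whole skeleton containing no
  junction node is a solitary rod; each rod is exactly one branch, which
  makes fragmentation = R/B a proper fraction in [0, 1].
* **Branch length.**  Pixel count of the branch including one junction
  pixel per attached junction node (each shared terminal counted once per
  branch), times the pixel size.  This matches the generator's bookkeeping
  exactly on un-rendered skeletons.
* **Spur pruning.**  Re-skeletonizing a rendered tube occasionally leaves
  1–2 px junction-attached spurs.  The measurement pipeline removes
  endpoint-bearing junction-attached segments shorter than 3 px (single
  pass, never rods) and re-thins.  True branches are ≥ 6 px by
  construction in the generator, so pruning cannot delete them.

Degenerate inputs never crash the pipeline: a blank field or an empty
post-threshold mask yields a flagged record (`qc_flag`) with NaN metrics.

## Thresholding and background

Two threshold policies: the 99.5th percentile of a same-stain
negative-control image (bounds the false-positive pixel rate at 0.5 %
under the control distribution; the percentile is configurable), or Otsu's
between-class-variance criterion on the channel itself.  Pixels strictly
above threshold are foreground.  Background is a per-field scalar: the
median of the negative control when available, else the channel's 5th
percentile.  No flat-field correction or cross-replicate intensity
normalization is attempted — acquisition gain is assumed constant within a
replicate only, and compartment means are background-corrected per field.

For the *compartment masks* used in calcium quantification, the marker
channels (mito, ER) take the maximum of the control threshold and the
in-field Otsu threshold.  The control percentile alone sits far below a
blurred tube's half-maximum, so by itself it swallows the PSF skirt and
dilutes the compartment mean by ~2×; Otsu restores the boundary near
half-max, while the control threshold still rules when the channel is
effectively blank.  The refinement is deliberately not applied to the
calcium channel: there Otsu could separate organelle from cytosol rather
than cell from background and truncate the whole-cell mask.  Even so, a
one-pixel boundary error on a 3-px-wide tube costs ~0.3 in Jaccard
overlap, so measured mito masks agree with the generating truth at
Jaccard ≈ 0.65–0.85, and measured organelle calcium is mildly attenuated
toward the cytosol level.  This attenuation scales effects and
between-replicate spread alike, so factorial inference on the measured
values remains calibrated and powered; absolute compartment means should
be interpreted as marker-mask-restricted estimates, not physical
concentrations.

The whole-cell mask is the union of all three channel masks,
morphologically closed (disk radius 3) and hole-filled; the organelle
masks are therefore contained in it by construction.  Mito ∩ ER pixels
contribute to both compartment means — masks are marker-defined and
overlap is physical.

## Synthetic ground truth

**Geometry.**  Networks are drawn directly on the pixel grid from
primitives whose topology is known by construction.  Rods are straight
8-connected digital lines (length ≥ 2 px, default 8–16 px).  Branched
components are diagonal backbones carrying degree-3/4 junctions, each
junction sprouting one or two teeth along the perpendicular diagonal.
The arm directions are chosen so that no two arms of a junction have
8-adjacent first pixels — every junction is a single pixel whose degree
equals its arm count, the skeleton is a fixed point of thinning, and the
graph builder recovers the requested (B, J, R) exactly.  A component with
j junctions and e extra teeth carries 2j + 1 + e branches, so requested
counts are feasible iff B − R ∈ [2J + 1, 4J] (or B = R when J = 0).
Components are packed by rejection-sampling bounding boxes with a minimum
gap (default 6 px ≈ 2·tube_radius + 3·psf_sigma) so rendering can never
merge distinct components; packing failure raises after bounded retries.

**Rendering.**  The mito channel is the skeleton dilated by a disk
(radius 1 px default), scaled to amplitude 150 AU, blurred with a
Gaussian PSF (σ = 0.8 px), plus constant background (10 AU) and additive
Gaussian noise (sd 5 AU), clipped at zero.  Pixel size defaults to
0.1 µm/px on 192–512 px fields; neither is a claim about any real
acquisition, both are configurable.  The ER channel renders
smoothed-noise threshold blobs covering 10 % of the cell area (disjoint
from the mito tube by default).  The cell is the convex hull of the
network plus a 5 px margin — one cell per field, since per-cell metrics
need a cell and the pipeline does not attempt cell segmentation.  The
calcium channel is piecewise constant over the true compartment masks;
the cytosol level is solved so the whole-cell mask mean equals the
requested level exactly, and the channel is *not* PSF-blurred by default,
so compartment means are exactly their nominal values and recovery errors
are pure CLT noise (bleed-free).  Poisson shot noise is available as an
option but off by default, keeping variance accounting purely Gaussian.
Negative controls (background + noise) are generated per field and
channel.  Identical seeds give bit-identical output.

**Noiseless fidelity.**  With noise and background at zero, the full
measure path (Otsu threshold → clean → thin → prune → graph) recovers
(B, J, R) exactly and the mean branch length within ±1 px: tube dilation
extends tips by ~1 px while thinning a blurred tube shortens arms at
junctions by a comparable amount, leaving per-network mean errors well
inside one pixel at the default tube radius.  This was verified over
random topologies before the defaults were frozen, and is asserted by the
test suite.

**Experiments.**  A balanced 2 (vehicle/rotenone) × k (default
ctrl/agonist/antagonist) design.  For each variable the per-condition
mean is baseline + additive level shifts; replicate latent means are
N(condition, between_sd); field values are N(replicate, within_sd).
Defaults (chosen as plausible magnitudes for this kind of assay, with
effect magnitudes fixed at 2 × between-replicate sd): fragmentation
0.30 (between 0.04 / within 0.05), branching 0.25 (0.03/0.04), branch
length 1.2 µm (0.10/0.15), calcium 40/100/60 AU for cell/mito/ER
(3–6/4–8), MTT 100 % (8/6), cell count 120 (10/12); 5 replicates ×
5 fields per condition.  Default effect directions: rotenone raises
fragmentation and lowers branching, calcium (all compartments), MTT and
counts; both modulator classes lengthen branches and raise counts;
agonists lower and antagonists raise organelle calcium.  When an
experiment is rendered, each field's latent morphology targets are
realized as the nearest feasible integer topology on a 16-branch network
(quantization acts as extra within-field noise) and its calcium targets
as the rendered compartment levels; the measured tables then come from
re-measuring the rendered images, not from the latent values.

**What the generator does not emulate** — and hence what passing tests do
not certify about real data: 3-D structure, photobleaching and temporal
dynamics, realistic organelle texture and intensity heterogeneity,
cell-to-cell variation within a field, segmentation of touching cells,
illumination gradients, and gain changes between replicates.

## Inference layer

Analysis unit is the biological replicate: fields are averaged per
replicate first, avoiding pseudo-replication.  Designs must be balanced
and complete with ≥ 2 replicates per cell; unbalanced input is an error.

* **ANOVA.**  Classical balanced fixed-effects decomposition from
  explicit marginal/cell means; SS_A + SS_B + SS_AB + SS_E equals SS_total
  to machine precision; F tested against the residual MS with exact
  F p-values.  Zero residual variance is handled explicitly (p = 0 for
  any between-cell variation, else p = 1).
* **Tukey HSD.**  q = |mᵢ − mⱼ| / √(MS_w/2 · (1/nᵢ + 1/nⱼ))
  (Tukey–Kramer for unequal n).  Adjusted p comes from the studentized
  range distribution computed by direct numerical integration: the
  conditional range probability k ∫ φ(z)[Φ(z) − Φ(z − q u)]^{k−1} dz
  integrated over the scale density u ~ √(χ²_ν/ν), both on fixed
  160-point Gauss–Legendre grids (absolute error ≲ 1e-12 for the df used
  here, verified against an independent implementation; ~1 ms per call).
  With k = 2 the adjusted p equals the pooled t-test p to 1e-9.
* **Gatekeeping.**  Interaction significant → Tukey on cell means; else
  Tukey on the marginal means of each significant main effect (pooling
  over the other factor — the "combined data" comparison), using the
  factorial model's residual MS and df; nothing significant → an empty
  result with an explanatory note.
* **Student's t.**  Pooled-variance two-sided by default (Welch by flag);
  zero pooled variance with unequal means reports p = 0 with an infinite
  statistic rather than NaN.
* **Pearson.**  Product-moment sums, pairwise-complete over missing
  values, p from t = r√((n−2)/(1−r²)); constant variables yield flagged
  NaN.  The default matrix pools replicate-level records across all
  groups (per-group matrices are available by subsetting); this choice is
  the package's own, made because a single pooled matrix is what a
  cross-variable correlation figure displays.

Type-I calibration was a design gate: under the zero-effect generator the
empirical rejection rate of every test at α = 0.05 must sit inside the
99 % binomial band for 1000 simulated datasets (asserted in the test
suite, recomputed by `scripts/acceptance.py`).

## Problem sizes

The validation suite uses 100 networks for exact-recovery checks, 25 for
the noiseless end-to-end check, 200 rendered fields for calcium recovery,
1000 tabular datasets for calibration, and 100 fully rendered
experiments (192×192 px, 150 fields each) for directional power — sizes
at which every result above is stable under reseeding while the whole
suite stays desk-scale.

## Known limitations

* Per-field single-cell assumption; multi-cell fields need user ROIs.
* Compartment calcium is a masked mean, not a calibrated concentration;
  marker-mask boundary errors attenuate organelle means (see above).
* Balanced designs only; no mixed-effects modelling of the
  field-within-replicate hierarchy.
* 2-D only; loops are counted but not otherwise characterized.
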