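# mitomorph

Quantitative analysis of mitochondrial network morphology, compartmental
calcium, and cell viability from multi-channel fluorescence microscopy —
with a ground-truth synthetic data generator so that every stage of the
pipeline is verifiable without real microscopy data.

## The problem

Neurodegeneration models (for example SH-SY5Y cells stressed with the
complex-I inhibitor rotenone, with or without pharmacological modulation of
ATP-sensitive potassium channels) are commonly read out through three
kinds of measurements:

1. **Mitochondrial network morphology.**  The MitoTracker channel is
   binarized and thinned to a 1-pixel skeleton, which is decomposed into
   branches (B), junction points (J) and solitary rod-shaped mitochondria
   (R).  Three per-cell statistics summarize the network:

   * fragmentation  = R / B  ∈ [0, 1] (a rod is itself one branch),
   * branching      = J / B,
   * mean branch length  = (1/B) Σᵢ ℓᵢ, with ℓᵢ the branch pixel count
     times the pixel size in µm.

2. **Compartmental calcium.**  The Fluo-4 calcium signal is averaged inside
   marker-derived masks — whole cell, mitochondria (MitoTracker), ER
   (ER-Tracker) — after subtracting a per-field scalar background derived
   from negative-control images: Ī = mean(F | mask) − b, clipped at 0.

3. **Viability.**  MTT absorbances as percent of the untreated-control
   mean (the control mean is 100 % by construction) and mean cell counts
   per biological replicate.

Inference is a balanced two-way factorial ANOVA (KATP treatment ×
rotenone) per variable, with Tukey HSD post-hoc comparisons gated on the
ANOVA (cell means when the interaction is significant, marginal means for
significant main effects), Student's t against the untreated control, and
a Pearson correlation matrix across variables.  The ANOVA sums of squares
and the studentized-range distribution are computed from first principles
so every p-value can be checked against an independent oracle.

Because studies of this kind rarely deposit raw images, the package ships
a synthetic generator that produces tubular networks of *known* skeleton
topology, renders them to three-channel fields (tube dilation, Gaussian
PSF, background, additive Gaussian noise), and simulates full factorial
experiments with configurable effect directions and between-/within-
replicate variance components.

## Worked example

```python
from mitomorph import synthetic as syn, morphometry as morph
from mitomorph.pipeline import AnalysisConfig

net = syn.generate_network(n_branches=12, n_junctions=4, n_rods=3, seed=7)
g = morph.build_graph(net.skeleton)
print(g.branch_count, g.junction_count, g.rod_count)   # 12 4 3
print(morph.fragmentation(g))                           # 0.25
print(morph.branching(g))                               # 0.3333...
print(morph.mean_branch_length(g, pixel_size=0.1))      # 1.267 (µm)

fld = syn.render_field(net, render_spec=syn.RenderSpec(seed=1))
m = morph.measure_field(fld, AnalysisConfig())
print(m.branch_count, m.junction_count, m.rod_count)    # 12 4 3
print(m.mean_branch_length_um)                          # 1.35
```

The generated network has exactly the requested topology, so the graph
builder recovers (12, 4, 3) and the ratios 3/12 = 0.25 and 4/12 = 0.333
exactly.  After rendering with the default noise (background 10 AU,
Gaussian sd 5 AU) the full measurement pipeline — negative-control
threshold, speckle cleaning, thinning, spur pruning, graph extraction —
still recovers the exact counts; the mean branch length (1.35 µm vs the
true 1.267 µm) carries the expected sub-pixel-per-branch error of
re-skeletonizing a blurred tube.

The command-line workflow runs a whole simulated experiment (a 3 × 2
factorial, 5 replicates × 5 fields per condition):

```sh
mitomorph all --seed 11 --out run1
```

which writes the dataset (TIFFs + truth + design), the tidy per-field
metrics, and `run1/stats/{anova,tukey,ttests,correlations_*}.csv`.  The
same steps are available as numbered scripts under `analysis/`
(`01_simulate.py`, `02_measure.py`, `03_stats.py`, `04_validation.py`)
which also print measurement-vs-truth summaries and write `results/`.

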