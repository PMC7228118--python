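# icmgraph

Quantitative three-dimensional cell-neighbourhood analysis of NANOG and
GATA6 patterning in the inner cell mass (ICM) of mouse blastocysts.

During preimplantation development, ICM cells choose between the
epiblast fate (high NANOG) and the primitive-endoderm fate (high
GATA6).  `icmgraph` is for developmental biologists and image analysts
who have segmented-nucleus tables from quantitative immunofluorescence
(e.g. MINS output: 3D centroid, TE/ICM lineage call and per-nucleus
mean marker intensities) and want to ask how fate-marker expression is
organised in space: does a cell's level relate to its number of
neighbours, to its neighbours' levels, or to its position within the
ICM?

## What it computes

* **Delaunay cell graph (DCG).** Cell neighbourhood is the Delaunay
  tetrahedralization of nucleus centroids with edges longer than
  30 μm pruned.  Analyses run on all ICM cells plus TE cells adjacent
  to at least one ICM cell.
* **Staging and normalization.** Embryos are staged from total cell
  number (early 32–64, mid 65–90, late >90).  Batches are aligned by
  dividing each channel by a per-batch positivity threshold
  (configured, or derived by 1-D 2-means on log intensities), so the
  N+/G6+ boundary is 1.0 everywhere; a 2-SD rule flags intensity
  outliers, and optional exponential z-decay correction and z-rescaling
  handle acquisition artefacts.
* **Populations.** ICM cells are classified into DP (N+G6+), DN
  (N−G6−), Epi progenitor (N+G6−) and PrE progenitor (N−G6+);
  proportions are compared with Bonferroni-corrected two-proportion
  z-tests.
* **Neighbourhood correlation.** For a population at a stage, the
  Spearman correlation ρ between a cell's level and the median level of
  its graph neighbours, with a 100-fold bootstrap SE, a
  geometry-preserving shuffle null (levels permuted across ICM
  positions per embryo) compared by Mann–Whitney, Evans strength bands
  (very weak < 0.20 ≤ weak < 0.40 ≤ moderate < 0.60 ≤ strong < 0.80 ≤
  very strong), and a reliability flag for populations under 108 cells.
* **Positional profiles.** Marker level (or neighbour count) versus
  neighbour number, and versus distance to the ICM centroid in 5 μm
  bins, with Mann–Whitney bin tests.
* **Two-rule simulator.** ICM composition from three parameters: each
  cell is G6+ with probability `p_gata6`; exactly `round(p_nanog · n)`
  cells are N+, chosen closest-first to `start_num_neigh` (9)
  neighbours.  Setting `p_nanog = 0` gives the Nanog-null arm.
* **Synthetic embryos.** A seeded generator (TE shell + ICM cap
  geometry, NANOG peaked at nine neighbours, GATA6 from a spatially
  correlated Gaussian field, late-stage radial sorting) so the whole
  pipeline is testable without microscope data.

## Worked example

```python
import icmgraph as ig
from icmgraph.populations import PopulationLabel
from icmgraph.correlation import Channel

cohort = ig.generate_cohort({"early": 20}, seed=5)
norm = ig.align_batches(cohort, [ig.reference_thresholds()])
graphs = {e.embryo_id: ig.build_embryo_graph(e) for e in norm}
labels = ig.classify_cohort(norm)

props = ig.population_proportions(labels)
for lab in ig.ICM_LABELS:
    print(f"{lab.value:7s} {props[lab]['mean']:.3f} +/- {props[lab]['sem']:.3f}")

res = ig.correlate_population(norm, graphs, labels, PopulationLabel.DP,
                              Channel.GATA6, Channel.GATA6, seed=1)
print(f"DP GATA6 rho = {res.rho:.3f} (SE {res.bootstrap_se:.3f}, "
      f"n = {res.n_cells}, {res.strength.value}, null p = {res.null_p_adjusted:.3g})")
```

prints

```
DN      0.028 +/- 0.008
DP      0.695 +/- 0.027
EpiPro  0.123 +/- 0.019
PrEPro  0.155 +/- 0.019
DP GATA6 rho = 0.645 (SE 0.041, n = 278, strong, null p = 2.56e-34)
```

The proportions are the across-embryo mean ICM composition (± SEM) of
20 synthetic early blastocysts: mostly double-positive cells with small
progenitor fractions, as expected before lineage resolution.  The
correlation line says that a DP cell's GATA6 level and the median GATA6
level of its neighbours are strongly rank-correlated (ρ = 0.645 over
278 pooled cells — above the 108-cell reliability gate), and that this
clustering is far outside what the position-shuffling null model
produces: GATA6-high cells sit next to GATA6-high cells.

The same pipeline is available from the shell:

```sh
icmgraph run-all --out results/ --seed 42 --n-embryos 10
```

which chains synth → preprocess → graph → classify → features →
correlate → simulate, writing tidy CSV/JSON plus a run manifest per
stage.

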