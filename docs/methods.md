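# Methods

This note documents the models, conventions and numerical choices
behind `icmgraph`, and what the synthetic-data tests do and do not
establish about real embryo data.

## Data model and units

Nuclei carry a 3D centroid in micrometres, a TE/ICM lineage call, and
mean NANOG and GATA6 intensities in arbitrary fluorescence units
(a.u.).  Raw segmentation exports in voxel units must be read with an
explicit per-axis `unit_scale`; there is no silent voxel-size default
because acquisition metadata varies between setups.  Column names are
configuration (`column_map`) since segmentation-tool exports differ
between versions.  Rows with non-finite or negative intensities are
excluded with a logged count rather than aborting the read (a `strict`
mode aborts instead), mirroring the manual removal of gross
segmentation errors in curated data sets.  Processed cohorts are
versioned JSON; invariants (unique ids, stage consistent with cell
count) are re-validated on load.

## Staging and preprocessing

Stage is a function of total cell number: early 32–64, mid 65–90,
late >90.  The intervals are closed as printed; counts below 32 are
rejected rather than called early.

Batch alignment divides each channel by a per-batch positivity
threshold so the positive/negative boundary is 1.0 in every batch.
Thresholds are first-class configuration because threshold derivation
is dataset-specific; the automatic option is 1-D 2-means on
log-transformed intensities, initialised deterministically at the
25th/75th log-percentiles, with the threshold at the back-transformed
midpoint of the two centres (the geometric mean on the original
scale).  This is scale-equivariant: scaling all levels by c scales the
threshold by c.  Degenerate inputs (all levels equal) raise and ask
for a configured threshold.

Intensity outliers: a cell is flagged when either channel is more than
k = 2 sample standard deviations (n−1 denominator) from the cohort ICM
mean; boundary values are kept (non-strict ≤).  Flagged cells are
excluded from all downstream statistics.  Filtering is per cohort by
default.

z-decay correction (for unmounted samples imaged deep) fits
`level = a·exp(−z/λ)` per channel per embryo by least squares on log
levels and divides by `exp(−z/λ)`, preserving the amplitude.  The
exponential form is a model choice behind an enum (`none` is the
identity); a fit implying increase with depth leaves the channel
untouched with a warning, since "correcting" such a trend would
amplify it.  Position rescaling multiplies z by a user factor
(default 1.0 — no rescaling, as no universal mounting-compression
factor exists).

## The Delaunay cell graph

Neighbourhood is the Delaunay tetrahedralization of nucleus centroids
(scipy/Qhull) with edges longer than 30 μm removed after
triangulation; ties at exactly 30 μm are kept.  Tests verify the edge
set against a brute-force empty-circumsphere oracle for small point
sets, plus pruning monotonicity in the cutoff and invariance under
rigid motions.  Degenerate configurations (fewer than 5 points,
coplanar/collinear sets) fall back deterministically to the complete
distance graph thresholded at the cutoff, with a log note — real
embryos never hit this case, toy inputs do.  Duplicate positions
(within 1e−6 μm) are an error naming the pair.

Analyses restrict to the analysis set: all ICM cells plus TE cells
with at least one ICM graph neighbour.  Degrees are reported within
the induced subgraph on that set; whole-graph degrees are available
via `degree_distribution` on the full node set.

## Populations and proportion tests

With normalized levels, N+ means nanog > 1 and G6+ means gata6 > 1 —
positivity is strict, so a cell exactly at threshold is negative (the
boundary convention is configurable).  Proportions are averaged per
embryo first and SEMs are across embryos, not binomial over pooled
cells; pooled counts are used only by the z-tests.  The two-proportion
test is the pooled z statistic with a two-sided normal p, multiplied
by the Bonferroni factor and capped at 1; identical proportions return
p = 1 exactly.

## Neighbourhood correlation

For each focal cell the statistic pairs its own level with the median
level of its in-scope graph neighbours; cells with no in-scope
neighbour are dropped with a logged count.  The default scope is the
analysis set (TE neighbours' levels enter the medians); `icm_only`
restricts to ICM neighbours.  Pairs are pooled across embryos within
(population, stage); at least 3 pairs are required.  Spearman's ρ uses
average ranks for ties.

The bootstrap SE is the SD of ρ over 100 with-replacement resamples of
the pairs; degenerate resamples (a constant column) contribute ρ = 0
as they carry no rank information.  The null model permutes the
(NANOG, GATA6) level pairs jointly across each embryo's ICM positions
— geometry, graph and TE cells untouched — and recomputes labels from
the permuted levels, so the null respects the per-embryo level
multiset and the within-cell marker pairing; an independent-channel
variant is available behind a flag.  Observed bootstrap replicates are
compared with null replicates by a two-sided Mann–Whitney test with
Bonferroni correction.

Note a small-sample property: permuting within finite per-embryo pools
leaves a slight negative exchangeability bias in the pooled null mean
(a high focal value depletes its neighbours' pool), of order −1/(n−1)
per embryo.  Tests therefore judge "null centred at zero" against the
null's own spread rather than the standard error of its mean.

Strength bands on |ρ| (sign reported separately): [0, 0.20) very
weak, [0.20, 0.40) weak, [0.40, 0.60) moderate, [0.60, 0.80) strong,
[0.80, 1.0] very strong.  Results from fewer than 108 cells are
flagged unreliable — 108 itself passes, matching the convention that
populations "of less than 108 cells" are excluded from statistics —
and the null comparison is skipped for them.  The subsampling
sensitivity analysis draws `reps` without-replacement subsamples per
grid size and returns the smallest n whose replicate-ρ SD is below the
variability threshold (0.03, i.e. 3% in absolute ρ units).

## The two-rule simulator

Three parameters: `p_gata6`, `p_nanog`, `start_num_neigh`.  Rule 1
assigns G6+ independently per cell with probability `p_gata6`.  Rule 2
marks exactly `round(p_nanog · n)` cells N+ in ascending order of
|degree − start_num_neigh|, breaking ties among equal distances
uniformly at random.  Exact-count selection (rather than a per-cell
probability) makes the realized N+ fraction deterministic —
`round(p_nanog·n)/n`, exactly `p_nanog` whenever `p_nanog·n` is
integral — which matches reading the parameters as measured
proportions of positive cells; the stochastic alternative is noted but
not implemented.  The two rules draw from independent seeded streams.
Population labels are the 2×2 state combination and sum to 1 by
construction.  `p_nanog = 0` reproduces the Nanog-null arm: no DP or
Epi-progenitor cells, PrE-progenitor fraction ≈ `p_gata6`.  Because
rule 2 depends only on how many cells are selected, composition is
insensitive to `start_num_neigh` (verified over 7–14); the spatial
arrangement of N+ cells is what changes.

The simulator consumes only per-cell neighbour counts, which may come
from measured embryos or the synthetic generator.

## The synthetic generator

Geometry: TE nuclei are dart-thrown onto a sphere shell (radius 40 μm)
and ICM nuclei into an interior spherical cap (half-angle 70°,
attached to one pole; the blastocoele remains empty), all with a
minimum spacing of 8 μm; packing failure after bounded retries raises
with advice to lower density.  Default counts are 30 TE + 20 ICM
(early), 50 + 28 (mid), 70 + 35 (late), falling inside the staging
windows with an ICM share of roughly 40% early.  The cap half-angle
gives early ICM cells on the cap boundary a large TE-neighbour share,
comparable to measured early embryos.

Expression: NANOG is assigned after graph construction as
`baseline + amplitude · exp(−(degree − 9)² / (2·2.5²)) + noise`
(30 + 70·bump + N(0,10) a.u.) on analysis-subgraph degrees.  GATA6 is
`baseline + field + noise` where the field is a zero-mean Gaussian
random field with squared-exponential covariance (length 15 μm ≈ three
cell radii, SD 40 a.u., noise SD 5), sampled by exact Cholesky
factorization — cheap at these sizes.  The field covers TE nuclei too
(GATA6 is expressed in TE; ICM and TE differ in baseline only, 60 vs
30 a.u.), so analysis-set neighbour medians carry the field signal.
The field is mean-centred per embryo: the planted phenomenon is local
clustering, and embryo-wide brightness shifts — which batch alignment
removes in real data — would otherwise masquerade as pooled
correlation.  Late-stage embryos add opposing radial terms (−1.5 and
+1.5 a.u./μm for NANOG and GATA6) around the ICM centroid, emulating
sorted lineages.  Levels are clipped at zero.  Everything is seeded;
cohorts spawn independent per-embryo seeds and record all parameters
as ground truth.

Reference thresholds (NANOG 60, GATA6 25 a.u.) are calibrated so early
synthetic cohorts reproduce realistic early-blastocyst state fractions
(~85% G6+, ~82% N+) and hence a DP-dominated composition.

What the generator does *not* emulate: nuclear shapes and volumes,
segmentation errors, z-dependent attenuation (unless added via the
corruption utilities in tests), cell division or motion, and the
coupling between NANOG and GATA6 within a cell (channels are generated
independently).  Passing recovery tests therefore demonstrate that the
pipeline detects these patterns when present at plausible effect
sizes, not that real embryos contain them, and the cross-channel
correlation analyses are exercised only for the null case on synthetic
data.

## Problem sizes and determinism

The acceptance script uses 50 synthetic early embryos × 200 simulator
replicates for the state-fraction checks, 50- and 100-cell ICM ball
geometries (where `round(p·n)` is integral) for the exact N+ checks,
and 30 embryos (~600 pooled ICM cells) for the NANOG-peak recovery;
the test suite uses 8–30 embryos per fixture.  All randomness flows
through explicit seeds (numpy `SeedSequence` spawning for per-embryo
and per-stage streams), so every result — including bootstrap SEs and
null distributions — is reproducible from the recorded seed.  Argmax
ties in the degree profile resolve to the smallest degree; radial bins
are half-open `[k·w, (k+1)·w)` with `w = 5 μm`.

## Known limitations

* Pooling pairs across embryos treats cells as exchangeable between
  embryos; the per-embryo mode exists but small per-embryo cell counts
  make it noisy.
* The shuffle null's negative small-sample bias (above) means null p
  values are marginally conservative for positive observed ρ.
* The k-means threshold assumes a roughly bimodal log-intensity
  mixture; unimodal channels yield a median-like split that should be
  overridden by configured thresholds.
* The DCG approximates cell contact from nucleus centroids only;
  membrane geometry, contact areas and anisotropic nuclei are out of
  scope.
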