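# Methods

This note records the modelling assumptions, parameter defaults, and
numerical conventions of `pdacpheno`, and what the synthetic-data results
do and do not establish about real tissue.

## Pipeline model

The unit of analysis is the **tile**: a 200-μm square of an annotated tumor
region, described by the fraction of positive pixels per channel for PanCK
and seven subtype markers. The pipeline assumes

- binary positive-pixel masks are given (pixel classification is upstream
  and out of scope; the mask is the input contract);
- serial-section misalignment is rigid at the scale analyzed (translation +
  rotation); deformable residuals are ignored;
- tiles are exchangeable within a phenotype: clustering treats tiles as
  i.i.d. samples in marker space and ignores spatial adjacency;
- PanCK separates tumor epithelium from stroma well enough that the >10%
  PanCK gate defines "tumor tiles".

### Tiling conventions

Pixel coordinates are 0-based with half-open boxes; the grid is anchored at
the floored annotation bounding-box origin, without overlap or offset
sweeps — the simplest reproducible convention. Tile side =
`round(tile_size_um / mpp)` px. A tile is *nontruncated* when its
inside-annotation area fraction reaches `truncation_min_inside` (default
1.0; the filter description "based on size" gives no threshold, so it is
configurable). Proportions are computed over tile∩annotation pixels rather
than the whole tile, so boundary tiles remain unbiased if a relaxed
truncation threshold retains them. Filtering is two-step and strict:
nontruncated first, then PanCK proportion **strictly greater than** 0.10.

### Features and clustering

Features are PCA scores of `log2(p + ε)` over the seven subtype markers
(PanCK is a gate, not a phenotype axis). Defaults and rationale:

- `log_epsilon = 1e-3` — pseudo-count on proportions; the published
  analysis says only "logged values", so the base (2) and ε are exposed.
- Columns are centered, not variance-scaled (`scale_pca = False`): the log
  transform already stabilizes scale across markers. Scaling is a flag.
- Components with explained variance ratio > 0.05 are retained; component
  signs are fixed by making the largest-magnitude loading positive, so the
  embedding is deterministic.
- k-means uses k-means++ with 25 restarts and a fixed master seed; the
  cluster count maximizes mean silhouette over k ∈ {2..8}, ties toward
  smaller k. Silhouette is computed in the retained PCA space and, above
  10,000 tiles, on a seeded subsample (whether the original analysis
  subsampled is unknown; at the sizes used here the exact and subsampled
  values agree to the third decimal).

### Naming rules

Clusters are named from raw marker centroids, in order: (1) the cluster
with maximal MUC16 mean, if MUC16 is *dominant* there, is Basal.MUC16;
(2) likewise S100A2 → Basal.S100A2; (3) the remaining cluster maximizing
mean(CLDN18, GATA6, TFF1) is Classical; (4) a remaining cluster topped by
KRT17 with classical mean < 0.25 is Intermediate; anything left is
Unassigned. *Dominant* means ≥ 1.5× every other marker mean in that
cluster (`dominance_ratio`, configurable). The 1.5 factor is a design
choice: low enough that a merged basal cluster at k < 4 does not
masquerade as Basal.MUC16, high enough to fire on genuinely
marker-dominated centroids.

### Composition calls

Presence is **strictly** > 1% of a tumor's tiles (values at or below can be
detection artifacts), predominance strictly > 50%. Because the predominant
phenotype of a real tumor often sits below 50%, `predominant` is reported
as the argmax regardless, alongside the boolean `predominance_strict`;
argmax ties break in the fixed order Classical, Intermediate, Basal.MUC16,
Basal.S100A2. Basal presence applies the 1% rule to the summed basal
proportion.

### Registration

A rigid transform maps moving → fixed coordinates, rotation about the
origin, (x, y) = (column, row). Estimation is exhaustive: for each rotation
candidate (±5° at 0.5° by default) the translation maximizing foreground
overlap is found by FFT cross-correlation within ±50 px, scoring Dice;
coordinate-wise hill climbing then refines at 0.1 px / 0.1° on bilinear
(soft) Dice. Registration aligns per-slide tissue footprints, then warps
all channel masks of the slide with nearest-neighbor resampling, which
keeps masks binary at the cost of boundary-pixel flips. There is no
published registration accuracy figure to match, so the contract is
property-based: planted noiseless shifts are recovered to ≤ 1 px and the
rotation grid step.

### Statistics

- **Co-occurrence**: per phenotype pair, a 2×2 table of per-tumor presence,
  two-sided Fisher exact test (point-probability summation), BH adjustment
  across the six pairs. The unit of analysis is the tumor; a tile-level
  table would pseudo-replicate thousands of correlated tiles. Degenerate
  margins (a phenotype present everywhere or nowhere) leave the odds ratio
  undefined and p = 1.
- **Shifts**: among tumors with ≥ 2 slides, each consecutive slide pair
  disagreeing on the predominant phenotype records one (from, to) shift.
- **Survival**: Kaplan–Meier product-limit curves with median = earliest
  time at survival ≤ 0.5 (undefined if never reached); two-group log-rank;
  Cox partial likelihood with Breslow tie handling, Wald intervals.
  Constant covariates raise; non-finite estimates (separation,
  collinearity) raise with a diagnostic rather than returning garbage.
- **Scorer concordance**: Pearson by default (the choice of coefficient is
  not documented in the source analysis), Spearman as a flag.

### Marker triage

The TMA specificity rule (ii) — "less than one strong expression or less
than two moderate expressions" in the opposite subtype — is genuinely
ambiguous as printed. The default is the conjunction (zero strong AND at
most one moderate), the stricter reading consistent with "lack of
expression"; `lenient=True` gives the disjunctive reading. AUC treats the
marker's own subtype as the positive class, so a good marker always scores
above 0.5; ties are rank-averaged (Mann–Whitney convention).

## Synthetic data: what it emulates and what it cannot show

The generators plant known answers so every stage is testable without the
(non-public) patient cohorts.

**Profile catalog.** No per-cluster marker means were ever published; the
default catalog is chosen to reproduce the qualitative expression ordering
of the four phenotypes (Classical: CLDN18 0.50 / GATA6 0.45 / TFF1 0.40;
Intermediate: KRT17 0.35, GATA6 0.12; Basal.MUC16: MUC16 0.45, KRT17 0.12;
Basal.S100A2: S100A2 0.50, PanBS 0.20, KRT17 0.10; background markers
0.02–0.05; PanCK 0.80–0.85). These numbers are implementation defaults,
not measurements.

**Noise model.** Per tile and marker, proportions are Beta(μc, (1−μ)c)
draws with concentration c = 50 (sd ≈ 0.07 at μ = 0.5, heavier relative
spread near 0 after the log transform). This is a realistic per-tile
dispersion under which the planted four-cluster structure remains
recoverable — the regime any cohort must be in for this pipeline to find
its clusters. `c = ∞` is the exact noise-free mode used by degenerate-case
tests. Pixel masks are independent Bernoulli fields at the region's
profile mean, so observed tile proportions are binomial around the means.

**Cohorts.** Compositions are Dirichlet with prevalence (0.29, 0.43, 0.14,
0.14) over (Classical, Intermediate, Basal.MUC16, Basal.S100A2) and
concentration 1.2, which makes roughly two thirds to four fifths of tumors
basal-present and almost all intermediate-present — the sparse-mixture
regime reported for resected PDAC. Event times are exponential (constant
baseline hazard 0.015/month ⇒ median ≈ 46 months; Weibull shape is a
config option) with the hazard multiplied by the planted ratio (default
1.9) when basal share > 1%. Censoring is an independent exponential whose
rate targets the configured censored fraction. Clinicopathological
covariates are independent binaries with realistic prevalences and **no
effect on the hazard**, so the planted basal effect is the only true
signal.

**What passing tests show.** That the implementation of each stage is
correct against its definition (exact oracles), and that the chain
recovers planted structure under the stated noise. They do **not** show
that four phenotypes exist in real tissue, that the default catalog
matches real marker distributions, or that real misalignment is rigid;
deformable warping, stain variation, pixel-classifier error and spatially
correlated noise are all absent from the generators by design.

## Problem sizes

Test and acceptance runs use sizes at which each claim is already
well-powered: 5,000 tiles (4 × 1,250) for cluster-count and label
recovery; 640-px canvases with four 200-px regions for stack-level checks;
n = 500 cohorts (and 100 × n = 300 replicates for null coverage) for
hazard-ratio recovery; exhaustive enumeration up to total 30 for Fisher,
50 points for silhouette, 12 cases for AUC. The large-sample Cox bias
check averages five independent n = 5,000 cohorts so that per-cohort
sampling error (se ≈ 0.04 on the log-HR) is not mistaken for bias.

## Known limitations

- Rigid-only registration; masks warp by nearest neighbor, so repeated
  re-registration accumulates boundary error.
- The whole-canvas annotation raster uses pixel centers; tiles whose
  annotation overlap contains no pixel center quantify as zero-denominator
  and return 0.
- Silhouette-based k selection is evaluated on the k-means solution per
  candidate k; other clusterings of equal k are not explored.
- `Unassigned` is a first-class label: at k below the true phenotype
  count, merged clusters that fail every naming rule are reported as such
  rather than forced into a name.
- The exponential survival generator has proportional hazards by
  construction; it cannot probe robustness to non-proportionality.
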