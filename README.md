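# pdacpheno

Tile-based multiplex-IHC phenotyping of pancreatic ductal adenocarcinoma
(PDAC).

PDAC carries two major transcriptomic subtypes — **classical** (better
prognosis) and **basal-like** — but individual tumors are mosaics of both,
plus an intermediate state, and bulk RNA cannot see that spatial mixture.
`pdacpheno` implements an image-analysis route to intratumor subtype
heterogeneity: serial sections are stained for a panel of one epithelial
gate (PanCK) and seven subtype markers (GATA6, CLDN18, TFF1 — classical;
MUC16, S100A2, KRT17, PanBS — basal-like, where PanBS is a KRT5/KRT14/p63
cocktail read as one channel), rigidly co-registered, virtually cut into
200-μm square tiles, and each tile is summarized by its positive-pixel
proportion per marker. Tiles are then clustered into phenotypes, and
per-tumor composition drives presence/predominance calls, co-occurrence
and survival statistics. The package is aimed at computational
pathologists and biostatisticians who want the full chain — or any single
stage — reproducible on synthetic data with known ground truth, since the
original patient cohorts are not public.

## The method

Given a filtered tile table (nontruncated tiles with PanCK proportion
strictly > 10%), tiles are embedded as

> PCA scores of log2(p + ε) over the 7 subtype markers, keeping components
> with explained variance ratio > 5%,

clustered by k-means (25 restarts, seeded), with the cluster count k chosen
to maximize mean silhouette over k ∈ {2,…,8}. Clusters are named from their
raw marker centroids: a MUC16-dominant cluster is **Basal.MUC16**, an
S100A2-dominant cluster is **Basal.S100A2**, the cluster with highest mean
CLDN18/GATA6/TFF1 is **Classical**, and a remaining KRT17-topped cluster
with low classical expression is **Intermediate**. Per tumor, a phenotype
is *present* when it occupies strictly > 1% of tiles and *predominant*
above 50%; a tumor is *basal-present* when the two basal phenotypes sum to
> 1%. Downstream: pairwise Fisher exact tests of phenotype co-occurrence
(BH-adjusted), predominant-phenotype shifts between slides of the same
tumor, Kaplan–Meier / log-rank survival stratified by basal presence, and
Cox proportional-hazards models (Breslow ties) with the usual
clinicopathological covariates. The marker-triage machinery that justified
the panel is included: signature correlation/AUC screening, the three-rule
TMA specificity filter, and the IHC–RNA concordance drop rule. H-scores
(intensity 0–3 × percent positive cells, range 0–300) are supported
throughout.

Every input has a synthetic generator with planted ground truth: tile
tables (Beta noise around a phenotype profile catalog), slide stacks
(Bernoulli positive-pixel masks over annotated regions, with planted rigid
misalignments), survival cohorts (Dirichlet compositions; exponential event
times with a planted hazard ratio for basal presence), and H-score TMA
tables.

## Worked example

```python
import pdacpheno as pp
from pdacpheno.stats import cox_fit, km_logrank

tiles, truth = pp.generate_tile_table(n_per_phenotype=1250, seed=42)
res = pp.TilePhenotypeModel(tiles).fit()
print(res.summary())
```

```
Tile phenotype clustering
=============================================
tiles: 5000    k: 4    components: 3
explained variance (retained): 55.5%, 19.3%, 11.6%
mean silhouette: k=2: 0.468, k=3: 0.498, k=4: 0.626, k=5: 0.545, k=6: 0.462, k=7: 0.379, k=8: 0.296

cluster centroids (raw marker proportions):
      phenotype  GATA6  CLDN18   TFF1  MUC16  S100A2  KRT17  PanBS
0     Classical  0.448   0.497  0.398  0.020   0.020  0.030  0.020
1   Basal.MUC16  0.019   0.020  0.020  0.445   0.031  0.119  0.052
2  Intermediate  0.119   0.050  0.039  0.021   0.019  0.351  0.020
3  Basal.S100A2  0.019   0.020  0.019  0.030   0.499  0.101  0.202

pooled tile composition:
  Classical       25.0%
  Intermediate    24.9%
  Basal.MUC16     25.1%
  Basal.S100A2    25.0%
```

The silhouette curve peaks at k = 4 — the four planted phenotypes — and the
named tile labels agree with the planted ground truth for 99.9% of tiles.
The centroid table shows why the naming rules fire: cluster 1 is
MUC16-dominant, cluster 3 S100A2-dominant, cluster 0 carries the mixed
classical trio, cluster 2 is KRT17-topped with little else.

Survival on a synthetic 95-patient cohort with a planted basal hazard
ratio of 1.9:

```python
comp, surv, _ = pp.generate_cohort(pp.CohortConfig(n_tumors=95, seed=1))
print(km_logrank(surv, "basal_present").summary())
print(cox_fit(surv, ["basal_present", "age_gt_65", "positive_margins",
                     "vascular_emboli", "lymph_node_invasion",
                     "vascular_invasion", "perineural_invasion"]).summary())
```

```
Kaplan–Meier / log-rank
----------------------------------------
False: n=21, events=14, median survival=74.0 months
True: n=74, events=61, median survival=27.5 months
log-rank chi2=7.4554, p=0.006325

Cox proportional hazards (Breslow ties): n=95, events=75
------------------------------------------------------------
basal_present          HR=2.233 [1.214, 4.104] p=0.00973
age_gt_65              HR=0.902 [0.541, 1.503] p=0.6912
...
```

Tumors with even a minor (>1%) basal component show sharply reduced median
survival, and the multivariable Cox model recovers an HR near the planted
effect while the null covariates stay near 1.

## Command-line pipeline

```bash
pdacpheno simulate  --out run/sim --seed 5          # stack + cohort + TMA
pdacpheno register  --stack run/sim/stack --out run/reg
pdacpheno tile      --stack run/reg/stack --out run/tiles.csv
pdacpheno cluster   --tiles run/tiles.csv --out-model run/model.json \
                    --out-labels run/labels.csv --seed 5
pdacpheno phenotype --tiles run/tiles.csv --labels run/labels.csv \
                    --out run/compositions.csv
pdacpheno stats     --compositions run/compositions.csv \
                    --survival run/sim/survival.csv --out run/stats
```

Each stage logs its tile/record accounting, every threshold is a flag with
the published value as default, and the whole chain is bit-reproducible
for a fixed seed.

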