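# sgctme

Spatial single-cell analysis of the salivary gland carcinoma (SGC) tumor
microenvironment (TME): hierarchical marker-based phenotyping of imaging
mass cytometry (IMC) cell tables, cellular-neighborhood and cell–cell
interaction analysis, cancer-associated fibroblast (CAF) signature scoring
on bulk RNA-seq and spatial transcriptomics, and survival stratification —
with a first-class synthetic-cohort generator that plants recoverable
ground truth under every stage.

The package is aimed at computational pathology / spatial-omics analysts
who start from segmented single-cell tables (CellProfiler-style CSV: one
row per cell with centroid coordinates in µm and raw counts for a
13-marker panel) and want a reproducible, scriptable version of the
semi-supervised IMC workflow: no interactive cluster annotation, every
choice a seeded parameter.

## The methods at its core

**Phenotyping.** Raw counts are variance-stabilized with
`asinh(x / cofactor)`. Tumor cells are gated by a two-component 1-D
Gaussian mixture on cytokeratin (posterior > 0.5 for the high-mean
component). Remaining TME cells are clustered with a self-organizing map
plus consensus metaclustering, and metaclusters are labeled by
deterministic marker rules — endothelia (CD31⁺), immune (CD45⁺/CD138⁺),
CAFs by negative selection; then immune subsets (plasma CD138⁺, CD8 T,
CD4 T with proliferating/CD74⁺ refinements) and CAF subsets
(mCAF = aSMA⁺Collagen1⁺, Collagen CAF, SMA CAF, dCAF = Ki67⁺Vimentin⁺,
apCAF = CD74⁺Vimentin⁺, Vimentin-only). A metacluster is marker-positive
when its mean exceeds the across-cluster midrange for that marker.

**Spatial analysis.** Per ROI a directed exact k-nearest-neighbor graph
(k = 20) over cell centroids; each cell is summarized by the label
fractions of its 20 neighbors and those profiles are k-means-clustered
into cellular neighborhoods (9 by default; 6 and 12 supported). Tumor
patches are connected components of ≥ 10 tumor cells in the symmetrized
graph; TME cells get signed distances to the nearest patch cell (negative
inside a patch hull). For each ordered type pair (A, B) the statistic
mean<sub>A-cells</sub>(# B-neighbors) is tested against a null of P random
label permutations: `p = (1 + #{null ≥ obs}) / (P + 1)`, and avoidance
analogously.

**Signatures.** The mCAF-like signature keeps the top 20% of genes
overexpressed in mCAFs, weighted by log2 fold change; a sample's score is
`mean_g(expr_g · log2FC_g)`. Spatial-transcriptomics spots get
expression-bin-matched module scores (set mean minus control-gene mean, no
weights), quantile co-expression categories
(mCAF^high/low × endothelia^high/low per sample), rank-sum differential
expression with BH correction, and pre-ranked KS-running-sum gene-set
enrichment with a gene-label permutation null (sets under 40% coverage
dropped).

**Outcomes.** Per-ROI label fractions → per-patient medians; group
comparison by Mann–Whitney-U / Kruskal–Wallis with BH adjustment; Spearman
correlation with ECM module eigengenes; median dichotomization
(positive-vs-zero when the median is 0); Kaplan–Meier, one- and two-sided
log-rank, and Cox proportional hazards with complete-separation detection.

## Worked example

`examples/05_signature_survival.py` builds the weighted signature, scores
simulated bulk samples, and tests a planted survival contrast:

```
signature: 98 genes (top 20% of 490 overexpressed)
score range: 3115.9 .. 11470.4; 20 high / 20 low

one-sided log-rank (high worse): chi2=43.0, p=2.69e-11
five-year recurrence-free probability, mCAF-high: 0.02
five-year recurrence-free probability, mCAF-low: 0.34
Cox HR 3.9 (95% CI 2.5-6.0); the planted group hazard ratio is 6.
```

98 of 490 overexpressed genes survive the 20% cut; the simulated cohort
plants a six-fold recurrence hazard between mCAF-high and -low patients,
and the downstream Kaplan–Meier / log-rank / Cox stack recovers a large,
significant contrast (the single-cohort Cox point estimate scatters around
the planted ratio; its CI covers it ~95% of the time across replicates).
The other scripts in `examples/` each demonstrate one capability
(simulation, phenotyping, neighborhoods, interaction testing, spatial
transcriptomics) and print a short interpretation with their numbers.

A thin CLI mirrors the stage order for shell use:
`sgctme simulate | phenotype | spatial | signature | survival | run-all`,
each taking `--config config.yaml --seed N --out-dir DIR`.

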