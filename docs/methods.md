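# Methods

This note records the models, parameter choices and numerical conventions
behind `sgctme`, and what the synthetic-data studies do and do not
establish about real imaging-mass-cytometry (IMC) data.

## Preprocessing and the tumor gate

Raw per-cell marker counts are transformed with the inverse hyperbolic
sine, `asinh(x / cofactor)`. The cofactor defaults to 1 (the convention of
IMC single-cell workflows, where counts are small; mass-cytometry
suspension data typically uses 5) and is exposed in
`PhenotypingConfig.cofactor`. The transform is strictly increasing and
fixes 0, so any common positive rescaling of counts combined with the same
rescaling of the cofactor leaves the pipeline invariant.

The tumor gate fits a two-component 1-D Gaussian mixture to transformed
cytokeratin by EM (scikit-learn, 3 restarts, seeded). A cell is tumor when
its posterior for the high-mean component exceeds 0.5; ties go to
non-tumor. The reported threshold is the posterior crossing point between
the component means (bisection on the fitted posterior; midpoint fallback
if the posterior does not cross 0.5 between the means, which only happens
for extreme weight imbalance). Degenerate input (zero variance) is an
error — there is nothing to separate.

## Clustering and the marker-rule hierarchy

TME cells are clustered per stage with a batch self-organizing map
(default 10×10 grid, shrunk for small stages; codebook initialized from
sampled cells; Gaussian grid neighborhood annealed from half the grid side
to 0.2 over 20 epochs) followed by consensus metaclustering of the node
codebook: 100 average-linkage hierarchical clusterings of 80% node
subsamples accumulate a co-clustering matrix, and the final partition cuts
average-linkage on (1 − consensus) at the stage's k. With one repetition
and full subsampling this reduces exactly to a single hierarchical cut.

The interactive workflow this mirrors chooses cluster numbers and labels
by visual inspection. Here both are explicit parameters and rules:

- stage k's: level-1 k=6, immune k=6, CD4 re-cluster k=4, CAF k=8
  (`PhenotypingConfig`), chosen to give each expected subpopulation at
  least one metacluster at the default panel;
- a metacluster is **marker-positive** when its mean transformed value
  exceeds the midrange of cluster means for that marker. When a marker has
  essentially no spread across a stage's clusters (range < 1 asinh unit —
  e.g. Vimentin among CAFs, CD45 among immune cells) the cluster-level
  midrange is meaningless, and the uniform level is instead compared to
  the stage-wide midrange over all markers' cluster means, calling all
  clusters positive or all negative together;
- CD4 "high" vs "low-positive" uses a second midrange among the
  CD4-positive clusters (ties to high), mapping CD4-high clusters to the
  CD4 T branch and low-positive ones to "other CD4⁺".

Label assignment order encodes rule precedence: level 1 assigns CAF by
default, overrides with immune (CD45⁺ or CD138⁺), then endothelia (CD31⁺).
CAF subsets check aSMA/Collagen1 first, then Ki67⁺Vimentin⁺ (dCAF),
CD74⁺Vimentin⁺ (apCAF), then sole Vimentin. Clusters negative for every
CAF marker are re-clustered once; cells still negative are relabeled
tumor — the all-marker-negative population sits inside tumor patches and
calling it tumor is the conservative choice for TME statistics.

## Spatial analysis

The spatial graph is the exact directed Euclidean kNN (k = 20) over
centroids; distance ties break by ascending cell id. ROIs up to 2,500
cells use a brute-force distance matrix; larger ROIs use a KD-tree with an
8-candidate margin for tie resolution. Cellular neighborhoods are k-means
(10 restarts, seeded) over the per-cell neighbor-fraction vectors;
9 clusters by default, 6 and 12 supported.

Tumor patches are connected components (≥ 10 cells) of the symmetrized
graph restricted to tumor cells. "Inside a patch" for the signed border
distance and the infiltration flag means patch membership for tumor cells
and containment in the convex hull of a patch's members for TME cells —
a deterministic, testable stand-in for morphological patch expansion;
concave pockets at patch borders are treated as inside.

The interaction statistic for an ordered pair (A, B) is the mean number of
B-neighbors over A-cells. The null permutes all labels over fixed
positions within the ROI (tumor cells included), P = 1000 by default, and
p-values use the add-one convention `p = (1 + #{null ≥ obs}) / (P + 1)`,
so they are never 0 and the test is exact at its achievable levels under
label exchangeability. A pair is called interacting (+1) at
p_interact ≤ α, avoiding (−1) at p_avoid ≤ α (α = 0.01 default); the
cross-ROI summary counts significant ROIs per direction.

## Signatures and spot analysis

The weighted signature keeps genes with log2FC > 0, ranks them descending
and retains ⌈q_sel · n⌉ (q_sel = 0.2 default; 98 genes out of 490). The
bulk score is the unweighted mean of expression × log2FC over signature
genes present; missing genes are dropped with a warning and the
denominator adjusted. Scores are computed on the TPM scale by default
(log2(TPM+1) available as a flag) — the score is linear, so monotone
stratification at the median is unaffected by overall scaling.

Module scores follow the bin-matched control convention: genes are cut
into 24 equal-occupancy bins by average expression; each set gene draws
100 controls from its bin (the whole bin when smaller); the score is the
per-spot set mean minus control-pool mean. Weights are deliberately not
used. When the controls exhaust the pool the score is exactly 0 for the
all-genes set, and a constant matrix scores 0 for any set.

Spot categories take, per sample, the top and bottom ⌊q·n⌋ spots by each
score (q = 0.2; 0.1/0.3 supported; ties broken by spot id), intersect the
mCAF and endothelia flags into four categories plus "other", and pool
across samples. Differential expression contrasts one category against the
rest per gene with a two-sided rank-sum test;
avg_log2FC = log2((mean_A + ε)/(mean_B + ε)) with ε = 1e-9, so the sign is
stable near zero and exactly antisymmetric under group swap; BH adjustment
is per contrast. Pre-ranked enrichment uses the classic unweighted
KS running sum (ES = extreme deviation, in [−1, 1]); its null permutes
gene labels, equivalently the hit-indicator vector; sets with < 40% of
their genes present are excluded before testing.

## Outcomes

Per-ROI label fractions (rows sum to 1 by construction) are aggregated as
per-patient medians; a primaries-only flag restricts to primary-tumor ROIs
when the table carries an `is_primary` column. Two-group comparisons use
Mann–Whitney U, multi-group Kruskal–Wallis, each BH-adjusted across the
cell types of one table (one family per analysis table). Eigengene
correlations use Spearman with BH across the whole cell-type × module
matrix.

Dichotomization is a median split with ties to "low"; when the median is
exactly 0 the split is positive-vs-zero instead (frequencies of rare
populations). Kaplan–Meier estimation and Cox regression use lifelines;
the 60-month survival is reported as the five-year rate. The log-rank test
is computed from the standard O−E / √V form so the signed deviate is
available: the one-sided p tests the alternative "first group has the
higher hazard" via Φ̄(z); the two-sided p equals the χ²₁ tail of z² and
matches lifelines to machine precision. Before a Cox fit, binary
covariates with all or no events in one level are flagged
`complete separation` and excluded (the partial likelihood is unbounded);
non-convergence is likewise caught and reported rather than returned as a
spurious estimate.

## The synthetic cohort

The generator emulates the study design end to end: entity mix from a
54-patient cohort's proportions (SDC/ACC/MEC/Sec ≈ 23/13/12/6),
entity-specific compositions (SDC mCAF/Collagen-CAF-rich, ACC
lymphocyte-rich), 500×500 µm ROIs with planted niches — tumor cells in
Gaussian patches (3 patches, 80 µm radius), endothelia on vessel line
segments, mCAFs within a 20 µm vessel buffer with probability
`mcaf_vessel_affinity` (0.8 default), lymphoid cells in aggregates —
and lognormal raw counts per cell type: "high" markers at
lognormal(ln 60, 0.35), background at lognormal(0, 0.5), an intermediate
tier at ln 12 for weak CD4. On the asinh scale the high/background tiers
sit ≈ 11 SD apart, comfortably beyond the ≥ 4 SD separation the recovery
guarantees assume. Lognormal (rather than negative-binomial) counts match
the continuous positive intensities the asinh transform expects.

Survival: recurrence times are exponential with hazard
`0.008 · exp(β · mCAF fraction)` per month (β defaults to log 6 / 0.3),
death times exponential and independent of mCAF (the motivating cohort
showed a recurrence/distant-metastasis effect, not an overall-survival
one), distant recurrence occurs with probability 0.6 at the recurrence
time, and censoring is administrative at 120 months plus an independent
exponential calibrated to place `censor_rate` mass before the horizon.
For planted *group* hazard ratios the per-patient mCAF fraction can be
drawn from two tight clusters (0.1 / 0.4, jitter SD 0.01) assigned by
patient-index parity: the balanced design makes the cohort median fall
between the clusters, so the dichotomized contrast carries exactly
`exp(β·0.3)` and the linear-in-fraction model coincides with a two-group
model. One global seed fans out to per-(patient, ROI) child seeds through
`numpy.random.SeedSequence`, so any ROI regenerates in isolation.

Spatial transcriptomics: spots on a grid mix three profiles (mCAF,
endothelia, other) whose genes are 8-fold enriched in their own program,
times lognormal noise (σ = 0.2). mCAF and endothelia abundances are
bounded logistic transforms of two Gaussian random fields correlated at
`st_colocalization`; because the abundances are additive (no shared
normalization denominator), the planted correlation passes through to the
true compositions — exactly ±1 at the extremes, near 0 when independent.
Field smoothing (Gaussian, σ = 0.8 grid units) keeps spatial structure
while leaving enough effective samples that 2,000 independent-field spots
stay below |r| ≈ 0.1.

**What the synthetic data does not emulate:** segmentation errors and
lateral spillover between touching cells, batch/slide effects, marker
tiers closer than 4 SD (real CAF subsets blur into each other),
non-exponential hazards, informative censoring, and ST spots whose
composition drifts with library size. Passing recovery studies therefore
show the pipeline is correct and calibrated under its stated model, not
that real SGC cohorts will separate as cleanly.

## Validation studies and problem sizes

`sgctme.studies` (exercised by `scripts/acceptance.py` and the test
suite) uses these sizes, chosen so each estimate's Monte-Carlo error is
small against its acceptance band while the whole battery stays
interactive: interaction-test calibration on 200 random-label ROIs
(300 cells, 3 types, P = 1000, α = 0.01; 1,800 pooled tests — pooling
across the 9 ordered pairs, since a single pair at 200 ROIs has a ~14%
chance of zero rejections under perfect calibration); avoidance detection
on 100 segregated two-block ROIs; phenotype recovery on a 2,500-cell ROI
with 8 planted types; neighborhood recovery on a 600-cell two-niche ROI
plus a 50,000-cell 9-neighborhood timing run; patch-detection agreement
with a BFS flood-fill oracle on 50 random ROIs; and survival recovery
over 100 cohorts of 200 patients at a planted group hazard ratio of 6
(clinical-only fast path, no cell synthesis).

## Known limitations

- The SOM and k-means stages are seeded but floating-point order
  sensitive; permuting input rows can flip borderline cells (the tests
  allow 3% flips on well-separated data).
- The hull-based "inside a patch" convention over-calls infiltration for
  cells in concave indentations of large patches.
- The module-score control draw excludes nothing: a signature gene can be
  drawn as its own control when its bin is small, shrinking the score
  toward 0 (the convention of the reference implementation).
- Complete-separation detection covers binary covariates; a continuous
  covariate that perfectly orders events is only caught by the
  convergence guard.
- `categorize_spots` loops per sample and spot; it is comfortable at 10⁴–10⁵
  spots but not engineered for millions.
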