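"""Gene-signature construction and scoring.

The mCAF-like signature takes the top fraction (default 20%) of genes
overexpressed in matrix CAFs from a differential-expression table, keeping
each gene's log2 fold change as its weight.  Bulk samples are scored by the
weight-expression product averaged over signature genes; spatial-
transcriptomics spots are scored by expression-bin-matched module scores
(set mean minus control-gene mean, no weights), then categorized by
quantile co-expression of the mCAF-like and endothelial scores, compared by
rank-sum differential expression, and annotated by pre-ranked gene-set
enrichment on user-supplied sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CATEGORIES = (
    "mCAF_high_endothelia_high",
    "mCAF_high_endothelia_low",
    "mCAF_low_endothelia_high",
    "mCAF_low_endothelia_low",
    "other",
)


@dataclass
class WeightedSignature:
    """Gene list with positive log2FC weights."""

    genes: tuple[str, ...]
    weights: dict = field(default_factory=dict)   # gene -> log2FC

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature gene names must be unique")


def build_weighted_signature(de_table: pd.DataFrame,
                             q_sel: float = 0.2) -> WeightedSignature:
    """Top-``q_sel`` fraction of overexpressed genes ranked by log2FC.

    Keeps genes with log2FC > 0, sorts descending and retains
    ``ceil(q_sel * count)`` of them (98 of 490 at the default 20%).
    """
    if not 0 < q_sel <= 1:
        raise ValueError("q_sel must be in (0, 1]")
    over = de_table[de_table["log2FC"] > 0]
    if over.empty:
        raise ValueError("no overexpressed genes in the DE table")
    n_keep = math.ceil(q_sel * len(over))
    top = over.sort_values("log2FC", ascending=False, kind="mergesort")
    top = top.head(n_keep)
    return WeightedSignature(
        genes=tuple(top["gene"]),
        weights=dict(zip(top["gene"], top["log2FC"])),
    )


def score_weighted_signature(expression: pd.Series,
                             signature: WeightedSignature,
                             log_transform: bool = False) -> float:
    """Mean of expression x log2FC over the signature genes present.

    Signature genes missing from the expression vector are dropped with a
    warning; ``log_transform`` applies log2(x + 1) first.
    """
    present = [g for g in signature.genes if g in expression.index]
    if not present:
        raise ValueError("no signature gene present in the expression vector")
    if len(present) < len(signature.genes):
        warnings.warn(
            f"{len(signature.genes) - len(present)} signature genes absent; "
            f"averaging over {len(present)}", stacklevel=2)
    expr = expression.loc[present].to_numpy(dtype=float)
    if log_transform:
        expr = np.log2(expr + 1.0)
    w = np.array([signature.weights[g] for g in present])
    return float(np.mean(expr * w))


def score_matrix(expression: pd.DataFrame, signature: WeightedSignature,
                 log_transform: bool = False) -> pd.Series:
    """Weighted signature score per sample of a genes x samples matrix."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pd.Series(
            {s: score_weighted_signature(expression[s], signature,
                                         log_transform)
             for s in expression.columns}, name="mcaf_score")


def stratify_by_signature(scores: pd.Series) -> pd.Series:
    """Median split: score > median -> 'high', else 'low'."""
    if len(scores) < 2:
        raise ValueError("need at least 2 samples to stratify")
    if scores.nunique() == 1:
        raise ValueError("degenerate stratification: all scores equal")
    med = scores.median()
    return pd.Series(np.where(scores > med, "high", "low"),
                     index=scores.index, name="group")


# ---------------------------------------------------------------------------
# module scores


@dataclass
class ModuleScoreConfig:
    n_bins: int = 24
    n_ctrl: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_bins < 1 or self.n_ctrl < 1:
            raise ValueError("n_bins and n_ctrl must be >= 1")


def module_score(expression: pd.DataFrame, gene_set,
                 config: ModuleScoreConfig | None = None) -> pd.Series:
    """Expression-bin-matched module score per spot.

    ``expression`` is spots x genes.  Per spot: mean expression of the set
    genes minus the mean over a control pool drawn per set gene from the
    same average-expression bin (``n_ctrl`` controls per gene, whole bin if
    smaller).  Gene weights are deliberately not used.
    """
    config = config or ModuleScoreConfig()
    genes = list(expression.columns)
    present = [g for g in gene_set if g in expression.columns]
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    rng = np.random.default_rng(config.seed)

    avg = expression.mean(axis=0)
    # rank-based cut: equal-occupancy bins regardless of the distribution
    order = avg.rank(method="first")
    bins = np.minimum((order - 1) // math.ceil(len(genes) / config.n_bins),
                      config.n_bins - 1).astype(int)
    genes_in_bin = {b: list(avg.index[bins == b]) for b in np.unique(bins)}

    ctrl: set = set()
    for g in present:
        pool = genes_in_bin[int(bins[g])]
        if len(pool) <= config.n_ctrl:
            ctrl.update(pool)
        else:
            ctrl.update(rng.choice(pool, size=config.n_ctrl, replace=False))
    ctrl_genes = sorted(ctrl)
    score = (expression[present].mean(axis=1)
             - expression[ctrl_genes].mean(axis=1))
    return score.rename("module_score")


def categorize_spots(mcaf_scores: pd.Series, endo_scores: pd.Series,
                     sample_ids: pd.Series, q: float = 0.2) -> pd.Series:
    """Quantile co-expression categories, assigned per sample then pooled.

    Per sample the top-floor(q*n) spots by each score are "high", the
    bottom-floor(q*n) "low" (ties broken by spot id); the four
    intersections plus "other" partition all spots.
    """
    cats = pd.Series("other", index=mcaf_scores.index, dtype=object)
    for sample in pd.unique(sample_ids):
        idx = sample_ids.index[sample_ids == sample]
        n_sel = int(math.floor(q * len(idx)))
        if n_sel < 1:
            raise ValueError(
                f"q={q} selects no spots in sample {sample} (n={len(idx)})")

        def top_bottom(score):
            s = score.loc[idx].reset_index()
            s.columns = ["spot", "score"]
            s = s.sort_values(["score", "spot"], ascending=[False, True],
                              kind="mergesort")
            hi = set(s["spot"].head(n_sel))
            s = s.sort_values(["score", "spot"], ascending=[True, True],
                              kind="mergesort")
            lo = set(s["spot"].head(n_sel))
            return hi, lo

        m_hi, m_lo = top_bottom(mcaf_scores)
        e_hi, e_lo = top_bottom(endo_scores)
        for spot in idx:
            m = "high" if spot in m_hi else ("low" if spot in m_lo else None)
            e = "high" if spot in e_hi else ("low" if spot in e_lo else None)
            if m and e:
                cats[spot] = f"mCAF_{m}_endothelia_{e}"
    return cats.rename("category")


# ---------------------------------------------------------------------------
# differential expression + enrichment


def rank_sum_de(expression: pd.DataFrame, in_group: pd.Series,
                eps: float = 1e-9) -> pd.DataFrame:
    """Per-gene two-sided rank-sum test of group A vs the rest.

    ``expression`` is spots x genes, ``in_group`` a boolean per spot.
    avg_log2FC = log2((mean_A + eps) / (mean_B + eps)), BH-adjusted across
    genes.
    """
    mask = np.asarray(in_group, dtype=bool)
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise ValueError("both groups must be non-empty")
    A = expression.loc[mask].to_numpy(dtype=float)
    B = expression.loc[~mask].to_numpy(dtype=float)
    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    lfc = np.log2((mean_a + eps) / (mean_b + eps))
    with np.errstate(invalid="ignore"):
        _, p = stats.mannwhitneyu(A, B, axis=0, alternative="two-sided")
    # genes constant across both groups carry no evidence
    const = (expression.nunique(axis=0) == 1).to_numpy()
    p = np.where(const | ~np.isfinite(p), 1.0, p)
    padj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"gene": expression.columns, "avg_log2FC": lfc,
                         "p": p, "p_adj": padj}).set_index("gene")


def _running_sum_es(ranked_genes, gene_set: set) -> float:
    """Classic KS-style enrichment score on a ranked gene list."""
    hits = np.fromiter((g in gene_set for g in ranked_genes), dtype=bool,
                       count=len(ranked_genes))
    n_hit = int(hits.sum())
    n_miss = len(hits) - n_hit
    if n_hit == 0 or n_miss == 0:
        return 0.0
    step = np.where(hits, 1.0 / n_hit, -1.0 / n_miss)
    rs = np.cumsum(step)
    return float(rs[np.argmax(np.abs(rs))])


@dataclass
class EnrichmentResult:
    table: pd.DataFrame           # per set: es, p, q, size, coverage
    dropped: dict                 # set -> coverage, below the filter


def preranked_enrichment(ranked: pd.Series, gene_sets: dict,
                         n_perm: int = 1000, seed: int = 0,
                         min_coverage: float = 0.4) -> EnrichmentResult:
    """Pre-ranked gene-set enrichment with a gene-label permutation null.

    ``ranked`` maps gene -> ranking statistic (sorted descending
    internally).  Sets with under ``min_coverage`` of their genes present
    in the ranking are excluded.  ES is the KS running-sum max deviation;
    p-values compare |ES| against permuted-ranking nulls and are
    BH-adjusted into q-values.
    """
    ranked = ranked.sort_values(ascending=False, kind="mergesort")
    universe = list(ranked.index)
    uset = set(universe)

    kept, dropped = {}, {}
    for name, genes in gene_sets.items():
        genes = list(dict.fromkeys(genes))
        coverage = sum(g in uset for g in genes) / max(1, len(genes))
        if coverage < min_coverage:
            dropped[name] = coverage
        else:
            kept[name] = (set(g for g in genes if g in uset), coverage)
    if not kept:
        raise ValueError("no gene set survives the coverage filter")

    rng = np.random.default_rng(seed)
    rows = []
    N = len(universe)
    for name, (gset, coverage) in kept.items():
        es = _running_sum_es(universe, gset)
        hits = np.fromiter((g in gset for g in universe), dtype=bool, count=N)
        n_hit = int(hits.sum())
        # permuting gene labels == permuting the hit-indicator vector
        null_hits = np.zeros((n_perm, N), dtype=bool)
        for i in range(n_perm):
            null_hits[i, rng.choice(N, size=n_hit, replace=False)] = True
        step = np.where(null_hits, 1.0 / n_hit, -1.0 / (N - n_hit))
        rs = np.cumsum(step, axis=1)
        null_es = np.take_along_axis(
            rs, np.argmax(np.abs(rs), axis=1)[:, None], axis=1).ravel()
        pval = (1.0 + int((np.abs(null_es) >= abs(es)).sum())) / (n_perm + 1.0)
        rows.append({"set": name, "es": es, "p": pval,
                     "size": len(gset), "coverage": coverage})
    table = pd.DataFrame(rows).set_index("set")
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    return EnrichmentResult(table=table, dropped=dropped)


def score_correlation(x: pd.Series, y: pd.Series) -> tuple[float, float]:
    """Pearson correlation of two per-spot score vectors."""
    if len(x) != len(y):
        raise ValueError("score vectors must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a score vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
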