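"""Hierarchical marker-based cell phenotyping.

The hierarchy mirrors validated CAF/immune classification practice for
imaging mass cytometry: a Gaussian-mixture gate on cytokeratin separates
tumor from microenvironment cells; microenvironment cells are clustered
(self-organizing map + consensus metaclustering) and metaclusters are
labeled by deterministic marker-positivity rules — endothelia (CD31+),
immune (CD45+/CD138+), CAFs by negative selection, then immune and CAF
subsets by their defining markers (e.g. mCAF = aSMA+Collagen1+).

A metacluster counts as marker-positive when its mean transformed value
exceeds the across-cluster midrange for that marker; when a marker shows no
spread across clusters (uniformly expressed within a compartment, e.g.
Vimentin among CAFs) the midrange of the per-cell values stands in.  Both
rules are deterministic surrogates for the visual annotation step of the
interactive workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import brentq
from scipy.spatial.distance import cdist, squareform
from sklearn.mixture import GaussianMixture

from .panel import DEFAULT_PANEL, LEVEL1_OF_FINAL, MARKERS

TRANSFORM_PREFIX = "t_"


def arcsinh_transform(raw, cofactor: float = 1.0):
    """Inverse hyperbolic sine variance-stabilizing transform.

    ``asinh(raw / cofactor)``; strictly increasing, maps 0 to 0.
    """
    if cofactor <= 0:
        raise ValueError("cofactor must be > 0")
    arr = np.asarray(raw, dtype=float)
    if (arr < 0).any():
        raise ValueError("raw counts must be nonnegative")
    out = np.arcsinh(arr / cofactor)
    return out if out.ndim else float(out)


def transform_cell_table(cells: pd.DataFrame, markers=MARKERS,
                         cofactor: float = 1.0) -> pd.DataFrame:
    """Append ``t_<marker>`` asinh-transformed columns (copy)."""
    out = cells.copy()
    for m in markers:
        out[TRANSFORM_PREFIX + m] = arcsinh_transform(out[m].to_numpy(),
                                                      cofactor)
    return out


# ---------------------------------------------------------------------------
# tumor gate


@dataclass
class GateResult:
    threshold: float
    means: tuple[float, float]          # (low, high) component means
    weights: tuple[float, float]
    sigmas: tuple[float, float]
    posterior_high: np.ndarray          # per-cell posterior of high component
    calls: np.ndarray                   # True = tumor


def gate_tumor(ck_values, seed: int = 0) -> GateResult:
    """Two-component 1-D Gaussian mixture gate on cytokeratin.

    Cells whose posterior for the high-mean component exceeds 0.5 are called
    tumor (ties go to non-tumor); the reported threshold is the posterior
    crossing point, which always lies between the two component means.
    """
    x = np.asarray(ck_values, dtype=float).reshape(-1, 1)
    if len(x) < 100:
        raise ValueError("tumor gate requires >= 100 cells")
    if np.ptp(x) == 0 or np.std(x) == 0:
        raise ValueError("no separable components")
    gm = GaussianMixture(n_components=2, n_init=3, random_state=seed)
    gm.fit(x)
    order = np.argsort(gm.means_.ravel())
    lo, hi = (int(order[0]), int(order[1]))
    post = gm.predict_proba(x)[:, hi]
    calls = post > 0.5

    m_lo, m_hi = float(gm.means_.ravel()[lo]), float(gm.means_.ravel()[hi])

    def post_high(v):
        return gm.predict_proba(np.array([[v]]))[0, hi] - 0.5

    try:
        thr = float(brentq(post_high, m_lo, m_hi))
    except ValueError:  # no sign change: fall back to midpoint
        thr = 0.5 * (m_lo + m_hi)
    return GateResult(
        threshold=thr,
        means=(m_lo, m_hi),
        weights=(float(gm.weights_[lo]), float(gm.weights_[hi])),
        sigmas=(float(np.sqrt(gm.covariances_.ravel()[lo])),
                float(np.sqrt(gm.covariances_.ravel()[hi]))),
        posterior_high=post,
        calls=calls,
    )


# ---------------------------------------------------------------------------
# SOM + consensus metaclustering


@dataclass
class ClusterModel:
    grid: tuple[int, int]
    markers: tuple[str, ...]
    codebook: np.ndarray                # nodes x d
    node_of_cell: np.ndarray            # cell -> node id
    metacluster_of_node: np.ndarray | None = None
    consensus: np.ndarray | None = None
    consensus_params: dict = field(default_factory=dict)

    @property
    def metacluster_of_cell(self) -> np.ndarray:
        if self.metacluster_of_node is None:
            raise ValueError("metaclustering not yet run")
        return self.metacluster_of_node[self.node_of_cell]


def _som_train(X: np.ndarray, grid, seed: int, n_epochs: int = 20):
    """Batch self-organizing map; deterministic given seed."""
    gx, gy = grid
    n_nodes = gx * gy
    rng = np.random.default_rng(seed)
    # init from sampled data points so every mode can claim a node
    codebook = X[rng.choice(len(X), size=n_nodes, replace=False)].astype(float)

    gi, gj = np.divmod(np.arange(n_nodes), gy)
    grid_d2 = (gi[:, None] - gi[None, :]) ** 2 + (gj[:, None] - gj[None, :]) ** 2
    sigma0, sigma_end = max(gx, gy) / 2.0, 0.2
    for epoch in range(n_epochs):
        sigma = sigma0 * (sigma_end / sigma0) ** (epoch / max(1, n_epochs - 1))
        bmu = np.argmin(cdist(X, codebook, "sqeuclidean"), axis=1)
        h = np.exp(-grid_d2 / (2 * sigma**2))
        sums = np.zeros_like(codebook)
        np.add.at(sums, bmu, X)
        counts = np.bincount(bmu, minlength=n_nodes).astype(float)
        num = h @ sums
        den = (h @ counts)[:, None]
        good = den[:, 0] > 1e-12
        codebook[good] = num[good] / den[good]
    bmu = np.argmin(cdist(X, codebook, "sqeuclidean"), axis=1)
    return codebook, bmu


def som_cluster(cells: pd.DataFrame, markers, grid=(10, 10),
                seed: int = 0) -> ClusterModel:
    """Train a SOM on transformed markers; assign each cell to its node."""
    DEFAULT_PANEL.validate(markers)
    n_nodes = grid[0] * grid[1]
    if len(cells) < n_nodes:
        raise ValueError(
            f"need at least {n_nodes} cells for a {grid[0]}x{grid[1]} SOM, "
            f"got {len(cells)}")
    cols = [TRANSFORM_PREFIX + m for m in markers]
    missing = [c for c in cols if c not in cells.columns]
    if missing:
        raise KeyError(f"transformed columns missing: {missing}")
    X = cells[cols].to_numpy(dtype=float)
    codebook, bmu = _som_train(X, grid, seed)
    return ClusterModel(grid=tuple(grid), markers=tuple(markers),
                        codebook=codebook, node_of_cell=bmu)


def consensus_metacluster(model: ClusterModel, k: int, reps: int = 100,
                          subsample: float = 0.8, seed: int = 0) -> np.ndarray:
    """Consensus metaclustering of SOM node codebook vectors.

    Repeated subsampled average-linkage hierarchical clusterings build a
    consensus co-clustering matrix; the final partition is an average-
    linkage cut of (1 - consensus) at ``k``.  With ``reps=1`` and
    ``subsample=1.0`` this reduces to a single hierarchical cut.
    """
    n_nodes = len(model.codebook)
    if k > n_nodes:
        raise ValueError(f"k={k} exceeds node count {n_nodes}")
    if k < 1 or reps < 1 or not 0 < subsample <= 1:
        raise ValueError("invalid consensus parameters")
    rng = np.random.default_rng(seed)
    co = np.zeros((n_nodes, n_nodes))
    together = np.zeros((n_nodes, n_nodes))
    m = max(k, int(np.floor(subsample * n_nodes)))
    for _ in range(reps):
        idx = np.sort(rng.choice(n_nodes, size=m, replace=False))
        sub = model.codebook[idx]
        if len(idx) > 1:
            cl = fcluster(linkage(sub, method="average"), k,
                          criterion="maxclust")
        else:
            cl = np.ones(1, dtype=int)
        same = cl[:, None] == cl[None, :]
        co[np.ix_(idx, idx)] += same
        together[np.ix_(idx, idx)] += 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(together > 0, co / np.maximum(together, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)

    if k == 1:
        meta = np.ones(n_nodes, dtype=int)
    else:
        d = squareform(1.0 - consensus, checks=False)
        meta = fcluster(linkage(d, method="average"), k, criterion="maxclust")
    model.metacluster_of_node = meta
    model.consensus = consensus
    model.consensus_params = {"reps": reps, "subsample": subsample,
                              "k": k, "seed": seed}
    return meta


# ---------------------------------------------------------------------------
# marker-rule engine


#: below this spread (asinh units) of cluster means, fall back to the
#: per-cell midrange — the marker is uniformly high or low in this stage
MIN_CLUSTER_SPREAD = 1.0


def _cluster_means(cells, cluster_ids, markers) -> pd.DataFrame:
    cols = [TRANSFORM_PREFIX + m for m in markers]
    df = cells[cols].copy()
    df.columns = markers
    df["_cl"] = np.asarray(cluster_ids)
    return df.groupby("_cl").mean()


def _positivity(means: pd.DataFrame, cells: pd.DataFrame) -> pd.DataFrame:
    """Marker-positive calls per cluster by the midrange rule.

    A marker with no spread across clusters (uniformly expressed in this
    compartment) is called for all clusters at once by comparing its level
    against the stage-wide midrange over every marker's cluster means.
    """
    global_mid = 0.5 * (means.to_numpy().min() + means.to_numpy().max())
    pos = {}
    for m in means.columns:
        col = means[m]
        if col.max() - col.min() >= MIN_CLUSTER_SPREAD:
            thr = 0.5 * (col.max() + col.min())
            pos[m] = col > thr
        else:
            pos[m] = pd.Series(col.mean() > global_mid, index=col.index)
    return pd.DataFrame(pos)


def _split_high_low(means: pd.Series, positive: pd.Series) -> pd.Series:
    """Among positive clusters, split into high/low by a second midrange."""
    out = pd.Series(False, index=means.index)
    pos_means = means[positive]
    if pos_means.empty:
        return out
    thr = 0.5 * (pos_means.min() + pos_means.max())
    out.loc[pos_means.index[pos_means >= thr]] = True
    return out


# ---------------------------------------------------------------------------
# hierarchy stages


@dataclass
class PhenotypingConfig:
    """Stage parameters of the phenotyping hierarchy.

    Metacluster counts are explicit (reproducibility over interactive
    choice): level-1 k=6, immune k=6, CD4 re-cluster k=4, CAF k=8.
    """

    cofactor: float = 1.0
    som_grid: tuple[int, int] = (10, 10)
    level1_k: int = 6
    immune_k: int = 6
    cd4_k: int = 4
    caf_k: int = 8
    consensus_reps: int = 100
    consensus_subsample: float = 0.8


LEVEL1_MARKERS = ("CD31", "CD45", "CD138")
IMMUNE_MARKERS = ("CD45", "CD4", "CD8a", "CD138")
CD4_MARKERS = ("CD45", "CD4", "CD74", "Ki67")
CAF_MARKERS = ("Vimentin", "aSMA", "Collagen1", "Ki67", "CD74", "CD34")


def _cluster_stage(cells, markers, k, config, seed):
    """SOM + consensus on one stage; returns per-cell metacluster ids."""
    grid = config.som_grid
    n_nodes = grid[0] * grid[1]
    if len(cells) < n_nodes:  # shrink the map for small stages
        side = max(2, int(np.floor(np.sqrt(len(cells)))))
        grid = (min(side, grid[0]), min(side, grid[1]))
    model = som_cluster(cells, markers, grid=grid, seed=seed)
    consensus_metacluster(model, k=min(k, grid[0] * grid[1]),
                          reps=config.consensus_reps,
                          subsample=config.consensus_subsample, seed=seed + 1)
    return model, model.metacluster_of_cell


def classify_level1(cells: pd.DataFrame, cluster_ids) -> pd.Series:
    """Label TME metaclusters: endothelia / immune / CAF.

    CD31+ clusters are endothelia; CD45+ or CD138+ clusters are immune;
    clusters negative for CD31/CD45/CD138 are CAFs (explicit negative
    selection).
    """
    if len(cells) == 0:
        return pd.Series(dtype=object, index=cells.index)
    means = _cluster_means(cells, cluster_ids, LEVEL1_MARKERS)
    if means.isna().any().any():
        bad = means[means.isna().any(axis=1)]
        raise ValueError(f"unlabelable metacluster(s):\n{bad}")
    pos = _positivity(means, cells)
    label_of_cluster = pd.Series("CAF", index=means.index)
    label_of_cluster[pos["CD45"] | pos["CD138"]] = "immune"
    label_of_cluster[pos["CD31"]] = "endothelia"
    return pd.Series(label_of_cluster[np.asarray(cluster_ids)].to_numpy(),
                     index=cells.index)


def classify_immune(cells: pd.DataFrame, config: PhenotypingConfig,
                    seed: int = 0) -> pd.Series:
    """Final immune labels.

    CD138+ -> plasma cell; CD8a+ -> CD8 T; CD4 high -> CD4 T branch
    (re-clustered with CD45/CD4/CD74/Ki67 into proliferating CD4 T (Ki67+),
    CD4+CD74+ T (CD74+), CD4 T); CD4 low-positive -> other CD4+;
    CD45 only -> other immune.
    """
    if len(cells) == 0:
        return pd.Series(dtype=object, index=cells.index)
    _, cl = _cluster_stage(cells, IMMUNE_MARKERS, config.immune_k, config, seed)
    means = _cluster_means(cells, cl, IMMUNE_MARKERS)
    pos = _positivity(means, cells)
    cd4_high = _split_high_low(means["CD4"], pos["CD4"])

    label_of_cluster = pd.Series("other immune", index=means.index)
    label_of_cluster[pos["CD4"] & ~cd4_high] = "other CD4+"
    label_of_cluster[cd4_high] = "CD4 T"
    label_of_cluster[pos["CD8a"]] = "CD8 T"
    label_of_cluster[pos["CD138"]] = "plasma cell"
    labels = pd.Series(label_of_cluster[np.asarray(cl)].to_numpy(),
                       index=cells.index)

    cd4_cells = cells[labels == "CD4 T"]
    if len(cd4_cells) >= 4:
        _, cl4 = _cluster_stage(cd4_cells, CD4_MARKERS, config.cd4_k,
                                config, seed + 101)
        m4 = _cluster_means(cd4_cells, cl4, CD4_MARKERS)
        p4 = _positivity(m4, cd4_cells)
        sub = pd.Series("CD4 T", index=m4.index)
        sub[p4["CD74"]] = "CD4+CD74+ T"
        sub[p4["Ki67"]] = "proliferating CD4 T"
        labels.loc[cd4_cells.index] = sub[np.asarray(cl4)].to_numpy()
    return labels


def _caf_rules(pos: pd.DataFrame) -> pd.Series:
    label = pd.Series("", index=pos.index)  # "" = no specific CAF marker
    label[pos["Vimentin"]] = "other CAF (Vimentin+)"
    label[pos["CD74"] & pos["Vimentin"]] = "apCAF"
    label[pos["Ki67"] & pos["Vimentin"]] = "dCAF"
    label[pos["aSMA"] & ~pos["Collagen1"]] = "SMA CAF"
    label[~pos["aSMA"] & pos["Collagen1"]] = "Collagen CAF"
    label[pos["aSMA"] & pos["Collagen1"]] = "mCAF"
    return label


def classify_caf(cells: pd.DataFrame, config: PhenotypingConfig,
                 seed: int = 0, _depth: int = 0) -> pd.Series:
    """Final CAF labels with residual reassignment.

    mCAF = aSMA+Collagen1+; Collagen CAF = aSMA-Collagen1+; SMA CAF =
    aSMA+Collagen1-; dCAF = Ki67+Vimentin+; apCAF = CD74+Vimentin+; sole
    Vimentin -> other CAF (Vimentin+).  Cells in clusters negative for every
    marker are re-clustered once; those still negative are relabeled tumor
    (all-marker-negative cells sit inside tumor patches).
    """
    if len(cells) == 0:
        return pd.Series(dtype=object, index=cells.index)
    if len(cells) < 4:
        return pd.Series("tumor", index=cells.index)
    _, cl = _cluster_stage(cells, CAF_MARKERS, config.caf_k, config, seed)
    means = _cluster_means(cells, cl, CAF_MARKERS)
    pos = _positivity(means, cells)
    label_of_cluster = _caf_rules(pos)
    labels = pd.Series(label_of_cluster[np.asarray(cl)].to_numpy(),
                       index=cells.index)

    residual = labels == ""
    if residual.any():
        if _depth == 0:
            labels.loc[residual] = classify_caf(
                cells[residual], config, seed + 211, _depth=1)
        else:
            labels.loc[residual] = "tumor"
    return labels


def run_phenotyping(cells: pd.DataFrame, config: PhenotypingConfig | None = None,
                    seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Full hierarchy: gate -> level-1 -> immune/CAF subsets.

    Returns the labeled cell table (``label_level1``, ``label_final``
    columns added) and an audit log of cluster -> label assignments.
    """
    config = config or PhenotypingConfig()
    missing = [m for m in MARKERS if m not in cells.columns]
    if missing:
        raise KeyError(f"panel markers missing from table: {missing}")
    cells = transform_cell_table(cells, MARKERS, config.cofactor)
    audit: dict = {"stages": {}}

    gate = gate_tumor(cells[TRANSFORM_PREFIX + "CKAE13"].to_numpy(), seed=seed)
    audit["gate"] = {"threshold": gate.threshold, "means": gate.means,
                     "weights": gate.weights}
    final = pd.Series("tumor", index=cells.index, dtype=object)

    tme = cells[~gate.calls]
    if len(tme) >= 4:
        model1, cl1 = _cluster_stage(tme, LEVEL1_MARKERS, config.level1_k,
                                     config, seed + 1)
        lvl1 = classify_level1(tme, cl1)
        audit["stages"]["level1"] = _stage_audit(tme, cl1, LEVEL1_MARKERS, lvl1)

        final.loc[lvl1.index[lvl1 == "endothelia"]] = "endothelia"
        immune = tme[lvl1 == "immune"]
        if len(immune):
            final.loc[immune.index] = classify_immune(immune, config,
                                                      seed + 2)
        caf = tme[lvl1 == "CAF"]
        if len(caf):
            final.loc[caf.index] = classify_caf(caf, config, seed + 3)

    out = cells.copy()
    out["label_final"] = final
    out["label_level1"] = final.map(LEVEL1_OF_FINAL)
    audit["label_counts"] = out["label_final"].value_counts().to_dict()
    return out, audit


def _stage_audit(cells, cluster_ids, markers, cell_labels) -> dict:
    means = _cluster_means(cells, cluster_ids, markers)
    lab = pd.DataFrame({"_cl": np.asarray(cluster_ids),
                        "label": cell_labels.to_numpy()})
    cluster_label = lab.groupby("_cl")["label"].agg(
        lambda s: s.value_counts().idxmax())
    return {
        int(c): {"mean_profile": means.loc[c].round(3).to_dict(),
                 "label": cluster_label.get(c, "?")}
        for c in means.index
    }
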