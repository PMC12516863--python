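"""Per-ROI spatial analysis.

Builds directed k-nearest-neighbor graphs over cell centroids (k = 20 by
default), summarizes each cell by the phenotype fractions of its neighbors,
clusters those profiles into cellular neighborhoods, detects tumor patches
(connected components of at least 10 tumor cells), computes signed distances
of microenvironment cells to the tumor border, and tests pairwise cell-type
interaction/avoidance against a per-ROI permutation null in the style of
classic histoCAT neighborhood analysis: the statistic for an ordered pair
(A, B) is the mean number of B-neighbors over A-cells, and the null
permutes phenotype labels over fixed positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, QhullError, cKDTree
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .panel import FINAL_LABELS

_BRUTE_FORCE_MAX = 2500  # exact O(n^2) search below this ROI size


@dataclass
class SpatialGraph:
    """Directed kNN adjacency for one ROI.

    ``indices[i]`` holds the positional indices of cell i's
    ``min(k, n - 1)`` nearest neighbors, nearest first, distance ties broken
    by ascending cell_id.
    """

    roi_id: str
    k: int
    cell_ids: np.ndarray
    coords: np.ndarray            # n x 2, um
    indices: np.ndarray           # n x min(k, n-1)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


def build_knn_graph(cells: pd.DataFrame, k: int = 20,
                    roi_id: str | None = None) -> SpatialGraph:
    """Exact Euclidean kNN over (x_um, y_um) centroids."""
    if k <= 0:
        raise ValueError("k must be positive")
    n = len(cells)
    if n < 2:
        raise ValueError("an ROI needs at least 2 cells")
    coords = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    ids = cells["cell_id"].to_numpy()
    kk = min(k, n - 1)
    # columns pre-permuted into ascending cell_id order so that a stable
    # sort on distance breaks ties by cell_id
    id_order = np.argsort(ids, kind="stable")

    if n <= _BRUTE_FORCE_MAX:
        d = cdist(coords, coords)
        np.fill_diagonal(d, np.inf)
        dperm = d[:, id_order]
        nearest = np.argsort(dperm, axis=1, kind="stable")[:, :kk]
        indices = id_order[nearest]
    else:
        nn = NearestNeighbors(n_neighbors=min(n, kk + 1 + 8)).fit(coords)
        dist, cand = nn.kneighbors(coords)
        indices = np.empty((n, kk), dtype=int)
        rank = np.empty(n, dtype=int)
        rank[id_order] = np.arange(n)
        for i in range(n):
            row = cand[i][cand[i] != i]
            dr = dist[i][cand[i] != i]
            order = np.lexsort((rank[row], dr))
            indices[i] = row[order][:kk]
    if roi_id is None:
        rid = str(cells["roi_id"].iloc[0]) if "roi_id" in cells else "ROI"
    else:
        rid = roi_id
    return SpatialGraph(roi_id=rid, k=k, cell_ids=ids, coords=coords,
                        indices=indices)


def neighbor_fractions(graph: SpatialGraph, labels: pd.Series,
                       vocabulary=FINAL_LABELS) -> pd.DataFrame:
    """Per-cell phenotype fraction vector over the k nearest neighbors."""
    lab = np.asarray(labels)
    if pd.isna(lab).any():
        raise ValueError("every cell must carry a label")
    vocab = [v for v in vocabulary]
    extra = sorted(set(lab) - set(vocab))
    vocab += extra
    code_of = {v: i for i, v in enumerate(vocab)}
    codes = np.array([code_of[v] for v in lab])
    nbr_codes = codes[graph.indices]
    counts = np.stack([(nbr_codes == t).sum(axis=1)
                       for t in range(len(vocab))], axis=1)
    frac = counts / counts.sum(axis=1, keepdims=True)
    return pd.DataFrame(frac, columns=vocab, index=graph.cell_ids)


@dataclass
class NeighborhoodModel:
    n_neighborhoods: int
    centroids: np.ndarray              # clusters x labels, fraction space
    columns: tuple[str, ...]
    cn_of_cell: pd.Series              # cell_id -> CN id in 1..n


def assign_neighborhoods(profiles: pd.DataFrame, n_neighborhoods: int = 9,
                         seed: int = 0, n_init: int = 10) -> NeighborhoodModel:
    """K-means over neighbor-fraction space; CN ids are 1-based."""
    if len(profiles) < n_neighborhoods:
        raise ValueError("fewer cells than requested neighborhoods")
    km = KMeans(n_clusters=n_neighborhoods, n_init=n_init, random_state=seed)
    ids = km.fit_predict(profiles.to_numpy()) + 1
    return NeighborhoodModel(
        n_neighborhoods=n_neighborhoods,
        centroids=km.cluster_centers_,
        columns=tuple(profiles.columns),
        cn_of_cell=pd.Series(ids, index=profiles.index, name="cn"),
    )


# ---------------------------------------------------------------------------
# tumor patches


@dataclass
class TumorPatchSet:
    min_size: int
    patches: dict = field(default_factory=dict)   # patch id -> positional idx
    patch_of_cell: np.ndarray | None = None       # 0 = not in a patch
    graph: SpatialGraph | None = None


def detect_patches(graph: SpatialGraph, labels: pd.Series,
                   min_size: int = 10,
                   tumor_label: str = "tumor") -> TumorPatchSet:
    """Connected components of the symmetrized graph among tumor cells."""
    n = graph.n_cells
    lab = np.asarray(labels)
    tumor = lab == tumor_label
    result = TumorPatchSet(min_size=min_size,
                           patch_of_cell=np.zeros(n, dtype=int), graph=graph)
    t_idx = np.flatnonzero(tumor)
    if len(t_idx) == 0:
        return result
    pos = -np.ones(n, dtype=int)
    pos[t_idx] = np.arange(len(t_idx))
    src = np.repeat(np.arange(n), graph.indices.shape[1])
    dst = graph.indices.ravel()
    keep = tumor[src] & tumor[dst]
    rows, cols = pos[src[keep]], pos[dst[keep]]
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)),
                     shape=(len(t_idx), len(t_idx)))
    _, comp = connected_components(adj, directed=False)
    pid = 0
    for c in np.unique(comp):
        members = t_idx[comp == c]
        if len(members) >= min_size:
            pid += 1
            result.patches[pid] = members
            result.patch_of_cell[members] = pid
    return result


def _hulls(patchset: TumorPatchSet):
    hulls = []
    for members in patchset.patches.values():
        pts = patchset.graph.coords[members]
        if len(np.unique(pts, axis=0)) >= 3:
            try:
                hulls.append(Delaunay(pts))
            except QhullError:
                pass
    return hulls


def distance_to_border(cells: pd.DataFrame, patchset: TumorPatchSet,
                       labels: pd.Series) -> pd.DataFrame:
    """Signed distance of each TME cell to the nearest tumor-patch cell.

    Negative inside a patch (convex hull of the patch members, or patch
    membership for tumor cells); ``infiltrating`` flags TME cells inside a
    patch.  With no patches, distances are NaN and flags False.
    """
    n = len(cells)
    out = pd.DataFrame({"dist_to_tumor_border": np.full(n, np.nan),
                        "infiltrating": np.zeros(n, dtype=bool)},
                       index=cells.index)
    if not patchset.patches:
        return out
    coords = patchset.graph.coords
    member_idx = np.concatenate(list(patchset.patches.values()))
    tree = cKDTree(coords[member_idx])
    dist, _ = tree.query(coords)

    inside = patchset.patch_of_cell > 0
    hulls = _hulls(patchset)
    not_member = ~inside
    if hulls and not_member.any():
        pts = coords[not_member]
        in_hull = np.zeros(len(pts), dtype=bool)
        for h in hulls:
            in_hull |= h.find_simplex(pts) >= 0
        inside = inside.copy()
        inside[np.flatnonzero(not_member)[in_hull]] = True

    signed = np.where(inside, -dist, dist)
    tme = np.asarray(labels) != "tumor"
    out.loc[cells.index[tme], "dist_to_tumor_border"] = signed[tme]
    out.loc[cells.index[tme], "infiltrating"] = inside[tme]
    return out


# ---------------------------------------------------------------------------
# permutation interaction testing


def test_interactions(graph: SpatialGraph, labels: pd.Series,
                      n_perm: int = 1000, alpha: float = 0.01,
                      seed: int = 0) -> pd.DataFrame:
    """Permutation test of pairwise interaction/avoidance in one ROI.

    For each ordered pair (A, B) present, the observed statistic is the
    mean count of B-neighbors over A-cells; the null permutes all labels
    over fixed positions.  ``p_gt`` tests interaction (null >= observed),
    ``p_lt`` avoidance; ``sig`` is +1/-1/0 at level ``alpha``.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    lab = np.asarray(labels)
    types = sorted(set(lab))
    T = len(types)
    code_of = {t: i for i, t in enumerate(types)}
    codes = np.array([code_of[t] for t in lab])
    nbr = graph.indices
    sizes = np.bincount(codes, minlength=T).astype(float)

    def pair_stats(c):
        nbr_c = c[nbr]
        counts = np.stack([(nbr_c == t).sum(axis=1) for t in range(T)],
                          axis=1).astype(float)
        onehot = np.zeros((len(c), T))
        onehot[np.arange(len(c)), c] = 1.0
        return (onehot.T @ counts) / sizes[:, None]

    obs = pair_stats(codes)
    rng = np.random.default_rng(seed)
    ge = np.zeros((T, T))
    le = np.zeros((T, T))
    for _ in range(n_perm):
        null = pair_stats(codes[rng.permutation(len(codes))])
        ge += null >= obs
        le += null <= obs
    p_gt = (1.0 + ge) / (n_perm + 1.0)
    p_lt = (1.0 + le) / (n_perm + 1.0)

    rows = []
    for a in range(T):
        for b in range(T):
            sig = 1 if p_gt[a, b] <= alpha else (-1 if p_lt[a, b] <= alpha
                                                 else 0)
            rows.append({"roi_id": graph.roi_id, "from_label": types[a],
                         "to_label": types[b], "ct": obs[a, b],
                         "p_gt": p_gt[a, b], "p_lt": p_lt[a, b], "sig": sig})
    return pd.DataFrame(rows)


def summarize_interactions(tables) -> pd.DataFrame:
    """Per ordered pair: ROI counts with significant interaction/avoidance."""
    if len(tables) == 0:
        return pd.DataFrame(columns=["from_label", "to_label",
                                     "n_pos", "n_neg", "net"])
    allt = pd.concat(tables, ignore_index=True)
    grp = allt.groupby(["from_label", "to_label"])["sig"]
    out = pd.DataFrame({
        "n_pos": grp.apply(lambda s: int((s == 1).sum())),
        "n_neg": grp.apply(lambda s: int((s == -1).sum())),
    }).reset_index()
    out["net"] = out["n_pos"] - out["n_neg"]
    return out
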