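"""Per-donor graph clustering, cross-donor cluster matching and subgroup
annotation.

Each donor is clustered separately (PCA -> kNN graph -> Louvain), with the
clustering resolution chosen as the largest value at which every cluster
still contains every treatment condition. Clusters are then matched across
donors by the percentage overlap of their top-1000 marker-gene lists
(average-linkage hierarchical clustering on 100 - overlap), and the matched
groups are annotated as subgroups I-III by marker-panel scores, or as
subgroup IV (loss of expression) when a group's fraction-of-cells-expressing
falls far below the best group's.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import igraph
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.cluster.hierarchy as sch
import scipy.sparse as sp
from anndata import AnnData

from .simulate import MARKER_SET_NAMES

UNASSIGNED = "unassigned"
UNMATCHED = "unmatched"


@dataclass
class MarkerPanel:
    """Named marker-gene sets used to annotate subgroups.

    ``subgroup_of_set`` maps each set name to the subgroup it identifies; by
    default the field-standard names (sterol/bile-acid -> I,
    carbohydrate/phase-II -> II, lipid/phase-III -> III) are recognized.
    """

    sets: dict[str, list[str]]
    subgroup_of_set: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.subgroup_of_set:
            inverse = {v: k for k, v in MARKER_SET_NAMES.items()}
            self.subgroup_of_set = {name: inverse.get(name, name) for name in self.sets}
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"marker set {name!r} is empty")

    @classmethod
    def from_tsv(cls, path) -> "MarkerPanel":
        """Read a two-column TSV (set_name, gene)."""
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lower() for c in df.columns]
        sets = {name: grp["gene"].tolist() for name, grp in df.groupby(df.columns[0])}
        return cls(sets=sets)

    def resolve(self, genes: pd.Index) -> dict[str, list[str]]:
        """Intersect sets with the matrix genes; unresolved ids are logged, not fatal."""
        out = {}
        for name, gs in self.sets.items():
            present = [g for g in gs if g in genes]
            missing = len(gs) - len(present)
            if missing:
                warnings.warn(f"marker set {name!r}: {missing} gene id(s) not in the matrix")
            out[name] = present
        return out


@dataclass
class ClusterMap:
    """Per-cell cluster labels (per donor) with optional subgroup labels and
    per-cluster ranked marker lists."""

    cells: pd.DataFrame  # columns: cluster, and optionally subgroup
    markers: dict[str, pd.DataFrame] = field(default_factory=dict)


def _pca_embedding(nm: AnnData, n_pcs: int, seed: int) -> np.ndarray:
    if n_pcs >= min(nm.n_obs, nm.n_vars):
        raise ValueError(f"n_pcs={n_pcs} must be < min(n_cells, n_genes)={min(nm.n_obs, nm.n_vars)}")
    work = AnnData(X=nm.X.copy() if sp.issparse(nm.X) else np.array(nm.X))
    sc.pp.scale(work, max_value=10)
    sc.tl.pca(work, n_comps=n_pcs, svd_solver="arpack", random_state=seed)
    return work.obsm["X_pca"]


def cluster_cells(nm: AnnData, n_pcs: int = 50, k_neighbors: int = 15,
                  resolution: float = 1.0, seed: int = 0) -> pd.Series:
    """Louvain community labels from a kNN graph of the PCA embedding.

    PCA is computed on standardized log-normalized expression; the graph uses
    scanpy's neighbor connectivities as edge weights; communities come from
    igraph's multilevel (Louvain) algorithm at the given resolution,
    deterministic for a fixed seed.
    """
    if nm.n_obs < k_neighbors + 1:
        raise ValueError("need at least k_neighbors + 1 cells")
    emb = _pca_embedding(nm, n_pcs, seed)
    work = AnnData(X=np.zeros((nm.n_obs, 1), dtype=np.float32))
    work.obsm["X_pca"] = emb
    sc.pp.neighbors(work, n_neighbors=k_neighbors, use_rep="X_pca", random_state=seed)
    adj = sp.triu(work.obsp["connectivities"].tocoo())
    g = igraph.Graph(n=nm.n_obs, edges=list(zip(adj.row, adj.col)), edge_attrs={"weight": adj.data})
    igraph.set_random_number_generator(random.Random(seed))
    part = g.community_multilevel(weights="weight", resolution=resolution)
    labels = np.asarray(part.membership)
    # relabel by decreasing cluster size for stable, readable ids
    sizes = pd.Series(labels).value_counts()
    remap = {old: new for new, old in enumerate(sizes.index)}
    return pd.Series([str(remap[l]) for l in labels], index=nm.obs_names, name="cluster")


def select_resolution(nm: AnnData, treatments: pd.Series | np.ndarray,
                      grid: list[float], min_cells: int = 1,
                      **cluster_kwargs) -> float:
    """Largest grid resolution at which every cluster contains >= ``min_cells``
    cells of every treatment; falls back to the smallest grid value with a
    warning when none qualifies."""
    if not grid:
        raise ValueError("resolution grid is empty")
    grid = sorted(grid)
    if isinstance(getattr(treatments, "dtype", None), pd.CategoricalDtype):
        levels = [str(c) for c in treatments.cat.categories]
    else:
        levels = sorted(pd.unique(np.asarray(treatments).astype(str)))
    treatments = pd.Series(np.asarray(treatments).astype(str), index=nm.obs_names)
    counts = treatments.value_counts()
    if (counts.reindex(levels).fillna(0) == 0).any():
        raise ValueError("a treatment level is absent from the dataset")
    for res in reversed(grid):
        labels = cluster_cells(nm, resolution=res, **cluster_kwargs)
        tab = pd.crosstab(labels, treatments)
        if tab.reindex(columns=levels).fillna(0).to_numpy().min() >= min_cells:
            return res
    warnings.warn("no resolution satisfies the treatment-coverage rule; using the smallest")
    return grid[0]


def welch_t_one_vs_rest(nm: AnnData, labels: pd.Series | np.ndarray) -> pd.DataFrame:
    """Welch t-statistics (genes x clusters), each cluster vs all other cells."""
    labels = np.asarray(labels).astype(str)
    X = nm.X
    X = X.toarray() if sp.issparse(X) else np.asarray(X)
    tstats = {}
    for cl in sorted(set(labels)):
        in_g = labels == cl
        n1, n2 = int(in_g.sum()), int((~in_g).sum())
        if n1 < 2 or n2 < 2:
            warnings.warn(f"cluster {cl!r} has fewer than 2 cells on one side; excluded")
            continue
        m1, m2 = X[in_g].mean(axis=0), X[~in_g].mean(axis=0)
        v1, v2 = X[in_g].var(axis=0, ddof=1), X[~in_g].var(axis=0, ddof=1)
        se = np.sqrt(v1 / n1 + v2 / n2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, (m1 - m2) / se, 0.0)
        tstats[cl] = t
    return pd.DataFrame(tstats, index=nm.var_names)


def rank_markers(nm: AnnData, labels, n: int = 1000) -> dict[str, pd.DataFrame]:
    """Top-``n`` genes per cluster by one-vs-rest Welch t, descending.

    Ties are broken lexicographically by gene id.
    """
    T = welch_t_one_vs_rest(nm, labels)
    if T.shape[1] < 2:
        raise ValueError("need at least 2 clusters with >= 2 cells")
    out = {}
    genes = T.index.to_numpy()
    for cl in T.columns:
        t = T[cl].to_numpy()
        order = np.lexsort((genes, -t))[:n]
        out[cl] = pd.DataFrame({
            "gene": genes[order],
            "score": t[order],
            "rank": np.arange(1, len(order) + 1),
        })
    return out


def overlap_matrix(lists: dict[str, pd.DataFrame | list], n: int = 1000) -> pd.DataFrame:
    """Percentage overlap of top-``n`` marker lists across (donor, cluster) pairs.

    Every list must contain exactly ``n`` unique genes; entry(a, b) =
    100 * |top_n(a) & top_n(b)| / n. Symmetric, 100 on the diagonal.
    """
    sets = {}
    for key, lst in lists.items():
        genes = lst["gene"].tolist() if isinstance(lst, pd.DataFrame) else list(lst)
        if len(genes) != n:
            raise ValueError(f"list {key!r} has {len(genes)} genes, expected exactly {n}")
        s = set(genes)
        if len(s) != n:
            raise ValueError(f"list {key!r} contains duplicate genes")
        sets[key] = s
    keys = list(sets)
    om = pd.DataFrame(100.0, index=keys, columns=keys)
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            ov = 100.0 * len(sets[a] & sets[b]) / n
            om.loc[a, b] = om.loc[b, a] = ov
    return om


def _donor_of(key: str) -> str:
    return str(key).split(":", 1)[0]


def match_clusters(om: pd.DataFrame, n_groups: int, linkage: str = "average",
                   unmatched_floor: float = 20.0) -> dict[str, object]:
    """Match (donor, cluster) pairs into shared groups.

    A cluster whose best cross-donor overlap is below ``unmatched_floor``
    percent is flagged ``"unmatched"`` first (donor-specific outliers must
    not consume a shared group); the remaining clusters are matched by
    agglomerative clustering on distance 100 - overlap with the tree cut to
    ``n_groups``. Keys are expected as ``"donor:cluster"`` strings.
    """
    keys = list(om.index)
    if n_groups > len(keys):
        raise ValueError(f"n_groups={n_groups} exceeds the {len(keys)} clusters available")
    donors = np.array([_donor_of(k) for k in keys])
    mapping: dict[str, object] = {}
    kept = []
    for i, key in enumerate(keys):
        cross = [om.iloc[i, j] for j in range(len(keys)) if donors[j] != donors[i]]
        if cross and max(cross) < unmatched_floor:
            mapping[key] = UNMATCHED
        else:
            kept.append(i)
    if n_groups > len(kept):
        raise ValueError(
            f"n_groups={n_groups} exceeds the {len(kept)} matchable clusters")
    D = 100.0 - om.iloc[kept, kept].to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    condensed = sch.distance.squareform(D, checks=False)
    Z = sch.linkage(condensed, method=linkage)
    assign = sch.fcluster(Z, t=n_groups, criterion="maxclust")
    for pos, i in enumerate(kept):
        mapping[keys[i]] = int(assign[pos])
    return mapping


@dataclass
class FractionExpressing:
    """Per-(gene, group) detection percentages with the loss-of-expression score."""

    fractions: pd.DataFrame  # genes x groups, percent of cells with count > 0
    medians: pd.Series  # per-group median across genes
    loss_score: pd.Series  # max(median) / median per group


def fraction_expressing(m: AnnData, labels) -> FractionExpressing:
    """Percentage of cells with count > 0 per gene and group.

    Uses the raw counts (``layers['counts']`` when present, else ``X``). The
    per-group median across genes, and the ratio of the best group's median
    to each group's (the loss-of-expression score), are returned alongside.
    """
    labels = np.asarray(labels).astype(str)
    X = m.layers["counts"] if "counts" in m.layers else m.X
    X = sp.csr_matrix(X)
    cols = {}
    for g in sorted(set(labels)):
        rows = labels == g
        det = (X[rows] > 0).sum(axis=0)
        cols[g] = 100.0 * np.asarray(det).ravel() / max(int(rows.sum()), 1)
    frac = pd.DataFrame(cols, index=m.var_names)
    med = frac.median(axis=0)
    with np.errstate(divide="ignore"):
        loss = med.max() / med
    return FractionExpressing(fractions=frac, medians=med, loss_score=loss)


def annotate_subgroups(nm: AnnData, group_labels, panel: MarkerPanel,
                       loss_cutoff: float = 3.0) -> ClusterMap:
    """Assign subgroup labels I-IV to matched groups.

    Per group, the mean log-normalized expression of each panel set is
    computed and centered across groups (so a set's global baseline cancels);
    the group gets the subgroup of its argmax set. Groups whose
    loss-of-expression score (see :func:`fraction_expressing`) is >=
    ``loss_cutoff`` are labeled IV first, regardless of panel scores. Exact
    ties between sets give ``"unassigned"`` with a warning.
    """
    groups = pd.Series(np.asarray(group_labels).astype(str), index=nm.obs_names)
    resolved = panel.resolve(nm.var_names)
    usable = {name: gs for name, gs in resolved.items() if gs}
    if not usable:
        raise ValueError("no panel set resolves against the matrix")
    X = nm.X
    X = X.toarray() if sp.issparse(X) else np.asarray(X)
    gnames = sorted(groups.unique())
    score = pd.DataFrame(index=gnames, columns=list(usable), dtype=float)
    gi = {g: i for i, g in enumerate(nm.var_names)}
    for name, gs in usable.items():
        idx = [gi[g] for g in gs]
        for grp in gnames:
            score.loc[grp, name] = X[np.ix_((groups == grp).to_numpy(), idx)].mean()
    centered = score - score.mean(axis=0)

    fe = fraction_expressing(nm, groups)
    subgroup_of_group = {}
    for grp in gnames:
        if np.isfinite(fe.loss_score[grp]) and fe.loss_score[grp] >= loss_cutoff:
            subgroup_of_group[grp] = "IV"
            continue
        row = centered.loc[grp]
        best = row.max()
        winners = row.index[row == best]
        if len(winners) != 1:
            warnings.warn(f"group {grp!r}: tied panel scores; left unassigned")
            subgroup_of_group[grp] = UNASSIGNED
        else:
            subgroup_of_group[grp] = panel.subgroup_of_set.get(winners[0], winners[0])

    cells = pd.DataFrame({"cluster": groups})
    cells["subgroup"] = groups.map(subgroup_of_group)
    return ClusterMap(cells=cells)


def discover_subgroups(nm: AnnData, panel: MarkerPanel, donor_col: str = "donor",
                       treatment_col: str = "treatment",
                       resolution_grid: tuple[float, ...] = (0.3, 0.5, 0.8, 1.0),
                       n_groups: int = 4, top_n: int = 1000, n_pcs: int = 50,
                       k_neighbors: int = 15, min_cells: int = 1,
                       loss_cutoff: float = 3.0, seed: int = 0,
                       exclude: tuple[str, ...] = ()) -> ClusterMap:
    """End-to-end subgroup discovery across donors.

    Per donor: resolution selection (treatment-coverage rule), Louvain
    clustering, top-``top_n`` marker ranking. Across donors: overlap matrix,
    hierarchical matching into ``n_groups`` shared groups, marker-panel
    annotation with the loss-of-expression override. Returns per-cell donor
    cluster (``"donor:cluster"``), matched group and subgroup labels; cells of
    unmatched clusters are labeled ``"unassigned"``.
    """
    donors = nm.obs[donor_col].astype(str)
    all_markers: dict[str, pd.DataFrame] = {}
    cluster_of_cell = pd.Series(index=nm.obs_names, dtype=object)
    for di, donor in enumerate(sorted(donors.unique())):
        sub = nm[donors == donor]
        res = select_resolution(sub, sub.obs[treatment_col], list(resolution_grid),
                                min_cells=min_cells, n_pcs=min(n_pcs, min(sub.shape) - 1),
                                k_neighbors=k_neighbors, seed=seed + di)
        labels = cluster_cells(sub, n_pcs=min(n_pcs, min(sub.shape) - 1),
                               k_neighbors=k_neighbors, resolution=res, seed=seed + di)
        if exclude:
            keep = ~labels.isin(exclude)
            sub, labels = sub[keep.to_numpy()], labels[keep]
        marker_n = min(top_n, sub.n_vars)
        for cl, tab in rank_markers(sub, labels, n=marker_n).items():
            all_markers[f"{donor}:{cl}"] = tab
        cluster_of_cell.loc[labels.index] = donor + ":" + labels
    om = overlap_matrix(all_markers, n=min(top_n, nm.n_vars))
    mapping = match_clusters(om, n_groups=n_groups)
    group_of_cell = cluster_of_cell.map(lambda k: mapping.get(k, UNMATCHED))
    matched = group_of_cell != UNMATCHED
    cm = annotate_subgroups(nm[matched.to_numpy()], group_of_cell[matched].astype(str),
                            panel, loss_cutoff=loss_cutoff)
    cells = pd.DataFrame(index=nm.obs_names)
    cells["cluster"] = cluster_of_cell
    cells["group"] = group_of_cell.astype(str)
    cells["subgroup"] = UNASSIGNED
    cells.loc[cm.cells.index, "subgroup"] = cm.cells["subgroup"]
    return ClusterMap(cells=cells, markers=all_markers)
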