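"""Quality control and normalization for hepatocyte count matrices.

The filtering chain is: cell count/gene filters -> gene prevalence filters ->
doublet flagging -> mitochondrial-fraction filter -> size-factor
log-normalization -> post-normalization cell filter. Boundary semantics
follow the stated rules: "at least" thresholds are inclusive, "more than" /
"fewer than" are strict, and a cell is flagged as a doublet when its score
is >= the cutoff (lenient by design, to spare tetraploid hepatocytes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors


class EmptyResultError(ValueError):
    """All cells (or genes) were removed by a filter."""


class AnnotationError(ValueError):
    """Required annotation is missing from the matrix."""


@dataclass
class QCThresholds:
    """Quality-control cutoffs.

    Defaults are the study's: cells need >= 1000 counts and >= 500 detected
    genes; genes must appear in >= 5 cells with < 5 million total reads;
    doublet score cutoff 0.15 (flag at >= cutoff); mitochondrial fraction
    must not exceed 1% (strictly more is removed); cells with more than
    20,000 size-factor-scaled counts are removed after normalization.
    """

    min_counts_per_cell: int = 1000
    min_genes_per_cell: int = 500
    min_cells_per_gene: int = 5
    max_reads_per_gene: float = 5_000_000
    doublet_score_cutoff: float = 0.15
    max_mito_fraction: float = 0.01
    max_normalized_counts: float = 20_000

    def validate(self) -> None:
        for name in ("min_counts_per_cell", "min_genes_per_cell", "min_cells_per_gene",
                     "max_reads_per_gene", "max_normalized_counts"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("doublet_score_cutoff", "max_mito_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def _counts(adata: AnnData) -> sp.csr_matrix:
    X = adata.X
    return X.tocsr() if sp.issparse(X) else sp.csr_matrix(X)


def filter_cells_genes(raw: AnnData, thr: QCThresholds | None = None) -> AnnData:
    """Apply the cell count/gene filters, then the gene prevalence filters.

    Cells are kept with total counts >= ``min_counts_per_cell`` and detected
    genes >= ``min_genes_per_cell``. On the surviving cells, genes are kept
    if detected in >= ``min_cells_per_gene`` cells and carrying fewer than
    ``max_reads_per_gene`` total reads. Order of cells and genes is preserved.
    """
    thr = thr or QCThresholds()
    thr.validate()
    if raw.n_obs == 0:
        raise EmptyResultError("input matrix has no cells")
    X = _counts(raw)
    totals = np.asarray(X.sum(axis=1)).ravel()
    n_genes_det = X.getnnz(axis=1)
    keep_cells = (totals >= thr.min_counts_per_cell) & (n_genes_det >= thr.min_genes_per_cell)
    if not keep_cells.any():
        raise EmptyResultError(
            "no cell passes min_counts_per_cell="
            f"{thr.min_counts_per_cell} and min_genes_per_cell={thr.min_genes_per_cell}"
        )
    sub = X[keep_cells]
    cells_per_gene = sub.getnnz(axis=0)
    reads_per_gene = np.asarray(sub.sum(axis=0)).ravel()
    keep_genes = (cells_per_gene >= thr.min_cells_per_gene) & (
        reads_per_gene < thr.max_reads_per_gene)
    if not keep_genes.any():
        raise EmptyResultError(f"no gene passes min_cells_per_gene={thr.min_cells_per_gene}")
    return raw[keep_cells, keep_genes].copy()


def doublet_scores(raw: AnnData, k: int = 20, n_sim_factor: float = 0.3,
                   seed: int = 0, n_pcs: int = 30) -> np.ndarray:
    """Simulated-doublet k-NN scores in [0, 1].

    Synthetic doublets (``n_sim_factor`` x n_cells of them) are sums of two
    random observed profiles. Observed and synthetic cells are embedded
    together by PCA of log1p counts — deliberately without depth scaling, so
    the doubled library size of a doublet stays visible — and each observed
    cell is scored by the fraction of its ``k`` nearest neighbors (excluding
    itself) that are synthetic. Deterministic given ``seed``.
    """
    n = raw.n_obs
    if n < 2:
        raise ValueError("doublet scoring needs at least 2 cells")
    rng = np.random.default_rng(seed)
    X = _counts(raw).astype(np.float64)
    n_sim = max(int(round(n_sim_factor * n)), 1)
    if k >= n + n_sim:
        raise ValueError(f"k={k} must be smaller than the pooled set size {n + n_sim}")
    pa = rng.integers(0, n, size=n_sim)
    pb = rng.integers(0, n, size=n_sim)
    pb = np.where(pb == pa, (pb + 1) % n, pb)
    sim = X[pa] + X[pb]
    pooled = sp.vstack([X, sim]).tocsr()
    dense = np.log1p(np.asarray(pooled.todense()))
    n_pcs = min(n_pcs, min(dense.shape) - 1)
    emb = PCA(n_components=n_pcs, random_state=int(rng.integers(2**31))).fit_transform(dense)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb[:n])
    neigh = idx[:, 1:]  # drop self
    return (neigh >= n).mean(axis=1)


def apply_doublet_and_mito_filter(m: AnnData, scores: np.ndarray | None,
                                  thr: QCThresholds | None = None) -> AnnData:
    """Remove cells with doublet score >= cutoff or mito fraction > max.

    ``mito_fraction`` is taken from ``.obs`` when present, otherwise computed
    from the genes flagged ``is_mito`` in ``.var``.
    """
    thr = thr or QCThresholds()
    keep = np.ones(m.n_obs, dtype=bool)
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (m.n_obs,):
            raise ValueError("scores are not aligned to cells")
        keep &= scores < thr.doublet_score_cutoff
    mito = mito_fraction(m)
    keep &= mito <= thr.max_mito_fraction
    if keep.all():
        return m
    if not keep.any():
        raise EmptyResultError("doublet/mito filter removed every cell")
    return m[keep].copy()


def mito_fraction(m: AnnData) -> np.ndarray:
    """Per-cell mitochondrial read fraction (stored or computed from is_mito genes)."""
    if "mito_fraction" in m.obs:
        return m.obs["mito_fraction"].to_numpy(dtype=float)
    if "is_mito" not in m.var:
        raise AnnotationError("need obs['mito_fraction'] or var['is_mito'] to apply the mito filter")
    X = _counts(m)
    tot = np.asarray(X.sum(axis=1)).ravel()
    tot[tot == 0] = 1.0
    mito = np.asarray(X[:, m.var["is_mito"].to_numpy(dtype=bool)].sum(axis=1)).ravel()
    return mito / tot


def size_factors(m: AnnData, method: str = "library", min_mean: float = 0.05,
                 n_pools: int = 10) -> np.ndarray:
    """Per-cell size factors rescaled to mean 1.

    ``method="library"`` (default, exact): s_i proportional to the cell's
    total counts. ``method="pooling"``: pooled-ratio deconvolution — cells are
    ordered by depth, overlapping pools of increasing size are summed, each
    pool's ratio to the average pseudo-cell (genes with mean count <
    ``min_mean`` excluded) gives one linear equation, and per-cell factors
    are recovered by least squares.
    """
    X = _counts(m)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals <= 0):
        bad = m.obs_names[np.flatnonzero(totals <= 0)[0]]
        raise ValueError(f"cell {bad!r} has zero total count")
    if method == "library":
        s = totals / totals.mean()
        return s
    if method != "pooling":
        raise ValueError(f"unknown size-factor method {method!r}")
    dense = np.asarray(X.todense(), dtype=float)
    gene_mean = dense.mean(axis=0)
    use = gene_mean >= min_mean
    if not use.any():
        raise ValueError("no gene passes min_mean for pooling deconvolution")
    Y = dense[:, use]
    n = Y.shape[0]
    order = np.argsort(totals, kind="stable")
    ref = Y.mean(axis=0)
    pool_sizes = [ps for ps in (21, 26, 31, 36, 41) if ps <= n] or [max(2, n // 2)]
    rows, cols, vals, b = [], [], [], []
    eq = 0
    for ps in pool_sizes:
        for start in range(n):
            members = order[(start + np.arange(ps)) % n]
            pooled = Y[members].sum(axis=0)
            # ratio of pooled counts to the reference pseudo-cell
            ratio = np.median(pooled / np.where(ref > 0, ref, np.nan))
            rows.extend([eq] * ps)
            cols.extend(members.tolist())
            vals.extend([1.0] * ps)
            b.append(ratio)
            eq += 1
    # anchor: per-cell library ratios stabilize the system
    lib = totals / totals.mean()
    for i in range(n):
        rows.append(eq)
        cols.append(i)
        vals.append(0.1)
        b.append(0.1 * lib[i])
        eq += 1
    A = sp.csr_matrix((vals, (rows, cols)), shape=(eq, n))
    from scipy.sparse.linalg import lsqr
    s = lsqr(A, np.asarray(b))[0]
    s = np.clip(s, 1e-8, None)
    return s / s.mean()


def lognormalize(m: AnnData, s: np.ndarray | None = None, method: str = "library") -> AnnData:
    """Natural-log normalization: value_ij = ln(count_ij / s_i + 1).

    Returns a new AnnData with float ``X``, the size factors in
    ``obs['size_factor']``, and the raw counts kept in ``layers['counts']``.
    """
    if s is None:
        s = size_factors(m, method=method)
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("size factors must be strictly positive")
    X = _counts(m).astype(np.float64)
    scaled = sp.diags(1.0 / s) @ X
    out = AnnData(X=scaled.log1p(), obs=m.obs.copy(), var=m.var.copy())
    out.layers["counts"] = _counts(m).copy()
    out.obs["size_factor"] = s
    return out


def scaled_totals(nm: AnnData) -> np.ndarray:
    """Per-cell sum of size-factor-scaled counts (before log)."""
    if "size_factor" not in nm.obs or "counts" not in nm.layers:
        raise AnnotationError("lognormalize() output required (size_factor + counts layer)")
    s = nm.obs["size_factor"].to_numpy(dtype=float)
    tot = np.asarray(sp.csr_matrix(nm.layers["counts"]).sum(axis=1)).ravel()
    return tot / s


def post_norm_filter(nm: AnnData, thr: QCThresholds | None = None) -> AnnData:
    """Remove cells whose scaled total exceeds ``max_normalized_counts`` (strict)."""
    thr = thr or QCThresholds()
    keep = scaled_totals(nm) <= thr.max_normalized_counts
    if keep.all():
        return nm
    return nm[keep].copy()


def exclude_clusters(m: AnnData, labels: np.ndarray | pd.Series, cluster_ids) -> AnnData:
    """Drop cells in explicitly named clusters (manual exclusion hook,
    e.g. for droplet wetting-failure artifacts)."""
    labels = np.asarray(labels).astype(str)
    drop = np.isin(labels, [str(c) for c in cluster_ids])
    if drop.all():
        raise EmptyResultError("cluster exclusion removed every cell")
    return m[~drop].copy()


def qc_report(raw: AnnData, thr: QCThresholds | None = None,
              scores: np.ndarray | None = None) -> pd.DataFrame:
    """Per-cell pass/fail table with the reason each rule fires."""
    thr = thr or QCThresholds()
    X = _counts(raw)
    totals = np.asarray(X.sum(axis=1)).ravel()
    ngenes = X.getnnz(axis=1)
    rep = pd.DataFrame(index=raw.obs_names)
    rep["total_counts"] = totals
    rep["n_genes"] = ngenes
    rep["fail_min_counts"] = totals < thr.min_counts_per_cell
    rep["fail_min_genes"] = ngenes < thr.min_genes_per_cell
    try:
        mito = mito_fraction(raw)
        rep["mito_fraction"] = mito
        rep["fail_mito"] = mito > thr.max_mito_fraction
    except AnnotationError:
        pass
    if scores is not None:
        rep["doublet_score"] = scores
        rep["fail_doublet"] = np.asarray(scores) >= thr.doublet_score_cutoff
    fail_cols = [c for c in rep.columns if c.startswith("fail_")]
    rep["pass"] = ~rep[fail_cols].any(axis=1)
    return rep
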