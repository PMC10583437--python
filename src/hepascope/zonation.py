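"""Liver zonation scoring and zone assignment.

Zonation marker genes carry an atlas zone index 1..35 along the
pericentral-periportal lobule axis. The 35 zones are binned into three gene
sets (pericentral / mid / periportal), cells are scored for each set with an
expression-bin-matched control signature score, and each cell is assigned a
zone by fixed cutoffs on its central-vein (CV) and periportal (PV) scores:
pericentral if CV > 0.45 and PV < 1; else periportal if PV >= 0.65 and
CV <= 0.45; else mid. The three predicates partition the score plane, so the
assignment is total and deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

N_ZONES = 35
ZONES = ("pericentral", "mid", "periportal")

CV_CUTOFF = 0.45
PV_LOW_CUTOFF = 1.0
PV_CUTOFF = 0.65


def read_zonation_table(path) -> pd.DataFrame:
    """Read a (gene, zone) TSV; zone indices must lie in 1..35, genes unique."""
    zt = pd.read_csv(path, sep="\t")
    zt.columns = [c.lower() for c in zt.columns]
    zt = zt.rename(columns={zt.columns[0]: "gene", zt.columns[1]: "zone"})
    return validate_zonation_table(zt)


def validate_zonation_table(zt: pd.DataFrame) -> pd.DataFrame:
    zones = zt["zone"].to_numpy()
    if np.any((zones < 1) | (zones > N_ZONES)):
        raise ValueError(f"zone indices must lie in [1, {N_ZONES}]")
    if zt["gene"].duplicated().any():
        raise ValueError("a gene appears more than once in the zonation table")
    return zt


def bin_zones(zt: pd.DataFrame, edges: tuple[int, int] = (12, 23)) -> dict[str, list[str]]:
    """Bin the 35 atlas zones into three gene sets.

    pericentral = zones [1, edge1]; mid = (edge1, edge2]; periportal =
    (edge2, 35]. Default edges (12, 23) split the axis into equal thirds.
    """
    e1, e2 = edges
    if not (1 <= e1 < e2 <= N_ZONES):
        raise ValueError(f"edges must satisfy 1 <= edge1 < edge2 <= {N_ZONES}")
    zt = validate_zonation_table(zt)
    z = zt["zone"].to_numpy()
    sets = {
        "pericentral": zt.loc[z <= e1, "gene"].tolist(),
        "mid": zt.loc[(z > e1) & (z <= e2), "gene"].tolist(),
        "periportal": zt.loc[z > e2, "gene"].tolist(),
    }
    for name, genes in sets.items():
        if not genes:
            raise ValueError(f"zone bin {name!r} is empty for edges {edges}")
    return sets


def score_gene_set(nm: AnnData, gene_set, n_bins: int = 25, ctrl_size: int = 50,
                   seed: int = 0) -> np.ndarray:
    """Expression-bin-matched signature score per cell.

    score = mean log-normalized expression of the gene set minus the mean of
    a control set: genes are binned by average expression into ``n_bins``
    bins, and for every bin occupied by the gene set, ``ctrl_size`` control
    genes are sampled (seeded) from that bin. Adding a constant to every
    gene of every cell cancels in the subtraction.
    """
    genes = pd.Index(gene_set)
    present = genes.intersection(nm.var_names)
    if len(present) == 0:
        raise ValueError("gene set does not intersect the matrix genes")
    X = nm.X
    X = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
    var_names = nm.var_names
    gene_mean = X.mean(axis=0)
    n_bins_eff = min(n_bins, nm.n_vars)
    if n_bins_eff < n_bins:
        warnings.warn(f"fewer genes than bins; using {n_bins_eff} bins")
    # equal-count bins on average expression (rank-based, scanpy-style)
    order = pd.Series(gene_mean, index=var_names).rank(method="first")
    bin_of = np.ceil(order / (nm.n_vars / n_bins_eff)).astype(int)
    bin_of = pd.Series(bin_of.to_numpy(), index=var_names)

    rng = np.random.default_rng(seed)
    set_idx = var_names.get_indexer(present)
    ctrl: set[str] = set()
    for b in sorted(bin_of.loc[present].unique()):
        pool = bin_of.index[bin_of == b]
        take = min(ctrl_size, len(pool))
        ctrl.update(rng.choice(pool, size=take, replace=False))
    ctrl_idx = var_names.get_indexer(pd.Index(sorted(ctrl)))
    return X[:, set_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)


def assign_zone(cv_score: float, pv_score: float) -> str:
    """Zone label from the CV/PV score cutoffs (total function)."""
    if cv_score > CV_CUTOFF and pv_score < PV_LOW_CUTOFF:
        return "pericentral"
    if pv_score >= PV_CUTOFF and cv_score <= CV_CUTOFF:
        return "periportal"
    return "mid"


def assign_zones(cv_scores: np.ndarray, pv_scores: np.ndarray) -> np.ndarray:
    """Vectorized :func:`assign_zone`."""
    cv = np.asarray(cv_scores, dtype=float)
    pv = np.asarray(pv_scores, dtype=float)
    out = np.full(cv.shape, "mid", dtype=object)
    out[(pv >= PV_CUTOFF) & (cv <= CV_CUTOFF)] = "periportal"
    out[(cv > CV_CUTOFF) & (pv < PV_LOW_CUTOFF)] = "pericentral"
    return out.astype(str)


@dataclass
class ZoneResult:
    """Per-cell zone scores and labels."""

    scores: pd.DataFrame  # columns: cv_score, mid_score, pv_score, zone


def score_zones(nm: AnnData, zt: pd.DataFrame, edges: tuple[int, int] = (12, 23),
                n_bins: int = 25, ctrl_size: int = 50, seed: int = 0) -> ZoneResult:
    """Score all three zone gene sets and assign a zone per cell."""
    sets = bin_zones(zt, edges)
    cv = score_gene_set(nm, sets["pericentral"], n_bins, ctrl_size, seed)
    mid = score_gene_set(nm, sets["mid"], n_bins, ctrl_size, seed + 1)
    pv = score_gene_set(nm, sets["periportal"], n_bins, ctrl_size, seed + 2)
    df = pd.DataFrame(
        {"cv_score": cv, "mid_score": mid, "pv_score": pv,
         "zone": assign_zones(cv, pv)},
        index=nm.obs_names,
    )
    return ZoneResult(scores=df)


def zone_composition(zr: ZoneResult, subgroups) -> pd.DataFrame:
    """Per-subgroup percentage of cells in each zone (rows sum to 100)."""
    sg = pd.Series(np.asarray(subgroups).astype(str), index=zr.scores.index)
    rows = {}
    for g in sorted(sg.unique()):
        zones = zr.scores.loc[(sg == g).to_numpy(), "zone"]
        if len(zones) == 0:
            warnings.warn(f"subgroup {g!r} is empty; composition row is NaN")
            rows[g] = {z: np.nan for z in ZONES}
            continue
        vc = zones.value_counts()
        rows[g] = {z: 100.0 * vc.get(z, 0) / len(zones) for z in ZONES}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(ZONES))
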