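"""Treatment-contrast differential expression within hepatocyte subgroups.

Per gene, a Welch t-test on log-normalized expression between two cell
groups, Bonferroni correction over the genes tested, and a dual-threshold
significance class: a gene is called up-regulated when its adjusted p-value
is below alpha AND |log2FC| exceeds the contrast's fold-change threshold
(1.0 for Cocktail contrasts, 0.75 for the subtler FFA contrasts). The fold
change is computed on the de-logged means, log2((e^mean_A - 1 + eps) /
(e^mean_B - 1 + eps)), matching the convention of standard scRNA-seq
rank-genes machinery. Pseudobulk contrasts run the same machinery with
subgroup labels ignored. A generic hypergeometric test over user-supplied
gene sets stands in for external enrichment services.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st
from anndata import AnnData
from statsmodels.stats.multitest import multipletests

EPS = 1e-9

LFC_THRESHOLD_COCKTAIL = 1.0
LFC_THRESHOLD_FFA = 0.75


@dataclass
class ContrastSpec:
    """A two-group contrast (A vs B) with its significance thresholds."""

    mask_a: np.ndarray
    mask_b: np.ndarray
    name_a: str = "A"
    name_b: str = "B"
    subgroup: str | None = None
    lfc_threshold: float = LFC_THRESHOLD_COCKTAIL
    alpha: float = 0.05
    min_cells: int = 3

    def validate(self) -> None:
        a = np.asarray(self.mask_a, dtype=bool)
        b = np.asarray(self.mask_b, dtype=bool)
        if a.shape != b.shape:
            raise ValueError("group masks differ in length")
        if np.any(a & b):
            raise ValueError("groups A and B overlap")
        if self.lfc_threshold <= 0 or not (0 < self.alpha < 1):
            raise ValueError("thresholds must be positive (alpha in (0, 1))")
        if a.sum() < self.min_cells or b.sum() < self.min_cells:
            raise ValueError(
                f"both groups need >= {self.min_cells} cells "
                f"(got {int(a.sum())} and {int(b.sum())})")


def contrast_by_treatment(nm: AnnData, treat_a: str, treat_b: str,
                          subgroup: str | None = None,
                          subgroup_labels=None, **kw) -> ContrastSpec:
    """Build a ContrastSpec for treatment A vs B, optionally within a subgroup."""
    tr = nm.obs["treatment"].astype(str).to_numpy()
    a, b = tr == treat_a, tr == treat_b
    if subgroup is not None:
        sg = np.asarray(subgroup_labels if subgroup_labels is not None
                        else nm.obs["subgroup"]).astype(str)
        a, b = a & (sg == subgroup), b & (sg == subgroup)
    return ContrastSpec(mask_a=a, mask_b=b, name_a=treat_a, name_b=treat_b,
                        subgroup=subgroup, **kw)


def _dense(nm: AnnData) -> np.ndarray:
    X = nm.X
    return X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)


def classify(padj: np.ndarray, log2fc: np.ndarray, alpha: float,
             lfc_threshold: float) -> np.ndarray:
    """Significance class from adjusted p and log2FC (pure function)."""
    out = np.full(padj.shape, "ns", dtype=object)
    sig = padj < alpha
    out[sig & (log2fc > lfc_threshold)] = "up_in_A"
    out[sig & (log2fc < -lfc_threshold)] = "up_in_B"
    return out.astype(str)


def de_test(nm: AnnData, spec: ContrastSpec) -> pd.DataFrame:
    """Welch t-test per gene between the contrast's two groups.

    Returns a DETable: per gene the group means (log scale), log2FC (A vs
    B), t statistic, raw and Bonferroni-adjusted p, and the significance
    class. Genes with zero variance in both groups get p = 1 and a fold
    change from the means alone.
    """
    spec.validate()
    X = _dense(nm)
    A = X[np.asarray(spec.mask_a, dtype=bool)]
    B = X[np.asarray(spec.mask_b, dtype=bool)]
    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = st.ttest_ind(A, B, equal_var=False)
    zero_var = (A.var(axis=0) == 0) & (B.var(axis=0) == 0)
    t = np.where(np.isfinite(t) & ~zero_var, t, 0.0)
    p = np.where(zero_var | ~np.isfinite(p), 1.0, p)
    m = X.shape[1]
    padj = np.minimum(p * m, 1.0)
    log2fc = np.log2((np.expm1(mean_a) + EPS) / (np.expm1(mean_b) + EPS))
    tab = pd.DataFrame({
        "mean_A": mean_a, "mean_B": mean_b, "log2fc": log2fc,
        "t": t, "pval": p, "padj": padj,
        "class": classify(padj, log2fc, spec.alpha, spec.lfc_threshold),
    }, index=nm.var_names)
    tab.attrs["contrast"] = {
        "A": spec.name_a, "B": spec.name_b, "subgroup": spec.subgroup,
        "lfc_threshold": spec.lfc_threshold, "alpha": spec.alpha,
        "n_A": int(np.sum(spec.mask_a)), "n_B": int(np.sum(spec.mask_b)),
        "n_genes_tested": m,
    }
    return tab


def pseudobulk_de(nm: AnnData, spec: ContrastSpec) -> pd.DataFrame:
    """The same contrast with all cells of each treatment pooled (subgroup
    structure ignored); cells are treated as replicates."""
    pooled = ContrastSpec(mask_a=spec.mask_a, mask_b=spec.mask_b,
                          name_a=spec.name_a, name_b=spec.name_b, subgroup=None,
                          lfc_threshold=spec.lfc_threshold, alpha=spec.alpha,
                          min_cells=spec.min_cells)
    return de_test(nm, pooled)


def up_set(table: pd.DataFrame, direction: str = "up_in_A") -> set[str]:
    return set(table.index[table["class"] == direction])


@dataclass
class DEIntersection:
    """Shared and subgroup-specific up-regulated gene sets."""

    shared: set[str]
    specific: dict[str, set[str]]
    counts: dict[str, int] = field(default_factory=dict)


def intersect_de(tables: dict[str, pd.DataFrame], direction: str = "up_in_A") -> DEIntersection:
    """Venn-style decomposition of up-regulated sets across subgroup tables.

    ``shared`` is the intersection over all tables; ``specific[s]`` contains
    genes up in ``s`` and in no other table. All tables must share one gene
    universe.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 tables to intersect")
    universes = [tuple(t.index) for t in tables.values()]
    if len(set(universes)) != 1:
        raise ValueError("tables have mismatched gene universes")
    ups = {name: up_set(t, direction) for name, t in tables.items()}
    shared = set.intersection(*ups.values())
    specific = {}
    for name, s in ups.items():
        others = set.union(*(o for n, o in ups.items() if n != name)) if len(ups) > 1 else set()
        specific[name] = s - others
    counts = {f"up_{n}": len(s) for n, s in ups.items()}
    counts["shared"] = len(shared)
    counts.update({f"specific_{n}": len(s) for n, s in specific.items()})
    return DEIntersection(shared=shared, specific=specific, counts=counts)


def cyp_induction_summary(nm: AnnData, subgroup_labels, cyp_genes=None,
                          contrasts=(("Cocktail", "DMSO"), ("FFA+Cocktail", "DMSO")),
                          lfc_threshold: float = LFC_THRESHOLD_COCKTAIL,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Long-format induction table for the designated CYP genes.

    One row per (subgroup, contrast, gene): log2FC, adjusted p, significance
    class, and the fraction of expressing cells in each group. Genes missing
    from the matrix yield NA rows with a warning.
    """
    from .simulate import CYP_GENES

    cyp_genes = list(cyp_genes) if cyp_genes is not None else list(CYP_GENES)
    sg = pd.Series(np.asarray(subgroup_labels).astype(str), index=nm.obs_names)
    counts = nm.layers["counts"] if "counts" in nm.layers else nm.X
    counts = sp.csr_matrix(counts)
    rows = []
    for subgroup in sorted(sg.unique()):
        for treat_a, treat_b in contrasts:
            try:
                spec = contrast_by_treatment(nm, treat_a, treat_b, subgroup=subgroup,
                                             subgroup_labels=sg.to_numpy(),
                                             lfc_threshold=lfc_threshold, alpha=alpha)
                tab = de_test(nm, spec)
            except ValueError as err:
                warnings.warn(f"subgroup {subgroup!r} contrast {treat_a} vs {treat_b}: {err}")
                tab = None
            for gene in cyp_genes:
                row = {"subgroup": subgroup, "contrast": f"{treat_a}_vs_{treat_b}", "gene": gene}
                if tab is None or gene not in (tab.index if tab is not None else []):
                    if tab is not None:
                        warnings.warn(f"gene {gene!r} absent from the matrix; NA row emitted")
                    row.update({"log2fc": np.nan, "padj": np.nan, "class": "NA",
                                "frac_expressing_A": np.nan, "frac_expressing_B": np.nan})
                else:
                    gi = nm.var_names.get_loc(gene)
                    col = np.asarray(counts[:, gi].todense()).ravel()
                    ma = np.asarray(spec.mask_a, bool)
                    mb = np.asarray(spec.mask_b, bool)
                    row.update({
                        "log2fc": tab.loc[gene, "log2fc"],
                        "padj": tab.loc[gene, "padj"],
                        "class": tab.loc[gene, "class"],
                        "frac_expressing_A": float((col[ma] > 0).mean()),
                        "frac_expressing_B": float((col[mb] > 0).mean()),
                    })
                rows.append(row)
    return pd.DataFrame(rows)


def enrich_hypergeometric(query: set[str], pathways: dict[str, set[str]],
                          universe: set[str]) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a gene set against pathways.

    p = P(overlap >= observed) from the hypergeometric tail, with
    Benjamini-Hochberg correction across pathways. The query must be a
    subset of the universe; pathways are intersected with it.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for name, genes in pathways.items():
        pw = set(genes) & universe
        k = len(query & pw)
        K = len(pw)
        # P(X >= k), X ~ Hypergeom(N, K, n)
        p = 1.0 if k == 0 else float(st.hypergeom.sf(k - 1, N, K, n))
        rows.append({"pathway": name, "overlap": k, "pathway_size": K,
                     "query_size": n, "universe_size": N, "pval": p,
                     "overlap_genes": ",".join(sorted(query & pw))})
    df = pd.DataFrame(rows).set_index("pathway")
    if len(df):
        df["padj"] = multipletests(df["pval"].to_numpy(), method="fdr_bh")[1]
    return df


def read_gmt(path) -> dict[str, set[str]]:
    """Read pathways in GMT format (name, description, genes...)."""
    pathways = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                pathways[parts[0]] = set(g for g in parts[2:] if g)
    return pathways
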