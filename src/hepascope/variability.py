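"""Transcriptional variability via the coefficient of variation on
log-normalized expression.

For log-normally distributed expression, the coefficient of variation on the
original scale is a closed function of the variance sigma^2 of the log
values: CV = sqrt(exp(sigma^2) - 1) (Canchola's log-normal form, the
default). An alternative reading, CV = sqrt(exp(sigma^2)) - 1, is available
behind ``form="sqrt_first"``; the two differ for sigma^2 > 0 and only the
default admits the empirical sd/mean oracle on de-logged data.

Lowly expressed genes have inflated CV, so genes with mean log-normalized
expression below ``min_mean`` (default 0.25) are removed before computing
CV; the filter is applied jointly on the union of the two compared groups so
both treatments score the same gene set. Treatment shifts in the per-gene CV
distribution are tested per subgroup with a two-sided Mann-Whitney U.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st
from anndata import AnnData

MIN_MEAN_DEFAULT = 0.25


def cv_from_sigma2(sigma2: np.ndarray | float, form: str = "canchola") -> np.ndarray | float:
    """CV from the variance of log values.

    ``form="canchola"``: sqrt(exp(sigma2) - 1); ``form="sqrt_first"``:
    sqrt(exp(sigma2)) - 1.
    """
    s2 = np.asarray(sigma2, dtype=float)
    if form == "canchola":
        out = np.sqrt(np.expm1(s2))
    elif form == "sqrt_first":
        out = np.sqrt(np.exp(s2)) - 1.0
    else:
        raise ValueError(f"unknown CV form {form!r}")
    return out if out.ndim else float(out)


def cv_log(nm: AnnData, cells: np.ndarray | None = None,
           min_mean: float = MIN_MEAN_DEFAULT, form: str = "canchola",
           gene_subset: pd.Index | None = None) -> pd.DataFrame:
    """Per-gene sigma^2 and CV within a cell group.

    Genes with group mean log-expression < ``min_mean`` are removed (pass
    ``gene_subset`` to impose a pre-computed joint filter instead).
    sigma^2 is the unbiased (n-1) variance of the log-normalized values.
    """
    mask = np.ones(nm.n_obs, dtype=bool) if cells is None else np.asarray(cells, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("CV needs at least 2 cells in the group")
    X = nm.X
    X = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
    G = X[mask]
    mean = G.mean(axis=0)
    if gene_subset is not None:
        keep = nm.var_names.isin(gene_subset)
    else:
        keep = mean >= min_mean
    if not keep.any():
        warnings.warn("no gene passes the mean filter; empty CV result")
        return pd.DataFrame(columns=["mean", "sigma2", "cv"])
    sigma2 = G[:, keep].var(axis=0, ddof=1)
    return pd.DataFrame(
        {"mean": mean[keep], "sigma2": sigma2, "cv": cv_from_sigma2(sigma2, form)},
        index=nm.var_names[keep],
    )


def joint_mean_filter(nm: AnnData, mask_a: np.ndarray, mask_b: np.ndarray,
                      min_mean: float = MIN_MEAN_DEFAULT) -> pd.Index:
    """Genes whose mean log-expression over the union of both groups is >= min_mean."""
    X = nm.X
    X = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
    union = np.asarray(mask_a, bool) | np.asarray(mask_b, bool)
    mean = X[union].mean(axis=0)
    return nm.var_names[mean >= min_mean]


def compare_cv(cv_a, cv_b) -> tuple[float, float, int]:
    """Two-sided Mann-Whitney U between two CV samples.

    Exact enumeration when both samples have n <= 8 and carry no ties;
    otherwise the tie-corrected normal approximation. Returns (U, p,
    direction) with direction the sign of median(A) - median(B). All values
    tied across both samples give p = 1.
    """
    a = np.asarray(cv_a, dtype=float)
    b = np.asarray(cv_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(a.size * b.size / 2.0), 1.0, 0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    res = st.mannwhitneyu(a, b, alternative="two-sided", method=method)
    direction = int(np.sign(np.median(a) - np.median(b)))
    return float(res.statistic), float(res.pvalue), direction


def variability_report(nm: AnnData, subgroups, treatments,
                       treat_a: str = "FFA", treat_b: str = "DMSO",
                       min_mean: float = MIN_MEAN_DEFAULT,
                       form: str = "canchola") -> pd.DataFrame:
    """Per-subgroup CV comparison between two treatments.

    For each subgroup, the gene filter is applied jointly over the two
    treatment groups, CV is computed per treatment on that shared gene set,
    and the two CV distributions are compared by Mann-Whitney U. Returns one
    row per subgroup: U, p, direction (sign of median CV_A - CV_B), n_genes,
    and the median CVs. Subgroups missing a treatment are skipped with a
    warning.
    """
    sg = pd.Series(np.asarray(subgroups).astype(str), index=nm.obs_names)
    tr = pd.Series(np.asarray(treatments).astype(str), index=nm.obs_names)
    rows = []
    for g in sorted(sg.unique()):
        in_g = (sg == g).to_numpy()
        ma = in_g & (tr == treat_a).to_numpy()
        mb = in_g & (tr == treat_b).to_numpy()
        if ma.sum() < 2 or mb.sum() < 2:
            warnings.warn(f"subgroup {g!r} lacks cells in one treatment; skipped")
            continue
        genes = joint_mean_filter(nm, ma, mb, min_mean=min_mean)
        if len(genes) == 0:
            warnings.warn(f"subgroup {g!r}: no gene passes the mean filter; skipped")
            continue
        cva = cv_log(nm, ma, form=form, gene_subset=genes)["cv"]
        cvb = cv_log(nm, mb, form=form, gene_subset=genes)["cv"]
        U, p, direction = compare_cv(cva.to_numpy(), cvb.to_numpy())
        rows.append({
            "subgroup": g, "treatment_A": treat_a, "treatment_B": treat_b,
            "U": U, "pval": p, "direction": direction, "n_genes": len(genes),
            "median_cv_A": float(cva.median()), "median_cv_B": float(cvb.median()),
        })
    return pd.DataFrame(rows)
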