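"""Synthetic single-cell count data with the structure of a multi-donor
primary-hepatocyte drug/fat-challenge experiment.

The generator emulates a design of four donors crossed with four treatment
conditions (DMSO vehicle, a five-drug phenotyping Cocktail, free-fatty-acid
loading, and FFA + Cocktail), with four planted hepatocyte subgroups:

* subgroups I-III carry distinct marker-gene modules (sterol/bile-acid,
  carbohydrate/phase-II, lipid/phase-III metabolism),
* subgroup IV loses expression: each of its cells silences a random
  Bernoulli fraction of genes,
* Cocktail induces a designated set of CYP genes; under FFA + Cocktail the
  induction is attenuated,
* FFA multiplies the negative-binomial dispersion per subgroup (inflation
  in I-II, deflation in III by default),
* a fixed set of "MT-" genes carries the mitochondrial read fraction,
* a configurable fraction of barcodes are doublets (sums of two profiles).

Counts are gene-wise negative binomial with a log-normal donor batch factor
and log-normal per-cell depth. In-vivo mode adds a latent lobule position in
[0, 1] with monotone pericentral/periportal marker gradients and a 35-zone
truth annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

TREATMENTS = ("DMSO", "Cocktail", "FFA", "FFA+Cocktail")
SUBGROUPS = ("I", "II", "III", "IV")
CYP_GENES = ("CYP1A2", "CYP2C9", "CYP2C19", "CYP2D6", "CYP3A4")
#: field-standard names for the marker modules of the metabolically active subgroups
MARKER_SET_NAMES = {
    "I": "sterol_bile_acid",
    "II": "carbohydrate_phase2",
    "III": "lipid_phase3",
}
N_ZONES_ATLAS = 35


class SimConfigError(ValueError):
    """Raised for an inconsistent simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Effect sizes are log2-scale; fractions are in [0, 1]. The defaults mirror
    the study design: 4 donors x 4 conditions x 500 cells, subgroup
    proportions 38.2/38.7/5.4/17.7 %, and FFA dispersion inflation in
    subgroups I-II with deflation in III.
    """

    n_donors: int = 4
    n_cells_per_donor_condition: int = 500
    n_genes: int = 1500
    subgroup_proportions: tuple[float, float, float, float] = (0.382, 0.387, 0.054, 0.177)
    marker_module_size: int = 40
    marker_lfc: float = 1.5
    cyp_induction_lfc: float = 2.0
    #: fraction of the Cocktail CYP induction retained under FFA + Cocktail
    cyp_ffa_retention: float = 0.3
    ffa_dispersion_factor_per_subgroup: tuple[float, float, float, float] = (1.5, 1.5, 0.7, 1.0)
    loss_fraction: float = 0.9
    mito_mean: float = 0.005
    mito_sd_log: float = 0.5
    n_mito_genes: int = 10
    doublet_rate: float = 0.05
    donor_batch_sd: float = 0.15
    mean_counts_per_cell: float = 3000.0
    lib_size_sd: float = 0.3
    base_dispersion: float = 0.3
    gene_mean_sd_log: float = 1.2
    #: in-vivo mode: log2 amplitude of the pericentral-periportal gradient
    zonation_amplitude: float = 7.0
    #: in-vivo mode: zonation marker genes per atlas zone (zones 1..35)
    zonation_genes_per_zone: int = 3
    #: in-vivo mode: abundance multiplier for zonation marker genes
    zonation_gene_mean_boost: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        props = np.asarray(self.subgroup_proportions, dtype=float)
        if props.shape != (4,) or np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
            raise SimConfigError("subgroup_proportions must be 4 nonnegative fractions summing to 1")
        if self.marker_module_size * 4 > self.n_genes:
            raise SimConfigError(
                f"4 marker modules of {self.marker_module_size} genes exceed n_genes={self.n_genes}"
            )
        for name in ("n_donors", "n_cells_per_donor_condition", "n_genes", "n_mito_genes"):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be positive")
        for name in ("doublet_rate", "loss_fraction", "mito_mean", "cyp_ffa_retention"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be a fraction in [0, 1]")
        if np.any(np.asarray(self.ffa_dispersion_factor_per_subgroup) <= 0):
            raise SimConfigError("dispersion factors must be positive")


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset.

    ``cells`` has one row per barcode (subgroup, donor, treatment, doublet
    flag, and in-vivo position/zone); ``genes`` has one row per gene with
    marker membership and planted log2 effects. ``marker_modules`` maps the
    field-standard set names to the planted marker genes of subgroups I-III,
    plus the subgroup-IV module under ``"subgroup_IV_module"``.
    """

    cells: pd.DataFrame
    genes: pd.DataFrame
    marker_modules: dict[str, list[str]] = field(default_factory=dict)
    cyp_genes: list[str] = field(default_factory=list)
    zonation_table: pd.DataFrame | None = None


def _gene_names(cfg: SimConfig) -> list[str]:
    n_regular = cfg.n_genes - cfg.n_mito_genes - len(CYP_GENES)
    if n_regular <= 4 * cfg.marker_module_size:
        raise SimConfigError("n_genes too small for mito + CYP + marker genes")
    names = [f"G{i + 1:04d}" for i in range(n_regular)]
    names += list(CYP_GENES)
    names += [f"MT-{i + 1}" for i in range(cfg.n_mito_genes)]
    return names


def _base_means(cfg: SimConfig, rng: np.random.Generator, boost_idx: np.ndarray) -> np.ndarray:
    """Log-normal gene abundances; genes in ``boost_idx`` are redrawn near the
    upper quartile so planted effects act on well-detected genes."""
    mu = rng.lognormal(mean=0.0, sigma=cfg.gene_mean_sd_log, size=cfg.n_genes)
    if boost_idx.size:
        hi = np.quantile(mu, 0.70)
        mu[boost_idx] = hi * rng.lognormal(mean=0.0, sigma=0.4, size=boost_idx.size)
    return mu


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Negative binomial via gamma-Poisson; var = mean + disp * mean^2."""
    shape = 1.0 / disp
    lam = rng.gamma(shape, mean * disp)
    return rng.poisson(lam)


def _assemble(cfg: SimConfig, rng_seq: np.random.SeedSequence, invivo: bool,
              n_zones_truth: int = 3) -> tuple[AnnData, SimTruth]:
    cfg.validate()
    rng_layout, rng_means, rng_cells, rng_counts, rng_doublet, rng_mito = (
        np.random.default_rng(s) for s in rng_seq.spawn(6)
    )

    genes = _gene_names(cfg)
    n_genes = cfg.n_genes
    is_mito = np.array([g.startswith("MT-") for g in genes])
    cyp_idx = np.array([genes.index(g) for g in CYP_GENES])

    # marker modules: disjoint blocks of regular genes, one per subgroup
    regular_idx = np.flatnonzero(~is_mito & ~np.isin(np.arange(n_genes), cyp_idx))
    chosen = rng_layout.choice(regular_idx, size=4 * cfg.marker_module_size, replace=False)
    module_idx = {sg: np.sort(chosen[i * cfg.marker_module_size:(i + 1) * cfg.marker_module_size])
                  for i, sg in enumerate(SUBGROUPS)}

    # in-vivo zonation marker genes: zonation_genes_per_zone per atlas zone,
    # drawn from regular genes outside the marker modules
    zon_table = None
    zon_idx = np.empty(0, dtype=int)
    zone_of_gene = None
    if invivo:
        free = np.setdiff1d(regular_idx, chosen)
        need = N_ZONES_ATLAS * cfg.zonation_genes_per_zone
        if free.size < need:
            raise SimConfigError("not enough genes for the zonation marker table")
        zon_idx = np.sort(rng_layout.choice(free, size=need, replace=False))
        zone_of_gene = np.repeat(np.arange(1, N_ZONES_ATLAS + 1), cfg.zonation_genes_per_zone)
        zon_table = pd.DataFrame({"gene": [genes[i] for i in zon_idx], "zone": zone_of_gene})

    boost = np.concatenate([chosen, cyp_idx, zon_idx]).astype(int)
    base_mu = _base_means(cfg, rng_means, boost)
    if invivo and zon_idx.size:
        base_mu[zon_idx] *= cfg.zonation_gene_mean_boost

    treatments = ("invivo",) if invivo else TREATMENTS
    n_cells = cfg.n_donors * len(treatments) * cfg.n_cells_per_donor_condition
    donors = np.repeat([f"D{d + 1}" for d in range(cfg.n_donors)],
                       len(treatments) * cfg.n_cells_per_donor_condition)
    treatment = np.tile(np.repeat(treatments, cfg.n_cells_per_donor_condition), cfg.n_donors)
    subgroup = rng_cells.choice(SUBGROUPS, size=n_cells, p=np.asarray(cfg.subgroup_proportions))
    position = rng_cells.uniform(0.0, 1.0, size=n_cells) if invivo else None

    # donor batch factor: log-normal per (donor, gene)
    donor_fac = np.exp(rng_cells.normal(0.0, cfg.donor_batch_sd, size=(cfg.n_donors, n_genes)))
    donor_ix = np.repeat(np.arange(cfg.n_donors), len(treatments) * cfg.n_cells_per_donor_condition)

    # expected profile per cell (non-mito part), then renormalized to depth
    M = base_mu[None, :] * donor_fac[donor_ix]
    for i, sg in enumerate(SUBGROUPS):
        rows = subgroup == sg
        if not rows.any():
            continue
        M[np.ix_(rows, module_idx[sg])] *= 2.0 ** cfg.marker_lfc
    if not invivo:
        M[np.ix_(treatment == "Cocktail", cyp_idx)] *= 2.0 ** cfg.cyp_induction_lfc
        M[np.ix_(treatment == "FFA+Cocktail", cyp_idx)] *= (
            2.0 ** (cfg.cyp_induction_lfc * cfg.cyp_ffa_retention))
    else:
        # monotone gradients: pericentral-type genes (atlas zones <= 12) fall
        # with position, periportal-type (zones > 23) rise; mid genes peak centrally
        amp = cfg.zonation_amplitude
        pc = zon_idx[zone_of_gene <= 12]
        mid = zon_idx[(zone_of_gene > 12) & (zone_of_gene <= 23)]
        pp = zon_idx[zone_of_gene > 23]
        M[:, pc] *= 2.0 ** (amp * (0.5 - position))[:, None]
        M[:, pp] *= 2.0 ** (amp * (position - 0.5))[:, None]
        M[:, mid] *= 2.0 ** (0.5 * amp * (0.5 - np.abs(position - 0.5)) - 0.125 * amp)[:, None]

    # subgroup IV: Bernoulli silencing of non-mito genes per cell
    iv_rows = np.flatnonzero(subgroup == "IV")
    if iv_rows.size and cfg.loss_fraction > 0:
        keep = rng_cells.random((iv_rows.size, n_genes)) >= cfg.loss_fraction
        keep[:, is_mito] = True
        M[iv_rows] *= keep

    # renormalize each cell to its depth (reads concentrate in expressed genes)
    depth = cfg.mean_counts_per_cell * rng_cells.lognormal(
        -0.5 * cfg.lib_size_sd ** 2, cfg.lib_size_sd, size=n_cells)
    mito_frac_target = cfg.mito_mean * rng_mito.lognormal(
        -0.5 * cfg.mito_sd_log ** 2, cfg.mito_sd_log, size=n_cells)
    mito_frac_target = np.clip(mito_frac_target, 0.0, 0.5)
    row_tot = M[:, ~is_mito].sum(axis=1)
    row_tot[row_tot == 0] = 1.0
    M[:, ~is_mito] *= ((1.0 - mito_frac_target) * depth / row_tot)[:, None]
    mito_w = base_mu[is_mito] / base_mu[is_mito].sum()
    M[:, is_mito] = (mito_frac_target * depth)[:, None] * mito_w[None, :]

    # per-gene dispersion, FFA multiplier per subgroup
    phi_g = cfg.base_dispersion * rng_means.lognormal(0.0, 0.3, size=n_genes)
    disp_mult = np.ones(n_cells)
    if not invivo:
        ffa = np.isin(treatment, ("FFA", "FFA+Cocktail"))
        for i, sg in enumerate(SUBGROUPS):
            rows = ffa & (subgroup == sg)
            disp_mult[rows] = cfg.ffa_dispersion_factor_per_subgroup[i]
    counts = _nb_draw(rng_counts, M, phi_g[None, :] * disp_mult[:, None])

    # doublets: replace a random fraction of barcodes with the sum of the host
    # profile and a fresh draw from another cell's expected profile
    is_doublet = np.zeros(n_cells, dtype=bool)
    n_doub = int(round(cfg.doublet_rate * n_cells))
    if n_doub > 0:
        hosts = rng_doublet.choice(n_cells, size=n_doub, replace=False)
        partners = rng_doublet.integers(0, n_cells, size=n_doub)
        partners = np.where(partners == hosts, (partners + 1) % n_cells, partners)
        extra = _nb_draw(rng_doublet, M[partners], phi_g[None, :] * disp_mult[partners][:, None])
        counts[hosts] += extra
        is_doublet[hosts] = True

    barcodes = [f"CELL-{i + 1:06d}" for i in range(n_cells)]
    totals = counts.sum(axis=1)
    totals_safe = np.where(totals > 0, totals, 1)
    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    obs["donor"] = pd.Categorical(donors)
    obs["treatment"] = pd.Categorical(treatment, categories=list(treatments))
    obs["mito_fraction"] = counts[:, is_mito].sum(axis=1) / totals_safe
    obs["true_subgroup"] = pd.Categorical(subgroup, categories=list(SUBGROUPS))
    obs["is_doublet"] = is_doublet
    if invivo:
        obs["position"] = position
        zone35 = np.minimum((position * N_ZONES_ATLAS).astype(int) + 1, N_ZONES_ATLAS)
        obs["true_zone35"] = zone35
        edges = np.linspace(0, N_ZONES_ATLAS, n_zones_truth + 1)
        zone_bin = np.searchsorted(edges[1:-1], zone35 - 0.5, side="left")
        labels3 = np.array(["pericentral", "mid", "periportal"])
        obs["true_zone"] = labels3[zone_bin] if n_zones_truth == 3 else zone_bin

    var = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    var["is_mito"] = is_mito
    marker_of = np.array([""] * n_genes, dtype=object)
    planted_lfc = np.zeros(n_genes)
    for sg in SUBGROUPS:
        marker_of[module_idx[sg]] = sg
        planted_lfc[module_idx[sg]] = cfg.marker_lfc
    planted_lfc[cyp_idx] = cfg.cyp_induction_lfc if not invivo else 0.0
    var["marker_of_subgroup"] = marker_of
    var["planted_lfc"] = planted_lfc
    var["is_cyp"] = np.isin(np.arange(n_genes), cyp_idx)

    adata = AnnData(X=sp.csr_matrix(counts.astype(np.int64)), obs=obs, var=var)

    modules = {MARKER_SET_NAMES[sg]: [genes[i] for i in module_idx[sg]] for sg in ("I", "II", "III")}
    modules["subgroup_IV_module"] = [genes[i] for i in module_idx["IV"]]
    truth = SimTruth(
        cells=obs.copy(),
        genes=var.copy(),
        marker_modules=modules,
        cyp_genes=list(CYP_GENES),
        zonation_table=zon_table,
    )
    return adata, truth


def simulate_invitro(config: SimConfig | None = None, **overrides) -> tuple[AnnData, SimTruth]:
    """Simulate the in-vitro experiment (donors x DMSO/Cocktail/FFA/FFA+Cocktail).

    Returns the raw count matrix as :class:`anndata.AnnData` (sparse integer
    ``X``; per-cell annotation in ``.obs``, per-gene in ``.var``) together with
    a :class:`SimTruth`. Fixed ``config.seed`` gives bit-identical output.
    """
    cfg = replace(config, **overrides) if config is not None else SimConfig(**overrides)
    return _assemble(cfg, np.random.SeedSequence(cfg.seed), invivo=False)


def simulate_invivo(config: SimConfig | None = None, n_zones: int = 3,
                    **overrides) -> tuple[AnnData, SimTruth]:
    """Simulate zonated in-vivo-like data with a latent lobule position.

    ``n_zones`` controls the truth binning of the latent position (>= 2).
    The returned truth carries the 35-zone marker table consumed by the
    zonation module.
    """
    if n_zones < 2:
        raise SimConfigError("n_zones must be >= 2")
    cfg = replace(config, **overrides) if config is not None else SimConfig(**overrides)
    if cfg.zonation_genes_per_zone <= 0:
        raise SimConfigError("zonation marker sets must be nonempty")
    return _assemble(cfg, np.random.SeedSequence(cfg.seed), invivo=True, n_zones_truth=n_zones)
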