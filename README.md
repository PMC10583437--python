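# hepascope

Primary human hepatocytes (PHH) are the workhorse in-vitro model for drug
metabolism, yet single-cell RNA-seq shows they are not one homogeneous
population: multi-donor experiments resolve four functional subgroups —
I (sterol/bile-acid metabolism), II (carbohydrate/phase-II), III
(lipid/phase-III), and IV (cells losing hepatic gene expression) — that
respond differently to a five-drug CYP-phenotyping cocktail and to free
fatty-acid (FFA) loading.

`hepascope` implements that inference chain as a tested, reusable library
for cell×gene count matrices:

- **QC and normalization** — cell/gene filters (≥1000 counts, ≥500 genes,
  gene in ≥5 cells with <5×10⁶ reads), simulated-doublet kNN scoring with a
  lenient 0.15 cutoff (flag at score ≥ cutoff, sparing tetraploid
  hepatocytes), >1% mitochondrial-read removal, size-factor
  log-normalization `xᵢⱼ = ln(cᵢⱼ/sᵢ + 1)`, and removal of cells with
  >20,000 normalized counts.
- **Subgroup discovery** — per-donor Louvain clustering on a 50-PC kNN
  graph, with the resolution chosen as the largest at which every cluster
  contains every treatment; cross-donor cluster matching by the percentage
  overlap of top-N marker lists (average-linkage hierarchical clustering on
  100 − overlap, donor-specific outliers flagged unmatched); marker-panel
  annotation with a loss-of-expression override for subgroup IV.
- **Zonation** — 35 atlas zones binned into pericentral/mid/periportal gene
  sets, expression-bin-matched signature scores, and the fixed assignment
  cutoffs: pericentral iff CV > 0.45 and PV < 1; else periportal iff
  PV ≥ 0.65 and CV ≤ 0.45; else mid.
- **Drug/fat response DE** — per-subgroup and pseudobulk Welch t-tests on
  log-normalized values, Bonferroni correction, and the dual significance
  thresholds |log₂FC| > 1 (Cocktail) and > 0.75 (FFA); Venn-style
  intersections of up-regulated sets; CYP induction summaries; a generic
  hypergeometric enrichment test over user-supplied gene sets.
- **Transcriptional variability** — per-gene coefficient of variation on
  log-normalized expression, CV = √(exp(σ²) − 1) with σ² the unbiased
  variance of the log values, after removing genes with mean < 0.25;
  treatment shifts tested per subgroup with a two-sided Mann–Whitney U.
- **Synthetic data** — a negative-binomial generator that plants the full
  study structure (4 donors × 4 treatments, marker modules, CYP induction
  and its FFA attenuation, per-subgroup dispersion shifts under FFA,
  Bernoulli gene silencing in subgroup IV, mitochondrial genes, doublets,
  and an in-vivo lobule-position gradient) with complete ground truth, so
  every downstream stage is testable without downloads.

## Worked example

```python
import hepascope as h
from sklearn.metrics import adjusted_rand_score

adata, truth = h.simulate_invitro(h.SimConfig(seed=42))   # 8000 cells x 1500 genes

thr = h.QCThresholds(min_genes_per_cell=100)  # gene floor scaled to 1500 genes
filtered = h.filter_cells_genes(adata, thr)
scores = h.doublet_scores(filtered, seed=42)
clean = h.apply_doublet_and_mito_filter(filtered, scores, thr)
norm = h.post_norm_filter(h.lognormalize(clean), thr)      # 6486 cells

panel = h.MarkerPanel(sets={k: v for k, v in truth.marker_modules.items()
                            if k != "subgroup_IV_module"})
cm = h.discover_subgroups(norm, panel, top_n=100, seed=42)
print(cm.cells["subgroup"].value_counts().to_dict())
# {'II': 2469, 'I': 2451, 'IV': 1200, 'III': 366}
print(adjusted_rand_score(norm.obs["true_subgroup"].astype(str),
                          cm.cells["subgroup"]))           # 0.984

spec = h.contrast_by_treatment(norm, "Cocktail", "DMSO", subgroup="I",
                               subgroup_labels=cm.cells["subgroup"])
print(h.de_test(norm, spec).loc[truth.cyp_genes, ["log2fc", "padj", "class"]])
#          log2fc  padj    class
# CYP1A2    1.984   0.0  up_in_A
# CYP2C9    1.979   0.0  up_in_A
# CYP2C19   2.147   0.0  up_in_A
# CYP2D6    2.028   0.0  up_in_A
# CYP3A4    1.992   0.0  up_in_A

rep = h.variability_report(norm, cm.cells["subgroup"], norm.obs["treatment"])
print(rep[["subgroup", "direction", "pval"]])
#   subgroup  direction          pval
#          I          1  2.77e-10     <- FFA raises CV in I and II
#         II          1  1.74e-11
#        III         -1  1.03e-13     <- and lowers it in III
#         IV          1  7.00e-01
```

The recovered subgroup proportions track the planted 38.2/38.7/5.4/17.7%
mixture, the five cocktail-target cytochromes come back at their planted
~4-fold induction, and FFA loading raises transcriptional variability in
subgroups I–II while the lipid-specialized subgroup III responds more
coordinately (lower CV) — the qualitative fingerprint of the biology the
generator plants.

A command-line interface mirrors the library
(`hepascope simulate | qc | normalize | cluster | zonate | de | intersect |
enrich | variability | run`); `hepascope run --config pipeline.yaml --seed 1`
executes the whole chain and emits a JSON run report.

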