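"""Readers and writers for 10x-style MTX directories and annotation tables.

The on-disk layout is the 10x triplet convention: ``matrix.mtx`` (features x
barcodes, 1-based integer coordinate format), ``features.tsv`` and
``barcodes.tsv``, optionally gzipped, plus a ``cell_annotation.tsv`` joined
on barcode. Genes are addressed by feature id internally.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData


class ParseError(ValueError):
    pass


def _find(dirpath: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dirpath / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}[.gz] not found in {dirpath}")


def _read_lines(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [ln.rstrip("\n") for ln in fh if ln.strip()]


def write_10x(adata: AnnData, outdir, annotation: bool = True) -> Path:
    """Write counts as matrix.mtx + barcodes.tsv + features.tsv (+ annotation)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    X = sp.csr_matrix(X) if not sp.issparse(X) else X.tocsr()
    scipy.io.mmwrite(outdir / "matrix.mtx", X.T.astype(np.int64), field="integer")
    (outdir / "barcodes.tsv").write_text("\n".join(adata.obs_names) + "\n")
    feat = pd.DataFrame({
        "gene_id": adata.var_names,
        "gene_name": adata.var_names,
        "feature_type": "Gene Expression",
    })
    feat.to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    if annotation and len(adata.obs.columns):
        ann = adata.obs.reset_index().rename(columns={"index": "barcode"})
        if ann.columns[0] != "barcode":
            ann = ann.rename(columns={ann.columns[0]: "barcode"})
        ann.to_csv(outdir / "cell_annotation.tsv", sep="\t", index=False)
    return outdir


def read_10x(dirpath, annotation: bool = True) -> AnnData:
    """Read a 10x-style directory back into AnnData (cells x genes).

    Validates that barcode/feature counts match the matrix dimensions and
    that neither barcodes nor feature ids are duplicated; the cell
    annotation TSV, when present, is joined on barcode.
    """
    dirpath = Path(dirpath)
    mtx_path = _find(dirpath, "matrix.mtx")
    opener = gzip.open if mtx_path.suffix == ".gz" else open
    with opener(mtx_path, "rb") as fh:
        M = scipy.io.mmread(fh)
    M = sp.csr_matrix(M)
    barcodes = _read_lines(_find(dirpath, "barcodes.tsv"))
    feat_lines = _read_lines(_find(dirpath, "features.tsv"))
    genes = [ln.split("\t")[0] for ln in feat_lines]
    n_genes, n_cells = M.shape
    if len(barcodes) != n_cells:
        raise ParseError(
            f"barcodes.tsv has {len(barcodes)} rows but matrix.mtx has {n_cells} columns")
    if len(genes) != n_genes:
        raise ParseError(
            f"features.tsv has {len(genes)} rows but matrix.mtx has {n_genes} rows")
    bseen = pd.Index(barcodes)
    if bseen.has_duplicates:
        dup = bseen[bseen.duplicated()][0]
        raise ParseError(f"duplicate barcode {dup!r} (line {barcodes.index(dup) + 1})")
    gseen = pd.Index(genes)
    if gseen.has_duplicates:
        dup = gseen[gseen.duplicated()][0]
        raise ParseError(f"duplicate feature id {dup!r} (line {genes.index(dup) + 1})")
    adata = AnnData(
        X=M.T.astype(np.int64).tocsr(),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )
    if annotation:
        try:
            ann_path = _find(dirpath, "cell_annotation.tsv")
        except FileNotFoundError:
            return adata
        ann = pd.read_csv(ann_path, sep="\t", dtype={"barcode": str})
        if "barcode" not in ann.columns:
            raise ParseError("cell_annotation.tsv lacks a 'barcode' column")
        ann = ann.set_index("barcode")
        missing = adata.obs_names.difference(ann.index)
        if len(missing):
            raise ParseError(f"annotation missing {len(missing)} barcode(s), e.g. {missing[0]!r}")
        adata.obs = adata.obs.join(ann.loc[adata.obs_names])
        for col in ("is_doublet",):
            if col in adata.obs:
                adata.obs[col] = adata.obs[col].astype(bool)
        adata.var["is_mito"] = [g.startswith("MT-") for g in adata.var_names]
    return adata


def write_truth_json(truth, path) -> None:
    """Persist the generator's gene-level truth (modules, CYPs, zonation table)."""
    payload = {
        "marker_modules": truth.marker_modules,
        "cyp_genes": truth.cyp_genes,
    }
    if truth.zonation_table is not None:
        payload["zonation_table"] = truth.zonation_table.to_dict(orient="list")
    Path(path).write_text(json.dumps(payload, indent=1))
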