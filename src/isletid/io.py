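"""10x-style Matrix Market triplet reading and writing.

A dataset directory holds ``matrix.mtx``, ``features.tsv`` (gene_id,
gene_symbol) and ``barcodes.tsv``, each optionally gzipped.  Matrices are
cells-by-genes internally; the on-disk orientation (10x convention is
genes-by-cells) is auto-detected by matching header dimensions against the
features/barcodes file lengths.
"""

from __future__ import annotations

import gzip
import logging
import os

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

log = logging.getLogger("isletid")

__all__ = ["read_10x", "write_10x", "read_truth", "write_truth"]


def _find(dirpath: str, stem: str) -> str:
    for name in (stem, stem + ".gz"):
        p = os.path.join(dirpath, name)
        if os.path.exists(p):
            return p
    raise FileNotFoundError(f"{stem}(.gz) not found in {dirpath}")


def _opener(path: str, mode: str):
    return gzip.open(path, mode) if path.endswith(".gz") else open(path, mode)


def _dedup_symbols(symbols: list[str]) -> list[str]:
    """Disambiguate duplicate gene symbols with .1, .2 suffixes in file order."""
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        if s in seen:
            seen[s] += 1
            log.warning("duplicate gene symbol %r -> %s.%d", s, s, seen[s])
            out.append(f"{s}.{seen[s]}")
        else:
            seen[s] = 0
            out.append(s)
    return out


def read_10x(dirpath: str) -> ad.AnnData:
    """Load a 10x triplet directory into a cells-by-genes AnnData."""
    mtx_path = _find(dirpath, "matrix.mtx")
    feat_path = _find(dirpath, "features.tsv")
    bc_path = _find(dirpath, "barcodes.tsv")

    with _opener(mtx_path, "rb") as fh:
        M = mmread(fh)
    M = sp.csr_matrix(M)
    if M.dtype.kind == "f":
        if np.any(M.data != np.round(M.data)):
            raise ValueError("matrix contains non-integer values")
        M = M.astype(np.int64)

    feats = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(bc_path, sep="\t", header=None, dtype=str)[0].tolist()
    n_genes, n_cells = len(feats), len(barcodes)

    if M.shape == (n_genes, n_cells):
        # ambiguous square matrices also take the 10x genes-by-cells reading
        M = M.T.tocsr()
    elif M.shape == (n_cells, n_genes):
        pass
    else:
        raise ValueError(
            f"matrix shape {M.shape} matches neither genes x cells "
            f"({n_genes}, {n_cells}) nor cells x genes"
        )

    gene_ids = feats[0].tolist()
    symbols = _dedup_symbols(feats[1].tolist() if feats.shape[1] > 1 else gene_ids)
    return ad.AnnData(
        X=M.astype(np.int32),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(
            {"gene_id": gene_ids}, index=pd.Index(symbols, name="gene_symbol")
        ),
    )


def write_10x(adata, dirpath: str, compress: bool = False) -> None:
    """Write an AnnData as a 10x triplet (genes-by-cells on disk)."""
    os.makedirs(dirpath, exist_ok=True)
    suffix = ".gz" if compress else ""
    X = adata.X
    X = sp.coo_matrix(X.T if sp.issparse(X) else np.asarray(X).T)

    with _opener(os.path.join(dirpath, "matrix.mtx" + suffix), "wb") as fh:
        mmwrite(fh, X, field="integer")
    gene_ids = (
        adata.var["gene_id"].tolist()
        if "gene_id" in adata.var
        else list(adata.var_names)
    )
    feats = pd.DataFrame({0: gene_ids, 1: list(adata.var_names)})
    with _opener(os.path.join(dirpath, "features.tsv" + suffix), "wt") as fh:
        feats.to_csv(fh, sep="\t", header=False, index=False)
    with _opener(os.path.join(dirpath, "barcodes.tsv" + suffix), "wt") as fh:
        fh.write("\n".join(adata.obs_names) + "\n")


def write_truth(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, sep="\t", index=True)


def read_truth(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="barcode", keep_default_na=False,
                       na_values=[""])
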