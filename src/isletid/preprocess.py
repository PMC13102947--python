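"""Cell QC, log-normalization, gene scaling, and SNN graph clustering.

QC keeps cells with ``min_features < n_features < max_features`` (strict on
both sides) and mitochondrial fraction strictly below ``max_mito_fraction``.
Normalization is log1p of counts-per-``scale_total`` and scaling is per-gene
z-scoring with clipping; together they supply the "RNA-slot"-style values
the gating step reads and the scaled values the centroids consume.
Clustering is PCA -> kNN -> shared-nearest-neighbor graph -> modularity
community detection (Leiden) at a configurable resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "QCParams",
    "ClusterParams",
    "qc_filter",
    "normalize_log",
    "scale_genes",
    "cluster_graph",
]


@dataclass
class QCParams:
    """Strict-bound QC thresholds.

    Defaults are the mouse-islet study values (2500/6000 features, 10%
    mitochondrial reads); synthetic panels with few genes need
    proportionally smaller feature bounds.
    """

    min_features: int = 2500
    max_features: int = 6000
    max_mito_fraction: float = 0.10
    mito_prefix: str = "mt-"

    def __post_init__(self) -> None:
        if not 0 <= self.min_features < self.max_features:
            raise ValueError("need 0 <= min_features < max_features")
        if not 0 < self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in (0, 1]")


@dataclass
class ClusterParams:
    n_pcs: int = 30
    k_neighbors: int = 20
    resolution: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pcs < 2:
            raise ValueError("n_pcs must be >= 2")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")


def qc_filter(adata, params: QCParams = QCParams()):
    """Filter cells on detected features and mitochondrial fraction.

    Returns ``(filtered_adata, cell_table)`` where the cell table covers all
    input cells with columns ``n_features``, ``total_counts``,
    ``mito_fraction``, ``qc_pass`` and ``removal_reason``.
    """
    X = adata.X
    if sp.issparse(X):
        n_features = np.asarray((X > 0).sum(axis=1)).ravel()
        total = np.asarray(X.sum(axis=1)).ravel()
    else:
        n_features = (np.asarray(X) > 0).sum(axis=1)
        total = np.asarray(X).sum(axis=1)
    mito_genes = [g for g in adata.var_names if g.startswith(params.mito_prefix)]
    if mito_genes:
        idx = [adata.var_names.get_loc(g) for g in mito_genes]
        sub = X[:, idx]
        mito = np.asarray(sub.sum(axis=1)).ravel() if sp.issparse(sub) else np.asarray(sub).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    else:
        mito_frac = np.zeros(adata.n_obs)

    low = n_features <= params.min_features
    high = n_features >= params.max_features
    mito_fail = mito_frac >= params.max_mito_fraction
    keep = ~(low | high | mito_fail)

    reason = np.full(adata.n_obs, "", dtype=object)
    reason[mito_fail] = "mito_fraction"
    reason[high] = "too_many_features"
    reason[low] = "too_few_features"
    table = pd.DataFrame(
        {
            "n_features": n_features,
            "total_counts": total,
            "mito_fraction": mito_frac,
            "qc_pass": keep,
            "removal_reason": reason,
        },
        index=adata.obs_names,
    )
    if not keep.any():
        raise ValueError(
            "QC removed every cell; override thresholds (min_features/"
            "max_features/max_mito_fraction) to fit this dataset"
        )
    return adata[keep].copy(), table


def normalize_log(adata, scale_total: float = 1e4, layer_out: str = "lognorm") -> None:
    """Store log1p counts-per-``scale_total`` in ``adata.layers[layer_out]``.

    Cells with zero total counts are flagged in ``obs["zero_total"]`` and
    left all-zero rather than divided.
    """
    X = adata.X
    dense = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
    total = dense.sum(axis=1)
    zero = total == 0
    safe = np.where(zero, 1.0, total)
    norm = np.log1p(scale_total * dense / safe[:, None])
    norm[zero] = 0.0
    adata.layers[layer_out] = norm
    adata.obs["zero_total"] = zero


def scale_genes(adata, clip: float = 10.0, layer: str = "lognorm",
                layer_out: str = "scaled") -> None:
    """Per-gene z-score (sample sd, ddof=1) clipped to ``[-clip, clip]``.

    Zero-variance genes come out identically zero.
    """
    X = np.asarray(adata.layers[layer], dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sd > 0, (X - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    adata.layers[layer_out] = np.clip(Z, -clip, clip)


def cluster_graph(adata, params: ClusterParams = ClusterParams(),
                  layer: str = "scaled") -> np.ndarray:
    """SNN-modularity clustering on a PCA of the scaled matrix.

    Builds ``n_pcs`` principal components, a ``k_neighbors`` kNN graph, and
    runs Leiden community detection at the given resolution.  Deterministic
    for a fixed seed; returns contiguous integer labels.
    """
    import scanpy as sc

    if adata.n_obs < params.k_neighbors + 1:
        raise ValueError(
            f"need at least k_neighbors+1={params.k_neighbors + 1} cells, "
            f"got {adata.n_obs}"
        )
    work = adata.copy()
    work.X = np.asarray(work.layers[layer], dtype=float)
    if np.allclose(work.X, work.X[0]):
        # all cells identical: one community, no PCA possible
        return np.zeros(adata.n_obs, dtype=int)
    n_pcs = min(params.n_pcs, min(work.shape) - 1)
    sc.pp.pca(work, n_comps=n_pcs, random_state=params.seed)
    sc.pp.neighbors(work, n_neighbors=params.k_neighbors, n_pcs=n_pcs,
                    random_state=params.seed)
    sc.tl.leiden(
        work,
        resolution=params.resolution,
        random_state=params.seed,
        flavor="leidenalg",
    )
    labels = work.obs["leiden"].astype(int).to_numpy()
    # contiguous relabeling in order of first appearance
    _, labels = np.unique(labels, return_inverse=True)
    return labels
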