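"""Marker gating and centroid-correlation cell-identity classification.

The classifier works in four steps:

1. :func:`gate_cells` thresholds canonical marker genes on log-normalized
   expression; cells exceeding exactly one threshold are "pure profile"
   cells for their marker's type.
2. :func:`top_discriminative_genes` runs a one-vs-rest rank-sum test over
   pure cells to pick the top-k genes per type; their union with the marker
   panel is the discriminative feature set F.
3. :func:`build_centroids` averages scaled expression of pure cells over F;
   :func:`build_mixed_centroids` adds artificial centroids for every pair
   and triple of types (unweighted mean of the pure centroids), modeling the
   in-between profile expected of polyhormonal cells and of doublets.
4. :func:`classify_by_correlation` assigns each cell the centroid with the
   highest Pearson correlation to its scaled profile over F.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml
from scipy import stats

__all__ = [
    "MarkerEntry",
    "MarkerPanel",
    "CentroidSet",
    "default_panel",
    "gate_cells",
    "top_discriminative_genes",
    "build_centroids",
    "build_mixed_centroids",
    "classify_by_correlation",
]


@dataclass(frozen=True)
class MarkerEntry:
    """One marker gene: gate threshold (log-normalized scale), target type."""

    threshold: float
    cell_type: str
    endocrine: bool


@dataclass
class MarkerPanel:
    """Canonical marker gene -> (threshold, cell type, endocrine flag)."""

    entries: dict[str, MarkerEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.entries:
            raise ValueError("marker panel is empty")
        for gene, e in self.entries.items():
            if e.threshold <= 0:
                raise ValueError(f"threshold for {gene} must be > 0")
        if len(self.endocrine_types()) < 2:
            raise ValueError("panel must define at least 2 endocrine types")

    @property
    def genes(self) -> list[str]:
        return list(self.entries)

    def types(self) -> list[str]:
        return [e.cell_type for e in self.entries.values()]

    def endocrine_types(self) -> list[str]:
        return [e.cell_type for e in self.entries.values() if e.endocrine]

    def type_of(self, gene: str) -> str:
        return self.entries[gene].cell_type

    def marker_of(self, cell_type: str) -> str:
        for gene, e in self.entries.items():
            if e.cell_type == cell_type:
                return gene
        raise KeyError(cell_type)

    def is_endocrine(self, cell_type: str) -> bool:
        for e in self.entries.values():
            if e.cell_type == cell_type:
                return e.endocrine
        raise KeyError(cell_type)

    def to_yaml(self, path) -> None:
        data = {
            g: {
                "threshold": float(e.threshold),
                "cell_type": e.cell_type,
                "endocrine": bool(e.endocrine),
            }
            for g, e in self.entries.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "MarkerPanel":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        entries = {
            g: MarkerEntry(float(v["threshold"]), str(v["cell_type"]), bool(v["endocrine"]))
            for g, v in data.items()
        }
        return cls(entries)


def default_panel() -> MarkerPanel:
    """Default mouse islet panel: 9 markers, one per detected cell type.

    Thresholds are on the log-normalized scale and were set by inspection of
    the expression distributions in the study this package reimplements; the
    marker-to-type mapping is the canonical islet assignment.
    """
    return MarkerPanel(
        {
            "Gcg": MarkerEntry(2.1, "alpha", True),
            "Ins1": MarkerEntry(2.0, "beta", True),
            "Sst": MarkerEntry(2.0, "delta", True),
            "Ppy": MarkerEntry(2.2, "pp", True),
            "Cd86": MarkerEntry(1.0, "immune", False),
            "Trac": MarkerEntry(0.1, "t_cell", False),
            "Cd34": MarkerEntry(0.1, "endothelial", False),
            "Vim": MarkerEntry(0.6, "mesenchymal", False),
            "Krt19": MarkerEntry(0.5, "ductal", False),
        }
    )


# ---------------------------------------------------------------------------
# gating


def gate_cells(adata, panel: MarkerPanel, layer: str = "lognorm") -> pd.DataFrame:
    """Threshold marker expression per cell; strict ">" comparison.

    Returns a per-cell frame with columns ``markers_above`` (comma-joined
    marker genes over threshold), ``n_markers_above``, ``status`` in
    {``pure``, ``candidate_mixed``, ``unassigned``} and ``pure_type`` (the
    gated type for pure cells, empty otherwise).
    """
    missing = [g for g in panel.genes if g not in adata.var_names]
    if missing:
        raise KeyError(f"marker genes missing from matrix: {missing}")
    X = adata.layers[layer] if layer else adata.X
    idx = [adata.var_names.get_loc(g) for g in panel.genes]
    M = X[:, idx]
    if sp.issparse(M):
        M = M.toarray()
    M = np.asarray(M)
    thr = np.array([panel.entries[g].threshold for g in panel.genes])
    above = M > thr[None, :]
    n_above = above.sum(axis=1)

    genes = np.array(panel.genes)
    markers_above = [",".join(genes[row]) for row in above]
    status = np.where(n_above == 1, "pure", np.where(n_above >= 2, "candidate_mixed", "unassigned"))
    pure_type = [
        panel.type_of(genes[row][0]) if n == 1 else ""
        for row, n in zip(above, n_above)
    ]
    return pd.DataFrame(
        {
            "markers_above": markers_above,
            "n_markers_above": n_above,
            "status": status,
            "pure_type": pure_type,
        },
        index=adata.obs_names,
    )


# ---------------------------------------------------------------------------
# discriminative features


def top_discriminative_genes(
    adata,
    gate: pd.DataFrame,
    panel: MarkerPanel,
    k: int = 10,
    layer: str = "lognorm",
    min_pure_cells: int = 3,
) -> tuple[dict[str, list[str]], list[str]]:
    """Top-k one-vs-rest genes per type among pure cells, plus feature set F.

    For each gated type a two-sided rank-sum test compares that type's pure
    cells against all other pure cells, gene by gene; genes are ranked by
    p-value, then |log2 fold change| (pseudocount 1 on mean normalized
    expression), ties broken by gene symbol. F is the union of the marker
    panel and all per-type lists, panel genes first, order deterministic.
    """
    types = sorted(set(panel.types()))
    pure = gate["status"] == "pure"
    counts = gate.loc[pure, "pure_type"].value_counts()
    for t in types:
        if counts.get(t, 0) < min_pure_cells:
            raise ValueError(
                f"type {t!r} has {counts.get(t, 0)} pure cells; "
                f"need at least {min_pure_cells}"
            )

    X = adata.layers[layer] if layer else adata.X
    if sp.issparse(X):
        X = X.toarray()
    X = np.asarray(X)
    pure_mask = pure.to_numpy()
    Xp = X[pure_mask]
    labels = gate.loc[pure, "pure_type"].to_numpy()

    per_type: dict[str, list[str]] = {}
    symbols = np.asarray(adata.var_names)
    for t in types:
        if k == 0:
            per_type[t] = []
            continue
        in_t = labels == t
        x, y = Xp[in_t], Xp[~in_t]
        with warnings.catch_warnings():
            # constant genes yield a degenerate U test; give them p = 1
            warnings.simplefilter("ignore")
            res = stats.mannwhitneyu(x, y, axis=0, alternative="two-sided")
        p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        lfc = np.log2(x.mean(axis=0) + 1.0) - np.log2(y.mean(axis=0) + 1.0)
        order = sorted(
            range(X.shape[1]), key=lambda j: (p[j], -abs(lfc[j]), symbols[j])
        )
        per_type[t] = [symbols[j] for j in order[:k]]

    F = list(dict.fromkeys(panel.genes + [g for t in types for g in per_type[t]]))
    return per_type, F


# ---------------------------------------------------------------------------
# centroids


@dataclass
class CentroidSet:
    """Labeled mean scaled-expression profiles over the feature set F.

    Labels are sorted tuples of 1 (pure), 2 (pair) or 3 (triple) type names.
    """

    feature_genes: list[str]
    centroids: dict[tuple[str, ...], np.ndarray]

    def __post_init__(self) -> None:
        n = len(self.feature_genes)
        for label, v in self.centroids.items():
            if len(v) != n:
                raise ValueError(f"centroid {label} has length {len(v)} != |F|={n}")

    @property
    def labels(self) -> list[tuple[str, ...]]:
        """Labels sorted by order (pure < pair < triple) then lexicographically."""
        return sorted(self.centroids, key=lambda lab: (len(lab), lab))

    def pure_labels(self) -> list[tuple[str, ...]]:
        return [lab for lab in self.labels if len(lab) == 1]

    def to_frame(self) -> pd.DataFrame:
        rows = {"+".join(lab): self.centroids[lab] for lab in self.labels}
        return pd.DataFrame.from_dict(rows, orient="index", columns=self.feature_genes)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CentroidSet":
        cents = {tuple(lab.split("+")): df.loc[lab].to_numpy(float) for lab in df.index}
        return cls(list(df.columns), cents)


def build_centroids(
    adata, gate: pd.DataFrame, feature_genes: list[str], layer: str = "scaled"
) -> CentroidSet:
    """Mean scaled profile over F of each type's pure cells."""
    X = adata.layers[layer] if layer else adata.X
    if sp.issparse(X):
        X = X.toarray()
    X = np.asarray(X)
    idx = [adata.var_names.get_loc(g) for g in feature_genes]
    pure = gate["status"].to_numpy() == "pure"
    labels = gate["pure_type"].to_numpy()
    cents: dict[tuple[str, ...], np.ndarray] = {}
    for t in sorted(set(labels[pure])):
        mask = pure & (labels == t)
        if not mask.any():
            raise ValueError(f"no pure cells for type {t!r}")
        cents[(t,)] = X[np.ix_(mask, idx)].mean(axis=0)
    if not cents:
        raise ValueError("no pure cells at all; cannot build centroids")
    return CentroidSet(list(feature_genes), cents)


def build_mixed_centroids(
    pure: CentroidSet,
    orders: tuple[int, ...] = (2, 3),
    weights: dict[tuple[str, ...], np.ndarray] | None = None,
) -> CentroidSet:
    """Add artificial mixed centroids for every pair/triple of pure types.

    A mixed centroid is the unweighted mean of its constituent pure
    centroids (per-combination weights may be supplied via ``weights``).
    """
    pures = pure.pure_labels()
    if len(pures) < 3:
        raise ValueError("need at least 3 pure centroids to build mixtures")
    cents = {lab: pure.centroids[lab].copy() for lab in pures}
    names = sorted(lab[0] for lab in pures)
    for order in orders:
        for combo in itertools.combinations(names, order):
            parts = np.stack([pure.centroids[(t,)] for t in combo])
            if weights and combo in weights:
                w = np.asarray(weights[combo], float)
                w = w / w.sum()
                cents[combo] = w @ parts
            else:
                cents[combo] = parts.mean(axis=0)
    return CentroidSet(list(pure.feature_genes), cents)


# ---------------------------------------------------------------------------
# classification


def classify_by_correlation(
    adata, centroids: CentroidSet, layer: str = "scaled"
) -> pd.DataFrame:
    """Assign each cell the centroid with the highest Pearson correlation.

    Correlation is computed between the cell's scaled profile restricted to
    F and every centroid.  Ties are broken in favor of the smallest label
    order (pure < pair < triple), then lexicographically.  Cells with a
    constant profile over F have no defined correlation and come back
    ``unclassified``.  Zero-variance centroids are excluded with a warning.

    Returns a frame with ``best_label`` ("a+b" strings), ``best_order``,
    ``best_correlation`` and ``unclassified``.
    """
    F = centroids.feature_genes
    if len(F) < 3:
        raise ValueError("feature set must contain at least 3 genes")
    labels = centroids.labels
    C = np.stack([centroids.centroids[lab] for lab in labels]).astype(float)
    c_sd = C.std(axis=1)
    keep = c_sd > 0
    if not keep.all():
        dropped = [labels[i] for i in np.flatnonzero(~keep)]
        warnings.warn(f"excluding zero-variance centroids: {dropped}")
        labels = [lab for lab, k in zip(labels, keep) if k]
        C = C[keep]
    if C.shape[0] == 0:
        raise ValueError("all centroids have zero variance")

    X = adata.layers[layer] if layer else adata.X
    if sp.issparse(X):
        X = X.toarray()
    X = np.asarray(X, dtype=float)
    idx = [adata.var_names.get_loc(g) for g in F]
    P = X[:, idx]

    Pc = P - P.mean(axis=1, keepdims=True)
    p_norm = np.linalg.norm(Pc, axis=1)
    Cc = C - C.mean(axis=1, keepdims=True)
    Cc /= np.linalg.norm(Cc, axis=1, keepdims=True)

    ok = p_norm > 0
    R = np.zeros((P.shape[0], C.shape[0]))
    if ok.any():
        R[ok] = (Pc[ok] / p_norm[ok, None]) @ Cc.T
    # labels are pre-sorted by (order, lex); argmax returns the first of any
    # tied maxima, which realizes the tie-break rule
    best = R.argmax(axis=1)
    best_corr = R[np.arange(R.shape[0]), best]
    best_label = ["+".join(labels[b]) if o else "" for b, o in zip(best, ok)]
    best_order = [len(labels[b]) if o else 0 for b, o in zip(best, ok)]
    return pd.DataFrame(
        {
            "best_label": best_label,
            "best_order": best_order,
            "best_correlation": np.where(ok, best_corr, np.nan),
            "unclassified": ~ok,
        },
        index=adata.obs_names,
    )
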