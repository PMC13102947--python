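"""Module scores, nonparametric group inference, composition and DE tables.

Module scores follow the expression-binned control-gene scheme of Tirosh et
al.: each program gene is matched with control genes drawn from its average-
expression bin and the score is the mean program expression minus the mean
control expression.  Group comparisons use two-sided Wilcoxon rank-sum
tests with Holm adjustment across programs and the Hodges-Lehmann shift
(median of all cross-group differences, knockout minus control) as effect
size.  Per-gene differential expression between conditions uses the same
rank test with Benjamini-Hochberg adjustment, gated on fold change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ScoreParams",
    "DEParams",
    "MassInputs",
    "module_score",
    "wilcoxon_rank_sum",
    "holm_adjust",
    "hodges_lehmann_shift",
    "compare_module_scores",
    "composition_table",
    "ab_mass_ratio",
    "de_between_conditions",
]


@dataclass
class ScoreParams:
    n_bins: int = 25
    n_ctrl: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.n_ctrl < 1:
            raise ValueError("n_ctrl must be >= 1")


@dataclass
class DEParams:
    min_pct: float = 0.01
    lfc_threshold: float = 0.5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.min_pct <= 1:
            raise ValueError("min_pct must be in [0, 1]")


@dataclass
class MassInputs:
    """Histology inputs: stained cell area, total tissue area, organ weight."""

    cell_area: float
    total_tissue_area: float
    pancreatic_weight: float

    def __post_init__(self) -> None:
        if not 0 <= self.cell_area <= self.total_tissue_area:
            raise ValueError("need 0 <= cell_area <= total_tissue_area")
        if self.pancreatic_weight <= 0:
            raise ValueError("pancreatic_weight must be > 0")


# ---------------------------------------------------------------------------
# module scores


def module_score(
    adata,
    genes: Sequence[str],
    params: ScoreParams = ScoreParams(),
    layer: str = "lognorm",
) -> np.ndarray:
    """Per-cell program activity: program mean minus matched-control mean.

    Genes are binned into ``n_bins`` equal-size groups by average
    expression; for every program gene, ``n_ctrl`` control genes are drawn
    from its bin, excluding program genes (bins with at most ``n_ctrl``
    eligible genes are used exhaustively); the per-cell score is the mean
    over program genes minus the mean over the pooled controls.  Control
    draws are keyed by gene identity, so scores are invariant to gene
    order.  Program genes absent from the matrix are dropped with a
    warning.
    """
    import warnings

    present = [g for g in dict.fromkeys(genes) if g in adata.var_names]
    dropped = set(genes) - set(present)
    if dropped:
        warnings.warn(f"module_score: dropping absent genes {sorted(dropped)}")
    if not present:
        raise ValueError("program is empty after dropping absent genes")
    if adata.n_vars < params.n_bins:
        raise ValueError(
            f"matrix has {adata.n_vars} genes < n_bins={params.n_bins}"
        )

    X = adata.layers[layer] if layer else adata.X
    X = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
    avg = X.mean(axis=0)
    # equal-size bins by rank of average expression, gene symbol as a
    # deterministic tie-break so scores are permutation invariant
    order = np.lexsort((np.asarray(adata.var_names), avg))
    bins = np.empty(adata.n_vars, dtype=int)
    bins[order] = (np.arange(adata.n_vars) * params.n_bins) // adata.n_vars

    import zlib

    symbols = np.asarray(adata.var_names)
    prog_idx = np.array([adata.var_names.get_loc(g) for g in present])
    prog_set = set(prog_idx.tolist())
    ctrl_idx: list[int] = []
    for g in prog_idx:
        pool = np.flatnonzero(bins == bins[g])
        eligible = np.array([j for j in pool if j not in prog_set], dtype=int)
        if eligible.size == 0:
            # every gene in the bin is a program gene: use the whole bin as
            # its own matched control rather than resampling it
            ctrl_idx.extend(pool)
            continue
        eligible = eligible[np.argsort(symbols[eligible])]
        if eligible.size <= params.n_ctrl:
            ctrl_idx.extend(eligible)
        else:
            sub_rng = np.random.default_rng(
                [params.seed, zlib.crc32(symbols[g].encode())]
            )
            ctrl_idx.extend(
                sub_rng.choice(eligible, size=params.n_ctrl, replace=False)
            )
    ctrl_idx = np.asarray(ctrl_idx)
    return X[:, prog_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)


# ---------------------------------------------------------------------------
# nonparametric inference


class WilcoxonResult(NamedTuple):
    pvalue: float
    method: str


def wilcoxon_rank_sum(a, b) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when ``n*m <= 10000`` and the pooled sample is
    tie-free; otherwise the tie-corrected normal approximation (no
    continuity correction).  The method used is recorded in the result.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and a.size * b.size <= 10_000:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return WilcoxonResult(float(min(res.pvalue, 1.0)), "exact")
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return WilcoxonResult(float(min(res.pvalue, 1.0)), "normal_tie_corrected")


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values, order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def hodges_lehmann_shift(a, b) -> float:
    """Median of all pairwise differences ``b_j - a_i`` (b=KO, a=control)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    return float(np.median(np.subtract.outer(b, a)))


def compare_module_scores(
    scores: pd.DataFrame, groups: pd.Series, control: str, case: str
) -> pd.DataFrame:
    """Per-program rank-sum comparison of module scores between two groups.

    ``scores`` is cells x programs; ``groups`` aligns cells to condition
    labels.  Returns one row per program with raw and Holm-adjusted
    p-values and the Hodges-Lehmann shift (case minus control), sorted by
    adjusted p then program name.
    """
    g = groups.reindex(scores.index)
    a_mask = (g == control).to_numpy()
    b_mask = (g == case).to_numpy()
    if a_mask.sum() < 2 or b_mask.sum() < 2:
        raise ValueError("each group needs at least 2 cells")
    rows = []
    for prog in scores.columns:
        a = scores.loc[a_mask, prog].to_numpy()
        b = scores.loc[b_mask, prog].to_numpy()
        res = wilcoxon_rank_sum(a, b)
        rows.append(
            {
                "program": prog,
                "n_control": int(a_mask.sum()),
                "n_case": int(b_mask.sum()),
                "effect": hodges_lehmann_shift(a, b),
                "p_raw": res.pvalue,
                "method": res.method,
            }
        )
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    return out.sort_values(["p_holm", "program"], ignore_index=True)


# ---------------------------------------------------------------------------
# composition and histology


def composition_table(final: pd.DataFrame, conditions: pd.Series) -> pd.DataFrame:
    """Counts and within-condition proportions per final label.

    Doublets and non-quantifiable mixed labels are excluded; proportions sum
    to 1 within each condition.
    """
    cond = conditions.reindex(final.index)
    keep = (final["status"] != "doublet") & (final["status"] != "unclassified")
    keep &= final["quantifiable"]
    df = pd.DataFrame({"label": final.loc[keep, "label"], "condition": cond[keep]})
    counts = (
        df.groupby(["condition", "label"], sort=True).size().rename("count").reset_index()
    )
    counts["proportion"] = counts.groupby("condition")["count"].transform(
        lambda c: c / c.sum()
    )
    return counts


def ab_mass_ratio(alpha: MassInputs, beta: MassInputs) -> tuple[float, float, float]:
    """Total cell mass per lineage and the alpha/beta mass ratio.

    mass = (cell area / total tissue area) * pancreatic weight.
    """
    a_mass = alpha.cell_area / alpha.total_tissue_area * alpha.pancreatic_weight
    b_mass = beta.cell_area / beta.total_tissue_area * beta.pancreatic_weight
    if b_mass == 0:
        raise ZeroDivisionError("beta-cell mass is zero; ratio undefined")
    return a_mass, b_mass, a_mass / b_mass


# ---------------------------------------------------------------------------
# differential expression


def de_between_conditions(
    adata,
    cell_mask,
    control: str,
    case: str,
    params: DEParams = DEParams(),
    layer: str = "lognorm",
    condition_col: str = "condition",
) -> pd.DataFrame:
    """Per-gene rank-sum DE between two conditions within one cell subset.

    Genes expressed in at least ``min_pct`` of cells in either condition are
    tested; p-values are BH-adjusted; a gene is significant iff
    ``|log2FC| > lfc_threshold`` and ``p_adj < alpha``.  log2FC uses a
    pseudocount of 1 on mean normalized expression (case over control).
    """
    sub = adata[np.asarray(cell_mask)]
    cond = sub.obs[condition_col].to_numpy()
    a_mask = cond == control
    b_mask = cond == case
    if a_mask.sum() < 3 or b_mask.sum() < 3:
        raise ValueError("need at least 3 cells per condition")
    X = sub.layers[layer]
    X = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
    Xa, Xb = X[a_mask], X[b_mask]

    pct_a = (Xa > 0).mean(axis=0)
    pct_b = (Xb > 0).mean(axis=0)
    tested = (pct_a >= params.min_pct) | (pct_b >= params.min_pct)
    if params.min_pct > 0:
        tested &= (pct_a > 0) | (pct_b > 0)

    genes = np.asarray(sub.var_names)[tested]
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(
            Xa[:, tested], Xb[:, tested], axis=0, alternative="two-sided"
        )
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    lfc = np.log2(Xb[:, tested].mean(axis=0) + 1.0) - np.log2(
        Xa[:, tested].mean(axis=0) + 1.0
    )
    p_adj = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "gene": genes,
            "log2fc": lfc,
            "pct_control": pct_a[tested],
            "pct_case": pct_b[tested],
            "p": p,
            "p_adj": p_adj,
        }
    )
    out["significant"] = (np.abs(out["log2fc"]) > params.lfc_threshold) & (
        out["p_adj"] < params.alpha
    )
    return out.sort_values(["p_adj", "gene"], ignore_index=True)
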