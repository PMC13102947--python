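"""Doublet/polyhormonal discrimination by majority vote over three detectors.

A cell classified onto a mixed centroid may be a genuine polyhormonal cell
or a droplet doublet.  Three independent detectors vote: the centroid call
itself (``centroid_mixed``) and two simulated-doublet kNN detectors (or
externally ingested flags).  Cells flagged by two or more detectors are
doublets and leave the analysis; cells flagged only by the centroid call are
retained as suggestive polyhormonal cells under their mixed label; mixed
labels containing a non-endocrine type are kept but marked non-quantifiable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .identity import MarkerPanel

__all__ = [
    "detect_doublets_simulated",
    "read_external_flags",
    "majority_vote",
    "finalize_labels",
]


def detect_doublets_simulated(
    adata,
    expected_rate: float = 0.08,
    n_sim: int | None = None,
    k: int = 20,
    n_pcs: int = 30,
    seed: int = 0,
    scale_total: float = 1e4,
    depth_weight: float = 1.0,
) -> pd.DataFrame:
    """Score cells by proximity to artificial doublets in PCA space.

    ``n_sim`` artificial doublets are synthesized by summing the raw counts
    of uniformly sampled pairs of distinct observed cells.  Observed and
    artificial profiles are log-normalized together and embedded in an
    ``n_pcs`` PCA; a cell's score is the fraction of its ``k`` nearest
    neighbors (excluding itself) that are artificial.  The top
    ``round(expected_rate * n_cells)`` scores are flagged, ties broken by
    cell index.

    With ``depth_weight > 0`` a z-scored log library-size coordinate
    (scaled to the spread of PC1) is appended to the embedding.  Doublets
    carry roughly twice the library of a singlet while a genuinely
    polyhormonal cell does not, so retaining depth keeps intermediate
    expression profiles from being mistaken for doublets; set
    ``depth_weight=0`` for a purely profile-based embedding.

    Returns a frame with ``score`` and ``flagged`` per observed cell.
    """
    from sklearn.decomposition import PCA
    from sklearn.neighbors import NearestNeighbors

    if not 0.0 < expected_rate < 1.0:
        raise ValueError("expected_rate must lie in (0, 1)")
    n = adata.n_obs
    if n < 2 * k:
        raise ValueError(f"need at least 2k={2 * k} cells, got {n}")
    if n_sim is None:
        n_sim = n
    if n_sim < 10 * k:
        warnings.warn(f"n_sim={n_sim} < 10*k={10 * k}; scores will be noisy")

    rng = np.random.default_rng(seed)
    X = adata.X
    X = X.toarray() if sp.issparse(X) else np.asarray(X)
    X = X.astype(float)

    left = rng.integers(0, n, size=n_sim)
    shift = rng.integers(1, n, size=n_sim)
    right = (left + shift) % n          # distinct partner
    sim = X[left] + X[right]

    combined = np.vstack([X, sim])
    totals = combined.sum(axis=1)
    totals[totals == 0] = 1.0
    norm = np.log1p(scale_total * combined / totals[:, None])

    n_pcs = min(n_pcs, min(norm.shape) - 1)
    emb = PCA(n_components=n_pcs, random_state=int(seed) % (2**31)).fit_transform(norm)
    if depth_weight > 0:
        log_depth = np.log(totals)
        z = (log_depth - log_depth.mean()) / max(log_depth.std(), 1e-12)
        emb = np.hstack([emb, (depth_weight * emb[:, 0].std() * z)[:, None]])

    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, ind = nn.kneighbors(emb[:n])
    neigh = ind[:, 1:]                  # drop self (always nearest at dist 0)
    score = (neigh >= n).mean(axis=1)

    n_flag = int(round(expected_rate * n))
    order = np.argsort(-score, kind="stable")   # ties -> smaller cell index
    flagged = np.zeros(n, dtype=bool)
    flagged[order[:n_flag]] = True
    return pd.DataFrame({"score": score, "flagged": flagged}, index=adata.obs_names)


def read_external_flags(path, barcodes) -> pd.DataFrame:
    """Ingest external detector output as TSV (barcode, flagged[, score])."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index("barcode").reindex(barcodes)
    if df["flagged"].isna().any():
        missing = df.index[df["flagged"].isna()][:5].tolist()
        raise ValueError(f"external flags missing barcodes, e.g. {missing}")
    out = pd.DataFrame(index=pd.Index(barcodes))
    out["flagged"] = df["flagged"].astype(bool).to_numpy()
    out["score"] = df["score"].to_numpy(float) if "score" in df else np.nan
    return out


def majority_vote(flags: pd.DataFrame) -> pd.DataFrame:
    """Vote over >=3 aligned detectors; ``centroid_mixed`` must be one.

    Outcomes: ``doublet`` for >=2 votes; ``polyhormonal_candidate`` when the
    single vote is the centroid call; ``singlet`` otherwise (a lone doublet-
    detector vote is recorded but does not override a pure centroid call).
    """
    cols = list(flags.columns)
    if "centroid_mixed" not in cols:
        raise ValueError("flags must include a 'centroid_mixed' column")
    if len(cols) < 3:
        raise ValueError(f"majority vote needs >=3 detectors, got {len(cols)}")
    F = flags.astype(bool)
    votes = F.sum(axis=1)
    outcome = np.where(
        votes >= 2,
        "doublet",
        np.where(
            (votes == 1) & F["centroid_mixed"], "polyhormonal_candidate", "singlet"
        ),
    )
    lone = (votes == 1) & ~F["centroid_mixed"]
    return pd.DataFrame(
        {"votes": votes, "outcome": outcome, "lone_detector_flag": lone},
        index=flags.index,
    )


def finalize_labels(
    vote: pd.DataFrame, calls: pd.DataFrame, panel: MarkerPanel
) -> pd.DataFrame:
    """Merge vote outcomes with centroid calls into final per-cell statuses.

    Statuses partition the cells: ``doublet`` (removed downstream, with a
    removal reason), ``polyhormonal`` (mixed tuple label retained;
    ``quantifiable`` False when any constituent is non-endocrine),
    ``singlet`` (pure centroid label), or ``unclassified``.
    """
    if not vote.index.equals(calls.index):
        raise ValueError("vote and centroid-call tables are misaligned")
    endocrine = set(panel.endocrine_types())

    status = np.empty(len(vote), dtype=object)
    label = calls["best_label"].to_numpy(object).copy()
    quant = np.ones(len(vote), dtype=bool)
    reason = np.full(len(vote), "", dtype=object)

    unclassified = calls["unclassified"].to_numpy(bool)
    outcome = vote["outcome"].to_numpy(object)
    mixed = calls["best_order"].to_numpy() >= 2
    for i in range(len(vote)):
        if unclassified[i]:
            status[i] = "unclassified"
            label[i] = ""
            quant[i] = False
            continue
        if outcome[i] == "doublet":
            status[i] = "doublet"
            quant[i] = False
            reason[i] = (
                "majority_vote_mixed" if mixed[i] else "detector_consensus_pure_profile"
            )
        elif outcome[i] == "polyhormonal_candidate":
            status[i] = "polyhormonal"
            parts = label[i].split("+")
            quant[i] = all(t in endocrine for t in parts)
            if not quant[i]:
                reason[i] = "mixed_with_non_endocrine"
        else:
            status[i] = "singlet"
            quant[i] = True
    return pd.DataFrame(
        {
            "status": status,
            "label": label,
            "quantifiable": quant,
            "removal_reason": reason,
        },
        index=vote.index,
    )
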