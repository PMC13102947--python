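"""End-to-end orchestration: QC -> normalize -> gate -> centroids ->
classify -> consensus -> score -> tables, with a reproducibility manifest.

:func:`run_pipeline` executes the analysis in memory on an AnnData;
:func:`run_all` wraps it with 10x-triplet input, TSV outputs and a manifest
carrying the config echo, seed, package versions and output checksums, so
two runs with the same config and seed can be compared byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consensus import detect_doublets_simulated, finalize_labels, majority_vote
from .identity import (
    MarkerPanel,
    build_centroids,
    build_mixed_centroids,
    classify_by_correlation,
    default_panel,
    gate_cells,
    top_discriminative_genes,
)
from .io import read_10x
from .preprocess import ClusterParams, QCParams, cluster_graph, normalize_log, scale_genes
from .scoring import (
    DEParams,
    ScoreParams,
    compare_module_scores,
    composition_table,
    de_between_conditions,
    module_score,
)

log = logging.getLogger("isletid")

__all__ = ["RunConfig", "run_pipeline", "run_all"]


@dataclass
class RunConfig:
    """Validated pipeline configuration (YAML-loadable)."""

    inputs: dict[str, str]              # condition -> 10x triplet directory
    out_dir: str
    control_condition: str = "ctrl"
    case_condition: str = "ko"
    panel_path: str | None = None
    programs_path: str | None = None
    qc: QCParams = field(default_factory=QCParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    score: ScoreParams = field(default_factory=ScoreParams)
    de: DEParams = field(default_factory=DEParams)
    top_k_genes: int = 10
    mixed_orders: tuple[int, ...] = (2, 3)
    expected_doublet_rate: float = 0.08
    detector_k: int = 20
    detector_n_pcs: int = 30
    score_cell_type: str = "beta"
    run_clustering: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for name, typ in (("qc", QCParams), ("cluster", ClusterParams),
                          ("score", ScoreParams), ("de", DEParams)):
            if name in raw and isinstance(raw[name], dict):
                raw[name] = typ(**raw[name])
        if "mixed_orders" in raw:
            raw["mixed_orders"] = tuple(raw["mixed_orders"])
        cfg = cls(**raw)
        for cond, d in cfg.inputs.items():
            if not os.path.isdir(d):
                raise FileNotFoundError(f"input directory for {cond!r} missing: {d}")
        for p in (cfg.panel_path, cfg.programs_path):
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(p)
        return cfg

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["mixed_orders"] = list(self.mixed_orders)
        return d


def load_programs(path: str) -> dict[str, list[str]]:
    """Programs as YAML mapping or two-column TSV (program, gene)."""
    if path.endswith((".yaml", ".yml")):
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return {str(k): list(v) for k, v in data.items()}
    df = pd.read_csv(path, sep="\t")
    return {
        str(prog): grp["gene"].tolist() for prog, grp in df.groupby("program", sort=True)
    }


def run_pipeline(
    adata: ad.AnnData,
    panel: MarkerPanel | None = None,
    programs: dict[str, list[str]] | None = None,
    qc: QCParams = QCParams(),
    cluster: ClusterParams | None = None,
    score_params: ScoreParams | None = None,
    de_params: DEParams | None = None,
    control: str = "ctrl",
    case: str = "ko",
    top_k_genes: int = 10,
    mixed_orders: tuple[int, ...] = (2, 3),
    expected_doublet_rate: float = 0.08,
    detector_k: int = 20,
    detector_n_pcs: int = 30,
    score_cell_type: str = "beta",
    run_clustering: bool = False,
    seed: int = 0,
) -> dict:
    """Run the full identity analysis in memory; returns a results dict.

    ``adata`` must carry raw counts in X and ``obs["condition"]``.  Stage
    outputs: ``cell_table`` (QC metrics for all input cells), ``gate``,
    ``features``, ``centroids``, ``calls``, ``flags``, ``vote``, ``final``,
    ``composition``, and, when both conditions are present, ``module`` and
    ``de`` tables computed on the singlets of ``score_cell_type``.
    """
    panel = panel or default_panel()
    filtered, cell_table = qc_filter_logged(adata, qc)
    normalize_log(filtered)
    scale_genes(filtered)

    if run_clustering and cluster is not None:
        cell_table.loc[filtered.obs_names, "cluster"] = cluster_graph(filtered, cluster)

    gate = gate_cells(filtered, panel)
    per_type, F = top_discriminative_genes(filtered, gate, panel, k=top_k_genes)
    pure = build_centroids(filtered, gate, F)
    centroids = build_mixed_centroids(pure, orders=mixed_orders)
    calls = classify_by_correlation(filtered, centroids)

    seed_a = (seed * 7919 + 1) % (2**31)
    seed_b = (seed * 7919 + 2) % (2**31)
    det_a = detect_doublets_simulated(
        filtered, expected_doublet_rate, k=detector_k, n_pcs=detector_n_pcs, seed=seed_a
    )
    det_b = detect_doublets_simulated(
        filtered, expected_doublet_rate, k=detector_k, n_pcs=detector_n_pcs, seed=seed_b
    )
    flags = pd.DataFrame(
        {
            "centroid_mixed": (calls["best_order"] >= 2) & ~calls["unclassified"],
            "detector_a": det_a["flagged"],
            "detector_b": det_b["flagged"],
        },
        index=filtered.obs_names,
    )
    vote = majority_vote(flags)
    final = finalize_labels(vote, calls, panel)
    composition = composition_table(final, filtered.obs["condition"])

    results = {
        "adata": filtered,
        "cell_table": cell_table,
        "gate": gate,
        "per_type_genes": per_type,
        "features": F,
        "centroids": centroids,
        "calls": calls,
        "flags": flags,
        "vote": vote,
        "final": final,
        "composition": composition,
    }

    conditions = set(filtered.obs["condition"])
    if programs and control in conditions and case in conditions:
        beta_mask = (
            (final["status"] == "singlet") & (final["label"] == score_cell_type)
        ).to_numpy()
        if beta_mask.sum() >= 6:
            sp_params = score_params or ScoreParams(seed=seed)
            scores = pd.DataFrame(
                {
                    name: module_score(filtered, genes, sp_params)
                    for name, genes in programs.items()
                },
                index=filtered.obs_names,
            ).loc[beta_mask]
            results["module_scores"] = scores
            results["module"] = compare_module_scores(
                scores, filtered.obs.loc[beta_mask, "condition"], control, case
            )
            results["de"] = de_between_conditions(
                filtered, beta_mask, control, case, de_params or DEParams()
            )
    return results


def qc_filter_logged(adata, qc: QCParams):
    from .preprocess import qc_filter

    filtered, table = qc_filter(adata, qc)
    log.info("QC retained %d / %d cells", filtered.n_obs, adata.n_obs)
    return filtered, table


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """File-level pipeline: read triplets, run, write tables and manifest."""
    parts = []
    for cond in sorted(config.inputs):
        a = read_10x(config.inputs[cond])
        a.obs["condition"] = cond
        a.obs_names = [f"{bc}" for bc in a.obs_names]
        parts.append(a)
    adata = ad.concat(parts, join="outer", merge="first") if len(parts) > 1 else parts[0]
    adata.obs_names_make_unique()

    panel = MarkerPanel.from_yaml(config.panel_path) if config.panel_path else default_panel()
    programs = load_programs(config.programs_path) if config.programs_path else None

    results = run_pipeline(
        adata,
        panel=panel,
        programs=programs,
        qc=config.qc,
        cluster=config.cluster,
        score_params=config.score,
        de_params=config.de,
        control=config.control_condition,
        case=config.case_condition,
        top_k_genes=config.top_k_genes,
        mixed_orders=config.mixed_orders,
        expected_doublet_rate=config.expected_doublet_rate,
        detector_k=config.detector_k,
        detector_n_pcs=config.detector_n_pcs,
        score_cell_type=config.score_cell_type,
        run_clustering=config.run_clustering,
        seed=config.seed,
    )

    os.makedirs(config.out_dir, exist_ok=True)
    outputs = {
        "cell_table.tsv": results["cell_table"],
        "gate.tsv": results["gate"],
        "centroids.tsv": results["centroids"].to_frame(),
        "final_status.tsv": results["final"],
        "composition.tsv": results["composition"],
    }
    if "module" in results:
        outputs["module_comparison.tsv"] = results["module"]
        outputs["de.tsv"] = results["de"]
    else:
        outputs["module_comparison.tsv"] = pd.DataFrame()
        outputs["de.tsv"] = pd.DataFrame()

    checksums = {}
    for name, df in outputs.items():
        path = os.path.join(config.out_dir, name)
        index = name not in ("composition.tsv", "module_comparison.tsv", "de.tsv")
        df.to_csv(path, sep="\t", index=index)
        checksums[name] = _sha256(path)

    import anndata, scanpy, scipy, sklearn  # noqa: F401  (versions for manifest)

    manifest = {
        "config": config.echo(),
        "seed": config.seed,
        "package_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "anndata": anndata.__version__,
            "scanpy": scanpy.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "checksums": checksums,
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
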