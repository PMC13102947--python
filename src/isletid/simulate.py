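"""Synthetic two-condition droplet scRNA-seq generator for islet data.

Emulates the statistical structure the identity classifier assumes: nine
islet cell types each dominated by one canonical marker, negative-binomial
UMI counts with lognormal library sizes, ambient contamination drawn from
the abundance-weighted tissue average, doublets formed by summing the counts
of two cells sharing a droplet, and polyhormonal cells whose expected
profile lies between two endocrine types.  Every dataset ships with a
ground-truth table so downstream recovery can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .identity import MarkerPanel, default_panel

__all__ = [
    "ProgramEffect",
    "ConditionEffect",
    "SimulationConfig",
    "default_config",
    "simulate_dataset",
]


@dataclass
class ProgramEffect:
    """Scale expression of one gene program in cells of one type."""

    program: str
    cell_type: str
    scale: float


@dataclass
class ConditionEffect:
    """Per-condition composition multipliers and program perturbations."""

    composition: dict[str, float] = field(default_factory=dict)
    program_effects: list[ProgramEffect] = field(default_factory=list)


@dataclass
class SimulationConfig:
    """Full parameterization of a two-condition islet simulation.

    ``mu`` holds per-type expected expression fractions (rows sum to 1 over
    the gene panel, mitochondrial genes at their nominal share);
    ``dispersion`` is the per-gene NB size (inverse dispersion).  The
    mitochondrial share is redrawn per cell from ``Beta(mito_beta)`` with a
    heavy-tail mixture component (``mito_tail_prob`` / ``mito_tail_beta``)
    to create realistic QC failures.
    """

    panel: MarkerPanel
    n_cells_per_type: dict[str, int]
    mu: pd.DataFrame                      # types x genes, rows sum to 1
    dispersion: pd.Series                 # per-gene NB size
    condition_effects: dict[str, ConditionEffect]
    programs: dict[str, list[str]] = field(default_factory=dict)
    libsize_logmean: float = float(np.log(5000.0))
    libsize_logsd: float = 0.35
    doublet_rate: float = 0.08
    polyhormonal_rate: float = 0.02
    polyhormonal_weight: float = 0.5
    ambient_fraction: float = 0.02
    mito_beta: tuple[float, float] = (2.0, 38.0)
    mito_tail_prob: float = 0.0
    mito_tail_beta: tuple[float, float] = (2.0, 8.0)
    seed: int = 0

    @property
    def types(self) -> list[str]:
        return list(self.mu.index)

    @property
    def genes(self) -> list[str]:
        return list(self.mu.columns)

    @property
    def mito_genes(self) -> list[str]:
        return [g for g in self.genes if g.startswith("mt-")]

    def validate(self) -> None:
        for name, val in [
            ("doublet_rate", self.doublet_rate),
            ("polyhormonal_rate", self.polyhormonal_rate),
            ("ambient_fraction", self.ambient_fraction),
            ("mito_tail_prob", self.mito_tail_prob),
        ]:
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} outside [0, 1]")
        if not 0.0 < self.polyhormonal_weight < 1.0:
            raise ValueError("polyhormonal_weight must lie strictly in (0, 1)")
        if self.doublet_rate + self.polyhormonal_rate >= 1.0:
            raise ValueError("doublet_rate + polyhormonal_rate must be < 1")
        if not self.n_cells_per_type:
            raise ValueError("n_cells_per_type is empty")
        for t, n in self.n_cells_per_type.items():
            if n <= 0 or int(n) != n:
                raise ValueError(f"cell count for {t!r} must be a positive integer")
        row_sums = self.mu.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-8):
            raise ValueError("expression fractions must sum to 1 per type")
        if (self.mu.to_numpy() < 0).any():
            raise ValueError("expression fractions must be nonnegative")
        if set(self.n_cells_per_type) != set(self.mu.index):
            raise ValueError("n_cells_per_type keys must match mu rows")
        if (self.dispersion <= 0).any():
            raise ValueError("NB size parameters must be positive")
        if not self.condition_effects:
            raise ValueError("at least one condition is required")
        for prog, genes in self.programs.items():
            unknown = set(genes) - set(self.genes)
            if unknown:
                raise ValueError(f"program {prog!r} references unknown genes {unknown}")


# ---------------------------------------------------------------------------
# default configuration


_MARKER_MU_ENDOCRINE = 0.015
_MARKER_MU_OTHER = 0.004
_SIG_MU = 0.008
_N_SIG = 12
_N_HK = 72
_N_MITO = 12
_MITO_NOMINAL = 0.05

# control-condition composition of an islet cell suspension (fractions of
# singlets); beta-dominant with small non-endocrine populations
_BASE_COMPOSITION = {
    "beta": 525,
    "alpha": 300,
    "delta": 150,
    "pp": 120,
    "ductal": 105,
    "mesenchymal": 90,
    "endothelial": 75,
    "immune": 75,
    "t_cell": 60,
}

# knockout condition: beta depletion with compensatory enrichment of the
# other endocrine types, mirroring the phenotype the pipeline quantifies
_KO_COMPOSITION_MULT = {
    "beta": 0.45,
    "alpha": 1.35,
    "delta": 1.3,
    "pp": 1.35,
}


def _signature_genes(cell_type: str) -> list[str]:
    return [f"Sig-{cell_type}-{i + 1:02d}" for i in range(_N_SIG)]


def default_config(scale: str = "small") -> SimulationConfig:
    """Nine-type two-condition config; ``small`` is ~3000 cells in total,
    ``paper_like`` targets 10000 cells per condition."""
    if scale == "small":
        factor = 1.0
    elif scale == "paper_like":
        factor = 10000.0 / sum(_BASE_COMPOSITION.values())
    else:
        raise ValueError(f"unknown scale {scale!r}; use 'small' or 'paper_like'")

    panel = default_panel()
    types = sorted(set(panel.types()))
    markers = panel.genes
    sig = {t: _signature_genes(t) for t in types}
    hk = [f"Hk{i + 1:03d}" for i in range(_N_HK)]
    mito = [f"mt-g{i + 1:02d}" for i in range(_N_MITO)]
    genes = markers + [g for t in types for g in sig[t]] + hk + mito

    hk_w = 1.0 / (np.arange(_N_HK) + 5.0)
    hk_w /= hk_w.sum()
    mito_w = 0.8 ** np.arange(_N_MITO)
    mito_w /= mito_w.sum()

    mu = pd.DataFrame(0.0, index=types, columns=genes)
    for t in types:
        marker = panel.marker_of(t)
        m_mu = _MARKER_MU_ENDOCRINE if panel.is_endocrine(t) else _MARKER_MU_OTHER
        mu.loc[t, marker] = m_mu
        mu.loc[t, sig[t]] = _SIG_MU
        rest = 1.0 - _MITO_NOMINAL - m_mu - _SIG_MU * _N_SIG
        mu.loc[t, hk] = rest * hk_w
        mu.loc[t, mito] = _MITO_NOMINAL * mito_w

    dispersion = pd.Series(10.0, index=genes)
    n_cells = {t: int(round(n * factor)) for t, n in _BASE_COMPOSITION.items()}
    programs = {
        "maturity": sig["beta"][:8],
        "housekeeping_null": hk[:8],
    }
    effects = {
        "ctrl": ConditionEffect(),
        "ko": ConditionEffect(
            composition=dict(_KO_COMPOSITION_MULT),
            program_effects=[ProgramEffect("maturity", "beta", 0.5)],
        ),
    }
    cfg = SimulationConfig(
        panel=panel,
        n_cells_per_type=n_cells,
        mu=mu,
        dispersion=dispersion,
        condition_effects=effects,
        programs=programs,
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# simulation


def _adjusted_profiles(cfg: SimulationConfig, condition: str) -> pd.DataFrame:
    """Per-type expression fractions with this condition's program effects
    applied and rows renormalized."""
    mu = cfg.mu.copy()
    for eff in cfg.condition_effects[condition].program_effects:
        genes = cfg.programs[eff.program]
        mu.loc[eff.cell_type, genes] *= eff.scale
    return mu.div(mu.sum(axis=1), axis=0)


def _condition_weights(cfg: SimulationConfig, condition: str) -> tuple[np.ndarray, int]:
    mult = cfg.condition_effects[condition].composition
    counts = np.array(
        [round(cfg.n_cells_per_type[t] * mult.get(t, 1.0)) for t in cfg.types],
        dtype=int,
    )
    return counts / counts.sum(), int(counts.sum())


def _sample_distinct_pair(rng, p: np.ndarray) -> tuple[int, int]:
    a = rng.choice(len(p), p=p)
    q = p.copy()
    q[a] = 0.0
    q /= q.sum()
    b = rng.choice(len(p), p=q)
    return a, b


def _mito_shares(rng, cfg: SimulationConfig, n: int) -> np.ndarray:
    f = rng.beta(*cfg.mito_beta, size=n)
    if cfg.mito_tail_prob > 0:
        tail = rng.random(n) < cfg.mito_tail_prob
        f[tail] = rng.beta(*cfg.mito_tail_beta, size=int(tail.sum()))
    return f


def simulate_dataset(cfg: SimulationConfig) -> tuple[ad.AnnData, pd.DataFrame]:
    """Simulate counts and ground truth for every configured condition.

    Per condition, each droplet is a doublet with probability
    ``doublet_rate`` (two distinct types drawn from the composition, two
    full singlet count vectors summed), a polyhormonal cell with probability
    ``polyhormonal_rate`` (a singlet whose mean profile is
    ``w*mu[A] + (1-w)*mu[B]`` for two distinct endocrine types), and
    otherwise a singlet.  Singlet counts are NB-distributed around
    ``lib * ((1-lambda)*profile + lambda*ambient)`` where the ambient
    profile is the composition-weighted mean of the type profiles.  All
    draws come from a single generator seeded by ``cfg.seed``, so equal
    seeds give bit-identical output.

    Returns the cells-by-genes count matrix as :class:`anndata.AnnData`
    (sparse integer X, ``obs["condition"]``) and the ground-truth table
    indexed by barcode.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = cfg.genes
    mito_mask = np.array([g.startswith("mt-") for g in genes])
    size = cfg.dispersion.to_numpy()
    types = cfg.types
    endo = [t for t in types if cfg.panel.is_endocrine(t)]
    endo_idx = np.array([types.index(t) for t in endo])
    lam = cfg.ambient_fraction
    w = cfg.polyhormonal_weight

    blocks, truth_rows, barcodes = [], [], []
    for condition in cfg.condition_effects:
        p_type, n_cells = _condition_weights(cfg, condition)
        if n_cells == 0:
            raise ValueError(f"condition {condition!r} has zero cells")
        prof = _adjusted_profiles(cfg, condition).to_numpy()
        # split each type profile into a normalized non-mito part A and the
        # mito weights; a cell's profile is ((1-f)*A, f*w_mito)
        A = prof * ~mito_mask
        A /= A.sum(axis=1, keepdims=True)
        w_mito = prof[:, mito_mask].sum(axis=0)
        w_mito /= w_mito.sum()
        ambient = p_type @ prof

        p_cat = [1.0 - cfg.doublet_rate - cfg.polyhormonal_rate,
                 cfg.doublet_rate, cfg.polyhormonal_rate]
        category = rng.choice(3, size=n_cells, p=p_cat)
        p_endo = np.zeros(len(types))
        p_endo[endo_idx] = p_type[endo_idx]
        p_endo /= p_endo.sum()

        # one simulated "component" per physical cell; doublets have two
        comp_type_profiles, comp_cell = [], []
        for i, cat in enumerate(category):
            if cat == 0:
                t = rng.choice(len(types), p=p_type)
                comp_type_profiles.append(A[t])
                comp_cell.append(i)
                truth_rows.append((condition, "singlet", types[t], "", np.nan))
            elif cat == 1:
                a, b = _sample_distinct_pair(rng, p_type)
                comp_type_profiles.append(A[a])
                comp_type_profiles.append(A[b])
                comp_cell.extend([i, i])
                pair = "+".join(sorted((types[a], types[b])))
                truth_rows.append((condition, "doublet", pair, pair, np.nan))
            else:
                a, b = _sample_distinct_pair(rng, p_endo)
                mix = w * A[a] + (1.0 - w) * A[b]
                comp_type_profiles.append(mix)
                comp_cell.append(i)
                pair = "+".join(sorted((types[a], types[b])))
                truth_rows.append((condition, "polyhormonal", pair, "", w))

        n_comp = len(comp_cell)
        libs = rng.lognormal(cfg.libsize_logmean, cfg.libsize_logsd, size=n_comp)
        f = _mito_shares(rng, cfg, n_comp)

        P = np.asarray(comp_type_profiles) * (1.0 - f)[:, None]
        P[:, mito_mask] = f[:, None] * w_mito[None, :]
        P = (1.0 - lam) * P + lam * ambient[None, :]
        mean = libs[:, None] * P
        counts = rng.negative_binomial(size[None, :], size[None, :] / (size[None, :] + mean))

        cell_counts = np.zeros((n_cells, len(genes)), dtype=np.int64)
        np.add.at(cell_counts, np.asarray(comp_cell), counts)
        blocks.append(sp.csr_matrix(cell_counts))
        barcodes.extend(f"{condition}_{i + 1:05d}" for i in range(n_cells))

    X = sp.vstack(blocks).astype(np.int32)
    truth = pd.DataFrame(
        truth_rows,
        columns=["condition", "category", "true_type", "doublet_constituents",
                 "polyhormonal_weight"],
        index=pd.Index(barcodes, name="barcode"),
    )
    truth["is_doublet"] = truth["category"] == "doublet"
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame({"condition": truth["condition"].to_numpy()},
                         index=truth.index.copy()),
        var=pd.DataFrame({"gene_id": [f"SYN{i + 1:05d}" for i in range(len(genes))]},
                         index=pd.Index(genes, name="gene_symbol")),
    )
    return adata, truth
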