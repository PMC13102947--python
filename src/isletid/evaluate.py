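"""Recovery metrics against simulator ground truth.

Only meaningful for synthetic datasets, where the per-cell truth channel
records the real type, doublet constituents and polyhormonal mixtures.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["recovery_metrics"]


def recovery_metrics(final: pd.DataFrame, truth: pd.DataFrame) -> dict[str, float]:
    """Singlet accuracy, doublet precision/recall, polyhormonal recall.

    ``final`` and ``truth`` are joined on barcode; cells dropped by QC are
    excluded from every denominator (the classifier never saw them).
    """
    t = truth.loc[truth.index.intersection(final.index)]
    f = final.loc[t.index]

    singlets = t["category"] == "singlet"
    called_singlet = f["status"] == "singlet"
    n_singlet = int(singlets.sum())
    correct = (
        (f.loc[singlets, "status"] == "singlet")
        & (f.loc[singlets, "label"] == t.loc[singlets, "true_type"])
    ).sum()
    singlet_accuracy = correct / n_singlet if n_singlet else float("nan")

    is_doublet = t["category"] == "doublet"
    called_doublet = f["status"] == "doublet"
    tp = int((is_doublet & called_doublet).sum())
    doublet_precision = tp / int(called_doublet.sum()) if called_doublet.any() else float("nan")
    doublet_recall = tp / int(is_doublet.sum()) if is_doublet.any() else float("nan")

    is_poly = t["category"] == "polyhormonal"
    poly_tp = int((is_poly & (f["status"] == "polyhormonal")).sum())
    polyhormonal_recall = poly_tp / int(is_poly.sum()) if is_poly.any() else float("nan")

    return {
        "n_cells": int(len(f)),
        "n_singlets_true": n_singlet,
        "singlet_accuracy": float(singlet_accuracy),
        "doublet_precision": float(doublet_precision),
        "doublet_recall": float(doublet_recall),
        "polyhormonal_recall": float(polyhormonal_recall),
        "n_called_singlet": int(called_singlet.sum()),
        "n_called_doublet": int(called_doublet.sum()),
    }
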