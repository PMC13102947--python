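# isletid

Cell-identity analysis for pancreatic islet single-cell RNA-seq, built
around the question of distinguishing genuinely **polyhormonal cells**
(single cells expressing two or more islet hormones, e.g. *Ins1*/*Gcg*⁺)
from **droplet doublets** (two cells sharing one droplet, whose summed
transcriptome mimics a polyhormonal profile). The distinction matters
because polyhormonal cells are a readout of β-cell de-/transdifferentiation
in diabetes models, while doublets are a technical artifact.

The package is aimed at computational biologists analyzing two-condition
(e.g. knockout vs. control) droplet scRNA-seq of islets, and at method
developers who want a fully ground-truthed sandbox: a synthetic islet
generator produces datasets with known cell types, doublets, polyhormonal
mixtures, ambient contamination and condition effects, so every stage of
the analysis can be verified against truth at desk scale.

## The method

1. **QC** — keep cells with `min_features < detected features <
   max_features` (strict bounds; tissue-scale defaults 2500/6000) and
   mitochondrial read fraction strictly below 10%.
2. **Marker gating** — canonical markers are thresholded on log-normalized
   expression (*Gcg* > 2.1 → α, *Ins1* > 2.0 → β, *Sst* > 2 → δ,
   *Ppy* > 2.2 → PP, *Cd86* > 1 → immune, *Trac* > 0.1 → T cell,
   *Cd34* > 0.1 → endothelial, *Vim* > 0.6 → mesenchymal, *Krt19* > 0.5 →
   ductal). Cells exceeding exactly one threshold are **pure profile
   cells**.
3. **Centroids** — a one-vs-rest rank-sum test over pure cells picks the
   top-10 genes per type; their union with the marker panel is the feature
   set F. Each type's centroid is the mean *scaled* expression of its pure
   cells over F. Artificial **mixed centroids** are added for every pair
   and triple of types (mean of the constituent pure centroids), encoding
   the assumption that a truly polyhormonal cell shows an in-between
   profile: with 9 types, 9 + C(9,2) + C(9,3) = 129 centroids.
4. **Classification** — every cell's scaled profile over F is Pearson-
   correlated with all 129 centroids; the cell takes the label of the
   highest correlation.
5. **Consensus** — three detectors vote: the centroid call (mixed label =
   flag) and two simulated-doublet kNN detectors (artificial doublets from
   summed cell pairs, score = fraction of artificial neighbors). Cells
   flagged by ≥ 2 detectors are doublets and are removed; cells flagged
   only by the centroid call are retained as suggestive polyhormonal cells;
   mixed labels involving non-endocrine types are excluded from
   quantification.
6. **Inference** — gene-program module scores (program mean minus
   expression-matched control-gene mean) are compared between conditions
   with two-sided Wilcoxon rank-sum tests, Holm adjustment across programs,
   and the Hodges–Lehmann shift (median over all cross-group differences,
   case − control) as effect size. Per-gene DE within a cell type uses the
   same rank test with Benjamini–Hochberg adjustment, gated at
   |log2FC| > 0.5, adjusted p < 0.05, min.pct = 0.01. A small histology
   helper computes cell mass = (cell area / total tissue area) × pancreatic
   weight and the α/β mass ratio.

## Worked example

```python
import isletid as ii
from isletid.preprocess import QCParams

cfg = ii.default_config("small")      # ~3000 cells, ctrl + ko conditions
cfg.seed = 1
adata, truth = ii.simulate_dataset(cfg)

res = ii.run_pipeline(
    adata, panel=cfg.panel, programs=cfg.programs,
    qc=QCParams(min_features=20, max_features=1000, max_mito_fraction=0.10),
    seed=1,
)
print(res["final"]["status"].value_counts().to_dict())
print(ii.recovery_metrics(res["final"], truth))
```

prints

```
{'singlet': 2386, 'doublet': 240, 'polyhormonal': 41}
{'n_cells': 2667, 'n_singlets_true': 2386, 'singlet_accuracy': 0.9908...,
 'doublet_precision': 0.8458..., 'doublet_recall': 0.8384...,
 'polyhormonal_recall': 0.75, ...}
```

i.e. of 2667 QC-passing cells the pipeline keeps 2386 singlets (99.1% of
true singlets correctly typed), removes 240 doublets (84.6% of them real,
catching 83.8% of all real doublets), and retains 41 suggestive
polyhormonal cells (75% of the planted ones). The composition table shows
the planted knockout β-cell depletion (β proportion 0.34 ctrl → 0.16 ko),
and the module-score comparison reports a strongly negative maturity-
program shift in knockout β-cells.

The same stages are available from the shell:

```sh
isletid simulate --scale small --seed 1 --out simdata
isletid qc --in simdata/ctrl --out qc.tsv --min-features 20 --max-features 1000
isletid classify --in simdata/ctrl --out calls.tsv --min-features 20 --max-features 1000
isletid run-all --config run.yaml --seed 1
```

## Layout

- `src/isletid/simulate.py` — synthetic islet generator + ground truth
- `src/isletid/preprocess.py` — QC, log-normalization, scaling, SNN/Leiden clustering
- `src/isletid/identity.py` — marker panel, gating, centroids, correlation classifier
- `src/isletid/consensus.py` — simulated-doublet kNN detector, majority vote, final labels
- `src/isletid/scoring.py` — module scores, rank-sum/Holm/Hodges–Lehmann, composition, DE, mass ratio
- `src/isletid/io.py`, `pipeline.py`, `cli.py` — 10x triplet I/O, orchestration, CLI
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
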