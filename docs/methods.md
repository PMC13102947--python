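# Methods notes

## The identity model

The classifier assumes each islet cell type is dominated by one canonical
marker and that cells carrying two transcriptomes — whether physically (a
doublet) or biologically (a polyhormonal cell) — show an expression profile
intermediate between the parent types. Identity is therefore represented
by centroids: the mean scaled expression of gated pure-profile cells over a
discriminative feature set F, plus artificial mixed centroids for every
pair and triple of types, formed as the unweighted mean of the constituent
pure centroids in scaled space. Averaging in scaled (z-score) space is the
operative choice: it makes a 50/50 mixture of two types sit exactly halfway
between their centroids regardless of absolute expression levels, matching
the in-between-profile premise. Per-combination weights can be supplied
when a mixture is expected to be asymmetric.

Classification is the Pearson correlation of each cell's scaled F-profile
against every centroid, taking the argmax. Pearson is used because the
profiles are centered-scale data where linear association is the natural
similarity; correlation is invariant to affine transforms of the cell
profile, so per-cell scaling artifacts do not change calls. Ties are broken
toward the smallest label order (pure before pair before triple) and then
lexicographically, so a cell equally close to a pure and a mixed centroid
keeps the more parsimonious label. Cells whose F-profile is constant have
no defined correlation and are returned unclassified.

The feature set F is the union of the marker panel and the top-10
one-vs-rest genes per type, computed among pure cells only with a two-sided
Wilcoxon rank-sum test, ranked by p-value then |log2 fold change|
(pseudocount 1 on mean normalized expression), ties by gene symbol — a
fully deterministic ordering. Restricting the test to gated pure cells
keeps ambiguous cells out of the reference profiles.

## Doublet vs. polyhormonal consensus

Three detectors vote per cell: the centroid call (a mixed best label is a
flag) and two runs of a simulated-doublet kNN detector. The detector sums
the raw counts of sampled cell pairs to create artificial doublets,
co-embeds observed and artificial profiles, and scores each cell by the
fraction of artificial profiles among its k nearest neighbors; the top
`expected_rate` quantile is flagged (rate default 8%, the typical 10x
loading at ~10k cells), with ties broken by cell index so the flag set is
deterministic.

The embedding is an `n_pcs` PCA of jointly log-normalized profiles plus one
z-scored log library-size coordinate (scaled to the spread of PC1;
`depth_weight` parameter, 0 disables it). The depth coordinate exists
because expression profile alone cannot separate an artificial doublet of
types A+B from a genuine polyhormonal A/B cell — both lie on the A–B
mixture line — whereas a physical doublet carries roughly two cells' worth
of UMIs and a polyhormonal cell does not. Without it the two detector runs
flag the majority of genuinely polyhormonal cells and the consensus calls
them doublets; with it, polyhormonal recall on synthetic data roughly
doubles while doublet recall is unchanged. Since library size is the one
covariate total-count normalization deliberately removes, it is reintroduced
only inside the detector, never in the classifier.

The vote follows a strict ≥2-of-3 rule: two or more flags → doublet
(removed); only the centroid flag → suggestive polyhormonal cell, which
keeps its mixed label; a lone doublet-detector flag does not override a
pure centroid call (the flag is recorded). Mixed labels containing a
non-endocrine type are kept in the per-cell table but marked
non-quantifiable and excluded from composition tables, as non-endocrine
"mixtures" have no polyhormonal interpretation. External detector output
(e.g. from other doublet callers) can be ingested as TSV flags in place of
either built-in run.

## Statistics

- Rank-sum p-values are exact (full enumeration) when the pooled sample is
  tie-free and n·m ≤ 10 000, otherwise the tie-corrected normal
  approximation without continuity correction; the method used is recorded
  in every output row.
- Holm's step-down adjustment is used across gene programs; Benjamini–
  Hochberg across genes in DE. Two different corrections because the
  program comparisons are few and call for family-wise control, while DE
  over hundreds of genes is an FDR problem.
- Effect sizes are Hodges–Lehmann shifts: the median over all cross-group
  pairwise differences (case − control), the location estimator naturally
  paired with the rank-sum test.
- Module scores follow the binned-control scheme: genes are ranked into 25
  equal-size average-expression bins and each program gene is matched with
  up to 100 control genes from its bin (program genes excluded). Bin and
  control counts are conventional defaults and configurable. Control draws
  are keyed by (seed, gene symbol), making scores invariant to gene order;
  control pools at most as large as `n_ctrl` are used exhaustively, and a
  bin consisting entirely of program genes serves as its own control —
  consequently a program spanning the whole gene universe scores exactly
  zero. On a ~200-gene panel the 25 bins are wide, so null program scores
  scatter around zero with a spread of ~0.1; the scorer is unbiased (the
  null score distribution is centered at zero) but per-program noise only
  shrinks with transcriptome-scale panels.

## The synthetic generator

The generator emulates a two-condition islet dissociation experiment:

- **Types and composition.** Nine types (α, β, δ, PP, immune, T cell,
  endothelial, mesenchymal, ductal), β-dominant control composition; the
  knockout condition multiplies type counts (default: β × 0.45 with
  compensatory endocrine enrichment), emulating β-cell loss.
- **Counts.** Negative binomial per gene (size 10) around
  `lib · ((1−λ)·profile + λ·ambient)`; library sizes lognormal
  (median ≈ 5000 UMIs, σ = 0.35); ambient profile λ = 0.02 of the
  composition-weighted tissue average, emulating cell-free RNA without
  modeling its removal.
- **Expression fractions.** Each type expresses its own marker (1.5% of
  non-mito counts for endocrine markers, 0.4% for non-endocrine) and 12
  private signature genes (0.8% each) over a shared housekeeping
  background; other types' markers are zero so that marker leakage comes
  only from ambient contamination. Marker fractions were chosen so that
  the gate thresholds stay separating under ambient noise: the ambient
  share of a marker scales with its source type's abundance, and at
  λ = 0.02 the expected stray marker counts stay below every gate
  threshold.
- **Mitochondrial fraction.** Redrawn per cell from Beta(2, 38) (mean 5%),
  with an optional heavy-tail mixture component Beta(2, 8) to create
  realistic QC failures.
- **Doublets** (default 8%) sum two full singlet count vectors of two
  distinct types drawn from the composition — the physical
  two-cells-one-droplet event. Homotypic doublets are excluded: at a given
  depth they are transcriptionally indistinguishable from singlets and are
  not the event the discriminator targets.
- **Polyhormonal cells** (default 2%) are singlets whose mean profile is
  `w·μ_A + (1−w)·μ_B` for two distinct endocrine types (default w = 0.5).
  The mixing happens in mean space before sampling, per the in-between
  profile assumption; the true mixing proportion of real polyhormonal
  cells is unknown, so w is a free parameter, not a claim about data.
- **Condition program effects.** Gene programs (e.g. a "maturity" set of
  β-signature genes) can be scaled per condition and cell type (default:
  × 0.5 in knockout β-cells), giving module scoring and DE a planted,
  recoverable signal.
- All draws flow from a single seeded generator in a fixed order
  (per condition: droplet categories, type assignments, library sizes,
  mitochondrial shares, counts), so equal seeds give bit-identical output.

What the generator does **not** emulate: empty droplets, UMI collisions,
read-level noise, batch effects beyond the condition label, within-type
continuous heterogeneity, and realistic transcriptome-wide gene counts
(~200 genes instead of ~20 000). Passing recovery tests therefore shows the
pipeline's logic is sound under its own assumptions, not that real-data
accuracy will match; in particular gating on a 200-gene panel requires
proportionally smaller QC feature bounds (the tissue-scale defaults
2500/6000 are kept as package defaults).

## Normalization stand-in

Normalization is log1p of counts-per-10k and scaling is per-gene z-scoring
(sample sd, ddof = 1) clipped at ±10; clipping bounds the leverage any
outlier cell has on a centroid. This is a deliberate, documented stand-in
for regularized NB variance stabilization: it preserves the two surfaces
the classifier needs (a normalized layer for gating, a scaled layer for
centroids) with simpler, dependency-free semantics. Variance-stabilization
differences mainly affect very-high-expression genes, which in this
pipeline are exactly the gated markers — thresholds are configurable per
panel for that reason.

## Problem sizes and determinism

The default "small" simulation is ~3000 cells / ~200 genes across two
conditions, chosen so that a complete end-to-end run (simulation through DE)
takes well under a minute; "paper_like" scales the same composition to
10 000 cells per condition. Clustering (30 PCs, SNN graph, Leiden at
resolution 2) is deterministic given the seed; community-label identity is
arbitrary, so partitions should be compared with adjusted Rand index rather
than label equality. `run_all` writes a manifest with the config echo,
seed, package versions and SHA-256 checksums of every output table;
identical config + seed reproduces identical checksums.

## Known limitations

- Separation of polyhormonal cells from doublets is imperfect by nature;
  a doublet whose two libraries happen to be small can evade the depth
  coordinate, and a polyhormonal cell with an atypical library size can be
  lost. Recovery thresholds on synthetic data are engineering targets, not
  biological claims.
- Polyhormonal cells with genuinely unique (not intermediate) expression
  are invisible to the mixed-centroid construction.
- The per-gene DE uses a rank test on individual cells between conditions;
  with pooled samples and no biological replicates this measures
  cell-level, not animal-level, variation.
- Ambient contamination is injected but not removed; the classifier is
  tested for robustness to it rather than corrected for it.
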