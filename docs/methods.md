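# Methods

## Pathway scores

The unit of analysis is the *pathway score*: for a curated gene set P and a
cell (or bulk sample) c, `score_P(c)` is the arithmetic mean of **raw**
counts over the members of P present in the expression panel. Three design
points matter:

* **Raw counts, not normalized values.** The score is a direct abundance
  readout; a normalized-layer variant exists behind the `layer` argument of
  `score_gene_set` for sensitivity analysis only.
* **Absent panel genes are dropped from the denominator.** Datasets differ
  in panel coverage; treating absence as zero would conflate coverage with
  activity. The genes actually used are recorded in every `PathwayScores`.
* **Zero-score exclusion.** Under heavy dropout a cell can miss every panel
  gene, scoring exactly 0. Such cells are flagged `excluded` and removed
  from every comparison vector and trajectory curve. `score == 0` and
  `excluded` are equivalent by construction.

Scores are computed as an integer column sum followed by one division, so
they agree exactly with loop-computed means on integer count data.

The curated panels assign 4 genes to NHEJ (XRCC5, XRCC6, TP53BP1, WRN),
5 to MMEJ (PARP1, RBBP8, MRE11, NBN, RAD50) and 8 to HDR (BRCA1, BRCA2,
RAD51, PALB2, RPA1, RPA2, EXO1, BLM). RPA1/RPA2 stay inside HDR with role
"SSA" exactly as curated, even though RPA binding also antagonizes MMEJ:
membership, not mechanism, defines the score. Mouse symbols are produced by
a title-case default rule with exactly two true divergences overridden
(Trp53bp1, Mre11a); protein aliases (Ku70/Ku80/CtIP) are stored as metadata
and never used for matrix lookup. Macaque and ground-squirrel tables are
assumed to use human-style upper-case symbols; no ortholog inference is
attempted. The shipped cell-cycle (G2M/S) and retinal-marker sets are
commonly used stand-ins and are user-replaceable through GMT or JSON input.

## Group comparisons

`compare_scores` gates a two-group test on Shapiro–Wilk normality per group
(alpha 0.05): if both pass, a t-test (Welch when unpaired, paired
otherwise); if not, the rank-based fallback (Mann–Whitney rank-sum, or
Wilcoxon signed-rank when paired). The branch taken and the gate p-values
are part of the report — count-derived score vectors usually fail the gate,
so the rank fallback is the common path. Pairing is the caller's decision;
the drivers default to unpaired.

The Wilcoxon signed-rank statistic drops zero differences, ranks |d| with
average ranks, and for n ≤ 12 remaining pairs computes the two-sided
p-value `P(|W − μ| ≥ |W_obs − μ|)`, μ = n(n+1)/4, by full enumeration of
all 2ⁿ sign assignments (exact even with tied magnitudes); above n = 12 it
falls back to the tie-corrected normal approximation.

## Single-cell chain

QC boundaries follow a literal reading of the source thresholds: "more
than"/"fewer than" are strict, "between a and b" is inclusive. Two presets
are shipped: `e15_mouse` (UMIs > 2000, 400–3500 genes) and `organoid`
(500–7000 genes, UMIs < 20,000, mitochondrial fraction < 0.001). The
organoid mitochondrial cut is unusually strict for the field (common
practice is 5–20%) and is implemented as printed but kept an ordinary
parameter. Normalization scales each cell to 10,000 counts then applies
natural log1p into a separate layer; raw counts are never mutated.

HVG selection ranks genes per batch by dispersion (variance/mean of the log
layer) standardized within ~20 equal-count mean bins using median/MAD — the
robust scale stops a bin's few genuinely variable genes from inflating
their own reference — and returns either the intersection of per-batch top
lists or the genes with the best worst-case rank when a target count is
requested. The neighbor graph links each cell to its k = 15 Euclidean
nearest neighbors in PCA space, symmetrized by union, with similarity
weights 1/(1+d); community detection is Leiden (or Louvain-style
multilevel) on modularity with resolution 1.0, seeded. Batch correction
(MNN) and batch-balanced neighborhoods are intentionally out of scope: the
graph is built on pooled coordinates, and batch structure is only exercised
on batch-free or mild-batch synthetic scenes.

Marker ranking is a vectorized Welch t-test of each cluster against the
rest on the log layer, keeping the top 100 upregulated genes. Cluster
annotation maximizes the overlap coefficient |M ∩ R| / min(|M|, |R|)
against reference marker sets, breaking ties by raw intersection then
lexical order; all-zero overlap yields "unassigned".

## Diffusion pseudotime

Pseudotime uses a diffusion-map distance: a kNN kernel with locally
adaptive Gaussian bandwidth (σ_i = distance to the ⌈k/2⌉-th neighbor),
density normalization (dividing by the outer product of kernel row sums),
conversion to a Markov transition operator via the symmetric conjugate, and
a dense eigendecomposition. The top n = 10 nontrivial eigenpairs (λ_i, ψ_i)
give coordinates ψ_i·λ_i/(1−λ_i), and a cell's pseudotime is its Euclidean
distance from the root in that space — zero at the root, finite exactly on
the root's connected component (disconnected cells get ∞ and leave the
curves). The root is the cell with the maximal G2/M score inside the
progenitor cluster (ties broken by barcode order): the most actively
cycling progenitor anchors the start of differentiation, standing in for
directionality that would otherwise come from RNA velocity, which is not
implemented here. Dense eigendecomposition is exact and comfortable at the
few-thousand-cell scale this package targets.

Trajectory curves use equal-count (quantile) bins — default 20 — so late,
sparse stretches of pseudotime keep stable confidence widths; each bin
reports mean and normal-approximation 95% CI (1.96·sd/√n). Polynomial fits
(default cubic) are ordinary least squares on (bin midpoint, bin mean).

## Bulk analyses

Bulk expression is log2(x+1)-transformed (the single-cell layer uses
natural log1p; both are fixed per module). Quantile normalization is
applied within a species: each sample's rank-r value becomes the mean of
rank-r values across the group, ties receiving the mean of their tied
targets. Note that tie-averaged quantile normalization is a fixed point
only on tie-free data; with ties, a second application can shift values
because tie averaging moves a column off the shared reference
distribution.

Pathway contrasts pair at the replicate level: pathways have unequal gene
counts, so the pairing unit is the per-sample pathway mean, and the
signed-rank test runs on sample-paired means (this pairing choice is
recorded in every report). The PCA/Spearman comparison merges samples on
the DSB genes shared by all tables (mapping mouse symbols to human
nomenclature first), drops zero-variance genes with a log entry, and uses
average ranks for ties.

## Synthetic data

The generator encodes the biological claims as ground truth so recovery is
testable. Each cell draws a true time t on its type's interval
(progenitor [0, 0.45], neuroblast [0.45, 0.65], cone/rod [0.65, 1]; types
sharing an identical interval are exclusive terminal branches). Expected
counts are `library × base_mean × amplitude` with:

* HDR amplitude 1 → 0.8 at the cell-cycle exit t_exit = 0.4, collapsing to
  0.08 by t = 0.6 (the mild pre-exit decline reflects the falling cycling
  fraction within the progenitor pool);
* MMEJ 1 → 0.9 → 0.5, settling at 0.45;
* NHEJ constant 1;
* cell-cycle genes on (1.0) iff t < t_exit, else 0.05;
* marker genes at 8× inside their type's interval with 0.04-wide linear
  membership ramps at the borders.

Counts are negative binomial (dispersion r = 4), multiplied by a log-normal
library factor (σ = 0.3) and thinned by Bernoulli dropout (rate 0.1, the
knob that controls the zero-score excluded fraction). Default scene: 500
progenitors, 400 neuroblasts, 300 cones, 300 rods (1500 cells), 17 DSB + 40
cell-cycle + 40 marker + 5 mitochondrial + 200 background genes. Bulk time
courses map calendar days onto the same amplitude schedules with cycle exit
at day 4 (a fast neuronal-induction profile) and log-normal replicate
noise; species panels rescale per-gene baselines so each pathway's mean TPM
equals its configured profile exactly — otherwise random baselines would
make equal-profile contrasts spuriously one-sided under replicate pairing.

What the generator does **not** emulate: ambient RNA, doublets, realistic
batch chemistry, gene–gene correlation beyond the shared programs, or
parameters fitted to any real dataset. Passing tests therefore demonstrate
that the algorithms recover structure of the kind the analyses assume, not
that any particular biological dataset would reproduce numerically.

## Numerical and design notes

* Scores on integer counts are exact (integer sum, single division).
* kNN ties break deterministically by cell index; duplicate points are
  legal.
* Eigenvector sign ambiguity cannot affect pseudotime (distances only).
* Equal-profile pathway contrasts *after* quantile normalization are not
  exchangeable across replicates (QN pins every replicate to one reference
  distribution), so null calibration of the signed-rank contrast is
  meaningful at the raw replicate level or at small n where the exact
  two-sided floor (2/2ⁿ) exceeds alpha.
* All drivers write a provenance record (config hash, seed, version)
  sufficient to reproduce a bundle byte-for-byte.

## Problem sizes

The shipped analyses run at desk scale by choice: 1500-cell scenes for
trajectory work (dense eigendecomposition in seconds), 150–200-cell
fixtures for linear-algebra oracles, 50-seed sweeps for calibration rates.
All scale parameters are ordinary arguments.
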