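# Methods

This note documents the models and procedures implemented in `mirglia`, the
parameters that matter, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## DE calls and the ΔΔCt utility

DE tables (feature, log2 fold change, FDR) are consumed as an input
contract; the upstream count model (edgeR/limma-style fits) is not refit.
Classification uses an inclusive fold-change bound for genes
(|log2FC| ≥ 0.7) and a strict one for miRNAs (|log2FC| > 1), with a strict
FDR comparison in both cases (FDR < 0.05 and < 0.01 respectively); both are
exposed as flags. Rows with missing statistics are treated as not tested
and excluded with a logged count before classification. `summarize_de`
reports the exact down-regulated fraction rather than a rounded percentage.
The qPCR utility returns 2^−ΔΔCt with
ΔΔCt = (Ct_target − Ct_ref)_sample − (Ct_target − Ct_ref)_calibrator; it is
exactly invariant to shifting both sample Cts by a constant.

## Target linking

Interaction tables carry a binding probability per (miRNA, gene) pair.
"At least 99%" is implemented as an inclusive ≥ 0.99 filter (flag-
controlled), applied uniformly to validated and predicted interactions,
which are pooled by default with a provenance filter available. Duplicated
pairs deduplicate to their maximum binding probability. Two backgrounds are
materialized per miRNA because they answer different questions: the
*anticorrelated DE targets* (opposite log2FC sign, DE in both tables) feed
enrichment-style summaries, while the *target / non-target partition of the
full tested universe* — including non-DE genes — is what the shift test
consumes. Interaction partners absent from the tested universe are logged
and ignored.

## The eCDF shift statistic

With X the non-target (control) log2FC sample and Y the target sample, the
test computes:

* the two-sample KS statistic D = sup_t |F_X(t) − F_Y(t)| with the
  asymptotic p-value; the exact small-sample distribution is used when the
  smaller sample has < 30 observations (target sets are typically large, so
  the asymptotic branch dominates);
* the signed area ∫(F_Y − F_X) dt evaluated on the sorted unique pooled
  grid with the right-continuous step convention — an exact finite sum that
  equals mean(X) − mean(Y); the identity is verified to 1e−9 in the tests.
  The orientation is a package convention (the source text does not bind
  the integrand to a sample): derepression — targets shifted toward higher
  log2FC — yields a **negative** signed area;
* the Wasserstein-1 distance ∫|F_X − F_Y| dt (scipy), always ≥ |signed
  area|, with equality under everywhere-dominance.

`shift_test` flags derepression when p < α (default 0.05) and the signed
area is negative. Target sets smaller than `min_targets = 5` are flagged
untested rather than raising — below that a KS comparison is not
meaningful. No multiple-testing correction is applied across miRNAs by
default (per-miRNA p-values are the reported quantity); BH-adjusted calls
are available behind a flag, and the adjusted p-values are always emitted.
Both the signed area and the Wasserstein distance are reported per miRNA,
since either can serve as the "shift" magnitude.

## Spatial pipeline

Distances are planar Euclidean in micrometres; a z coordinate, if present,
is ignored. Transcript-to-nucleus assignment is strict ("closer than
10 μm"): a spot at exactly 10.0 μm stays unassigned; exact ties break to
the lowest anchor id. Assignment is computed by chunked argmin over anchors
and is verified against an all-pairs oracle in the tests. The same
operation runs against deposits; deposit-assigned counts are emitted
without further downstream analysis.

The cell filter (≥ 30 transcripts) is applied before the gene filter
(expressed in ≥ 100 of the surviving cells); both thresholds are inclusive
and the ordering is fixed, which makes the filter idempotent. Microglia are
annotated by ≥ 1 *Aif1* transcript (marker and count configurable).

Cell-to-deposit distance defaults to **edge** distance — center distance
minus deposit radius, clamped at 0 — so colocalization (0 μm) is reachable
for cells overlapping a deposit; raw center distance is available as a
mode. Deposits are size-classed small (5–40 μm diameter, inclusive) or big
(> 40 μm); diameters below 5 μm are left unclassified.

Distance bins are left-open/right-closed with colocalized reserved for
exactly 0: (0, 9], (9, 17], (17, 27], > 27. Boundary ownership is a package
convention — the category descriptions ("0 to 9", "9 to 17") do not fix
it. The printed breaks are the default; they can equally be derived from
the breakpoint-density modes, since the categories originate in the
change-point analysis.

Group contrasts use the two-sided Wilcoxon rank-sum test on per-cell counts
with Benjamini–Hochberg correction across the genes of one contrast at
0.05 (a convention; the correction is not dictated by the procedure being
mirrored). Bin profiles are per-gene mean expression per bin, row-scaled
either to z-scores (zero-variance rows become 0) or min-max to [0, 1].

## Segmented regression

The breakpoint estimator is the iterative linearization of Muggeo: fit
y = β₀ + β₁d + Σ_k [β₂ₖ(d − ψₖ)₊ + γₖVₖ] with Vₖ = −1{d > ψₖ}, update
ψₖ ← ψₖ + γ̂ₖ/β̂₂ₖ, and iterate until the largest update falls below 1e−4
(≤ 50 iterations). Starts are taken on the interior deciles of the
distances (combinations of a thinned grid for ≥ 2 breaks); a start that
pushes a breakpoint out of the observed range is abandoned. Among
converged starts the lowest residual sum of squares wins. The number of
breaks (0…k) is selected by BIC with 2 + 2·(number of breaks) mean
parameters; a constant response short-circuits to the no-break line.
Breakpoint standard errors use the delta method SE(ψ̂) = SE(γ̂)/|β̂₂| from
the final working fit, giving 95% Wald intervals. Non-convergence returns
the last estimate with `converged=False`. Breakpoint densities are
Gaussian KDEs (Silverman bandwidth) normalized to integrate to 1 on the
evaluation grid; a degenerate point mass falls back to a fixed 1 μm kernel.

## Single-cell stage

QC applies the gene filter (≥ 3 cells), the cell filter (≥ 200 detected
genes), then the mitochondrial cut in that order; keep-thresholds are
inclusive and the mito cut is strict (> 5% removed), so a cell at exactly
5% survives. Mito genes come from a `var["mito"]` flag or an `mt-` name
prefix. Normalization is library-size scaling to a common total, log1p,
selection of the 2000 most variable genes, per-gene standardization, and
PCA with 20 components (reduced with a warning when the rank is smaller).
JackStraw-style component testing is deliberately replaced by the fixed
component count plus the explained-variance report. Clustering is Leiden
on a k-NN graph (resolution 0.2 by default — an opaque granularity knob;
identical cluster counts across implementations are not promised) or
k-means; both are deterministic under a fixed seed.

Cluster annotation uses a mean z-score signature — the per-cell mean of
per-gene z-scored log-normalized expression over a gene set, clusters
labeled by argmax — as a dependency-free stand-in for sample-wise
enrichment scoring, which at this scale ranks clusters identically.

`DAMSubclusterer` recomputes PCA on the signature genes restricted to the
DAM cells and splits them with 2-means; the subcluster with the higher
mean signature score is labeled phagocytic. The orientation is part of the
contract. Subcluster DE is a per-gene rank-sum test on library-size-
normalized counts with BH correction and a log2 fold change of normalized
group means (pseudocount 1e−9); shared DAM markers are removed from both
marker lists afterwards.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (config, seed).

**DE generator.** miRNA log2FCs come from planted down (40%), up (10%) and
null classes; gene log2FCs are a symmetric planted-effect mixture plus
Gaussian noise (sd 0.5), and each miRNA owns a disjoint target set whose
members gain +0.5 log2FC when their miRNA is down — the derepression
signal. p-values are computed from the observed log2FC against the null
noise sd, so null features get uniform p-values and BH-adjusted FDRs behave
like a real table. Interactions mix true pairs (binding ≥ 0.99) with
below-threshold decoys. Not emulated: overlapping target sets between
miRNAs, correlated genes, mean–variance trends of real count models.

**Spatial generator.** Deposits (10–60 μm diameter) and nuclei are placed
uniformly with separation constraints; profile-gene mean expression rises
linearly from the deposit edge to a peak at the 20 μm breakpoint, then
declines, floored far away — a two-stage activation profile. Counts are
Poisson; transcripts are jittered within 8 μm of their nucleus, strictly
inside the assignment radius and below half the minimum nucleus separation,
so every spot is recoverable to its true nucleus. Fits that must recover
the breakpoint exactly use distances below the flooring point recorded in
the truth record. Not emulated: tissue morphology, nucleus size, per-mouse
variability, segmentation noise.

**Single-cell generator.** Gamma–Poisson (negative binomial, dispersion
0.3) counts for four populations — homeostatic microglia, phagocytic DAM,
non-phagocytic DAM (40/60 split of DAM), and non-microglial cells — plus
planted low-depth and high-mito cells that the QC filters must remove.
The 28-gene phagocytic signature is induced 5-fold in phagocytic DAM: the
two DAM subpopulations are distinguished by expressing versus not
expressing the panel, so the planted contrast is an on/off state rather
than a marginal shift. Passing recovery tests on these data demonstrates
the pipeline's correctness on cleanly planted structure, not performance
on real droplet data with ambient RNA, doublets, or batch effects.

## Problem sizes

Tests and the acceptance script use desk-scale sizes chosen to exercise
every code path: 1000 sample pairs for the signed-area identity, 1000
simulated miRNAs for null calibration (100 targets vs 2000 non-targets),
100 replicates for power, 50 seeded runs for breakpoint recovery (n = 300
points each), 20 random fields for assignment equivalence, and 10–20
seeded single-cell draws (~800 cells each) for DAM recovery.
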