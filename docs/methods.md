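# Methods

## Grid-occupancy differential density

The embedding is treated as given: the method consumes per-cell 2-D
coordinates produced upstream (UMAP or any other layout shared across
libraries) and never recomputes them. The grid partitions the pooled
bounding box of all cells — expanded by 0.1% per axis so extreme cells stay
interior — into `n_bins_x × n_bins_y` sectors, half-open in each axis
except the last (closed) bin. Defaults are 50 × 50 for cell selection and
200 × 200 for visualization.

Per-library occupancy of sector *s* is normalized as
`norm = count_s / library_total × 10,000` and transformed to
`log2(norm + pseudocount)`. Two choices here are ours:

* **Pseudocount = 1** on the library-size-normalized scale, applied inside
  the log. Empty sectors would otherwise produce infinite fold changes;
  the pseudocount bounds the fold change contributed by a sector a library
  never visits. Configurable via `GridSpec`.
* **min_cells = 5** pooled over the two compared libraries for a sector to
  be flaggable. At 50 × 50 resolution single cells produce log2 fold
  changes above any threshold; a small pooled minimum suppresses these
  artifacts without touching genuinely occupied sectors.

A sector is flagged when the disease-minus-control difference of the
normalized log2 occupancies exceeds `threshold_log2 = 1` (a > 2-fold
density increase) and the pooled-cell minimum is met. The default
comparison is the last condition against the first; replicate libraries of
one condition may be pooled (counts summed before normalization) or
compared individually — pooled is the default because each comparison is
between one effective sample per condition.

**State assembly.** Flagged sectors are grouped into 8-connected
components; each component restricted to its modal cell type forms one
candidate state, other-type cells within the component stay unassigned,
and components with fewer than `min_state_cells = 20` members are dropped.
An optional merge map (state → state) reproduces manual curation of
adjacent states. This connected-component rule is a reproducible proxy for
what is, in practice, a curated delineation of enriched regions; the merge
map is the escape hatch when curation disagrees with connectivity.

## Marker signatures

Markers of a state are genes upregulated in state cells relative to
same-cell-type cells outside any flagged sector ("cells not changed in
abundance"). Genes are tested only if expressed (lognorm value > 0) in at
least 10% of one group and if the log fold change of de-logged group means
reaches 0.25 in magnitude. The log fold change uses natural log of
`(mean(expm1(x)) + 1)` ratios — the single-cell ecosystem's convention for
a "0.25 log fold change" threshold — with the base configurable.

The test is the two-sided Wilcoxon rank-sum. For small untied groups
(min size ≤ 8) the exact distribution is used, matching R's `wilcox.test`;
otherwise the normal approximation with tie correction and continuity
correction applies. The exact branch matters: in extreme tails at n = 8 + 8
the normal approximation misses the exact tail probability several-fold,
and the package guarantees agreement with an enumeration oracle to 10%
relative for all group sizes up to 8. BH adjustment runs across genes
within one state comparison only; retained markers have adjusted p < 0.05
and positive fold change. Sub-threshold tested genes remain in the table
(flagged insignificant) so ranked truncation can extend a short signature
to a fixed size when comparative analyses need equal-length gene lists.
Ranking for truncation is adjusted p ascending, then |log FC| descending,
then gene name — the tie-break is our choice, made for determinism.

Signature sharing across states is summarized exactly (per-gene membership
counts, per-state unique-gene counts, k-way sharing histogram). Enrichment
of external candidate lists in a signature is the upper-tail
hypergeometric p over an expressed-gene background universe; genes outside
the background are dropped with a warning.

## Bulk activity scores

Bulk matrices are quantile-normalized (each sample's order statistics
replaced by the across-sample mean of order statistics; ties receive the
mean of the reference values they would jointly occupy), then scored with
the bin-background module score: genes are ranked by average log
expression and split into `n_bins = 25` equal-frequency bins; for each set
gene, `n_ctrl = 100` control genes are drawn from its bin (excluding set
genes whenever the bin holds others; with replacement when the bin is
small); the score per sample is the mean of set-gene values minus the mean
of the pooled control draws. The method's source describes the binning but
not the counts, so 25/100 — the conventional defaults — are declared
parameters, not inferred ones. Control draws are seeded; identical seeds
give identical scores. Inputs must already be on a log scale; the scorer
is platform-agnostic (microarray or RNA-seq).

## Synthetic data

The generators produce the statistical structure the analyses assume, not
the measurement process:

* **Single cell.** Each cell type is an isotropic Gaussian cluster
  (sd 1.0) on a coarse grid of centres (spacing 40 embedding units, so a
  50 × 50 grid over the pooled bounding box resolves a cluster into sectors
  of roughly one sd). One library per condition; a condition-specific
  fraction of cells of the designated type (defaults 5% control, 30% late
  disease — a 6-fold expansion) forms the planted state: displaced to its
  own territory and drawn at half the parent cluster's spread, reflecting
  that a disease state is a compact subpopulation. Counts are negative
  binomial (dispersion 0.5); 50 planted marker genes have their means
  multiplied by `2^1.5`, and each type carries 30 identity genes at 4×.
  What this does **not** emulate: batch effects, ambient RNA, doublets, or
  an embedding actually computed from the counts — so passing tests show
  the grid method recovers planted density structure, not that UMAP
  produces such structure from real data.
* **Bulk.** Samples are proportion-weighted mixtures of expression
  profiles with multiplicative log-normal noise (sd 0.2 in the bundled
  scenarios) — composition shifts only, no sample-specific technical
  covariates.
* **GWAS.** Genotypes follow a Gaussian-threshold model: per haplotype, a
  latent normal with block-constant correlation (1,000 variants in 200
  contiguous blocks of 5, one variant per 5 kb) is thresholded at the MAF
  quantile (MAF ~ U(0.05, 0.5)); the dosage is the sum of two haplotypes.
  This gives analytic control of LD and allele frequency at desk scale;
  it does not model recombination hotspots, MAF–LD coupling or population
  structure. Causal variants are drawn inside a designated region set and
  standardized effects rescaled so the liability variance explained equals
  `h2 = 0.3`; case status thresholds liability at the standard-normal
  `1 − prevalence` quantile (prevalence 0.2). The base cohort (n = 5,000)
  yields per-variant summary statistics via the vectorized logistic score
  test (one-step effect `U/V`, two-sided p of `U/√V`); the target cohort
  (n = 4,000) is an independent draw with two pure-noise covariates (sex,
  age). INFO is 1.0 by construction and EAF is the realized base-cohort
  frequency.

## PRS construction and evaluation

Preferential clumping sweeps variants in (in-set, p, position, id)
priority order; each unclaimed variant indexes a clump and claims
unclaimed variants within 500 kb on its chromosome with dosage r² > 0.2,
computed from target dosages with per-variant mean imputation (an external
LD panel is unnecessary at this scale). Preferential retention as a
priority *ordering* is our concretization of "in-region SNPs are
preferentially retained per clump": it is deterministic and reduces to
ordinary p-ordered clumping when the region set is empty. Ties break by
position then variant id.

Scoring harmonizes allele orientation between summary statistics and
target (an effect/other swap negates β; a true allele mismatch drops the
variant with a warning) and mean-imputes missing dosages. PRS.R² is
Nagelkerke (PRSice's convention for binary traits; McFadden optional) of
the full model minus the covariates-only null, both fit on the identical
complete-covariate sample set. The stated definition of this difference in
the method's source reads null − full, which is negative as written; the
standard full − null is implemented. The competitive p draws, per
permutation, a random set with the observed score's SNP count from the
genome-wide post-clumping background pool ("identically clumped" at
tractable cost; count-only matching, no MAF matching) and is
`(1 + #{perm ≥ obs}) / (1 + n_perm)`; the default `n_perm = 10,000`
follows the source, while bundled scenarios use 199 permutations, which
already resolves p < 0.05. The hybrid score includes every retained SNP
with p ≤ t_strong plus retained SNPs with t_strong < p ≤ t_weak inside
the peak regions; `t_strong` defaults to the classical scan's best
threshold.

## Validation scenario sizes and metrics

The bundled scenarios are sized for a desk machine: 20 simulation
replicates for grid power/calibration, state recovery, PRS recovery and
the hybrid comparison; 3 replicates for marker recovery (each with ≥ 500
planted state cells); 100 random instances (≤ 200 variants) for the
clumping cross-check; 100 random gene sets for module-score null
centering. "Sector recall" is measured over the detectable planted region
— sectors holding at least `min_cells` planted disease-library cells —
since sparser sectors are unflaggable by design; the false-flag rate is
the flagged fraction of sectors containing no planted cells.

## Known limitations

* State assembly is purely geometric; transcriptionally distinct states
  sharing one embedding region are not separated.
* The competitive permutation refits only the full model per draw (the
  null is cached); covariate–score interactions are not modelled.
* The liability-scale h2 is realized exactly in-sample by rescaling,
  slightly understating between-replicate variability of the genetic
  signal.
* Region sets are applied through interval containment of point variant
  positions; indels spanning region edges are out of scope.
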