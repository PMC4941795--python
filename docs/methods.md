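# Methods

This package implements a stratified weighted gene co-expression analysis:
given case/control expression data split by APOE ε4 carriage into four
strata (AD-carrier, AD-noncarrier, CTRL-carrier, CTRL-noncarrier), it
identifies co-expression modules that exist in exactly one stratum, ranks
their hub genes, asks whether the modules carry genetic association signal,
and validates hub co-expression in time-course data. This note records the
model, its assumptions, the defaults that matter, and the choices made where
the design was genuinely open.

## Preprocessing

Transcripts detected (non-missing) in less than 90% of the case series *or*
of the control series are dropped; the boundary is inclusive (a transcript
detected in exactly 90% survives, because the exclusion rule is "less
than"). Arrays are then screened iteratively: each round computes every
sample's mean Pearson correlation with all other samples
(pairwise-complete over genes) and removes samples below
mean − 2·SD of those means, repeating until no removal. Two degenerate
cases are pinned down: SD = 0 removes nothing, and a round that would leave
≤ 2 samples aborts with an error. Missing values are carried as missing and
excluded pairwise from correlations, never imputed.

Iterative 2-SD trimming is not innocuous on exchangeable data: each round
re-estimates the spread on the surviving samples, so the left tail keeps
being clipped and total removal of ~5–10% of unremarkable arrays is normal.
On real arrays (and on the synthetic data once per-gene baselines dominate
inter-array correlation) it behaves as intended, flagging genuinely
discordant arrays first.

## Network construction

Unsigned weighted networks: a_ij = |r_ij|^β with Pearson r and integer
power β. The unsigned map is the default because no sign transformation is
applied to the correlations before powering; a signed variant
((1+r)/2)^β is available behind a flag. β is chosen per stratum as the
smallest integer in 1..20 whose approximate scale-free fit
(R² of log10 frequency vs log10 connectivity over 10 linear connectivity
bins) reaches 0.8; when no candidate qualifies, the best-fitting power is
used and flagged. The pipeline default is a fixed β = 6 — the conventional
unsigned default — so that all four strata share one network scale unless
per-stratum selection is requested (`beta: null`).

Topological overlap:

    TOM_ij = (Σ_{u∉{i,j}} a_iu·a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)

with k_i = Σ_{j≠i} a_ij; 1 − TOM is the clustering dissimilarity. The
shared-neighbour sum excluding u ∈ {i, j} is the standard unsigned TOM.

## Module detection

Average-linkage hierarchical clustering of 1 − TOM, cut by a static branch
decomposition: the tree is cut at `cut_height_frac` (default 0.99) of the
maximum merge height, branches with ≥ `min_module_size` (default 30) leaves
become modules, everything else is unassigned (module 0, "grey");
modules large enough to host two minimum-size children are recursively
re-clustered and split up to `deep_split` (default 2) levels. The cut is a
*fraction of the maximum merge height* rather than a quantile of the
merge-height distribution: with many background genes the upper quantiles
of merge heights sit inside the noise-gene merges near height 1 and a
quantile cut collapses everything into one cluster. The PAM-assisted
"hybrid" tree cut is deliberately not implemented; the tree variant is
fully deterministic and specifiable.

Module eigengenes (ME) are the first left-singular vector of the
gene-standardized module submatrix (samples × genes), unit norm, sign fixed
so cor(ME, mean standardized expression) ≥ 0. Modules whose MEs are closer
than `me_diss_threshold` = 0.25 in 1 − cor distance are merged iteratively
(closest pair first, MEs recomputed after every merge); the surviving id is
the larger module's and labels are re-ranked by size at the end. Internally
modules are size-ranked integers; colour names are presentation aliases
only.

Consensus modules across strata: each TOM is rescaled multiplicatively so
its 0.95 off-diagonal quantile matches the first TOM's (clipped to [0,1]),
the consensus TOM is the elementwise minimum, and the same cut/merge
machinery runs on it (merging uses the maximum ME dissimilarity over the
contributing datasets).

## Specificity calls

A module of a disease stratum is SPECIFIC when both of the following hold.

1. **Unmatched in consensus.** Fisher-exact (one-sided) overlap against
   every module of the two relevant consensus partitions (disease pair and
   same-carrier case/control pair), Bonferroni-corrected over pairs at
   α = 0.05; a module that matches nothing is unmatched. The
   cross-tabulation cutoff is our formalization — recorded in the output
   evidence trail — since "compared with the consensus modules" admits
   several readings.
2. **Not preserved.** Permutation Z_summary < 2 in both comparison strata
   (same phenotype/other carrier status; other phenotype/same carrier
   status). Z_summary is the mean of Z_density and Z_connectivity, each the
   median of three statistic Z-scores: density — mean within-module
   adjacency, mean |kME|, proportion of variance explained by the ME, all
   in the test stratum; connectivity — correlation of reference vs test
   intramodular connectivity (kIM), of reference vs test kME, and of the
   vectorized within-module correlation matrices. Each observed statistic
   is standardized against `n_perm` = 200 random same-size gene sets drawn
   from the test data (module-label permutation null). Statistics with zero
   permutation spread are dropped from their group median with a warning.
   The bands follow the preservation convention: Z < 2 no evidence of
   preservation (strong specificity evidence), 2–10 moderate, > 10 strong
   preservation (no specificity).

Modules missing either piece of evidence are reported "undetermined",
never silently specific.

Specific calls are then stress-tested by subsampling replication: samples
drawn without replacement at 50% and 75%, five runs each, the full
detection pipeline re-run, and the best single-module overlap with the
original module recorded; replication requires > 80% overlap in *every*
run (an any-run mode exists but is off by default, reflecting the strict
reading of the criterion).

Conserved (non-specific) modules can additionally be tested for
differential expression: OLS of the ME on the grouping variable adjusted
for the other stratification variable, age and sex, two-sided p on the
grouping coefficient.

## Hubs and cliques

kIM_i = Σ_{j∈module, j≠i} a_ij; kME_i = cor(x_i, ME). Genes are ranked by
the sum of their kIM rank and |kME| rank (both measures are named as hub
criteria; neither alone is), ties broken lexicographically by gene id. The
hub count defaults to the top 5% of the module (minimum 5) because the
cutoffs behind the reported hub counts are unstated. The top hubs form a
graph with an edge where |Pearson r| ≥ 0.5 in the stratum's data (the edge
rule is configurable, including an adjacency-based variant); completeness
is checked exactly and the maximum clique found by Bron–Kerbosch
enumeration with a deterministic lexicographic tie-break (exact search
limited to ≤ 64 nodes, far above any hub list).

## GWAS signal enrichment

SNP QC uses strict inequalities exactly as stated: missingness > 0.1,
MAF < 0.01, HWE p < 0.001 remove a SNP; boundary values survive. Each gene
is scored with the max −log10 p over SNPs within ±20 kb of its boundary
(inclusive window, 1-based coordinates; BED input is converted on read;
strand is ignored because the window is symmetric). A SNP may score several
overlapping genes; genes with no SNP are excluded.

Enrichment is GSEA-style on the descending gene-score ranking: in-set genes
add score^w (normalized over set members; w = 1 default, w = 0 gives the
rank-only statistic), others subtract 1/(N − m); ES is the maximum of the
running sum. Significant genes are the top 5% of gene scores (rank-based,
deterministic; the SNP-top-5% variant of the convention is an option), and

    SPES = k/K × ES

with k and K the significant-gene proportions in the set and genome-wide.
The null is SNP-label permutation: shuffling the p column over SNPs while
keeping the SNP→gene assignment fixed, which preserves per-gene SNP counts
and thereby addresses gene-length bias inside the null itself; p uses the
+1 smoothing convention (1 + #{SPES* ≥ SPES})/(1 + n_perm), so the floor is
1/(n_perm+1). FDR across gene sets normalizes observed and permuted SPES by
the mean positive permuted SPES per set and takes the clipped ratio of
pooled-permutation to observed exceedance proportions.

QQ diagnostics plot ranked observed −log10 p against the expected order
statistic −log10[i/(L+1)]; in subset (comparative) mode the subset's points
keep the expected values of their ranks among *all* L p-values. The genomic
dispersion factor λ defaults to the median estimator
median(χ²₁(1−p))/0.45494; the regression estimator (slope through the
origin of sorted observed on expected χ² quantiles) is provided and the two
can be compared.

## Cross-disease overlap and time-course validation

Overlap between specific-module gene sets of two diseases is the upper-tail
hypergeometric probability P(X ≥ x) over a declared universe — the
intersection of the measured gene sets, since no universe convention is
canonical — Bonferroni-adjusted over module pairs (few tests; BH optional).
Time-course co-expression is the mean |Pearson r| over gene pairs across
replicate-mean timepoint values (3 timepoints by default); constant
profiles are excluded from the mean with a count. With only 3 timepoints
|r| is high for many monotone profiles, so the contrast between conditions,
not the absolute level, is the informative quantity.

## Synthetic data: what it emulates and what it does not

All inputs are generated with the structure the analysis assumes, plus
machine-readable truth labels:

* **Stratified expression** — single-factor modules: within a stratum where
  a module is planted, x_g = ρ·e + √(1−ρ²)·ε with a shared per-stratum
  eigengene e, so the expected pairwise correlation is exactly ρ² and
  E[kME] ≈ ρ. An optional linear loading gradient (`loading_low`) plants a
  hub hierarchy. Per-gene baseline levels (`gene_mean_sd` = 2.0, shared
  across strata) dominate inter-array correlation as on real log-scale
  arrays, which is what makes the iterative outlier rule behave
  realistically; baselines are location shifts and change no
  correlation-based statistic. Default stratum sizes are the real study
  composition 121/55/40/148 scaled by 0.5 (→ 60/27/20/74), preserving its
  imbalance. The default study design plants one 50-gene carrier-only
  module and one 50-gene module present in all four strata, in a 300-gene
  background; ρ = 0.8 throughout. ρ is a free choice of the simulation —
  the real modules' effect sizes are unknown — and is documented config,
  not an estimate.
* **GWAS tables** — genes tiled on one synthetic chromosome (10 kb genes,
  30 kb gaps), SNP positions uniform, null p ~ Uniform(0,1); SNPs inside
  enriched genes draw p ~ Beta(a,1) with a = 1/(1+signal_strength), so
  signal 0 reproduces the null exactly and the Uniform limit is a = 1.
  QC columns are drawn passing with configurable failing fractions.
* **Time course** — per condition, gene mean-profiles share a latent trend
  with coupling ρ_c (ρ_c = 1, zero replicate noise ⇒ all |r| = 1; ρ_c = 0 ⇒
  independent profiles), three timepoints, ≥ 3 replicates averaged.

Not emulated: microarray platform artifacts (bead-level noise,
rank-invariant normalization), LD structure between SNPs, genotype-level
data, and multi-factor (overlapping) modules. Passing tests therefore show
that the statistical machinery recovers the structures it assumes at
realistic sizes and noise — not that any particular biological dataset
contains them.

One sizing constraint worth knowing: the Z_summary permutation null draws
random gene sets from the test stratum, so when planted-module genes are a
large fraction of the universe (≳ 25%), random sets reliably straddle the
module and the connectivity statistics' null inflates, compressing Z for
genuinely preserved modules. Preservation experiments therefore use a
500-gene universe with a single 50-gene module (10%), the realistic regime
— real modules are small fractions of the ~8,650-transcript background.

## Determinism and numerics

Every stochastic stage consumes a 31-bit sub-seed derived from the global
seed via `numpy.random.SeedSequence.spawn` (stage index = spawn index), so
stage-level reruns reproduce exactly and two runs with the same seed yield
byte-identical reports up to wall-clock timings. Hypergeometric and Fisher
tails are evaluated by scipy in log space; TOM denominators ≤ 0 (isolated
gene pairs) yield TOM = 0; eigengene computation drops zero-variance genes
and fails only when none remain; correlation matrices are clipped to
[−1, 1] before powering. Problem sizes in the shipped study (300-gene
design, 500-gene preservation universe, 4,000-SNP GWAS, 200 preservation
permutations, 500–1,000 enrichment permutations) were chosen so planted
effects sit far from decision boundaries while a full run stays in the
tens of seconds.

## Known limitations

* The hybrid (PAM-assisted) tree cut and blockwise TOM for > 20k genes are
  out of scope; module counts on dense real data will differ from the
  reference R implementation's hybrid cut.
* The adaptive-permutation per-gene score correction used upstream of the
  enrichment test in the original protocol is approximated by the
  count-preserving SNP-label null rather than re-implemented.
* Consensus module merging requires expression matrices; with TOMs alone
  the merge step is skipped.
* With three timepoints, time-course |r| contrasts are descriptive, not
  inferential.
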