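# Methods

## The statistical model

Each curated LC-MS feature is treated as a quantitative phenotype of the
hybrid panel and analyzed (on natural-log scale) under the two-kinship
mixed model

    y_i = mu + sum_l x_i^l theta_a^l + w_i^l theta_d^l + A_i + D_i + e_i

with A ~ N(0, sigma2_a K_a), D ~ N(0, sigma2_d K_d), e ~ N(0, sigma2_e I).
x is the mean-centered 0/1/2 genotype code of a reference SNP, w the
mean-centered heterozygote indicator, and K_a / K_d the alike-in-state
(AIS) additive and dominance kinships:

    K_a[i,j] = mean over SNPs of (1 - |g_i - g_j| / 2)
    K_d[i,j] = mean over SNPs of 1(het_i == het_j)

computed with pairwise exclusion of missing genotypes.

Because both kinships enter the covariance, no single spectral rotation
diagonalizes it.  REML is maximized directly: V0 = e^la K_a + e^ld K_d + I
is Cholesky-factorized per evaluation, sigma2_e is profiled out
analytically, and the two log variance ratios (la, ld) are optimized by
Nelder–Mead from three starts (a coarse pass per start, then one polish of
the best to a 1e-8 tolerance on the criterion).  Later forward-selection
steps warm-start from the previous optimum.

### Per-marker tests

At each forward-selection step every remaining candidate reference SNP is
tested with a joint 2-df Wald test of (theta_a, theta_d) = 0 by
generalized least squares at the current step's fitted covariance (the
"score-style" shortcut of multi-locus mixed-model practice — a full REML
refit per marker would cost O(p) REML fits per step).  Candidates whose
dominance column is degenerate after projection fall back to a 1-df
additive test; candidates collinear with the current cofactors get p = 1
and a flag.  Ties in the admission p-value break by larger Wald statistic,
then genomic position, then SNP id, which makes the path deterministic.

### Model choice: eBIC at a common covariance

The forward path (at most 20 steps by default) is pruned with the extended
BIC,

    eBIC_k = -2 logLik_k + df_k log n + 2 gamma log C(p, k),

where df_k = 1 + 2k counts fixed effects, p is the candidate reference-SNP
count, and gamma defaults to max(0, 1 - log n / (2 log p)), the boundary
of the eBIC consistency region.

`logLik_k` is the Gaussian profile (GLS) log-likelihood of the step-k
model **with the covariance held at the cofactor-free REML fit** — the
"population parameters previously determined" (P3D) convention of fast
mixed-model GWAS.  With this convention the eBIC difference between
consecutive models equals the admitted marker's Wald statistic, and the
selection rule is exactly "statistic > 2 log n + 2 gamma log C-increment".
The alternative — re-maximizing the variance components inside every
step's likelihood — makes successive differences systematically exceed the
marker's own 2-df statistic (the variance ratios sit at the sigma = 0
boundary under near-null phenotypes, where profile-LR asymptotics are
distorted, and any optimizer noise enters the extreme tail of the
max-over-candidates), which we measured as an inflated null selection
rate.  The admission tests and the per-step REML refits are unaffected by
this convention.

Reported "associations" are the cofactors of the eBIC-minimizing step,
with the admission p-value and GLS effect estimates attached.

### Genomic heritability

h2_g per feature comes from an additive-only REML fit via the standard
single-kinship spectral rotation (one eigendecomposition, then a cheap 1-d
search over the log variance ratio).  The AIS similarity matrix carries a
large identity-by-state baseline — unrelated hybrids still share most
alleles by chance, so its off-diagonal mean is ~0.5–0.7 — and the raw
component ratio sigma2_a/(sigma2_a + sigma2_e) would then not be a
fraction of phenotypic variance.  `estimate_h2g` therefore normalizes the
kinship first (subtract the off-diagonal mean, rescale to unit diagonal);
mixed-model likelihood-ratio and Wald tests are invariant to this affine
change when an intercept is fitted, but it puts h2_g on the
variance-explained scale, where the panel-mean anchor of 0.66 and the
recovery checks are defined.  The synthetic generator draws its polygenic
term from the same normalized kinship.

## Feature-table curation

Stages run in the order: spatial adjustment -> drift correction -> quality
filters -> redundancy collapse -> dry-mass normalization (each stage can
be toggled; the order is fixed as the package's convention).

* **Spatial adjustment.**  Replicated control hybrids (default 4 genotypes
  over 65 plots) sample the field.  Per feature, control log intensities
  (control-genotype medians removed) are decomposed into additive row and
  column effects by median polish on the incomplete row x column table;
  the predicted surface is subtracted from every field plot and control
  plots are discarded.  Rows/columns never sampled by a control get a zero
  effect and a log message.
* **Drift correction.**  Per feature, a support-vector smoother (RBF
  kernel) is fit to log QC intensity against injection index (local
  regression when fewer than 5 QCs); samples are divided by the
  exponentiated curve scaled to mean 1.  Features whose QC CV would not
  improve, or with non-positive QC intensities, are flagged and left
  unchanged, so the correction can only tighten QC repeatability.
* **Filters.**  First failing rule per feature, in order: detected in
  blank extracts (mean blank intensity > 10% of mean QC intensity — the
  blank rule threshold is a package default, exposed in config), m/z apex
  spread > 0.005 Da, RT apex spread > 40 s, QC CV > 20%.  Zero-variance QC
  series count as CV 0.
* **Redundancy collapse.**  Features eluting within 2 s whose m/z
  difference matches a catalogue delta (13C, 2x13C, +Na-H, +NH4, -H2O) at
  5 ppm and whose intensity profiles correlate at r >= 0.9 are clustered
  by union-find; the most intense member represents the cluster.  The
  correlation threshold, RT window and catalogue are package defaults
  (the upstream binning tool's settings are not published) and are
  configurable.
* **Mass normalization** divides by per-sample dry mass (mg); pooled-QC
  and blank injections have no powder mass and are left unchanged.  A flag
  prevents double application.
* **PCA** is computed on unit-scaled, mean-centered biological samples via
  SVD; constant features are dropped with a warning.

## Genotype structure

Complete LD is interpreted as r^2 = 1 (tolerance 1e-9) between genotype
columns on complete cases — sign-invariant, so allele-flipped copies
group together.  Co-inherited sets are connected components of the
same-chromosome r^2 ~ 1 graph (union-find); the reference SNP is the
member with the smallest position (ties by id).  Reference SNPs with
MAF < 0.1 (strict) or whose variant allele segregates in only one parental
panel are excluded from the candidate list.  LD sets are built on the
hybrid panel by default (the alternative — parental lines — is a
constructor away, since the generator produces both).

## Interpretation stages

* **Co-localization**: a co-inherited member SNP hits a QTL when it lies
  within 50 kb (inclusive at exactly 50 kb) of any SNP defining that QTL
  on the same chromosome; all hits are recorded, so a feature can be
  counted under two QTLs ("multi" roll-up).  QTLs are SNP lists; a BED
  adapter contributes interval endpoints.  Chromosome-namespace mismatches
  raise immediately.
* **Gene mapping**: 1-based inclusive coordinates throughout; a SNP on an
  exon boundary is exonic, exon beats intron for nested models.  A gene is
  linked to a feature when >= 1 SNP of the feature's co-inherited set lies
  in one of its exons.
* **Variant effects**: codon substitution through the standard genetic
  code (strand- and phase-aware); synonymous iff the amino acid is
  unchanged, stop gain/loss collapses to "other", non-CDS SNPs are "na".
  A reference-allele mismatch with the genome sequence is a hard error.
* **Hot spots**: 5 Mb windows advanced by 1 Mb; a gene belongs to a window
  through its start coordinate (midpoint optional); windows qualify when
  the metabolite-associated gene frequency is strictly > 0.075 AND their
  count strictly > 10; overlapping/adjacent qualifying windows merge, and
  hot-spot statistics are recomputed over the merged span.
* **Enrichment**: two-tailed hypergeometric p-value (sum of point
  probabilities not exceeding the observed one) with Benjamini–Hochberg
  adjustment at 0.05.  Ontology-graph clustering of terms is out of scope.

## The synthetic-data generator

The generator emulates the study design so every stage has ground truth:

* 36 + 36 fully homozygous parents; one latent allele per parent per LD
  block, repeated (up to random allele relabeling) across the block's
  SNPs, so within-block r^2 = 1 holds exactly by construction and the
  LD-grouping oracle is trivial.  Block allele frequencies are drawn
  uniformly in [0.1, 0.5] and redrawn until the empirical parental MAF
  respects the floor.
* An incomplete factorial of 450 hybrids (default) sampled from the 36x36
  grid; hybrid genotype = sum of parental gametes; names "female_male".
* Phenotypes on log scale: QTN contributions (additive + dominance,
  rescaled so each QTN's variance fraction is exact on the sample),
  a polygenic draw from the normalized additive kinship (default variance
  fraction 0.66, the panel-mean heritability anchor), and Gaussian
  residual filling the budget to unit variance; exponentiated into
  positive right-skewed intensities with feature base abundances of
  1e5–1e7 counts.  Realized narrow-sense h2 per feature is recorded.
* Field and acquisition artifacts: a smooth row+column log-scale bias
  (sd 0.2) applied to biological and control plots (4 control genotypes
  over 65 plots, replicate noise sd 0.05); a randomized injection order
  with pooled-QC pseudo-samples every 10 injections (QC noise sd 0.02) and
  leading blanks; a linear-plus-smooth multiplicative drift (default 20%
  loss over the run).  Optional planted filter violations (blank
  contaminants, unstable m/z or RT features).
* Redundancy: derived features at exact catalogue m/z deltas, jittered RT,
  intensities equal to the parent times a fixed ratio in [0.1, 0.8] times
  optional log-normal noise (0 = exact copies).

One root seed feeds one child stream per operation, so scenes are
bit-reproducible and individual stages can be re-run in isolation.

What the generator does **not** emulate: chromatographic peak shapes and
co-elution, missing values and detection limits, recombination within
blocks (LD is exactly 1 or 0), linkage *between* blocks, non-Gaussian
phenotype tails, genotype errors, or population structure beyond the
factorial parent sharing.  Passing recovery tests therefore demonstrate
internal consistency of the pipeline under its own model, not robustness
to every artifact of real LC-MS or resequencing data.

## Problem sizes in the test suite

The statistical checks run at reduced but structurally faithful sizes,
chosen once: null calibration on 200 pure-noise features against 2000
SNPs in 400 blocks over 200 hybrids with the forward scan truncated at 3
steps (the eBIC penalty grows by roughly 2 log n + 2 gamma log p per step
while null per-step gains are bounded far below it, so null selections
surface in the first steps); single-QTN power at n = 300 over ~200
candidate loci with one forward step (the claim concerns the first
cofactor); h2 recovery at the study's n = 450; end-to-end truth recovery
on a 150-hybrid, 2-chromosome scene.

## Numerical choices and degenerate inputs

* V0 Cholesky with a 1e-8 ridge retry; variance ratios clipped to
  e^±25; REML criterion tolerance 1e-8.
* Collinearity: fixed-effect columns are pruned by sequential
  orthogonalization at 1e-8 relative tolerance; df counts surviving
  columns.
* Monomorphic SNPs yield zero design columns (flagged); all-heterozygous
  columns center to zero dominance.
* Compact letter display: maximal cliques of the "not significantly
  different" graph (Tukey HSD at alpha 0.05), letters ordered by group
  mean; groups with < 2 observations are untestable and receive the union
  of letters, with a warning.
* p-values of 0 are floored at 1e-300 before -log10 for plot tables.

## Known limitations

* The forward scan refits REML once per step (not per marker); strong
  cofactors therefore sharpen later tests only through the fixed effects
  and the re-estimated variance ratios.
* Proximal contamination is not addressed (no leave-one-chromosome-out
  kinship): a tested marker also contributes to K_a, which slightly
  deflates its own statistic — conservative for detection.
* The two-kinship REML surface can be flat when K_a and K_d are nearly
  collinear (as in panels of closely related hybrids); the reported split
  between sigma2_a and sigma2_d is then less stable than their sum.
* Hot-spot windows assign genes by start coordinate; genes spanning a
  window boundary count once.
* The redundancy collapse assumes one representative per cluster suffices;
  chained adduct-of-adduct relations merge through transitivity.
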