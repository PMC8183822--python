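# Methods

`magicgp` implements a complete genomic-prediction workflow for
multi-parent (MAGIC) barley-style populations: simulation of the
population and its field trials, phenotype adjustment, kernel and
marker-based whole-genome regression with and without
genotype-by-environment (G×E) terms, training-set optimization and
cross-validated assessment. This note records the models, the defaults and
why, and the numerical choices where the design was genuinely open.

## Population and trial simulator

The simulator reproduces the structure of an eight-way MAGIC population of
doubled-haploid (DH) winter barley lines:

* **Founders.** Eight fully inbred founders, four "old" and four "modern"
  varieties, with binary haplotypes drawn so the panel-wide minor-allele
  frequency per marker lies in a configurable range (default 0.1–0.5, the
  alternate allele placed on `round(8f)` founders, so a forced frequency of
  0.5 gives an exact 4/4 split).
* **Funnel design.** Stage 1 crosses each old founder to one modern
  founder (4 F1s); stage 2 performs all six half-diallel F1 crosses
  (four-way sets); stage 3 pairs the three disjoint four-way sets so each
  funnel unites all eight founders exactly once. Lines are spread evenly
  across funnels, remainder assigned in seeded random order. Every DH line
  descends from an independently simulated funnel.
* **Meiosis.** Haldane model: per chromosome the crossover count is
  Poisson with mean equal to the genetic length in Morgans, crossover
  positions uniform on the cM axis, no interference. A DH line is one
  gamete of the eight-way F1 with its genome doubled, so lines carry zero
  heterozygous calls by construction and each founder's expected genome
  share is 1/8. Founder-origin labels are propagated through every meiosis
  so the mosaic can be asserted marker-by-marker against the alleles.
* **Genome.** The default map emulates a barley-scale genome: 7
  chromosomes of 150 cM / 550 Mb with uniformly placed markers and a flat
  cM–bp relationship. Few meioses between founders and DH lines give the
  slow LD decay characteristic of MAGIC panels (mean r² above 0.4 at short
  range, ~0.1–0.2 at long range in the default panels).
* **Traits.** Each QTL effect is the sum of an environment-common main
  effect b0 and an independent environment-specific deviation b_j; the
  genetic value of line i in environment j is Σ_k x_ik (b0_k + b_jk). With
  independent deviations the expected cross-environment genetic correlation
  is σ²_main/(σ²_main+σ²_dev), which is how G×E strength is dialed (default
  dev/main = 0.3 for moderately correlated environments). A per-line
  days-to-heading covariate is simulated with a narrow spread
  (SD 1.2 days), consistent with founders differing by under four days.
* **Trials.** Two-replicate alpha lattices: each genotype appears once per
  replicate, incomplete blocks filled by seeded random permutation (formal
  alpha-design generators are unnecessary because the analysis model only
  uses replicate and block factors). Plot yield = genetic value +
  replicate effect + block-within-replicate effect + covariate effect ×
  DH-days + Gaussian residual. The residual variance is solved from the
  line-mean heritability identity H² = σ²_g/(σ²_g + σ²_e/r), i.e.
  σ²_e = r σ²_g (1−H²)/H²; replicate and block SDs default to 0.25 and 0.5
  of the genetic SD. Default per-environment H² targets span the 0.12–0.8
  range observed across contrasting sites.

What the simulator does **not** emulate: segregation distortion, selection
during population development, spatial field trends, genotyping error and
marker ascertainment, and any sequence-level features (markers are
abstract biallelic loci). Tests passing on this generator therefore show
the estimators recover the structure they model, not that real field data
satisfy that structure.

## Adjusted means (alpha-lattice mixed model)

Per environment: y = μ + Rep (fixed) + Block-within-Rep (random) +
Genotype (random) + β·DH (fixed) + e. Variance components are estimated by
EM-REML on Henderson's mixed-model equations, with Aitken extrapolation of
the variance-component sequence every third sweep (EM converges linearly;
the extrapolated jump is capped to a factor of three per component because
zero is an EM fixed point and an uncapped jump can collapse a component
onto it). Convergence is declared when the relative change of every
component falls below 1e-6 (default; cap 500 iterations), which matched
lme4's REML estimates to four decimals on every case checked.
Blocks-within-replicate are random, the standard treatment for alpha
lattices. Genotype BLUPs at the REML estimates are the adjusted means;
H² = σ²_g/(σ²_g + σ²_e/r) on a line-mean basis (no formula is canonical;
this is the usual plant-breeding definition). Missing plots are simply
excluded — genotypes seen in fewer plots are shrunk harder. Adjusted means
are standardized per environment (mean 0, sample SD 1) before genomic
prediction, constants stored for back-transformation.

At H² ≈ 0.12 with 300 lines × 2 replicates the REML H² estimate has a
sampling SD of ~0.085 (mean error under 0.01), so individual estimates
scatter well beyond ±0.05 at low heritability; only the mean over seeds is
a sharp check there.

## Kernels

Markers are QC'd (drop > 10% missing, drop monomorphic, mode-impute the
rest — at simulator missingness levels mode imputation is accuracy-neutral,
and the QC transformer stores training constants so new lines are
standardized consistently) and column-standardized. GB is K = XX′/p; GK is
K(i,i′) = exp(−h·d²_ii′) on squared Euclidean distances, which are divided
by their off-diagonal mean so one unitless bandwidth grid
{0.1, 0.25, 0.5, 0.75, 1, 1.5, 2, 3, 5} transfers across datasets. The
bandwidth is chosen by empirical Bayes: for each candidate h the marginal
likelihood of y = μ + u + e, u ~ N(0, σ²_u K(h)) is profiled over a
19-point grid on the genetic-variance fraction (the total variance has a
closed-form profile in the eigenbasis), and the evidence-maximizing h is
returned with ties broken toward smaller h. Kernels are PSD-checked and
repaired by diagonal jitter escalating tenfold from 1e-8 to 1e-4.

## Bayesian whole-genome regression

BayesA (per-marker scaled-inverse-χ² variances ⇒ scaled-t prior), BayesB
(spike-and-slab: exact zero with probability π₀, else the BayesA slab) and
the Bayesian LASSO (double-exponential via the exponential-mixture
augmentation, λ² with a diffuse Gamma hyper-prior), all as single-site
Gibbs samplers over markers with a running residual, compiled with numba.
Variance priors partition an assumed model R² of 0.5 between genetic and
residual variance with 5 prior degrees of freedom (configurable). The
short chain profile is 5 000 iterations / 1 000 burn-in / thinning 5; the
long profile (500 000 / 10 000 / 5) mirrors full-scale practice. Chains
are bit-reproducible for a fixed seed; convergence is monitored by a
Geweke z-score and effective sample size on the residual-variance chain,
and thinned variance chains are exportable.

BayesB's inclusion probability is estimated by default (Beta-Binomial
update with a uniform prior on the inclusion fraction, starting at
π₀ = 0.5, plus a conjugate Gamma update of the slab scale). This was a
deliberate design change after measurement: with π₀ fixed at 0.95 the
chain is trapped in a sparse configuration on dense polygenic traits and
loses ~0.1 of held-out predictive ability relative to the other four
methods, destroying the equivalence that holds empirically among
GB/GK/BayesA/BayesB/BL. `estimate_pi=False` restores a fixed π₀.

## Kernel GP, single- and multi-environment

All kernel models are Gibbs samplers in a rotated eigenbasis: writing a
genetic term u = L b with K = LL′ and taking the SVD of the observed-row
design U d T′, the rotated coefficients have an orthonormal design, so the
entire coefficient vector is drawn *jointly* in O(n) per iteration — no
per-iteration matrix factorizations. Lines (or cells) with masked
phenotypes are excluded from the likelihood but still predicted, which is
what CV1/CV2 need. Environment intercepts get flat priors (sampled as
per-environment means, reported as a grand mean plus centered contrasts);
variance components get scaled-inverse-χ² priors, df = 5, scales matching
an R² of 0.5 split equally among the genetic terms.

* **MM**: one genetic effect u₀ ~ N(0, σ²_u0 K) shared by all
  environments; equivalent (balanced data) to a single GP on per-line
  environment means.
* **MDs**: adds an interaction with covariance
  σ²_ue [Z_u K Z_u′] ∘ [Z_e Z_e′]. Because the second factor is the
  same-environment indicator, this Hadamard covariance is exactly one
  independent effect per environment sharing a single variance, which is
  how it is sampled — the N×N product matrix is never formed.
* **MDe**: per-environment deviations u_Ej ~ N(0, σ²_uEj K_j) with one
  variance per environment (block-diagonal K_E); K_j is the shared GB
  kernel or a per-environment Gaussian kernel whose bandwidth is estimated
  on that environment's training data only.

A caution established with an independent oracle (direct numerical
integration of the marginal posterior over a variance grid, genetic
effects marginalized analytically): with ~80 lines the per-environment
deviation variance is only weakly identified against iid noise — the null
posterior sits near 0.2 rather than 0 — and concentrates toward zero as
the population grows (~0.12 at 250 lines). Null-G×E recovery is therefore
a large-sample property, and the MDe variance table should be read
accordingly at small n. MDe also presumes positively correlated
environments (the shared main effect forces non-negative between-
environment covariance); with a strongly decorrelated environment the
model responds by inflating that environment's specific variance, which is
the diagnostic pattern rather than a failure.

## Training-set optimization

CD_mean, PEV and rScore all work from a kernel and the variance ratio
λ = σ²_e/σ²_g, which defaults to (1−h²)/h² with h² from a preliminary GB
fit. Contrasts are line-minus-population-mean; untargeted mode scores the
non-selected lines. PEV is reported in units of σ²_g = 1 (the context
carries only the ratio). rScore is realized as the kernel-block expected
accuracy sqrt(k′_jT (K_TT + λI)^(-1) k_Tj / k_jj); published estimators
differ in derivation, so cross-package values agree in ordering rather
than magnitude. The exchange optimizer is seeded-random-start,
first-improvement single swaps with a deterministic scan order (ties break
toward the lowest line index), stopping on a full pass without improvement.
Entry-to-nearest-entry maximizes the mean modified-Rogers distance
(f = dosage/2; bounded by 1/√2 for inbreds) of each selected entry to its
closest selected neighbor, by greedy max-min seeding plus swap refinement,
with support for forced inclusions (e.g. founders in a diverse core).

## Cross-validation and summaries

Random TP/VP partitions at a swept TP size (80–160 by default), LOO within
an optimized TP, and CV1/CV2 for multi-environment data at a 90/10 split:
CV1 masks all environments of the sampled lines; CV2 samples cells
stratified by environment with the guarantee that every masked line keeps
at least one observed environment (the exact protocol is under-determined
in the field; this stratified variant is documented as ours). Predictive
ability is the Pearson correlation (n−1 denominators) between GEBVs and
adjusted means at the validated cells, per environment for ME schemes,
summarized as mean ± SD over partitions; model pairs are compared with
Welch's unequal-variance t-test on the per-partition correlation samples.
PCA is centered SVD. LD decay uses squared allelic correlations between
within-chromosome marker pairs (DH dosage columns are haplotypes), an
association p-value from χ²(1) on n·r² (no canonical test exists; this is
the standard allelic χ²), a p ≤ 0.001 retention filter, and half-open
100-kb physical-distance bins averaged per chromosome plus a
pair-weighted genome-wide profile.

## Problem sizes

The default test and acceptance runs use desk-scale versions of the study
conditions chosen so every property is measured where it is statistically
identified: populations of 60–352 lines, 280–700 markers over 7
chromosomes, 3–4 environments, 20–30 CV partitions, and the short MCMC
profile; simulator invariants use 1 000 DH lines and 20 000–100 000
gametes. The acceptance script prints each quantity with the problem size
it was computed at.

## Known limitations

* EM-REML handles exactly the two random factors of the lattice model; it
  is not a general mixed-model engine.
* The Gibbs samplers assume homoscedastic residuals within and across
  environments.
* Small-n MDe variance tables overstate environment-specific variance
  under weak G×E (see above).
* The heuristic optimizers guarantee local optimality only; the
  entry-to-nearest-entry objective is non-submodular and the greedy+swap
  solution can be beaten by exhaustive search on adversarial instances.
* VCF support is a minimal GT-only reader/writer for biallelic SNPs.
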