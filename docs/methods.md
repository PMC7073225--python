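# Methods

`wheatgs` implements the analysis workflow of a genomic-selection study on a
diversity panel of inbred winter-wheat cultivars: marker quality control
(QC), diversity and linkage-disequilibrium (LD) statistics, empirical
imputation, seven genomic prediction models compared by replicated
cross-validation, multi-environment variance-component analysis, and
GWAS-derived marker selection feeding genomic selection. Because the
workflow is validated end to end on simulated data, the synthetic-panel
generator is a first-class, tested module, not a fixture.

## The trial model

Phenotypes follow a randomized complete block design repeated over
environments,

    y_ijk = mu + R_k(j) + G_i + E_j + GE_ij + eps_ijk,

with genotype i = 1..g, environment j = 1..e, replication k = 1..r nested in
environment, and eps ~ N(0, sigma_eps^2). `anova_components` computes the
exact balanced-layout sums of squares (an unbalanced layout falls back to a
sequential least-squares decomposition via statsmodels and is flagged).

Two moment estimators of the genetic variance are provided and both are
always reported:

* `estimator="ratio"` (default): sigma_G^2 = (MS_G − MS_eps)/(e·r), the form
  conventionally printed alongside this design. Under a generating model
  with genuine G×E variance it absorbs sigma_GE^2/e into sigma_G^2 (e.g., at
  components (1, 1, 1) and e = 3 it converges to 4/3, a +33% bias).
* `estimator="textbook"`: sigma_G^2 = (MS_G − MS_GE)/(e·r), the
  expected-mean-squares solution, unbiased under the generating model. All
  parameter-recovery tests and the acceptance script use this estimator; the
  ratio form is retained because published variance-component tables for
  this design are frequently computed with it, and surfacing both makes the
  discrepancy auditable instead of silently "fixing" it.

Negative moment estimates are truncated to zero and flagged. Heritability is
H2_plot = sG2/(sG2+sGE2+se2) and H2_mean = sG2/(sG2+sGE2/e+se2/(e·r)); e and
r are always taken from the data, never hard-coded.

Line-level adjusted means (BLUEs) come from the two-way fixed model
y = mu + G_i + E_j solved by least squares with a sum-to-zero environment
constraint; replication effects are pooled into the residual and G×E is
excluded (it is not estimable jointly with line effects for prediction
purposes). On balanced data the BLUE equals the raw line mean.

## Marker statistics and QC

Allele frequencies use observed calls only. For a biallelic locus with
frequencies p, q: gene diversity GD = 2pq and PIC = 2pq − 2p²q² (so
PIC ≤ GD always; both 0 at monomorphic loci).

The QC grid crosses five missing-rate levels (0, 20, 40, 60, 80%) with
three MAF levels (0, 5, 10%). Boundary semantics are strict — retain when
missing rate **<** level and MAF **>** level — with two deliberate
exceptions: the 0% missing level keeps only markers with no missing call,
and the 80% level is inclusive (≤ 0.80) because panels of this kind are
pre-cleaned of markers missing in more than 80% of lines, making the 80%
row the full panel. Counts over the grid are therefore monotone: rising
along missing levels, falling along MAF levels.

Redundancy binning groups markers whose call vectors and missing patterns
are byte-identical and keeps one representative (lowest missing rate, ties
by map order — within a group missing patterns are identical, so the rule
reduces to map order). The report lists every removed→representative pair
so the collapse is auditable.

Empirical imputation replaces each missing call with an independent draw
from that marker's observed genotype frequencies; it is seeded,
reproducible, preserves expected allele frequency, and refuses all-missing
markers (QC first).

LD is the squared Pearson correlation of genotype codes over co-observed
lines — appropriate for homozygous inbred panels, where genotype codes are
haplotypes; no haplotype-frequency EM is attempted (a non-goal, with
phasing and outbred-sample LD). Pairs are same-chromosome with known
positions, markers above 40% missing are excluded by default, and pairs
with fewer than 3 co-observed lines are skipped and counted. Distance-bin
edges for the decay summary are caller-supplied (default 0–1–10–100–1000
Mb), since there is no canonical windowing rule.

## The seven prediction models

All models regress the BLUE on the marker design and predict genomic
estimated breeding values (GEBVs). They are scikit-learn-style estimators
(fit/predict, `get_params`, fitted attributes with trailing underscores) so
they compose with sklearn tooling; `make_model(model_id)` maps the
conventional model names to classes.

* **RidgeReg** — beta = (X′X + λI)⁻¹X′y, intercept unpenalized. λ is not
  identified a priori, so when unsupplied it is chosen by inner 5-fold CV
  over 13 log-spaced candidates in m·[1e-3, 1e5].
* **GenInv** — the Moore–Penrose minimum-norm least-squares solution
  beta = (X′X)⁺X′y via SVD; singular values below rtol·σmax are zeroed
  (rtol = 1e-10 × max dimension).
* **BLUP** — the same ridge normal equations with plug-in shrinkage
  λ = m(1−h²)/h², h² supplied externally (e.g., the trial ANOVA H2_plot);
  default h² = 0.5 when none is given; falls back to REML when `h2=None`.
* **RRBLUP** — marker-effect mixed model y = 1μ + Zu + eps with
  u ~ N(0, K σu²), K = I by default (injectable); variance components by
  spectral REML (below); marker effects u = KZ′(ZKZ′ + δI)⁻¹(y − μ).
* **GBLUP** — line-level mixed model on a genomic relationship matrix
  (GRM); prediction for unobserved lines through the new-by-training
  G cross-block. Algebraically identical to RRBLUP when G ∝ ZZ′ and the
  variance ratio is matched — an equivalence the test suite asserts to
  1e-6 on random instances.
* **LASSO** — coordinate descent on (1/2n)‖y − Xβ‖² + λ‖β‖₁ with
  unpenalized intercept. Convergence: max coefficient change < 1e-7 per
  sweep, or an objective stall below 1e-13 relative (the floating-point
  floor on strongly collinear LD-block designs); full sweeps alternate with
  active-set sweeps. λ unsupplied → inner 5-fold CV on a geometric grid of
  15 values from λmax = max|X′(y−ȳ)|/n down to λmax/20 (smaller values are
  degenerate on m ≫ n marker designs and only slow the path); path fits use
  a relaxed 1e-4 tolerance since they only rank candidates, the final fit
  uses the strict one.
* **RForest** — a seeded regression forest: per tree a bootstrap sample of
  lines, variance-reduction splits over mtry random markers per node
  (vectorized exhaustive scan), growth stopped at min node size 5.
  Defaults: 500 trees, mtry = m/3 — standard regression-forest settings.
  sklearn's forest appears only as a test oracle for sanity ranges.

BLUP, RRBLUP and RidgeReg are deliberately three separately labelled
estimators that differ only in how the shrinkage is set (plug-in / REML /
inner CV): studies report different accuracies for the three names, which
is only possible if their hyperparameterizations differ.

**Design.** `build_design` codes genotypes (default: centered 0/1/2;
raw and centered-scaled available), marker-mean fills any missing calls
that survive QC un-imputed (the fill count is logged so imputed vs
non-imputed comparisons stay meaningful), and drops constant markers.

**GRM.** VanRaden's G = WW′/(2Σp(1−p)) on the centered matrix, with 1e-8
added to the diagonal. The denominator targets Hardy–Weinberg genotype
variance, so the mean diagonal is ≈1 for outbred HW-like panels and ≈2 for
fully inbred ones; the REML heritability ratio reported by GBLUP multiplies
σu² by the mean diagonal of G so it estimates h² on either panel type.

**Spectral REML.** For y = Xb + u + eps, u ~ N(0, Kσu²): one
eigendecomposition of the covariate-projected kernel, then the profiled
restricted likelihood in δ = σe²/σu² maximized by bounded scalar search on
log10 δ ∈ [−8, 8] to 1e-8. Exact and fast at panel scale (one
decomposition per CV fold).

## GWAS and marker selection

The scan fits the PCA + K null model — intercept, the first 5 principal
components of the centered mean-filled genotype matrix, and a polygenic
effect with GRM covariance — once by REML, then tests every marker by
generalized least squares with the null variance structure held fixed (the
population-parameters-previously-determined / EMMAX approximation; exact
per-marker REML would be ~m times slower for no material gain at this
scale). P-values are two-sided Wald with n − p − 1 degrees of freedom.
Markers with unknown physical position are excluded before scanning;
constant markers are skipped and logged.

Selection keeps markers at −log10 P ≥ 1 — deliberately permissive so
small-effect loci are not lost; under the null this admits ~10% of markers,
which the calibration tests confirm.

`gwas_derived_gs` reproduces the single-population design in which the scan
uses the **whole panel** (training and validation lines) before
cross-validation. This leaks phenotype information into marker selection
and inflates apparent accuracy; it is the default for fidelity to how such
studies are run, every result carries a `full-panel` scenario tag, and a
leakage-free alternative (re-scan inside each training fold,
`per_fold=True`) is provided. The null-guard test shows the per-fold route
stays at ~0 accuracy on pure-noise traits while the full-panel route does
not — which is exactly the point of labelling it.

## Cross-validation

Five folds, 50 replicates by default. Per replicate a seeded partition
assigns every line to exactly one validation fold (sizes differ by ≤1);
models are trained on the training folds only, including all hyperparameter
selection; accuracy is the Pearson correlation of BLUEs and GEBVs in the
validation fold, averaged over folds (per-fold pooling; the pooled-
across-folds alternative is a flag since the choice measurably shifts
values). Undefined correlations (constant predictions) count as 0 and are
flagged, keeping replicate vectors equal length for t-tests. The reported
SE is the standard error over replicate accuracies, and mean/SE are always
recomputable from the stored replicate vectors. QC-vs-non-QC contrasts use
Welch's unequal-variance t-test on the replicate vectors.

Seed policy: a master seed spawns per-replicate `SeedSequence` children for
partitions, and model-level stochastic seeds (forest bootstraps) derive from
the replicate stream — a rerun with the same master seed is byte-identical.

## The synthetic panel generator

Defaults mirror the scale of a 166-line Chinese winter-wheat diversity
panel: 6,000 markers on 21 chromosomes, e = 3 environments × r = 3
replications, per-marker missing rates Beta-distributed with mean ≈ 0.28
capped at 0.80, an allele-frequency spectrum (Beta(0.5, 2)) skewed toward
rare alleles, a 2% monomorphic fraction, and six traits whose variance
targets span the architecture range of a wheat yield trial (grain yield
G×E-dominated, heading days environment-dominated, plant height and kernel
weight strongly genetic).

Lines are fully inbred by default (codes 0/2; a heterozygosity-rate knob
exists and defaults to 0). LD is induced by an allele-copy chain: markers in
a block share one allele frequency, and each marker after the first copies
the previous marker's allele per line with probability rho
(`ld_within_block_corr`), else redraws. This makes the adjacent within-block
genotype correlation exactly rho in expectation regardless of allele
frequency (so adjacent r² ≈ rho²) with a geometric rho^k decay in marker
lag — one parameter, exact control. A latent-Gaussian-threshold construction
was considered and rejected because thresholding shrinks the binary
correlation below the latent one (at p = 0.5, to 2·arcsin(rho)/π), making
the r² level frequency-dependent and uncontrollable.

Missingness is completely at random per marker (no informative-missingness
mechanism is modelled). Phenotypes are generated from the trial model above:
additive QTL effects at a random polymorphic subset, rescaled so the panel
genetic variance hits the sigma_G^2 target exactly; environment, G×E,
replication and residual effects are independent normals at their targets.
The truth record stores QTL ids, rescaled effects and true breeding values
(centered-code weighted sums).

What the generator does **not** emulate: selection and pedigree structure,
dominance and epistasis, genotyping-error models, informative missingness,
allele-frequency/LD gradients along chromosomes, and population
substructure (beyond what block LD induces). Tests passing on this
generator therefore validate the estimators and the pipeline logic, not
robustness to structure confounding or non-additive architecture in real
panels.

## Problem sizes and numerical choices

Simulation studies in the test suite and the acceptance script run at
reduced sizes chosen as the package's own desk-scale defaults: variance-
component recovery at the full trial scale (166 × 3 × 3, 100 trials; the
ANOVA is cheap), REML recovery at n = 500, null-calibration CV at 250 lines
× 200 markers with 20 fresh permutations per model (fresh permutations per
replicate, because with a single fixed permutation the replicate accuracies
are strongly dependent and their mean does not concentrate), GWAS null
calibration at 166 × 2,000, and the directional CV studies at 120–140 lines
with 250–600 markers, 3–5 replicates, 50–80 forest trees. Degenerate cases
are handled explicitly: all-missing markers are flagged and excluded,
empty QC results warn and downstream fitting refuses them, constant traits
and constant predictions are flagged rather than propagating NaNs, and
negative variance estimates truncate to zero with a flag.

## Known limitations

* The GWAS effect sizes are GLS estimates under a fixed null variance
  structure; they are slightly conservative for very large effects (the
  usual P3D trade-off).
* BLUEs assume a connected line-by-environment incidence; disconnected
  designs error rather than reporting within-component estimates.
* The BLUP plug-in heritability defaults to 0.5 when no ANOVA estimate is
  supplied; its accuracy ranking relative to RRBLUP/RidgeReg depends on how
  good that plug-in is.
* Single-trait, single-population prediction only: no multi-trait, G×E
  prediction models, Bayesian-alphabet or kernel methods (non-goals).
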